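# Methods

`protsip` implements the computational core of a proteomic stable-isotope-
probing (SIP) experiment in which a microbial community is fed ¹⁵NH₄⁺ and
newly synthesised proteins are recognised by the elevated ¹⁵N content of
their tryptic peptides.  This note records the models, the numerical
choices, and what the synthetic benchmark does and does not demonstrate.

## Isotopologue model

A peptide's isotopologue distribution is computed on a *neutron-excess
lattice*: isotopologues are binned by total neutron count above the
all-lightest species, and the mass reported for a lattice index is the
abundance-weighted mean mass of the isotopologues in that bin.  At the
tolerances of the search (0.05 Da precursor, 0.02 Da fragment) this
aggregation is indistinguishable from fine structure for tryptic peptides.

Nitrogen is the only isotopically variable element: the ¹⁵N atom fraction
θ ∈ [0, 1] is a free parameter, applied uniformly to every nitrogen atom
(the labelling substrate is ¹⁵NH₄⁺ only).  C, H, O and S stay at fixed
natural abundance (¹³C 1.07%, ²H 0.0115%, ¹⁷O 0.038%, ¹⁸O 0.205%, ³³S
0.75%, ³⁴S 4.25%, ³⁶S 0.01%; the leading isotope of each element carries the
complement so every element's abundances sum to exactly 1).  Cysteine is
left unmodified — no fixed carbamidomethylation is assumed — with a
fixed-modification hook available in `peptide_composition`.

Because the CHOS part of the lattice is θ-independent and the nitrogen part
is a binomial that depends only on (n, θ), the distribution factorises as
`conv(CHOS lattice, Binomial(n, θ))`.  The search exploits this: binomial
row matrices are cached per grid θ, and the per-peptide work at each grid
point reduces to a short shifted-add convolution plus an argmax.  Lattices
are truncated at relative abundance 1e-10 and renormalised; the truncation
error is orders of magnitude below the fragment tolerance.

Two properties of the "most abundant mass" are worth stating because tests
rely on them:

* it is computed on the **neutral** mass scale and converted to m/z as
  (neutral + z·1.007276)/z;
* it is *non-decreasing in θ only up to a few mDa*: within a fixed neutron
  index the isotopologue mix shifts from ¹³C-containing (+1.00336 Da per
  index) toward ¹⁵N-containing (+0.99703 Da) species as θ grows, which can
  lower the index's mean mass slightly.  The net shift from θ=0 to θ=1 is
  n × 0.99703 Da exactly.

## Database and digestion

Proteins are deduplicated at 100% sequence identity, then reversed to make
decoys (`REV_` prefix) and digested in silico with trypsin: cleavage after
K/R except before P, up to 2 missed cleavages, peptide length 6–53 residues
(the bounds of detectable tryptic peptides; all configurable).  I and L are
distinct characters.  Identical peptide strings are merged with the union of
their parent proteins; peptides found in both a target and a decoy
(palindromic stretches) are flagged ambiguous and excluded from FDR
bookkeeping.

## Search

For each MS/MS spectrum, every atom% on the 0–100 grid (1% steps) is
evaluated.  A peptide (or PTM variant) is a candidate at a grid θ when its
most-abundant neutral mass lies within ±0.05 Da of one of **seven windows**
at the observed neutral parent mass offset by −3..+3 × 1.00335 Da: the
most-abundant peak of a ¹⁵N-shifted envelope can sit several isotopologue
indices from the selected precursor peak.

The score is this package's own surrogate (the original engine's formula is
not public): `total = fragment_fit + mass_accuracy`, where

* **fragment_fit ∈ [0, 1]** — theoretical b/y ions (1+, and 2+ when the
  precursor charge allows) match their nearest observed peak within 0.02 Da,
  each ion to at most one peak; a matched ion contributes the peak's linear
  intensity-rank weight scaled by (1 − |mass error|/tolerance); the sum is
  divided by the best sum achievable with that many ions.  Rank-based
  weighting makes the score invariant to peak permutation and uniform
  intensity scaling.
* **mass_accuracy ∈ [0, 1]** — 1 − |precursor error|/tolerance against the
  nearest of the seven window centres.

The single best (peptide, PTM assignment, θ) across the grid wins; exact
ties break toward lower θ, fewer PTMs, then the lexicographically smaller
peptide.  Totals are quantised to 1e-9 before comparison: candidates at
nearby θ often predict *mathematically identical* spectra (the isotopologue
mode does not move), and without quantisation floating-point noise rather
than the tie rule would pick among them.  All downstream guarantees rest on
ranking behaviour — round-trip atom% recovery and FDR control — not on
absolute score values.

The atom% resolution of this design is fundamentally n-limited: the
isotopologue mode of a peptide with n nitrogens moves only at θ steps of
about 100/(n+1) atom%, so low enrichments are not resolvable on short
peptides (a 0.5 atom% peptide with n ≤ ~15 is indistinguishable from 0–2
atom% and is reported at the lowest tying grid point).  This does not affect
the 5% enrichment demarcation for the bimodal data the method targets, and
mirrors the workflow's own caveat that its binomial detection limit for
short peptides is optimistic.

Dynamic PTMs are searched as residue-specific monoisotopic mass deltas (up
to 2 per peptide, one per position), with the Mcr-analysis modification list
shipped as a preset (`MCRA_PTM_SET`); the default PTM set is empty because
the modification search belongs to a focused ortholog analysis, not the
community-wide run.  PTM deltas are applied as pure mass offsets — the atoms
they add are not folded into the isotopologue lattice.  For the listed
modifications the resulting error in the predicted most-abundant mass is
well under the fragment tolerance; N-adding modifications (S-nitrosylation,
nitration) additionally ignore one labelled position, a known approximation.

## FDR filtering and protein inference

Peptide-level rollup keeps the best PSM per (peptide, PTM assignment); the
concatenated-database estimator FDR = 2D/(T+D) is evaluated down the
score-sorted list and the largest prefix within the level (default 1%) is
accepted; decoys count toward the estimate but are never reported.
Equal-scored records enter or leave the accepted set together.

Protein inference is parsimony: proteins with identical accepted-peptide
evidence collapse into groups, and the smallest set of groups explaining
every accepted peptide is selected — by exhaustive search when there are at
most 18 groups (greedy set cover can miss the optimum by one even on tiny
instances), greedily above that.  Reporting criteria [1%, 1TP, 1UP] and
[1%, 2TP, 1UP] are applied to the selected groups; "total peptides" counts
distinct sequences (not spectra), and a peptide is "unique" when all of its
parents lie within one group.

## Enrichment calling

Three rules classify a peptide with grid estimate θ̂ (atom%):

* **fixed** — θ̂ ≥ 5 atom% (the demarcation separating the bimodal pools);
  the boundary is inclusive.
* **empirical** — θ̂ ≥ the 99th nearest-rank percentile of an unlabelled
  control run's θ̂ values, rounded up to the 1% grid (a 1% false-call rate
  against the control distribution; the control-mean baseline presets are
  0.45%, 0.35% and 0.49%).
* **binomial** — per-peptide: θ̂ ≥ 100·k*/n where k* is the smallest ¹⁵N
  count with P(X ≥ k* | n, p₀) < α under natural incorporation
  (p₀ default 0.0049, α default 0.01; exact tail, no approximation).  The
  threshold falls with peptide length over decades of n but is a sawtooth
  locally, since k* is an integer.

A protein group is enriched when any of its accepted peptides is.  Pool
summaries report the mean atom% and the percentage of enriched peptides;
histogram modes (1 atom% bins) are reported separately below and at/above
the demarcation.

## Bin contrasts

Within the enriched and unenriched protein pools, per-bin relative
abundances are computed as protein-group counts (peptide-count weighting is
available; the choice of unit is a documented convention, group counts being
the most conservative).  Each bin contributes the squared difference of its
two relative abundances; contributions are reported as fractions of the
total with the sign of (enriched − unenriched) indicating direction, and
bins contributing at least 1% are summarised with their cumulative share.

## Synthetic data generator

The generator emulates the study conditions end to end and writes a truth
ledger sufficient to compute true false-discovery proportions and atom%
recovery errors:

* proteins: random residue strings (K+R ≈ 9.3%, P 4%, tuned so tryptic
  peptides average ~8–25 residues), lengths uniform on 80–300, taxonomy and
  function bins drawn from methane-seep-flavoured label sets;
* a fixed fraction of proteins (default 0.3) is planted as newly
  synthesised; their peptides draw a true θ from Normal(49, 3) atom%
  truncated to [1, 100], while pre-existing proteins sit at the natural
  baseline (0.5 atom%) — the bimodal structure the method targets, with an
  alternate preset at 64 atom% for the second labelled sample;
* spectra: charge 2+ by default; the precursor is reported exactly at the
  most-abundant isotopologue of the generating peptide at its true θ (an
  optional Gaussian precursor error is off by default); fragments are the
  b/y most-abundant m/z (1+ and 2+) with 15% dropout, Gaussian m/z jitter
  (σ = 0.006 Da, below a third of the fragment tolerance) and 1/rank
  intensities under multiplicative lognormal noise; 15 uniform noise peaks
  per scan; peaks closer than 1 mDa are merged as a centroider would
  (coincident b/y ions otherwise create duplicate peaks no instrument
  produces).

All randomness flows from one integer seed; reruns are byte-identical.

What passing tests on this generator do **not** show: real chromatography
and acquisition effects (chimeric spectra, dynamic exclusion, charge-state
errors, calibration drift), real protein homology structure (shared-peptide
networks here arise only by chance), semi-tryptic or modified backgrounds,
and instrument-specific noise physics.  FDR control and recovery results on
synthetic data are necessary, not sufficient, evidence for real-data
performance.

## Benchmark problem sizes

The standard benchmark is 300 proteins / 2000 spectra / 30% labelled
(seed-controlled), on which the accepted set's decoy-estimated FDR and
true false-discovery proportion are both ~0 and the planted enriched
fraction is recovered within ±3 points.  Bimodal-mode recovery uses 120
proteins / 2000 spectra at enriched_fraction 0.5 so the enriched pool holds
~900 peptides: the mode of ~600 draws from Normal(49, 3) fluctuates over
±2 bins by sampling noise alone, and the larger pool makes the 49 ± 1
check a property of the method rather than of one seed.  Smaller sizes used
in unit tests are noted in the tests themselves.

## Known limitations

* The score is a surrogate; absolute values are not comparable to other
  engines.
* Atom% resolution degrades as ~100/(n+1) for short peptides (above).
* The empirical-threshold rule needs ≥ 20 control peptides and reports
  integer atom% only.
* Protein-level FDR is out of scope; the criteria-based reporting
  ([1TP/2TP, 1UP]) is the only protein-level filter.
* FDR is estimated per run; multi-run joint filtering is not implemented.
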