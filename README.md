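# protsip

Proteomic stable-isotope-probing (SIP) analysis for ¹⁵N-labelled
metaproteomes: a grid search of MS/MS spectra over ¹⁵N atom%, target/decoy
FDR filtering, parsimony protein inference, enrichment thresholding, and
enriched-vs-unenriched bin contrasts — with a ground-truth spectrum
simulator so every stage is testable without instrument data.

## The problem

In a proteomic SIP experiment a microbial community (here, methane-seep
sediment dominated by anaerobic methanotrophic archaea and their
sulfate-reducing partners) is incubated with ¹⁵NH₄⁺.  Proteins synthesised
during the incubation incorporate ¹⁵N far above natural abundance
(~0.4 atom%), so the ¹⁵N content of identified peptides separates newly
made proteins from pre-existing ones.  The computational task is twofold:

1. **Identify peptides whose isotopic composition is unknown.**  For each
   candidate peptide the most abundant isotopologue mass of its b/y
   fragments is predicted at every ¹⁵N atom% θ from 0 to 100% in 1% steps
   (assuming uniform labelling), and each spectrum is matched against
   candidates whose precursor mass falls within seven windows at the
   observed parent mass offset by −3..+3 average neutron spacings.
   Candidates are scored on b/y fragment fit plus precursor mass accuracy;
   the best (peptide, θ̂) per spectrum survives 1% peptide-level FDR
   filtering against a reversed-sequence decoy database
   (FDR = 2D/(T+D)), and proteins are inferred by parsimony under the
   [1%, 1TP, 1UP] and [1%, 2TP, 1UP] reporting criteria.

2. **Decide which peptides are enriched.**  Either empirically — the 99th
   percentile of an unlabelled control run sets the threshold — or from the
   binomial model of natural incorporation: a peptide with n nitrogen atoms
   contains k ¹⁵N with probability C(n,k) p₀ᵏ (1−p₀)ⁿ⁻ᵏ at baseline
   frequency p₀, and the smallest k whose tail probability drops below 1%
   defines the minimum detectable atom% 100·k*/n.  A fixed 5 atom%
   demarcation separates the two pools of the bimodal atom% distribution
   (unenriched near 0, enriched peaked near 49 atom%).  Functional and
   taxonomic structure of the enriched pool is summarised by the squared
   difference of per-bin relative abundances between pools.

## Worked example

```python
from protsip import binom_pmf, atom_percent, min_detectable_enrichment

# a 53-residue tryptic peptide carries ~70 nitrogen atoms; at the control
# baseline of 0.49 atom%, how likely is natural 15N incorporation?
n, p0 = 70, 0.0049
for k in (1, 2, 3):
    print(f"k={k}: P = {100*binom_pmf(n, k, p0):5.2f}%  "
          f"atom% = {atom_percent(k, n):.2f}")
print(f"min detectable: {min_detectable_enrichment(n, p0, alpha=0.01):.2f} atom%")
```

prints

```
k=1: P = 24.44%  atom% = 1.43
k=2: P =  4.15%  atom% = 2.86
k=3: P =  0.46%  atom% = 4.29
min detectable: 4.29 atom%
```

i.e. one ¹⁵N atom in a long peptide is common (24%) but represents only
1.43 atom%; the chance of three or more atoms is already below 1%, so for
this peptide 4.29 atom% (k* = 3) is the smallest enrichment distinguishable
from natural abundance at the 1% level — just under the fixed 5 atom%
demarcation.

Running the full pipeline on a simulated two-arm experiment:

```bash
protsip report --out run/ --seed 17
```

```
peptides accepted: 1998; mean atom% 14.2; 28.6% enriched; proteins [1TP,1UP]: 299, [2TP,1UP]: 293
```

With 30% of the 300 simulated proteins planted as newly synthesised at a
49 atom% peak, the search recovers 28.6% enriched peptides (within
sampling noise of the planted fraction), a bimodal atom% histogram
(`run/histogram.csv`), protein reports under both criteria, and
taxonomy/function bin contrasts (`run/bin_contrasts_*.tsv`).  The decoy
FDR of the accepted set and every threshold applied are recorded in
`run/manifest.json`.

The library surface mirrors the stages: `isotope_model` (compositions and
isotopologue lattices), `database` (FASTA → target/decoy tryptic search
space), `sip_search` (grid search and scoring), `identification` (FDR and
parsimony), `enrichment_stats` (thresholds and pool summaries),
`bin_contrasts` (variance partitioning), `synthetic_data` (the generator and
truth ledger), `pipeline` (orchestration).  See `docs/methods.md` for the
models, defaults and their rationale.

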