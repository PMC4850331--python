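"""¹⁵N-grid spectral search.

Each MS/MS spectrum is matched against the target/decoy peptide search space
at every ¹⁵N atom% on a 0-100% grid (1% steps).  A peptide is a candidate at
a given atom% when its most-abundant isotopologue mass falls inside one of
seven precursor windows centred at the observed neutral parent mass and
offset by -3..+3 average neutron spacings (the most-abundant peak of a
¹⁵N-shifted envelope can sit several isotopologue indices away from the
selected precursor peak).  Candidates are scored by b/y fragment fit plus
precursor mass accuracy, and the single best (peptide, PTM variant, atom%)
across the whole grid is reported per spectrum.

The score formula is this package's own explicit surrogate: downstream
guarantees rest on its ranking behaviour (round-trip atom% recovery and
target/decoy FDR control), not on absolute score values.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .database import PeptideEntry
from .isotope_model import (
    NEUTRON_SPACING,
    PROTON_MASS,
    WATER,
    LatticeEngine,
    chos_lattice,
    peptide_chos_prefix_lattices,
    peptide_composition,
    _convolve_moment,
    _trim,
)

# --------------------------------------------------------------------------
# Spectra
# --------------------------------------------------------------------------


@dataclass
class Spectrum:
    """A centroided MS/MS scan: precursor m/z + charge and a sorted peak list."""

    id: str
    precursor_mz: float
    charge: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def neutral_mass(self) -> float:
        """Observed neutral parent mass, (m/z - proton) * z."""
        return (self.precursor_mz - PROTON_MASS) * self.charge


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read centroided spectra from an MGF peak list."""
    spectra = []
    with _mgf.read(str(path), convert_arrays=1, use_index=False) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            charge = int(params["charge"][0]) if "charge" in params else 2
            spectra.append(
                Spectrum(
                    id=str(params.get("title", f"scan={i}")),
                    precursor_mz=float(params["pepmass"][0]),
                    charge=charge,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF with fixed-precision formatting (byte-stable)."""
    with open(path, "w") as fh:
        for sp in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={sp.id}\n")
            fh.write(f"PEPMASS={sp.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={sp.charge}+\n")
            for mz, inten in zip(sp.mz, sp.intensity):
                fh.write(f"{mz:.5f} {inten:.2f}\n")
            fh.write("END IONS\n")


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PTMSpec:
    """A dynamic modification: a mass delta applicable to a set of residues."""

    name: str
    target_residues: frozenset[str]
    mass_delta: float

    def __post_init__(self) -> None:
        if self.mass_delta == 0:
            raise ValueError("PTM mass delta must be non-zero")
        if not self.target_residues:
            raise ValueError("PTM must target at least one residue")


def _ptm(name: str, residues: str, delta: float) -> PTMSpec:
    return PTMSpec(name, frozenset(residues), delta)


#: the dynamic modification list used for the Mcr ortholog analysis
#: (Unimod monoisotopic deltas)
MCRA_PTM_SET: tuple[PTMSpec, ...] = (
    _ptm("hydroxylation", "PK", 15.994915),
    _ptm("monomethylation", "RKDE", 14.015650),
    _ptm("dimethylation", "RK", 28.031300),
    _ptm("trimethylation", "K", 42.046950),
    _ptm("phosphorylation", "STYHD", 79.966331),
    _ptm("acetylation", "K", 42.010565),
    _ptm("s-nitrosylation", "C", 28.990164),
    _ptm("nitration", "Y", 44.985078),
    _ptm("methylthiolation", "D", 45.987721),
)


@dataclass(frozen=True)
class SearchConfig:
    """Search tolerances and grid (Orbitrap-profile defaults)."""

    precursor_tol: float = 0.05  # Da
    fragment_tol: float = 0.02  # Da
    theta_grid: tuple[int, ...] = tuple(range(0, 101))  # atom% values
    window_offsets: tuple[int, ...] = (-3, -2, -1, 0, 1, 2, 3)
    neutron_spacing: float = NEUTRON_SPACING
    ptm_set: tuple[PTMSpec, ...] = ()
    max_ptms_per_peptide: int = 2

    def __post_init__(self) -> None:
        if self.precursor_tol <= 0 or self.fragment_tol <= 0:
            raise ValueError("tolerances must be positive")
        if len(self.window_offsets) != 7:
            raise ValueError("exactly seven precursor windows are required")
        if min(self.theta_grid) != 0 or max(self.theta_grid) != 100:
            raise ValueError("theta grid must cover 0..100 atom%")


#: low-resolution (linear ion trap) tolerance preset
LTQ_CONFIG = SearchConfig(precursor_tol=3.0, fragment_tol=0.5)


@dataclass(frozen=True)
class PSM:
    """A peptide-spectrum match at the best grid atom%."""

    spectrum_id: str
    peptide: str
    ptm_assignment: tuple[tuple[int, str, float], ...]  # (1-based pos, name, delta)
    theta_hat: float  # atom%
    score: float
    fragment_fit: float
    mass_accuracy: float
    precursor_error: float  # Da, vs nearest window centre
    matched_fragments: int
    is_decoy: bool
    is_ambiguous: bool = False
    n_nitrogen: int = 0


# --------------------------------------------------------------------------
# Precursor windows
# --------------------------------------------------------------------------


def precursor_windows(neutral_mass: float, config: SearchConfig) -> list[tuple[float, float]]:
    """The seven precursor intervals around a neutral parent mass.

    Centres sit at ``neutral_mass + k * neutron_spacing`` for the seven
    configured offsets; each interval has half-width ``precursor_tol``.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    tol = config.precursor_tol
    centers = sorted(neutral_mass + k * config.neutron_spacing for k in config.window_offsets)
    return [(c - tol, c + tol) for c in centers]


# --------------------------------------------------------------------------
# PTM variant enumeration
# --------------------------------------------------------------------------


def enumerate_ptm_variants(
    sequence: str, config: SearchConfig
) -> list[tuple[tuple[int, str, float], ...]]:
    """All PTM assignments of a peptide: the unmodified form plus every
    combination of up to ``max_ptms_per_peptide`` site-specific mods with at
    most one modification per residue position."""
    variants: list[tuple[tuple[int, str, float], ...]] = [()]
    if not config.ptm_set:
        return variants
    site_mods: list[tuple[int, str, float]] = []
    for pos, aa in enumerate(sequence, start=1):
        for ptm in config.ptm_set:
            if aa in ptm.target_residues:
                site_mods.append((pos, ptm.name, ptm.mass_delta))
    for k in range(1, config.max_ptms_per_peptide + 1):
        for combo in itertools.combinations(site_mods, k):
            if len({c[0] for c in combo}) == k:  # one mod per position
                variants.append(combo)
    return variants


# --------------------------------------------------------------------------
# Search index: per-theta most-abundant precursor masses
# --------------------------------------------------------------------------


class SearchIndex:
    """Precomputed most-abundant precursor masses of every search-space
    entry (and PTM variant) at every grid atom%, sorted for window lookup."""

    def __init__(
        self,
        search_space: dict[str, PeptideEntry],
        config: SearchConfig,
        engine: LatticeEngine | None = None,
    ):
        self.config = config
        self.entries: list[PeptideEntry] = [search_space[k] for k in sorted(search_space)]
        self.engine = engine or LatticeEngine()

        chos_parts = [
            chos_lattice(peptide_composition(e.sequence)) for e in self.entries
        ]
        n_counts = np.array([e.n_nitrogen for e in self.entries], dtype=np.int64)

        # PTM variants as parallel arrays over a flat variant axis
        var_entry: list[int] = []
        var_ptms: list[tuple[tuple[int, str, float], ...]] = []
        var_delta: list[float] = []
        for i, e in enumerate(self.entries):
            for assignment in enumerate_ptm_variants(e.sequence, config):
                var_entry.append(i)
                var_ptms.append(assignment)
                var_delta.append(sum(p[2] for p in assignment))
        self.var_entry = np.array(var_entry, dtype=np.int64)
        self.var_ptms = var_ptms
        self.var_delta = var_delta_arr = np.array(var_delta)

        # masses[t, v]: most-abundant neutral mass of variant v at grid theta t.
        # Entries are bucketed by nitrogen count so the binomial width (and
        # the lattice padding) of each bucket stays tight.
        self._sorted_masses: list[np.ndarray] = []
        self._sorted_order: list[np.ndarray] = []
        self.base_masses = np.zeros((len(config.theta_grid), len(self.entries)))
        buckets = []
        if self.entries:
            for g in np.array_split(np.argsort(n_counts, kind="stable"), 6):
                if len(g):
                    F, Fm = LatticeEngine.pack_parts([chos_parts[i] for i in g])
                    buckets.append((F, Fm, n_counts[g], g))
        for t, theta_pct in enumerate(config.theta_grid):
            base = np.zeros(len(self.entries))
            for F, Fm, ng, g in buckets:
                base[g] = self.engine.most_abundant_packed(F, Fm, ng, theta_pct / 100.0)
            self.base_masses[t] = base
            masses = base[self.var_entry] + var_delta_arr
            order = np.argsort(masses, kind="stable")
            self._sorted_masses.append(masses[order])
            self._sorted_order.append(order.astype(np.int64))

    def theta_index(self, theta_pct: float) -> int:
        try:
            return self.config.theta_grid.index(round(theta_pct))
        except ValueError:
            raise ValueError(f"theta {theta_pct} not on the grid") from None

    def candidates_at(self, observed_neutral: float, theta_pct: float) -> np.ndarray:
        """Flat variant indices whose most-abundant mass at ``theta_pct``
        falls inside any of the seven windows around the observed mass."""
        t = self.theta_index(theta_pct)
        masses = self._sorted_masses[t]
        order = self._sorted_order[t]
        tol = self.config.precursor_tol
        hits: list[np.ndarray] = []
        for k in self.config.window_offsets:
            center = observed_neutral + k * self.config.neutron_spacing
            lo = np.searchsorted(masses, center - tol, side="left")
            hi = np.searchsorted(masses, center + tol, side="right")
            if hi > lo:
                hits.append(order[lo:hi])
        if not hits:
            return np.zeros(0, dtype=np.int64)
        return np.unique(np.concatenate(hits))


def generate_candidates(
    spectrum: Spectrum, index: SearchIndex, theta_pct: float
) -> list[tuple[PeptideEntry, tuple[tuple[int, str, float], ...]]]:
    """(peptide entry, PTM assignment) pairs passing the window test at one
    grid atom% for one spectrum."""
    out = []
    for v in index.candidates_at(spectrum.neutral_mass, theta_pct):
        out.append((index.entries[index.var_entry[v]], index.var_ptms[v]))
    return out


# --------------------------------------------------------------------------
# Fragment ladders and scoring
# --------------------------------------------------------------------------

_WATER_LATTICE = None


def _water_lattice():
    global _WATER_LATTICE
    if _WATER_LATTICE is None:
        _WATER_LATTICE = chos_lattice(WATER)
    return _WATER_LATTICE


@functools.lru_cache(maxsize=32768)
def _ladder_lattices(sequence: str):
    """Packed CHOS lattices + nitrogen counts of all b/y fragments.

    Returns (F, Fm, n_counts, labels): padded probability and mass-moment
    row matrices over the 2(L-1) fragments, their nitrogen counts, and
    labels[i] = (ion_type, index).  b fragments are residue prefixes; y
    fragments are residue suffixes plus one water.
    """
    L = len(sequence)
    b_parts, b_n = peptide_chos_prefix_lattices(sequence)
    rev_parts, rev_n = peptide_chos_prefix_lattices(sequence[::-1])
    water = _water_lattice()
    parts = []
    n_counts = []
    labels = []
    for i in range(1, L):  # b_1 .. b_{L-1}
        parts.append(b_parts[i - 1])
        n_counts.append(int(b_n[i - 1]))
        labels.append(("b", i))
    for j in range(1, L):  # y_1 .. y_{L-1}
        p, m = _trim(*_convolve_moment(rev_parts[j - 1], water), 1e-9)
        parts.append((p, m))
        n_counts.append(int(rev_n[j - 1]))
        labels.append(("y", j))
    F, Fm = LatticeEngine.pack_parts(parts)
    return F, Fm, np.array(n_counts, dtype=np.int64), tuple(labels)


def fragment_neutral_masses(
    sequence: str,
    theta: float,
    engine: LatticeEngine,
    ptm_assignment: tuple[tuple[int, str, float], ...] = (),
) -> tuple[np.ndarray, tuple[tuple[str, int], ...]]:
    """Most-abundant neutral masses of all b/y fragments at atom fraction
    theta, with PTM deltas folded into the fragments containing each site."""
    F, Fm, n_counts, labels = _ladder_lattices(sequence)
    masses = engine.most_abundant_packed(F, Fm, n_counts, theta)
    if ptm_assignment:
        masses = _apply_ptm_deltas(masses, labels, len(sequence), ptm_assignment)
    return masses, labels


def _apply_ptm_deltas(masses, labels, L, ptm_assignment):
    masses = masses.copy()
    for idx, (ion, i) in enumerate(labels):
        for pos, _name, delta in ptm_assignment:
            if (ion == "b" and pos <= i) or (ion == "y" and pos > L - i):
                masses[idx] += delta
    return masses


@dataclass(frozen=True)
class ScoreComponents:
    fragment_fit: float
    mass_accuracy: float
    total: float
    matched_fragments: int
    precursor_error: float
    empty_spectrum: bool = False


def _rank_weights(intensity: np.ndarray) -> np.ndarray:
    """Linear intensity-rank weights: the most intense of N peaks weighs 1,
    the least intense 1/N.  Rank-based, so uniform intensity rescaling and
    peak-list permutation leave scores unchanged."""
    n = len(intensity)
    rank = np.empty(n, dtype=np.int64)
    rank[np.argsort(-intensity, kind="stable")] = np.arange(1, n + 1)
    return (n - rank + 1) / n


def _score_candidates(
    spectrum: Spectrum,
    sequences: Sequence[str],
    ptms_list: Sequence[tuple],
    theta_pcts: np.ndarray,
    theo_precursors: np.ndarray,
    config: SearchConfig,
    engine: LatticeEngine,
) -> list[ScoreComponents]:
    """Score a batch of candidates against one spectrum (single code path
    for the public per-candidate scorer and the grid search).

    fragment_fit in [0, 1]: each theoretical b/y ion (charges 1+, plus 2+
    when the precursor charge allows) matches its nearest observed peak when
    within the fragment tolerance; a matched ion contributes the peak's
    intensity-rank weight scaled by (1 - |mass error| / tolerance); the sum
    is divided by the best sum achievable with that many ions (all matched,
    zero error).  mass_accuracy in [0, 1]: 1 - |precursor error| / precursor
    tolerance against the nearest of the seven window centres.
    total = fragment_fit + mass_accuracy, except that a peakless spectrum
    scores 0 outright (flagged).
    """
    m = len(sequences)
    charges = [1] if spectrum.charge < 2 else [1, 2]
    offsets = np.array(config.window_offsets, dtype=float) * config.neutron_spacing

    errs = spectrum.neutral_mass - (np.asarray(theo_precursors)[:, None] + offsets[None, :])
    k_best = np.argmin(np.abs(errs), axis=1)
    precursor_error = errs[np.arange(m), k_best]
    mass_accuracy = np.maximum(0.0, 1.0 - np.abs(precursor_error) / config.precursor_tol)

    n_peaks = len(spectrum.mz)
    if n_peaks == 0:
        return [
            ScoreComponents(0.0, 0.0, 0.0, 0, float(precursor_error[i]), empty_spectrum=True)
            for i in range(m)
        ]

    # concatenated fragment ladders of the whole batch
    ladders = [_ladder_lattices(seq) for seq in sequences]
    widths = [lad[0].shape[1] for lad in ladders]
    counts = [lad[0].shape[0] for lad in ladders]
    D = max(widths)
    F = np.zeros((sum(counts), D))
    Fm = np.zeros((sum(counts), D))
    n_counts = np.concatenate([lad[2] for lad in ladders])
    row_theta = np.repeat(np.asarray(theta_pcts, dtype=float) / 100.0, counts)
    at = 0
    for lad, cnt, w in zip(ladders, counts, widths):
        F[at : at + cnt, :w] = lad[0]
        Fm[at : at + cnt, :w] = lad[1]
        at += cnt
    neutrals = engine.most_abundant_packed(F, Fm, n_counts, row_theta)

    # PTM deltas (sparse path)
    at = 0
    for i, (lad, cnt) in enumerate(zip(ladders, counts)):
        if ptms_list[i]:
            neutrals[at : at + cnt] = _apply_ptm_deltas(
                neutrals[at : at + cnt], lad[3], len(sequences[i]), ptms_list[i]
            )
        at += cnt

    cand_of_frag = np.repeat(np.arange(m), counts)
    theo_mz = np.concatenate([(neutrals + z * PROTON_MASS) / z for z in charges])
    cand_of_ion = np.concatenate([cand_of_frag for _ in charges])

    pos = np.searchsorted(spectrum.mz, theo_mz)
    left = np.clip(pos - 1, 0, n_peaks - 1)
    right = np.clip(pos, 0, n_peaks - 1)
    d_left = np.abs(spectrum.mz[left] - theo_mz)
    d_right = np.abs(spectrum.mz[right] - theo_mz)
    nearest = np.where(d_left <= d_right, left, right)
    dist = np.minimum(d_left, d_right)
    matched = dist <= config.fragment_tol

    weights = _rank_weights(spectrum.intensity)
    contrib = weights[nearest[matched]] * (1.0 - dist[matched] / config.fragment_tol)
    achieved = np.bincount(cand_of_ion[matched], weights=contrib, minlength=m)
    n_matched = np.bincount(cand_of_ion[matched], minlength=m)

    sorted_w = np.sort(weights)[::-1]
    cum_w = np.concatenate([[0.0], np.cumsum(sorted_w)])
    n_theo = np.asarray(counts) * len(charges)
    best_possible = cum_w[np.minimum(n_theo, n_peaks)]
    fit = np.minimum(achieved / best_possible, 1.0)

    return [
        ScoreComponents(
            float(fit[i]),
            float(mass_accuracy[i]),
            float(fit[i] + mass_accuracy[i]),
            int(n_matched[i]),
            float(precursor_error[i]),
        )
        for i in range(m)
    ]


def score_psm(
    spectrum: Spectrum,
    peptide: str,
    ptm_assignment: tuple[tuple[int, str, float], ...],
    theta_pct: float,
    config: SearchConfig,
    engine: LatticeEngine | None = None,
    theoretical_precursor: float | None = None,
) -> ScoreComponents:
    """Score one candidate against one spectrum at one grid atom%.

    See :func:`_score_candidates` for the score definition; the total is
    fragment_fit + mass_accuracy in [0, 2].
    """
    engine = engine or LatticeEngine()
    if theoretical_precursor is None:
        comp = peptide_composition(peptide)
        theta = theta_pct / 100.0
        theoretical_precursor = float(
            engine.most_abundant_table([chos_lattice(comp)], np.array([comp.n]), theta)[0]
        ) + sum(p[2] for p in ptm_assignment)
    return _score_candidates(
        spectrum, [peptide], [ptm_assignment], np.array([theta_pct]),
        np.array([theoretical_precursor]), config, engine,
    )[0]


# --------------------------------------------------------------------------
# Whole-grid search
# --------------------------------------------------------------------------

_BATCH = 96


def search_spectrum(spectrum: Spectrum, index: SearchIndex) -> PSM | None:
    """Best PSM of one spectrum across the whole atom% grid, or None.

    Every grid theta contributes its window-passing candidates; PTM-expanded
    and unmodified candidates compete in one ranking.  Candidates are scored
    in batches ordered by decreasing precursor mass accuracy, which allows a
    sound cutoff: once 1 + mass_accuracy (the ceiling of a candidate's total
    score) falls below the best total already seen, no remaining candidate
    can win.  Exact score ties break toward lower theta, then fewer PTMs,
    then the lexicographically smaller peptide.
    """
    config = index.config
    obs = spectrum.neutral_mass

    cand_theta: list[np.ndarray] = []
    cand_var: list[np.ndarray] = []
    for t, theta_pct in enumerate(config.theta_grid):
        vs = index.candidates_at(obs, theta_pct)
        if len(vs):
            cand_var.append(vs)
            cand_theta.append(np.full(len(vs), theta_pct, dtype=float))
    if not cand_var:
        return None
    var = np.concatenate(cand_var)
    theta = np.concatenate(cand_theta)
    t_idx = np.searchsorted(np.asarray(config.theta_grid, dtype=float), theta)

    entry_idx = index.var_entry[var]
    theo_pre = index.base_masses[t_idx, entry_idx] + index.var_delta[var]

    offsets = np.array(config.window_offsets, dtype=float) * config.neutron_spacing
    acc = np.maximum(
        0.0,
        1.0 - np.min(np.abs(obs - theo_pre[:, None] - offsets[None, :]), axis=1)
        / config.precursor_tol,
    )
    order = np.argsort(-acc, kind="stable")

    best: PSM | None = None
    best_key: tuple | None = None
    for start in range(0, len(order), _BATCH):
        chunk = order[start : start + _BATCH]
        if best_key is not None and 1.0 + acc[chunk[0]] < -best_key[0]:
            break
        seqs = [index.entries[entry_idx[i]].sequence for i in chunk]
        ptms = [index.var_ptms[var[i]] for i in chunk]
        comps = _score_candidates(
            spectrum, seqs, ptms, theta[chunk], theo_pre[chunk], config, index.engine
        )
        for j, sc in enumerate(comps):
            i = chunk[j]
            entry = index.entries[entry_idx[i]]
            # totals are quantized for ranking: candidates at nearby thetas
            # can predict mathematically identical spectra (the isotopologue
            # mode does not move), and without quantization float rounding
            # would decide such ties instead of the lower-theta rule
            key = (-round(sc.total, 9), float(theta[i]), len(ptms[j]), entry.sequence)
            if best_key is None or key < best_key:
                best_key = key
                best = PSM(
                    spectrum_id=spectrum.id,
                    peptide=entry.sequence,
                    ptm_assignment=ptms[j],
                    theta_hat=float(theta[i]),
                    score=sc.total,
                    fragment_fit=sc.fragment_fit,
                    mass_accuracy=sc.mass_accuracy,
                    precursor_error=sc.precursor_error,
                    matched_fragments=sc.matched_fragments,
                    is_decoy=entry.is_decoy_only,
                    is_ambiguous=entry.is_ambiguous,
                    n_nitrogen=entry.n_nitrogen,
                )
    return best


def search_spectra(spectra: Sequence[Spectrum], index: SearchIndex) -> list[PSM]:
    """Search every spectrum; unidentified spectra are dropped."""
    out = []
    for sp in spectra:
        psm = search_spectrum(sp, index)
        if psm is not None:
            out.append(psm)
    return out


# --------------------------------------------------------------------------
# PSM table I/O
# --------------------------------------------------------------------------

PSM_COLUMNS = [
    "spectrum_id", "peptide", "ptms", "theta_hat", "score", "fragment_fit",
    "mass_accuracy", "precursor_error", "matched_fragments", "is_decoy",
    "is_ambiguous", "n_nitrogen",
]


def format_ptms(assignment: tuple[tuple[int, str, float], ...]) -> str:
    return ";".join(f"{pos}:{name}:{delta:+.6f}" for pos, name, delta in assignment)


def parse_ptms(text: str) -> tuple[tuple[int, str, float], ...]:
    if not text:
        return ()
    out = []
    for item in text.split(";"):
        pos, name, delta = item.split(":")
        out.append((int(pos), name, float(delta)))
    return tuple(out)


def write_psms(psms: Sequence[PSM], path: str | Path) -> None:
    import pandas as pd

    rows = [
        {
            "spectrum_id": p.spectrum_id,
            "peptide": p.peptide,
            "ptms": format_ptms(p.ptm_assignment),
            "theta_hat": p.theta_hat,
            "score": p.score,
            "fragment_fit": p.fragment_fit,
            "mass_accuracy": p.mass_accuracy,
            "precursor_error": p.precursor_error,
            "matched_fragments": p.matched_fragments,
            "is_decoy": p.is_decoy,
            "is_ambiguous": p.is_ambiguous,
            "n_nitrogen": p.n_nitrogen,
        }
        for p in psms
    ]
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(path, sep="\t", index=False)


def read_psms(path: str | Path) -> list[PSM]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        PSM(
            spectrum_id=str(r.spectrum_id),
            peptide=r.peptide,
            ptm_assignment=parse_ptms(str(r.ptms)),
            theta_hat=float(r.theta_hat),
            score=float(r.score),
            fragment_fit=float(r.fragment_fit),
            mass_accuracy=float(r.mass_accuracy),
            precursor_error=float(r.precursor_error),
            matched_fragments=int(r.matched_fragments),
            is_decoy=bool(r.is_decoy),
            is_ambiguous=bool(r.is_ambiguous),
            n_nitrogen=int(r.n_nitrogen),
        )
        for r in df.itertuples()
    ]
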