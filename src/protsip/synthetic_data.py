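"""Ground-truth metaproteome and SIP MS/MS spectrum simulator.

Emulates the statistical structure the analysis assumes: a mixed-community
protein database with taxon/function labels; a two-arm labelling design in
which a fraction of proteins was synthesised during a ¹⁵NH₄⁺ incubation
(peptide ¹⁵N bimodal: an unenriched pool at natural abundance ~0.5 atom% and
an enriched pool peaked near 49 atom%); and centroided CID spectra of
tryptic peptides with fragment dropout, m/z jitter and uniform noise peaks.

Every random draw flows from one integer seed, and a TruthLedger records the
generating peptide, true atom% and noise-peak count of every spectrum, so
downstream false-discovery proportions and atom%-recovery errors are exactly
computable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .database import (
    MAX_PEPTIDE_LEN,
    MIN_PEPTIDE_LEN,
    ProteinRecord,
    tryptic_digest,
)
from .isotope_model import (
    PROTON_MASS,
    LatticeEngine,
    chos_lattice,
    peptide_composition,
)
from .sip_search import Spectrum, _ladder_lattices

#: residue sampling frequencies; K+R ~9% with ~4% proline keeps simulated
#: tryptic peptides averaging ~8-25 residues
_RESIDUE_FREQS = {
    "A": 0.085, "C": 0.012, "D": 0.055, "E": 0.062, "F": 0.040,
    "G": 0.075, "H": 0.022, "I": 0.058, "K": 0.048, "L": 0.092,
    "M": 0.022, "N": 0.042, "P": 0.040, "Q": 0.038, "R": 0.045,
    "S": 0.065, "T": 0.055, "V": 0.070, "W": 0.012, "Y": 0.032,
}

#: default community structure: methane-seep lineages and the protein
#: function categories most often reported from them
DEFAULT_TAXONOMY_WEIGHTS = {
    "ANME-1": 0.15, "ANME-2": 0.15, "SEEP-SRB1": 0.15, "SEEP-SRB2": 0.10,
    "Sulfurovum": 0.10, "Methylococcales": 0.08, "Desulfobacterales": 0.10,
    "other_bacteria": 0.12, "unassigned": 0.05,
}
DEFAULT_FUNCTION_WEIGHTS = {
    "Mcr": 0.10, "Mer": 0.04, "RNAP": 0.09, "GroEL": 0.08, "ATPase": 0.10,
    "AprA": 0.07, "DsrB": 0.05, "ribosomal": 0.14, "chemotaxis": 0.05,
    "glutamine_synthetase": 0.05, "unknown": 0.23,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the simulated two-arm SIP experiment."""

    n_proteins: int = 300
    protein_length: tuple[int, int] = (80, 300)
    taxonomy_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TAXONOMY_WEIGHTS)
    )
    function_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FUNCTION_WEIGHTS)
    )
    #: fraction of proteins synthesised during the labelling period
    enriched_fraction: float = 0.3
    theta_peak: float = 49.0  # atom% centre of the enriched mode
    theta_sd: float = 3.0  # atom% spread of the enriched mode
    baseline_p: float = 0.005  # natural-abundance ¹⁵N frequency
    n_spectra: int = 2000
    spectra_per_peptide: int = 1
    charge: int = 2
    fragment_dropout: float = 0.15
    noise_peaks_per_spectrum: int = 15
    mz_jitter_sd: float = 0.006  # Da; below a third of the fragment tolerance
    #: the precursor is reported at the most-abundant isotopologue exactly;
    #: optional Gaussian error on the neutral-mass scale for robustness runs
    precursor_jitter_sd: float = 0.0
    seed: int = 17
    #: optional per-taxonomy multiplier on the enrichment probability
    enrichment_bias: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not 0.0 <= self.enriched_fraction <= 1.0:
            raise ValueError("enriched_fraction must lie in [0, 1]")
        if not 0.0 <= self.theta_peak <= 100.0:
            raise ValueError("theta_peak must lie in [0, 100] atom%")


@dataclass
class SpectrumTruth:
    peptide: str
    parent_id: str
    true_theta: float  # atom%
    n_noise_peaks: int


@dataclass
class TruthLedger:
    """Everything needed to score the pipeline against the planted truth."""

    protein_bins: dict[str, tuple[str, str]] = field(default_factory=dict)
    protein_enriched: dict[str, bool] = field(default_factory=dict)
    spectra: dict[str, SpectrumTruth] = field(default_factory=dict)

    @property
    def generated_peptides(self) -> set[str]:
        return {t.peptide for t in self.spectra.values()}

    def true_fdp(self, accepted_peptides: Sequence) -> float:
        """Truth-ledger false-discovery proportion of an accepted peptide set:
        the fraction of accepted target records whose (peptide, PTM) hypothesis
        never generated a spectrum (only unmodified peptides are generated)."""
        targets = [r for r in accepted_peptides if not r.is_decoy]
        if not targets:
            return 0.0
        good = self.generated_peptides
        false = sum(
            1 for r in targets if r.ptm_assignment or r.peptide not in good
        )
        return false / len(targets)

    def theta_errors(self, psms: Sequence) -> np.ndarray:
        """|theta_hat - true theta| (atom%) over PSMs that recovered the
        generating peptide of their spectrum."""
        errs = []
        for p in psms:
            truth = self.spectra.get(p.spectrum_id)
            if truth is not None and truth.peptide == p.peptide:
                errs.append(abs(p.theta_hat - truth.true_theta))
        return np.array(errs)

    def write(self, directory: str | Path) -> None:
        import pandas as pd

        directory = Path(directory)
        pd.DataFrame(
            [
                {
                    "protein_id": pid,
                    "taxonomy_bin": bins[0],
                    "function_bin": bins[1],
                    "enriched": self.protein_enriched[pid],
                }
                for pid, bins in sorted(self.protein_bins.items())
            ]
        ).to_csv(directory / "truth_proteins.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "spectrum_id": sid,
                    "peptide": t.peptide,
                    "parent_id": t.parent_id,
                    "true_theta": t.true_theta,
                    "n_noise_peaks": t.n_noise_peaks,
                }
                for sid, t in sorted(self.spectra.items())
            ]
        ).to_csv(directory / "truth_spectra.tsv", sep="\t", index=False)


def _weighted_choice(rng: np.random.Generator, weights: Mapping[str, float], size: int) -> list[str]:
    labels = sorted(weights)
    p = np.array([weights[l] for l in labels], dtype=float)
    p = p / p.sum()
    return list(rng.choice(labels, size=size, p=p))


def simulate_proteome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[ProteinRecord], TruthLedger]:
    """Random annotated metaproteome plus the truth ledger of its labels."""
    rng = rng or np.random.default_rng(config.seed)
    letters = sorted(_RESIDUE_FREQS)
    freqs = np.array([_RESIDUE_FREQS[a] for a in letters])
    freqs = freqs / freqs.sum()
    lo, hi = config.protein_length
    lengths = rng.integers(lo, hi + 1, size=config.n_proteins)
    taxa = _weighted_choice(rng, config.taxonomy_weights, config.n_proteins)
    funcs = _weighted_choice(rng, config.function_weights, config.n_proteins)
    records = []
    ledger = TruthLedger()
    width = len(str(config.n_proteins))
    for i in range(config.n_proteins):
        seq = "".join(rng.choice(letters, size=lengths[i], p=freqs))
        pid = f"P{i + 1:0{width}d}"
        records.append(ProteinRecord(pid, seq, taxa[i], funcs[i]))
        ledger.protein_bins[pid] = (taxa[i], funcs[i])

    # plant the enriched (newly synthesised) protein subset
    n_enriched = round(config.enriched_fraction * config.n_proteins)
    if config.enrichment_bias:
        w = np.array(
            [config.enrichment_bias.get(taxa[i], 1.0) for i in range(config.n_proteins)],
            dtype=float,
        )
        p = w / w.sum()
        chosen = rng.choice(config.n_proteins, size=n_enriched, replace=False, p=p)
    else:
        chosen = rng.choice(config.n_proteins, size=n_enriched, replace=False)
    enriched_ids = {records[i].id for i in chosen}
    for rec in records:
        ledger.protein_enriched[rec.id] = rec.id in enriched_ids
    return records, ledger


def _draw_true_theta(
    enriched: bool, config: SimulationConfig, rng: np.random.Generator
) -> float:
    """True atom% of one peptide: baseline for pre-existing proteins, a
    truncated normal around the enriched-mode peak for new ones."""
    if not enriched:
        return 100.0 * config.baseline_p
    if config.theta_sd == 0:
        return config.theta_peak
    for _ in range(1000):
        theta = rng.normal(config.theta_peak, config.theta_sd)
        if 1.0 <= theta <= 100.0:
            return theta
    return config.theta_peak


def assign_enrichment(
    records: Sequence[ProteinRecord],
    ledger: TruthLedger,
    config: SimulationConfig,
    rng: np.random.Generator,
    peptides_by_protein: Mapping[str, Sequence[str]],
) -> dict[tuple[str, str], float]:
    """True theta (atom%) per (protein, peptide) pair."""
    thetas: dict[tuple[str, str], float] = {}
    for rec in records:
        enriched = ledger.protein_enriched[rec.id]
        for pep in peptides_by_protein.get(rec.id, ()):
            thetas[(rec.id, pep)] = _draw_true_theta(enriched, config, rng)
    return thetas


def _merge_centroids(
    mz: np.ndarray, intensity: np.ndarray, resolution: float = 1e-3
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse peaks closer than the centroiding resolution into one peak
    (intensity-weighted mean m/z, summed intensity).  Real centroided scans
    never contain coincident peaks, e.g. a y 2+ ion on top of a b 1+ ion."""
    if len(mz) == 0:
        return mz, intensity
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    group = np.concatenate([[0], np.cumsum(np.diff(mz) >= resolution)])
    sums = np.bincount(group, weights=intensity)
    centers = np.bincount(group, weights=mz * intensity) / sums
    return centers, sums


def _fragment_mzs_at_theta(
    sequence: str, theta: float, charges: Sequence[int], engine: LatticeEngine
) -> np.ndarray:
    """Most-abundant fragment m/z values at an arbitrary (off-grid) theta."""
    F, Fm, n_counts, _labels = _ladder_lattices(sequence)
    neutrals = engine.most_abundant_packed(F, Fm, n_counts, theta)
    return np.concatenate([(neutrals + z * PROTON_MASS) / z for z in charges])


def simulate_spectra(
    records: Sequence[ProteinRecord],
    ledger: TruthLedger,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    engine: LatticeEngine | None = None,
) -> list[Spectrum]:
    """Simulated MS/MS scans of tryptic peptides at their true atom%.

    Per spectrum: the precursor sits at the most-abundant isotopologue of
    the generating peptide at its true theta; fragment peaks are the b/y
    most-abundant m/z (1+, and 2+ for multiply charged precursors) with
    dropout, Gaussian m/z jitter and 1/rank intensities under multiplicative
    lognormal noise; uniform random noise peaks are added and logged.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    engine = engine or LatticeEngine()

    # candidate (protein, peptide) pool: fully cleaved peptides in the window
    pool: list[tuple[str, str]] = []
    peptides_by_protein: dict[str, list[str]] = {}
    for rec in records:
        peps = [
            d.sequence
            for d in tryptic_digest(rec.sequence, max_missed=0,
                                    min_len=MIN_PEPTIDE_LEN, max_len=MAX_PEPTIDE_LEN)
        ]
        peptides_by_protein[rec.id] = peps
        pool.extend((rec.id, pep) for pep in peps)
    if not pool:
        raise ValueError("no tryptic peptides in the length window; proteome degenerate")

    thetas = assign_enrichment(records, ledger, config, rng, peptides_by_protein)

    n_distinct = min(config.n_spectra, len(pool))
    idx = rng.choice(len(pool), size=n_distinct, replace=False)
    sampled = [pool[i] for i in idx]
    if config.n_spectra > len(pool):
        extra = rng.choice(len(pool), size=config.n_spectra - len(pool), replace=True)
        sampled.extend(pool[i] for i in extra)

    charges = [1] if config.charge < 2 else [1, 2]
    spectra: list[Spectrum] = []
    scan = 0
    for parent_id, pep in sampled:
        theta_pct = thetas[(parent_id, pep)]
        theta = theta_pct / 100.0
        comp = peptide_composition(pep)
        precursor_neutral = float(
            engine.most_abundant_table([chos_lattice(comp)], np.array([comp.n]), theta)[0]
        )
        precursor_neutral += rng.normal(0.0, config.precursor_jitter_sd)
        z = config.charge
        precursor_mz = (precursor_neutral + z * PROTON_MASS) / z

        frag_mz = _fragment_mzs_at_theta(pep, theta, charges, engine)
        keep = rng.random(len(frag_mz)) >= config.fragment_dropout
        for _ in range(config.spectra_per_peptide):
            kept_mz = frag_mz[keep] + rng.normal(0.0, config.mz_jitter_sd, size=keep.sum())
            ranks = rng.permutation(len(kept_mz)) + 1
            intens = (1000.0 / ranks) * np.exp(rng.normal(0.0, 0.3, size=len(kept_mz)))
            n_noise = config.noise_peaks_per_spectrum
            noise_mz = rng.uniform(100.0, precursor_neutral + 20.0, size=n_noise)
            noise_int = rng.uniform(5.0, 100.0, size=n_noise)
            mz, intensity = _merge_centroids(
                np.concatenate([kept_mz, noise_mz]),
                np.concatenate([intens, noise_int]),
            )
            scan += 1
            sid = f"scan={scan}"
            spectra.append(
                Spectrum(
                    id=sid,
                    precursor_mz=precursor_mz,
                    charge=z,
                    mz=mz,
                    intensity=intensity,
                )
            )
            ledger.spectra[sid] = SpectrumTruth(
                peptide=pep, parent_id=parent_id,
                true_theta=theta_pct, n_noise_peaks=n_noise,
            )
    return spectra


def write_annotations(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Headerless 3-column annotation TSV (id, taxonomy_bin, function_bin)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.id}\t{rec.taxonomy_bin}\t{rec.function_bin}\n")


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[ProteinRecord], list[Spectrum], TruthLedger]:
    """One call producing the full two-arm benchmark inputs in memory."""
    rng = np.random.default_rng(config.seed)
    records, ledger = simulate_proteome(config, rng)
    spectra = simulate_spectra(records, ledger, config, rng)
    return records, spectra, ledger
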