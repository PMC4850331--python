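"""Enriched-vs-unenriched pool contrasts across taxonomy or function bins.

For each bin (family-level taxonomy or a function category), the relative
abundance of protein groups is computed within the enriched pool and within
the unenriched pool; the squared difference of the two relative abundances
is that bin's contribution to the total variance between the pools.  The
sign of the (enriched - unenriched) difference says which pool a bin favours.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class BinContrast:
    bin_label: str
    rel_abundance_enriched: float
    rel_abundance_unenriched: float
    delta: float  # enriched - unenriched
    variance_contribution: float  # delta^2
    variance_fraction: float  # share of total delta^2


def relative_abundances(
    protein_report: pd.DataFrame,
    bin_key: str,
    pool: str,
    unit: str = "protein_groups",
) -> dict[str, float]:
    """Per-bin relative abundance of one pool of the protein report.

    ``bin_key`` is ``taxonomy`` or ``function``; ``pool`` is ``enriched`` or
    ``unenriched`` (selected by the boolean ``enriched`` column).  The
    abundance unit defaults to protein-group counts; ``peptides`` weights
    each group by its distinct-peptide count instead.
    """
    if bin_key not in ("taxonomy", "function"):
        raise ValueError("bin_key must be 'taxonomy' or 'function'")
    if pool not in ("enriched", "unenriched"):
        raise ValueError("pool must be 'enriched' or 'unenriched'")
    col = f"{bin_key}_bin"
    mask = protein_report["enriched"] if pool == "enriched" else ~protein_report["enriched"]
    sub = protein_report[mask]
    if len(sub) == 0:
        raise ValueError(f"the {pool} pool is empty")
    labels = sub[col].fillna(UNASSIGNED).replace("", UNASSIGNED)
    if unit == "protein_groups":
        weights = pd.Series(1.0, index=sub.index)
    elif unit == "peptides":
        weights = sub["n_total_peptides"].astype(float)
    else:
        raise ValueError(f"unknown abundance unit {unit!r}")
    totals = weights.groupby(labels).sum()
    return (totals / totals.sum()).to_dict()


def variance_contributions(
    ra_enriched: Mapping[str, float],
    ra_unenriched: Mapping[str, float],
) -> list[BinContrast]:
    """Squared-difference variance contribution of every bin, sorted by
    descending variance fraction (bins missing from a pool count as 0)."""
    bins = sorted(set(ra_enriched) | set(ra_unenriched))
    deltas = {b: ra_enriched.get(b, 0.0) - ra_unenriched.get(b, 0.0) for b in bins}
    total = sum(d * d for d in deltas.values())
    out = []
    for b in bins:
        d = deltas[b]
        out.append(
            BinContrast(
                bin_label=b,
                rel_abundance_enriched=ra_enriched.get(b, 0.0),
                rel_abundance_unenriched=ra_unenriched.get(b, 0.0),
                delta=d,
                variance_contribution=d * d,
                variance_fraction=(d * d / total) if total > 0 else 0.0,
            )
        )
    out.sort(key=lambda c: (-c.variance_fraction, c.bin_label))
    return out


def report_major_bins(
    contrasts: Sequence[BinContrast], min_fraction: float = 0.01
) -> tuple[list[BinContrast], float]:
    """Bins contributing at least ``min_fraction`` of the variance, plus the
    cumulative variance share they jointly explain."""
    major = [c for c in contrasts if c.variance_fraction >= min_fraction and c.variance_contribution > 0]
    cumulative = sum(c.variance_fraction for c in major)
    return major, cumulative


def contrasts_frame(contrasts: Sequence[BinContrast]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "bin": c.bin_label,
                "ra_enriched": c.rel_abundance_enriched,
                "ra_unenriched": c.rel_abundance_unenriched,
                "delta": c.delta,
                "variance_contribution": c.variance_contribution,
                "variance_fraction": c.variance_fraction,
            }
            for c in contrasts
        ],
        columns=[
            "bin", "ra_enriched", "ra_unenriched", "delta",
            "variance_contribution", "variance_fraction",
        ],
    )
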