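"""Enrichment calling: which peptides (and proteins) carry excess ¹⁵N.

Three interchangeable rules classify a peptide with estimated atom% theta_hat
as enriched:

* ``fixed``     — theta_hat >= a stated atom% demarcation (default 5%);
* ``empirical`` — theta_hat >= the 99th percentile of the atom% values
  observed in an unlabelled (¹⁴NH₄⁺ control) run, i.e. a 1% false-call rate
  against the control distribution;
* ``binomial``  — per-peptide: theta_hat >= 100*k*/n where k* is the smallest
  ¹⁵N count whose natural-occurrence tail probability under
  Binomial(n, baseline_p) drops below alpha.  Longer peptides (larger n)
  resolve smaller enrichments.

Enrichment is decided at the peptide level; a protein group is enriched when
any of its accepted peptides is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

import numpy as np
from scipy import stats

#: control-incubation mean ¹⁵N frequencies (fraction), per sample preset
BASELINE_PRESETS = {
    "#3731_T17d": 0.0045,
    "#3731_T326d": 0.0035,
    "#5133_T160d": 0.0049,
}


@dataclass(frozen=True)
class EnrichmentConfig:
    baseline_p: float = 0.0049
    control_percentile: float = 99.0
    enriched_threshold: float = 5.0  # atom%
    alpha: float = 0.01
    histogram_bin: float = 1.0  # atom%

    def __post_init__(self) -> None:
        if not 0 < self.baseline_p < 1:
            raise ValueError("baseline_p must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.enriched_threshold < 0:
            raise ValueError("enriched_threshold must be >= 0")


@dataclass(frozen=True)
class EnrichmentCall:
    peptide: str
    n_nitrogen: int
    theta_hat: float  # atom%
    enriched: bool
    rule_applied: str  # fixed | empirical | binomial
    threshold: float  # atom% threshold actually applied


def binom_pmf(n: int, k: int, p: float) -> float:
    """P(X = k) for X ~ Binomial(n, p): C(n,k) p^k (1-p)^(n-k)."""
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside 0..{n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return float(stats.binom.pmf(k, n, p))


def atom_percent(k: int, n: int) -> float:
    """Atom% ¹⁵N represented by k labelled atoms out of n: 100*k/n."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"invalid (k={k}, n={n})")
    return 100.0 * k / n


def min_detectable_enrichment(n: int, baseline_p: float, alpha: float = 0.01) -> float:
    """Smallest atom% whose natural occurrence is rarer than alpha.

    Returns 100*k*/n with k* the smallest count where
    P(X >= k* | n, baseline_p) < alpha; the tail is exact (survival
    function), no normal approximation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for k in range(0, n + 1):
        if float(stats.binom.sf(k - 1, n, baseline_p)) < alpha:
            return atom_percent(k, n)
    return 100.0


def empirical_threshold(
    control_theta_values: Sequence[float],
    percentile: float = 99.0,
    grid: float = 1.0,
) -> float:
    """Control-distribution percentile threshold, on the atom% grid.

    Nearest-rank percentile of the ¹⁴N-control atom% values, rounded UP to
    the grid resolution (integer atom% by default) — consistent with a grid
    search that only reports whole-percent enrichments.
    """
    values = sorted(float(v) for v in control_theta_values)
    if len(values) < 20:
        raise ValueError(f"need >= 20 control values, got {len(values)}")
    rank = math.ceil(percentile / 100.0 * len(values))  # 1-based nearest rank
    raw = values[max(rank, 1) - 1]
    return math.ceil(raw / grid - 1e-9) * grid


class _HasTheta(Protocol):
    peptide: str
    n_nitrogen: int
    theta_hat: float


def classify(
    records: Iterable[_HasTheta],
    config: EnrichmentConfig = EnrichmentConfig(),
    rule: str = "fixed",
    control_theta_values: Sequence[float] | None = None,
) -> list[EnrichmentCall]:
    """Apply one enrichment rule to peptide records carrying theta_hat.

    The threshold is inclusive: a peptide exactly at the demarcation counts
    as enriched.
    """
    if rule not in ("fixed", "empirical", "binomial"):
        raise ValueError(f"unknown rule {rule!r}")
    if rule == "empirical":
        if control_theta_values is None:
            raise ValueError("empirical rule requires control_theta_values")
        thr = empirical_threshold(
            control_theta_values, config.control_percentile, config.histogram_bin
        )
    calls = []
    for r in records:
        if rule == "fixed":
            threshold = config.enriched_threshold
        elif rule == "empirical":
            threshold = thr
        else:
            threshold = min_detectable_enrichment(r.n_nitrogen, config.baseline_p, config.alpha)
        calls.append(
            EnrichmentCall(
                peptide=r.peptide,
                n_nitrogen=r.n_nitrogen,
                theta_hat=r.theta_hat,
                enriched=r.theta_hat >= threshold,
                rule_applied=rule,
                threshold=threshold,
            )
        )
    return calls


def pool_summary(calls: Sequence[EnrichmentCall]) -> tuple[float, float]:
    """(mean atom%, % of peptides flagged enriched) of a sample's calls."""
    if not calls:
        raise ValueError("empty call set")
    thetas = np.array([c.theta_hat for c in calls])
    pct = 100.0 * sum(c.enriched for c in calls) / len(calls)
    return float(thetas.mean()), float(pct)


def histogram(calls: Sequence[EnrichmentCall], bin_width: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of atom% values: (bin lower edges, counts) over [0, 100]."""
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    counts, _ = np.histogram([c.theta_hat for c in calls], bins=edges)
    return edges[:-1], counts


def histogram_modes(
    calls: Sequence[EnrichmentCall],
    bin_width: float = 1.0,
    enriched_threshold: float = 5.0,
) -> tuple[float, float | None]:
    """Modal atom% bins of the unenriched and enriched regions.

    The unenriched mode is the modal bin below the demarcation; the enriched
    mode the modal bin at/above it (None when that region is empty).  Count
    ties break toward the lower bin.
    """
    if not calls:
        raise ValueError("empty call set")
    lowers, counts = histogram(calls, bin_width)
    below = lowers < enriched_threshold
    unenriched_mode = float(lowers[below][np.argmax(counts[below])])
    enriched_mode: float | None = None
    if counts[~below].sum() > 0:
        enriched_mode = float(lowers[~below][np.argmax(counts[~below])])
    return unenriched_mode, enriched_mode


def protein_enrichment(member_calls: Sequence[EnrichmentCall]) -> bool:
    """A protein group is enriched iff any constituent peptide call is."""
    if not member_calls:
        raise ValueError("protein group has no accepted peptide calls")
    return any(c.enriched for c in member_calls)


def write_enrichment_table(calls: Sequence[EnrichmentCall], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "peptide": c.peptide,
                "n_nitrogen": c.n_nitrogen,
                "theta_hat": c.theta_hat,
                "enriched": c.enriched,
                "rule": c.rule_applied,
                "threshold": c.threshold,
            }
            for c in calls
        ],
        columns=["peptide", "n_nitrogen", "theta_hat", "enriched", "rule", "threshold"],
    ).to_csv(path, sep="\t", index=False)
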