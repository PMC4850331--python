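"""Peptide-level target/decoy FDR filtering and parsimony protein inference.

The concatenated-database estimator FDR = 2D / (T + D) is used: a decoy hit
above a score threshold signals one expected false target hit, so doubling
the decoy count estimates the false fraction of the combined accepted list.
Peptides that occur in both target and decoy sequences (flagged ambiguous
upstream) are excluded from both counts.

Protein inference follows parsimony: proteins indistinguishable by their
accepted-peptide evidence are collapsed into groups, and a greedy minimal
set cover selects the fewest groups explaining every accepted peptide.
Reporting criteria [1%, 1TP, 1UP] and [1%, 2TP, 1UP] (minimum total and
unique peptides per group at 1% peptide FDR) are applied afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .database import PeptideEntry
from .sip_search import PSM, format_ptms


@dataclass(frozen=True)
class IdentificationConfig:
    fdr_level: float = 0.01
    total_peptide_min: int = 2
    unique_peptide_min: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must lie in (0, 1)")
        if self.total_peptide_min < 1 or self.unique_peptide_min < 0:
            raise ValueError("invalid reporting criteria")


@dataclass(frozen=True)
class PeptideRecord:
    """Peptide-level rollup: the best PSM of one (peptide, PTM variant)."""

    peptide: str
    ptm_assignment: tuple[tuple[int, str, float], ...]
    theta_hat: float
    score: float
    is_decoy: bool
    is_ambiguous: bool
    n_nitrogen: int
    spectrum_id: str


@dataclass
class ProteinGroup:
    """Proteins indistinguishable by peptide evidence, plus their counts."""

    group_id: str
    members: tuple[str, ...]
    peptides: tuple[str, ...]
    n_total_peptides: int
    n_unique_peptides: int


def best_psm_per_peptide(psms: Sequence[PSM]) -> list[PeptideRecord]:
    """Keep the highest-scoring PSM per distinct (peptide, PTM assignment).

    Different PTM assignments of the same sequence stay separate records:
    they are distinct hypotheses with distinct fragment evidence.  Score ties
    break deterministically (lower theta, then spectrum id).
    """
    best: dict[tuple[str, tuple], PSM] = {}
    for p in psms:
        key = (p.peptide, p.ptm_assignment)
        cur = best.get(key)
        if cur is None or (-p.score, p.theta_hat, p.spectrum_id) < (
            -cur.score, cur.theta_hat, cur.spectrum_id
        ):
            best[key] = p
    return [
        PeptideRecord(
            peptide=p.peptide,
            ptm_assignment=p.ptm_assignment,
            theta_hat=p.theta_hat,
            score=p.score,
            is_decoy=p.is_decoy,
            is_ambiguous=p.is_ambiguous,
            n_nitrogen=p.n_nitrogen,
            spectrum_id=p.spectrum_id,
        )
        for _, p in sorted(best.items())
    ]


def _sorted_unambiguous(records: Iterable[PeptideRecord]) -> list[PeptideRecord]:
    usable = [r for r in records if not r.is_ambiguous]
    return sorted(usable, key=lambda r: (-r.score, r.is_decoy, r.peptide, format_ptms(r.ptm_assignment)))


def estimate_fdr(records: Sequence[PeptideRecord], score_threshold: float) -> float:
    """Concatenated target/decoy FDR estimate 2D/(T+D) at a score threshold,
    capped at 1.  An empty set has FDR 0 by convention."""
    T = D = 0
    for r in records:
        if r.is_ambiguous or r.score < score_threshold:
            continue
        if r.is_decoy:
            D += 1
        else:
            T += 1
    if T + D == 0:
        return 0.0
    return min(1.0, 2.0 * D / (T + D))


def filter_at_fdr(
    records: Sequence[PeptideRecord], fdr_level: float = 0.01
) -> tuple[list[PeptideRecord], float]:
    """Largest score-descending prefix whose estimated FDR is within level.

    Returns (accepted target records, score threshold).  Decoys count toward
    the estimate but are never reported; if no prefix qualifies the accepted
    set is empty and the threshold +inf.
    """
    if not records:
        raise ValueError("no peptide records to filter")
    ranked = _sorted_unambiguous(records)
    T = D = 0
    best_cut = -1  # index of last record of the chosen prefix
    for i, r in enumerate(ranked):
        if r.is_decoy:
            D += 1
        else:
            T += 1
        # evaluate only at score boundaries so equal-scored records stay together
        if i + 1 < len(ranked) and ranked[i + 1].score == r.score:
            continue
        if T + D > 0 and 2.0 * D / (T + D) <= fdr_level:
            best_cut = i
    if best_cut < 0:
        return [], float("inf")
    threshold = ranked[best_cut].score
    accepted = [r for r in ranked[: best_cut + 1] if not r.is_decoy]
    return accepted, threshold


# --------------------------------------------------------------------------
# Parsimony protein inference
# --------------------------------------------------------------------------


def infer_proteins(
    accepted: Sequence[PeptideRecord],
    search_space: Mapping[str, PeptideEntry],
    config: IdentificationConfig = IdentificationConfig(),
) -> list[ProteinGroup]:
    """Minimal set cover over protein groups, then reporting criteria.

    1. proteins with identical accepted-peptide evidence collapse into one
       group;
    2. the smallest set of groups explaining every accepted peptide is
       selected — exactly (exhaustive, lexicographic tie-break) when there
       are few groups, greedily by number of still-unexplained peptides
       (ties: more group-unique peptides, then smallest member id) on larger
       inputs where exact cover is not tractable;
    3. a selected group is reported iff it has >= total_peptide_min distinct
       peptides and >= unique_peptide_min unique peptides, where a peptide is
       unique when all of its parents lie inside the one group.
    """
    peptides = sorted({r.peptide for r in accepted if not r.is_decoy})
    evidence: dict[str, set[str]] = {}
    for pep in peptides:
        entry = search_space.get(pep)
        if entry is None:
            continue
        for parent in entry.parent_ids:
            evidence.setdefault(parent, set()).add(pep)

    # collapse identical-evidence proteins
    by_evidence: dict[frozenset[str], list[str]] = {}
    for protein, peps in evidence.items():
        by_evidence.setdefault(frozenset(peps), []).append(protein)
    groups = [
        (tuple(sorted(members)), peps) for peps, members in by_evidence.items()
    ]

    # parent map over groups for uniqueness: peptide -> set of group indices
    pep_groups: dict[str, set[int]] = {}
    for gi, (_members, peps) in enumerate(groups):
        for pep in peps:
            pep_groups.setdefault(pep, set()).add(gi)

    def unique_count(gi: int) -> int:
        return sum(1 for pep in groups[gi][1] if pep_groups[pep] == {gi})

    # exact minimal cover on small instances (set cover is tiny there and
    # greedy can miss the optimum by one); greedy beyond
    selected = None
    if 0 < len(groups) <= 18:
        order = sorted(range(len(groups)), key=lambda gi: groups[gi][0][0])
        all_peps = set(pep_groups)
        import itertools as _it

        for size in range(0, len(groups) + 1):
            for combo in _it.combinations(order, size):
                covered: set[str] = set()
                for gi in combo:
                    covered |= groups[gi][1]
                if covered == all_peps:
                    selected = list(combo)
                    break
            if selected is not None:
                break
    if selected is None:
        uncovered = set(pep_groups)
        selected = []
        remaining = set(range(len(groups)))
        while uncovered and remaining:
            best_gi = min(
                remaining,
                key=lambda gi: (
                    -len(groups[gi][1] & uncovered),
                    -unique_count(gi),
                    groups[gi][0][0],
                ),
            )
            if not groups[best_gi][1] & uncovered:
                break
            selected.append(best_gi)
            remaining.discard(best_gi)
            uncovered -= groups[best_gi][1]

    out: list[ProteinGroup] = []
    for gi in sorted(selected, key=lambda g: groups[g][0][0]):
        members, peps = groups[gi]
        total = len(peps)
        unique = unique_count(gi)
        if total >= config.total_peptide_min and unique >= config.unique_peptide_min:
            out.append(
                ProteinGroup(
                    group_id=members[0],
                    members=members,
                    peptides=tuple(sorted(peps)),
                    n_total_peptides=total,
                    n_unique_peptides=unique,
                )
            )
    return out


# --------------------------------------------------------------------------
# Tabular output
# --------------------------------------------------------------------------


def write_accepted_peptides(
    accepted: Sequence[PeptideRecord],
    search_space: Mapping[str, PeptideEntry],
    path: str | Path,
) -> None:
    import pandas as pd

    rows = []
    for r in accepted:
        entry = search_space.get(r.peptide)
        parents = ";".join(sorted(entry.parent_ids)) if entry else ""
        rows.append(
            {
                "peptide": r.peptide,
                "ptms": format_ptms(r.ptm_assignment),
                "theta_hat": r.theta_hat,
                "score": r.score,
                "n_nitrogen": r.n_nitrogen,
                "parents": parents,
            }
        )
    pd.DataFrame(
        rows, columns=["peptide", "ptms", "theta_hat", "score", "n_nitrogen", "parents"]
    ).to_csv(path, sep="\t", index=False)


def write_protein_report(
    groups_1tp: Sequence[ProteinGroup],
    groups_2tp: Sequence[ProteinGroup],
    records_by_id: Mapping[str, "object"],
    path: str | Path,
) -> None:
    """Protein report with flags for both reporting criteria."""
    import pandas as pd

    ids_2tp = {g.group_id for g in groups_2tp}
    rows = []
    for g in groups_1tp:
        rec = records_by_id.get(g.group_id)
        rows.append(
            {
                "group_id": g.group_id,
                "members": ";".join(g.members),
                "taxonomy_bin": getattr(rec, "taxonomy_bin", "unassigned"),
                "function_bin": getattr(rec, "function_bin", "unassigned"),
                "n_total_peptides": g.n_total_peptides,
                "n_unique_peptides": g.n_unique_peptides,
                "passes_1tp1up": True,
                "passes_2tp1up": g.group_id in ids_2tp,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "group_id", "members", "taxonomy_bin", "function_bin",
            "n_total_peptides", "n_unique_peptides", "passes_1tp1up", "passes_2tp1up",
        ],
    ).to_csv(path, sep="\t", index=False)
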