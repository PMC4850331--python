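"""Target/decoy peptide search space from an annotated protein FASTA.

Reads a mixed-community protein database with per-record taxonomy and
function labels, appends reversed-sequence decoys, digests in silico with
trypsin, and merges the resulting peptides into a search space keyed by
peptide sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

from Bio import SeqIO

from .isotope_model import (
    monoisotopic_mass,
    nitrogen_count,
    peptide_composition,
    residue_compositions,
)

DECOY_PREFIX = "REV_"
UNASSIGNED = "unassigned"

#: peptide length window; bounds follow the extremes of detectable tryptic
#: peptides (shortest 6 residues, longest 53)
MIN_PEPTIDE_LEN = 6
MAX_PEPTIDE_LEN = 53


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    taxonomy_bin: str = UNASSIGNED
    function_bin: str = UNASSIGNED
    is_decoy: bool = False


@dataclass
class PeptideEntry:
    """One distinct peptide sequence of the search space."""

    sequence: str
    parent_ids: frozenset[str]
    n_nitrogen: int
    missed_cleavages: int
    monoisotopic_mass: float
    is_decoy_only: bool = False
    #: peptide found in both a target and a decoy (e.g. palindromes); such
    #: entries are excluded from target/decoy FDR bookkeeping
    is_ambiguous: bool = False


class DigestPeptide(NamedTuple):
    sequence: str
    start: int  # 0-based position in the protein
    missed_cleavages: int


_VALID_RESIDUES = set(residue_compositions().keys())


def read_annotated_fasta(
    fasta_path: str | Path,
    annotations_path: str | Path | None = None,
) -> list[ProteinRecord]:
    """Load protein records and attach taxonomy/function bins.

    Annotations are a headerless 3-column TSV (id, taxonomy_bin,
    function_bin); records absent from the table fall in "unassigned".
    Sequences are upper-cased and trailing stop symbols ('*') stripped.
    """
    bins: dict[str, tuple[str, str]] = {}
    if annotations_path is not None:
        for lineno, line in enumerate(Path(annotations_path).read_text().splitlines(), 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"annotation line {lineno}: expected 3 tab-separated columns")
            bins[parts[0]] = (parts[1], parts[2])

    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA record id: {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().rstrip("*")
        bad = [(i, ch) for i, ch in enumerate(seq) if ch not in _VALID_RESIDUES]
        if bad:
            i, ch = bad[0]
            raise ValueError(f"record {rec.id}: non-residue character {ch!r} at position {i + 1}")
        tax, fun = bins.get(rec.id, (UNASSIGNED, UNASSIGNED))
        records.append(ProteinRecord(rec.id, seq, tax, fun))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def make_decoys(records: list[ProteinRecord]) -> list[ProteinRecord]:
    """Concatenate the database with its reversed-sequence decoys.

    Returns targets followed by one reversed decoy per target; decoys carry
    the reserved id prefix and no taxonomy/function assignment.
    """
    if any(r.is_decoy for r in records):
        raise ValueError("input records already contain decoys")
    decoys = [
        ProteinRecord(
            id=DECOY_PREFIX + r.id,
            sequence=r.sequence[::-1],
            taxonomy_bin="decoy",
            function_bin="decoy",
            is_decoy=True,
        )
        for r in records
    ]
    return records + decoys


def deduplicate_records(records: list[ProteinRecord]) -> list[ProteinRecord]:
    """Drop later records whose sequence is 100% identical to an earlier one
    (mirrors clustering a protein database at full identity)."""
    seen: set[str] = set()
    out = []
    for r in records:
        if r.sequence in seen:
            continue
        seen.add(r.sequence)
        out.append(r)
    return out


def tryptic_digest(
    sequence: str,
    max_missed: int = 2,
    min_len: int = MIN_PEPTIDE_LEN,
    max_len: int = MAX_PEPTIDE_LEN,
) -> list[DigestPeptide]:
    """In-silico tryptic digestion: cleave after K/R except before P.

    Emits all fragments with 0..max_missed internal missed cleavages whose
    length lies in [min_len, max_len], ordered by start position then
    missed-cleavage count.
    """
    if not sequence:
        return []
    # cleavage points: index i such that the bond sequence[i-1]|sequence[i] is cut
    cuts = [0]
    for i in range(1, len(sequence)):
        if sequence[i - 1] in "KR" and sequence[i] != "P":
            cuts.append(i)
    cuts.append(len(sequence))
    out: list[DigestPeptide] = []
    for a in range(len(cuts) - 1):
        for mc in range(0, max_missed + 1):
            b = a + 1 + mc
            if b >= len(cuts):
                break
            frag = sequence[cuts[a] : cuts[b]]
            if min_len <= len(frag) <= max_len:
                out.append(DigestPeptide(frag, cuts[a], mc))
    return out


def build_search_space(
    records: list[ProteinRecord],
    max_missed: int = 2,
    min_len: int = MIN_PEPTIDE_LEN,
    max_len: int = MAX_PEPTIDE_LEN,
) -> dict[str, PeptideEntry]:
    """Digest every record (targets and decoys) and merge identical peptides.

    Peptides whose parents are exclusively decoys are flagged decoy-only;
    peptides appearing in both pools (possible for palindromic stretches)
    are flagged ambiguous and excluded from FDR counting downstream.
    """
    space: dict[str, PeptideEntry] = {}
    parents: dict[str, set[str]] = {}
    min_mc: dict[str, int] = {}
    has_target: dict[str, bool] = {}
    has_decoy: dict[str, bool] = {}
    for rec in records:
        for frag in tryptic_digest(rec.sequence, max_missed, min_len, max_len):
            pep = frag.sequence
            parents.setdefault(pep, set()).add(rec.id)
            min_mc[pep] = min(min_mc.get(pep, frag.missed_cleavages), frag.missed_cleavages)
            has_target[pep] = has_target.get(pep, False) or not rec.is_decoy
            has_decoy[pep] = has_decoy.get(pep, False) or rec.is_decoy
    for pep in parents:
        comp = peptide_composition(pep)
        space[pep] = PeptideEntry(
            sequence=pep,
            parent_ids=frozenset(parents[pep]),
            n_nitrogen=nitrogen_count(comp),
            missed_cleavages=min_mc[pep],
            monoisotopic_mass=monoisotopic_mass(comp),
            is_decoy_only=has_decoy[pep] and not has_target[pep],
            is_ambiguous=has_decoy[pep] and has_target[pep],
        )
    return space
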