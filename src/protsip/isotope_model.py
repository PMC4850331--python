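"""Peptide chemistry under variable ¹⁵N enrichment.

Elemental compositions, monoisotopic masses, and aggregated isotopologue
distributions where nitrogen is the single isotopically variable element:
the ¹⁵N atom fraction ``theta`` is a free parameter (¹⁴N = 1-theta,
¹⁵N = theta) while C, H, O and S stay at fixed natural abundance.

Isotopologues are aggregated on a *neutron-excess lattice*: every
isotopologue is binned by its total neutron count above the all-lightest
species, and the mass reported for a lattice index is the abundance-weighted
mean mass of the isotopologues that landed there.  At Orbitrap-scale
tolerances (0.02-0.05 Da) this aggregation is indistinguishable from fine
structure for tryptic peptides.

The module also houses :class:`LatticeEngine`, a vectorised evaluator used
by the spectral search: it precomputes the nitrogen binomial pmf over the
whole atom% grid once and reduces the per-peptide work at each grid point to
a handful of short shifted-add convolutions.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

# --------------------------------------------------------------------------
# Physical constants
# --------------------------------------------------------------------------

PROTON_MASS = 1.007276466
WATER_MONO = 2 * 1.0078250319 + 15.9949146221

MASS_14N = 14.0030740052
MASS_15N = 15.0001088984
#: mass gained per ¹⁴N → ¹⁵N substitution
N15_SHIFT = MASS_15N - MASS_14N

#: average spacing of adjacent isotopologue lattice peaks, used for the
#: precursor mass windows of the search
NEUTRON_SPACING = 1.00335

# (isotope mass, natural abundance) per element, lightest first.  Nitrogen is
# listed at theta=0 here; its abundances are overridden by theta at run time.
_ELEMENT_ISOTOPES: dict[str, tuple[tuple[float, float], ...]] = {
    "c": ((12.0, 0.9893), (13.0033548378, 0.0107)),
    "h": ((1.0078250319, 0.999885), (2.0141017780, 0.000115)),
    "n": ((MASS_14N, 1.0), (MASS_15N, 0.0)),
    "o": ((15.9949146221, 0.99757), (16.9991315, 0.00038), (17.9991604, 0.00205)),
    "s": ((31.97207069, 0.9499), (32.97145850, 0.0075), (33.96786683, 0.0425), (35.96708088, 0.0001)),
}

_MONO_MASS = {el: iso[0][0] for el, iso in _ELEMENT_ISOTOPES.items()}


# --------------------------------------------------------------------------
# Compositions
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ElementalComposition:
    """CHNOS atom counts of a peptide, fragment or small molecule."""

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        for el in ("c", "h", "n", "o", "s"):
            v = getattr(self, el)
            if v < 0 or v != int(v):
                raise ValueError(f"negative or non-integer {el} count: {v}")

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            self.c + other.c, self.h + other.h, self.n + other.n,
            self.o + other.o, self.s + other.s,
        )

    def __mul__(self, k: int) -> "ElementalComposition":
        return ElementalComposition(self.c * k, self.h * k, self.n * k, self.o * k, self.s * k)

    __rmul__ = __mul__

    def as_dict(self) -> dict[str, int]:
        return {"c": self.c, "h": self.h, "n": self.n, "o": self.o, "s": self.s}


WATER = ElementalComposition(h=2, o=1)


@functools.cache
def residue_compositions() -> Mapping[str, ElementalComposition]:
    """Residue (monomer, water-free) compositions of the 20 standard amino
    acids, loaded from the versioned table shipped with the package."""
    table: dict[str, ElementalComposition] = {}
    text = resources.files("protsip.data").joinpath("residues.tsv").read_text()
    lines = text.strip().splitlines()
    header = lines[0].split("\t")
    assert header == ["residue", "c", "h", "n", "o", "s"]
    for line in lines[1:]:
        aa, *counts = line.split("\t")
        c, h, n, o, s = (int(x) for x in counts)
        table[aa] = ElementalComposition(c, h, n, o, s)
    return table


def peptide_composition(
    sequence: str,
    fixed_modifications: Mapping[str, ElementalComposition] | None = None,
) -> ElementalComposition:
    """Elemental composition of a peptide: residue sum plus one water.

    ``fixed_modifications`` maps a residue letter to an extra composition
    added per occurrence (hook for e.g. carbamidomethyl-C; none by default).
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    table = residue_compositions()
    total = WATER
    for i, aa in enumerate(sequence):
        comp = table.get(aa)
        if comp is None:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1} in {sequence!r}")
        total = total + comp
        if fixed_modifications and aa in fixed_modifications:
            total = total + fixed_modifications[aa]
    return total


def nitrogen_count(comp: ElementalComposition) -> int:
    """Number of nitrogen atoms (the n of the binomial enrichment model)."""
    return comp.n


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Neutral mass with every atom at its lightest isotope, in Da."""
    return sum(getattr(comp, el) * _MONO_MASS[el] for el in _MONO_MASS)


# --------------------------------------------------------------------------
# Aggregated isotopologue distributions
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IsotopeDistribution:
    """Aggregated isotopologue ladder of one composition at one theta.

    ``neutron_index`` counts neutrons above the all-lightest isotopologue;
    ``neutral_mass`` is the abundance-weighted mean mass within the index;
    abundances sum to 1 after truncation and renormalisation.
    """

    neutron_index: np.ndarray  # int
    neutral_mass: np.ndarray  # Da
    abundance: np.ndarray  # fractions summing to 1

    def __len__(self) -> int:
        return len(self.neutron_index)


def _atom_lattice(element: str, theta: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """(probability, mass-moment) lattice of a single atom.

    The lattice index is the neutron excess over the lightest isotope; the
    mass moment at index j is abundance(j) * mass(j) so that lattices can be
    convolved while tracking mean masses exactly.
    """
    isotopes = _ELEMENT_ISOTOPES[element]
    base = round(isotopes[0][0])
    size = round(isotopes[-1][0]) - base + 1
    p = np.zeros(size)
    m = np.zeros(size)
    for mass, ab in isotopes:
        j = round(mass) - base
        if element == "n" and theta is not None:
            ab = (1.0 - theta) if j == 0 else theta
        p[j] += ab
        m[j] += ab * mass
    return p, m


def _convolve_moment(a: tuple[np.ndarray, np.ndarray],
                     b: tuple[np.ndarray, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    pa, ma = a
    pb, mb = b
    p = np.convolve(pa, pb)
    m = np.convolve(ma, pb) + np.convolve(pa, mb)
    return p, m


def _trim(p: np.ndarray, m: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    keep = np.nonzero(p > tol)[0]
    if len(keep) == 0:
        return p[:1], m[:1]
    return p[: keep[-1] + 1], m[: keep[-1] + 1]


def _element_power(element: str, count: int, theta: float | None = None,
                   tol: float = 1e-14) -> tuple[np.ndarray, np.ndarray]:
    """Lattice of ``count`` i.i.d. atoms, by binary exponentiation."""
    if count == 0:
        return np.array([1.0]), np.array([0.0])
    if theta is None:
        return _element_power_fixed(element, count, tol)
    return _element_power_uncached(element, count, theta, tol)


@functools.cache
def _element_power_fixed(element: str, count: int, tol: float):
    # natural-abundance powers recur across peptides; results are shared and
    # must never be mutated by callers
    return _element_power_uncached(element, count, None, tol)


def _element_power_uncached(element, count, theta, tol):
    base = _atom_lattice(element, theta)
    result: tuple[np.ndarray, np.ndarray] | None = None
    sq = base
    k = count
    while k:
        if k & 1:
            result = sq if result is None else _convolve_moment(result, sq)
            result = _trim(*result, tol)
        k >>= 1
        if k:
            sq = _trim(*_convolve_moment(sq, sq), tol)
    assert result is not None
    return result


def chos_lattice(comp: ElementalComposition, tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """(probability, mass-moment) lattice of the fixed-abundance C/H/O/S part
    of a composition (nitrogen excluded)."""
    out = (np.array([1.0]), np.array([0.0]))
    for el in ("c", "h", "o", "s"):
        cnt = getattr(comp, el)
        if cnt:
            out = _trim(*_convolve_moment(out, _element_power(el, cnt)), tol)
    return out


def isotope_distribution(
    comp: ElementalComposition, theta: float, truncate: float = 1e-10
) -> IsotopeDistribution:
    """Aggregated isotopologue distribution of ``comp`` at ¹⁵N fraction theta.

    Peaks with relative abundance below ``truncate`` are dropped and the
    remainder renormalised to 1.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must lie in [0, 1], got {theta}")
    p, m = chos_lattice(comp)
    if comp.n:
        p, m = _convolve_moment((p, m), _element_power("n", comp.n, theta))
    keep = p >= truncate
    if not keep.any():  # degenerate empty composition
        keep[np.argmax(p)] = True
    idx = np.nonzero(keep)[0]
    p_kept = p[idx]
    mean_mass = m[idx] / p_kept
    p_kept = p_kept / p_kept.sum()
    return IsotopeDistribution(neutron_index=idx, neutral_mass=mean_mass, abundance=p_kept)


def most_abundant_mass(dist: IsotopeDistribution) -> float:
    """Neutral mass of the highest-abundance lattice peak (ties -> lower mass)."""
    if len(dist) == 0:
        raise ValueError("empty isotope distribution")
    return float(dist.neutral_mass[int(np.argmax(dist.abundance))])


def peptide_most_abundant_mass(sequence: str, theta: float) -> float:
    """Most abundant neutral mass of a peptide at theta."""
    return most_abundant_mass(isotope_distribution(peptide_composition(sequence), theta))


# --------------------------------------------------------------------------
# Fragment ions
# --------------------------------------------------------------------------


def _fragment_composition(sequence: str, ion_type: str, index: int) -> ElementalComposition:
    if ion_type not in ("b", "y"):
        raise ValueError(f"ion_type must be 'b' or 'y', got {ion_type!r}")
    if not 1 <= index <= len(sequence) - 1:
        raise ValueError(
            f"fragment index {index} out of range for a {len(sequence)}-residue peptide"
        )
    table = residue_compositions()
    if ion_type == "b":
        part = sequence[:index]
        comp = ElementalComposition()
    else:
        part = sequence[len(sequence) - index:]
        comp = WATER
    for aa in part:
        if aa not in table:
            raise ValueError(f"unknown residue {aa!r} in {sequence!r}")
        comp = comp + table[aa]
    return comp


def fragment_mz(sequence: str, ion_type: str, index: int, charge: int, theta: float) -> float:
    """m/z of the most abundant isotopologue of a b or y fragment at theta.

    b = N-terminal residues; y = C-terminal residues + water; protonation
    adds ``charge`` protons: m/z = (neutral + z * proton) / z.
    """
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    comp = _fragment_composition(sequence, ion_type, index)
    neutral = most_abundant_mass(isotope_distribution(comp, theta))
    return (neutral + charge * PROTON_MASS) / charge


# --------------------------------------------------------------------------
# Vectorised lattice engine (shared by search and simulator)
# --------------------------------------------------------------------------


def binomial_rows(n_max: int, theta: float) -> np.ndarray:
    """Matrix B with B[n, k] = Binomial(n, theta) pmf at k, for n = 0..n_max.

    Built by the Pascal recurrence, so a single call yields the pmf for every
    nitrogen count at once (each peptide/fragment reads its own row).
    """
    B = np.zeros((n_max + 1, n_max + 1))
    B[0, 0] = 1.0
    for n in range(1, n_max + 1):
        B[n, : n + 1] = B[n - 1, : n + 1] * (1.0 - theta)
        B[n, 1 : n + 1] += B[n - 1, :n] * theta
    return B


def _is_grid_theta(theta: float) -> bool:
    """True when theta sits on the 1-atom%-resolution grid (cacheable)."""
    return abs(theta * 100.0 - round(theta * 100.0)) < 1e-9


class LatticeEngine:
    """Fast most-abundant-mass evaluation over many (composition, theta) pairs.

    The isotopologue lattice of any CHNOS composition factorises as
    conv(CHOS part, nitrogen binomial).  The CHOS part is theta-independent
    and short; the nitrogen binomial depends only on (n, theta).  Binomial
    matrices are cached for atom%-grid thetas (the search evaluates the same
    101 values for every spectrum), so per-peptide evaluation reduces to a
    short shifted-add convolution plus an argmax.
    """

    def __init__(self):
        self._binom_cache: dict[float, np.ndarray] = {}

    def binom(self, theta: float, n_req: int) -> np.ndarray:
        """Binomial pmf rows for n = 0..n_req at this theta (cached on-grid)."""
        cacheable = _is_grid_theta(theta)
        key = round(theta * 100.0) / 100.0 if cacheable else None
        if cacheable:
            B = self._binom_cache.get(key)
            if B is not None and B.shape[0] > n_req:
                return B
        B = binomial_rows(n_req, theta)
        if cacheable:
            self._binom_cache[key] = B
        return B

    @staticmethod
    def _n_mass_moment(Bn: np.ndarray, n: np.ndarray) -> np.ndarray:
        """Mass moment of the nitrogen part: B[n,k] * (n*m14 + k*shift)."""
        k = np.arange(Bn.shape[1])
        return Bn * (n[:, None] * MASS_14N + k[None, :] * N15_SHIFT)

    @staticmethod
    def pack_parts(
        chos_parts: Sequence[tuple[np.ndarray, np.ndarray]]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Pad variable-width CHOS lattices into (F, Fm) row matrices."""
        D = max(len(p) for p, _ in chos_parts)
        m = len(chos_parts)
        F = np.zeros((m, D))
        Fm = np.zeros((m, D))
        for i, (p, mm) in enumerate(chos_parts):
            F[i, : len(p)] = p
            Fm[i, : len(p)] = mm
        return F, Fm

    def most_abundant_packed(
        self,
        F: np.ndarray,
        Fm: np.ndarray,
        n_counts: np.ndarray,
        theta: float | np.ndarray,
    ) -> np.ndarray:
        """Most-abundant neutral masses of packed compositions.

        ``theta`` is either one atom fraction for all rows or a per-row
        array; the conv(CHOS, binomial) lattice is built by shifted adds and
        the abundance-weighted mean mass at the argmax index returned.
        """
        n_counts = np.asarray(n_counts, dtype=np.int64)
        m, D = F.shape
        if m == 0:
            return np.zeros(0)
        n_req = int(n_counts.max(initial=0))
        K = n_req + 1
        if np.isscalar(theta) or getattr(theta, "ndim", 0) == 0:
            B = self.binom(float(theta), n_req)
            Bn = B[n_counts, :K]
        else:
            theta = np.asarray(theta, dtype=float)
            Bn = np.empty((m, K))
            for th in np.unique(theta):
                rows = theta == th
                B = self.binom(float(th), n_req)
                Bn[rows] = B[n_counts[rows], :K]
        Bm = self._n_mass_moment(Bn, n_counts)
        P = np.zeros((m, K + D - 1))
        M = np.zeros((m, K + D - 1))
        for d in range(D):
            P[:, d : d + K] += F[:, d, None] * Bn
            M[:, d : d + K] += Fm[:, d, None] * Bn + F[:, d, None] * Bm
        j = np.argmax(P, axis=1)
        rows = np.arange(m)
        return M[rows, j] / P[rows, j]

    def most_abundant_table(
        self,
        chos_parts: Sequence[tuple[np.ndarray, np.ndarray]],
        n_counts: np.ndarray,
        theta: float,
    ) -> np.ndarray:
        """Most-abundant neutral mass of each composition at one theta."""
        if len(chos_parts) == 0:
            return np.zeros(0)
        F, Fm = self.pack_parts(chos_parts)
        return self.most_abundant_packed(F, Fm, np.asarray(n_counts), theta)


def peptide_chos_prefix_lattices(
    sequence: str, tol: float = 1e-9
) -> tuple[list[tuple[np.ndarray, np.ndarray]], np.ndarray]:
    """Per-prefix CHOS lattices and nitrogen counts for fragment ladders.

    Returns lattices for prefixes of length 1..len(sequence); the full-length
    entry is the residue sum without water.  Built incrementally so a whole
    ladder costs one short convolution per residue.
    """
    table = residue_compositions()
    lattices: list[tuple[np.ndarray, np.ndarray]] = []
    n_counts = np.zeros(len(sequence), dtype=np.int64)
    acc = (np.array([1.0]), np.array([0.0]))
    n = 0
    for i, aa in enumerate(sequence):
        comp = table[aa]
        acc = _trim(*_convolve_moment(acc, _residue_chos_lattice(aa)), tol)
        n += comp.n
        lattices.append(acc)
        n_counts[i] = n
    return lattices, n_counts


@functools.cache
def _residue_chos_lattice(aa: str) -> tuple[np.ndarray, np.ndarray]:
    return chos_lattice(residue_compositions()[aa], 1e-12)
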