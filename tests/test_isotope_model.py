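"""Peptide chemistry: compositions, masses, and isotopologue distributions
under variable ¹⁵N enrichment, checked against closed forms and a brute-force
isotopologue enumeration oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protsip.isotope_model import (
    N15_SHIFT,
    PROTON_MASS,
    ElementalComposition,
    LatticeEngine,
    _ELEMENT_ISOTOPES,
    chos_lattice,
    fragment_mz,
    isotope_distribution,
    monoisotopic_mass,
    most_abundant_mass,
    nitrogen_count,
    peptide_composition,
    peptide_most_abundant_mass,
    residue_compositions,
)

RESIDUES = sorted(residue_compositions())


class TestComposition:
    def test_single_residue_plus_water(self):
        assert peptide_composition("G") == ElementalComposition(c=2, h=5, n=1, o=2)

    def test_two_glycines(self):
        # hand summation: 2 x C2H3NO + H2O
        assert peptide_composition("GG") == ElementalComposition(c=4, h=8, n=2, o=3)

    def test_unknown_residue_named(self):
        with pytest.raises(ValueError, match="'B'"):
            peptide_composition("GAB")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            peptide_composition("")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ElementalComposition(c=-1)

    @pytest.mark.parametrize("aa,n", [("G", 1), ("K", 2), ("R", 4), ("H", 3), ("W", 2)])
    def test_nitrogen_counts(self, aa, n):
        assert nitrogen_count(peptide_composition(aa)) == n

    def test_mean_nitrogen_per_residue_of_tryptic_peptides(self):
        # simulated tryptic peptides carry backbone N plus side-chain N from
        # K/R/N/Q/H/W; the average should sit between 1.2 and 1.5 per residue
        from protsip.database import tryptic_digest
        from protsip.synthetic_data import SimulationConfig, simulate_proteome

        records, _ = simulate_proteome(SimulationConfig(n_proteins=40, seed=7))
        ratios = []
        for rec in records:
            for frag in tryptic_digest(rec.sequence):
                comp = peptide_composition(frag.sequence)
                ratios.append(comp.n / len(frag.sequence))
        assert 1.2 <= np.mean(ratios) <= 1.5


class TestAbundanceModel:
    def test_element_abundances_sum_to_one(self):
        for el, isotopes in _ELEMENT_ISOTOPES.items():
            if el == "n":  # parameterised by theta at run time
                continue
            assert sum(ab for _, ab in isotopes) == pytest.approx(1.0, abs=1e-12)

    def test_masses_strictly_increasing_within_element(self):
        for isotopes in _ELEMENT_ISOTOPES.values():
            masses = [m for m, _ in isotopes]
            assert masses == sorted(masses)
            assert len(set(masses)) == len(masses)


class TestMonoisotopicMass:
    def test_water(self):
        assert monoisotopic_mass(ElementalComposition(h=2, o=1)) == pytest.approx(18.01056, abs=1e-5)

    def test_glycine(self):
        assert monoisotopic_mass(peptide_composition("G")) == pytest.approx(75.03203, abs=1e-5)

    def test_empty_composition_is_zero(self):
        assert monoisotopic_mass(ElementalComposition()) == 0.0

    def test_additivity(self):
        a = peptide_composition("PEPT")
        b = peptide_composition("IDE")
        total = monoisotopic_mass(a) + monoisotopic_mass(b)
        assert monoisotopic_mass(a + b) == pytest.approx(total, abs=1e-9)


def brute_force_distribution(comp: ElementalComposition, theta: float):
    """Exhaustive enumeration over every isotopologue (small compositions
    only): the independent oracle for the lattice convolution."""
    atoms = []
    for el in ("c", "h", "n", "o", "s"):
        isotopes = _ELEMENT_ISOTOPES[el]
        base = round(isotopes[0][0])
        opts = []
        for mass, ab in isotopes:
            if el == "n":
                ab = (1 - theta) if round(mass) - base == 0 else theta
            opts.append((round(mass) - base, mass, ab))
        atoms.extend([opts] * getattr(comp, el))
    agg: dict[int, list[float]] = {}
    for combo in itertools.product(*atoms):
        idx = sum(c[0] for c in combo)
        mass = sum(c[1] for c in combo)
        prob = float(np.prod([c[2] for c in combo]))
        agg.setdefault(idx, [0.0, 0.0])
        agg[idx][0] += prob
        agg[idx][1] += prob * mass
    return {k: (p, m / p) for k, (p, m) in sorted(agg.items()) if p > 0}


class TestIsotopeDistribution:
    def test_single_nitrogen_binomial(self):
        d = isotope_distribution(ElementalComposition(n=1), 0.3)
        assert list(d.neutron_index) == [0, 1]
        assert d.abundance == pytest.approx([0.7, 0.3])

    def test_theta_out_of_range(self):
        with pytest.raises(ValueError):
            isotope_distribution(ElementalComposition(n=1), 1.5)

    @pytest.mark.parametrize(
        "comp,theta",
        [
            (ElementalComposition(c=1, n=2), 0.5),
            (ElementalComposition(c=2, h=1, n=1, o=1), 0.2),
            (ElementalComposition(s=1, n=2, o=1), 0.37),
            (ElementalComposition(c=3, n=3), 0.0),
        ],
    )
    def test_matches_brute_force_enumeration(self, comp, theta):
        oracle = brute_force_distribution(comp, theta)
        d = isotope_distribution(comp, theta, truncate=1e-30)
        got = dict(zip(d.neutron_index.tolist(), zip(d.abundance, d.neutral_mass)))
        for idx, (p, m) in oracle.items():
            if p < 1e-12:
                continue
            assert got[idx][0] == pytest.approx(p, abs=1e-9)
            assert got[idx][1] == pytest.approx(m, abs=1e-9)

    @settings(max_examples=60, deadline=None)
    @given(
        st.text(alphabet=RESIDUES, min_size=1, max_size=40),
        st.floats(min_value=0.0, max_value=1.0),
    )
    def test_abundances_normalised(self, seq, theta):
        d = isotope_distribution(peptide_composition(seq), theta)
        assert d.abundance.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(d.neutron_index) > 0)
        assert np.all(np.diff(d.neutral_mass) > 0)


class TestMostAbundantMass:
    def test_unlabelled_small_peptide_is_monoisotopic(self):
        comp = peptide_composition("PEPTIDE")  # < 1000 Da
        d = isotope_distribution(comp, 0.0)
        assert most_abundant_mass(d) == pytest.approx(monoisotopic_mass(comp), abs=1e-9)

    def test_full_labelling_shift(self):
        for seq in ("PEPTIDEK", "GLSDGEWQK", "ACDEFGHIK"):
            comp = peptide_composition(seq)
            shift = peptide_most_abundant_mass(seq, 1.0) - monoisotopic_mass(comp)
            assert shift == pytest.approx(comp.n * N15_SHIFT, abs=1e-3)

    def test_monotone_in_theta(self):
        # non-decreasing up to the within-index mixing effect: as theta grows
        # the abundance at a fixed neutron index shifts from 13C-containing
        # toward 15N-containing isotopologues, which can lower the index's
        # mean mass by a few mDa
        seq = "LSAMPERK"
        masses = [peptide_most_abundant_mass(seq, t / 100) for t in range(0, 101)]
        assert all(b >= a - 0.01 for a, b in zip(masses, masses[1:]))
        assert masses[-1] > masses[0] + 10  # net shift ~ n x 0.997 Da

    def test_empty_distribution_rejected(self):
        import protsip.isotope_model as im

        empty = im.IsotopeDistribution(np.array([]), np.array([]), np.array([]))
        with pytest.raises(ValueError):
            most_abundant_mass(empty)


class TestFragmentMz:
    def test_b1_y1_of_gg(self):
        assert fragment_mz("GG", "b", 1, 1, 0.0) == pytest.approx(58.02874, abs=1e-4)
        assert fragment_mz("GG", "y", 1, 1, 0.0) == pytest.approx(76.03930, abs=1e-4)

    def test_index_out_of_range(self):
        with pytest.raises(ValueError):
            fragment_mz("GG", "b", 2, 1, 0.0)
        with pytest.raises(ValueError):
            fragment_mz("GG", "y", 0, 1, 0.0)

    def test_bad_charge_and_ion_type(self):
        with pytest.raises(ValueError):
            fragment_mz("GG", "b", 1, 0, 0.0)
        with pytest.raises(ValueError):
            fragment_mz("GG", "a", 1, 1, 0.0)

    @settings(max_examples=25, deadline=None)
    @given(st.text(alphabet=RESIDUES, min_size=2, max_size=15))
    def test_by_complementarity(self, seq):
        # on the singly protonated scale: b_i + y_(L-i) = M(neutral) + 2 protons
        M = monoisotopic_mass(peptide_composition(seq))
        for i in range(1, len(seq)):
            b = fragment_mz(seq, "b", i, 1, 0.0)
            y = fragment_mz(seq, "y", len(seq) - i, 1, 0.0)
            assert b + y == pytest.approx(M + 2 * PROTON_MASS, abs=2e-3)

    def test_doubly_charged(self):
        neutral = fragment_mz("PEPTIDEK", "y", 4, 1, 0.0) - PROTON_MASS
        assert fragment_mz("PEPTIDEK", "y", 4, 2, 0.0) == pytest.approx(
            (neutral + 2 * PROTON_MASS) / 2, abs=1e-9
        )


class TestLatticeEngine:
    def test_agrees_with_general_path(self):
        rng = np.random.default_rng(1)
        engine = LatticeEngine()
        peptides = ["PEPTIDEK", "GLSDGEWQQVLNVWGK", "ACDEFGHIKLMNPQRSTVWY", "RRRKKH"]
        parts = [chos_lattice(peptide_composition(p)) for p in peptides]
        ns = np.array([peptide_composition(p).n for p in peptides])
        for theta in (0.0, 0.05, 0.31, 0.49, 0.97, 1.0):
            fast = engine.most_abundant_table(parts, ns, theta)
            slow = np.array([peptide_most_abundant_mass(p, theta) for p in peptides])
            assert fast == pytest.approx(slow, abs=1e-6)

    def test_mixed_theta_rows(self):
        engine = LatticeEngine()
        peptides = ["PEPTIDEK", "PEPTIDEK", "GLSDGEWQK"]
        parts = [chos_lattice(peptide_composition(p)) for p in peptides]
        ns = np.array([peptide_composition(p).n for p in peptides])
        F, Fm = LatticeEngine.pack_parts(parts)
        got = engine.most_abundant_packed(F, Fm, ns, np.array([0.0, 0.49, 0.1]))
        expect = [
            peptide_most_abundant_mass("PEPTIDEK", 0.0),
            peptide_most_abundant_mass("PEPTIDEK", 0.49),
            peptide_most_abundant_mass("GLSDGEWQK", 0.1),
        ]
        assert got == pytest.approx(expect, abs=1e-6)
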