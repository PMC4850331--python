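"""Spectral grid search: precursor windows, candidate generation, the b/y
fit + mass-accuracy score, and whole-grid atom% recovery."""

import numpy as np
import pytest

from protsip.database import ProteinRecord, build_search_space, make_decoys
from protsip.isotope_model import PROTON_MASS, LatticeEngine, peptide_most_abundant_mass
from protsip.sip_search import (
    MCRA_PTM_SET,
    PTMSpec,
    SearchConfig,
    SearchIndex,
    Spectrum,
    enumerate_ptm_variants,
    fragment_neutral_masses,
    generate_candidates,
    precursor_windows,
    read_mgf,
    score_psm,
    search_spectrum,
    write_mgf,
)

ENGINE = LatticeEngine()


def make_self_spectrum(peptide: str, theta_pct: float, charge: int = 2,
                       scan_id: str = "s1") -> Spectrum:
    """Noiseless spectrum of a peptide at a given atom%: precursor at the
    most-abundant isotopologue, all b/y ions present at exact masses."""
    theta = theta_pct / 100.0
    neutral = peptide_most_abundant_mass(peptide, theta)
    charges = [1] if charge < 2 else [1, 2]
    frags, _ = fragment_neutral_masses(peptide, theta, ENGINE)
    mz = np.concatenate([(frags + z * PROTON_MASS) / z for z in charges])
    intensity = np.linspace(100.0, 10.0, len(mz))
    return Spectrum(
        id=scan_id,
        precursor_mz=(neutral + charge * PROTON_MASS) / charge,
        charge=charge,
        mz=mz,
        intensity=intensity,
    )


@pytest.fixture(scope="module")
def tiny_index():
    records = make_decoys(
        [
            ProteinRecord("p1", "MMMKLSAMPERKGGWADFK"),
            ProteinRecord("p2", "MWNKTAYIAEKQNPFLR"),
        ]
    )
    space = build_search_space(records, max_missed=1, min_len=5, max_len=53)
    return SearchIndex(space, SearchConfig())


class TestPrecursorWindows:
    def test_exactly_seven(self):
        wins = precursor_windows(1200.0, SearchConfig())
        assert len(wins) == 7

    def test_centre_window_is_parent_mass(self):
        cfg = SearchConfig()
        wins = precursor_windows(1200.0, cfg)
        lo, hi = wins[3]
        assert (lo + hi) / 2 == pytest.approx(1200.0)
        assert hi - lo == pytest.approx(2 * cfg.precursor_tol)

    def test_ascending_and_disjoint_at_default_tolerance(self):
        wins = precursor_windows(900.0, SearchConfig())
        for (lo1, hi1), (lo2, hi2) in zip(wins, wins[1:]):
            assert hi1 < lo2  # 0.05 < spacing/2

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            precursor_windows(0.0, SearchConfig())

    def test_seven_offsets_enforced(self):
        with pytest.raises(ValueError):
            SearchConfig(window_offsets=(-1, 0, 1))


class TestCandidateGeneration:
    def test_window_test_equals_brute_force(self, tiny_index):
        cfg = tiny_index.config
        rng = np.random.default_rng(4)
        masses0 = tiny_index.base_masses[tiny_index.theta_index(0)]
        obs_list = rng.uniform(masses0.min() - 2, masses0.max() + 2, size=1000)
        for obs in obs_list:
            got = set(map(int, tiny_index.candidates_at(obs, 0)))
            expect = set()
            for v in range(len(tiny_index.var_entry)):
                theo = masses0[tiny_index.var_entry[v]] + tiny_index.var_delta[v]
                if any(
                    abs(obs - (theo + k * cfg.neutron_spacing)) <= cfg.precursor_tol
                    for k in cfg.window_offsets
                ):
                    expect.add(v)
            assert got == expect

    def test_round_trip_candidate_present(self, tiny_index):
        sp = make_self_spectrum("LSAMPERK", 30.0)
        cands = {e.sequence for e, _ in generate_candidates(sp, tiny_index, 30.0)}
        assert "LSAMPERK" in cands

    def test_far_theta_not_candidate(self, tiny_index):
        sp = make_self_spectrum("LSAMPERK", 0.0)  # 12 nitrogens unlabelled
        cands = {e.sequence for e, _ in generate_candidates(sp, tiny_index, 80.0)}
        assert "LSAMPERK" not in cands

    def test_empty_search_space(self):
        idx = SearchIndex({}, SearchConfig())
        sp = make_self_spectrum("LSAMPERK", 0.0)
        assert len(idx.candidates_at(sp.neutral_mass, 0.0)) == 0


class TestScore:
    def test_noiseless_self_spectrum_perfect(self):
        sp = make_self_spectrum("LSAMPERK", 30.0)
        sc = score_psm(sp, "LSAMPERK", (), 30.0, SearchConfig(), ENGINE)
        assert sc.fragment_fit == pytest.approx(1.0, abs=1e-9)
        assert sc.mass_accuracy == pytest.approx(1.0, abs=1e-6)

    def test_random_far_peaks_zero_fit(self):
        sp = make_self_spectrum("LSAMPERK", 0.0)
        noise = Spectrum("n", sp.precursor_mz, 2,
                         mz=np.array([3000.0, 3100.0, 3200.0]),
                         intensity=np.array([5.0, 5.0, 5.0]))
        sc = score_psm(noise, "LSAMPERK", (), 0.0, SearchConfig(), ENGINE)
        assert sc.fragment_fit == 0.0

    def test_empty_spectrum_scores_zero_with_flag(self):
        sp = Spectrum("e", 500.0, 2, mz=np.array([]), intensity=np.array([]))
        sc = score_psm(sp, "LSAMPERK", (), 0.0, SearchConfig(), ENGINE)
        assert sc.total == 0.0
        assert sc.empty_spectrum

    def test_invariance_to_permutation_and_scaling(self):
        sp = make_self_spectrum("TAYIAEK", 10.0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(sp.mz))
        sp2 = Spectrum("s2", sp.precursor_mz, sp.charge,
                       mz=sp.mz[perm], intensity=7.3 * sp.intensity[perm])
        a = score_psm(sp, "TAYIAEK", (), 10.0, SearchConfig(), ENGINE)
        b = score_psm(sp2, "TAYIAEK", (), 10.0, SearchConfig(), ENGINE)
        assert a.total == pytest.approx(b.total, abs=1e-12)

    def test_generating_peptide_tops_ranking(self, small_run):
        """On noisy seeded spectra the generating peptide should win the
        whole-grid ranking nearly always."""
        psms, ledger = small_run["psms"], small_run["ledger"]
        hits = sum(1 for p in psms if ledger.spectra[p.spectrum_id].peptide == p.peptide)
        assert len(psms) >= 95
        assert hits / len(psms) >= 0.95

    def test_decoy_scores_not_above_targets(self, small_run):
        scores_t = [p.score for p in small_run["psms"] if not p.is_decoy]
        scores_d = [p.score for p in small_run["psms"] if p.is_decoy]
        if scores_d:
            assert np.median(scores_d) <= np.median(scores_t)


class TestSearchSpectrum:
    def test_round_trip_theta_sweep(self):
        """Noiseless spectra across theta 0..95: the recovered atom% sits
        within one grid step of the truth.

        The atom% grid resolution of the search scales as ~100/(n+1) for a
        peptide with n nitrogens (the isotopologue mode must move), so the
        sweep uses nitrogen-rich tryptic peptides (n >= 20)."""
        peptides = ("NQHWNQHNQER", "QNHQNHWQNK", "HNQRPHNQWHK")
        records = make_decoys(
            [ProteinRecord(f"p{i}", "MMMK" + pep + "GGGWAK")
             for i, pep in enumerate(peptides)]
        )
        space = build_search_space(records, max_missed=0, min_len=5, max_len=53)
        index = SearchIndex(space, SearchConfig())
        assert all(pep in space and space[pep].n_nitrogen >= 20 for pep in peptides)
        errors = []
        for theta in range(0, 100, 5):
            for pep in peptides:
                sp = make_self_spectrum(pep, float(theta))
                psm = search_spectrum(sp, index)
                assert psm is not None and psm.peptide == pep
                errors.append(abs(psm.theta_hat - theta))
        assert np.mean(np.array(errors) <= 1.0) >= 0.99

    def test_unlabelled_recovers_zero(self, tiny_index):
        sp = make_self_spectrum("TAYIAEK", 0.0)
        psm = search_spectrum(sp, tiny_index)
        assert psm.theta_hat == 0.0

    def test_tie_breaks_to_lower_theta(self, tiny_index):
        # an unlabelled short peptide predicts identical spectra over several
        # low grid atom% values; the tie rule must return the lowest
        sp = make_self_spectrum("GGWADFK", 0.0)
        psm = search_spectrum(sp, tiny_index)
        assert psm.theta_hat == 0.0

    def test_no_candidates_returns_none(self, tiny_index):
        sp = Spectrum("x", 4000.0, 2, np.array([500.0]), np.array([1.0]))
        assert search_spectrum(sp, tiny_index) is None

    def test_unmodified_preferred_over_ptm_variant(self):
        records = make_decoys([ProteinRecord("p1", "MMMKLSAMPERKGGWADFK")])
        space = build_search_space(records, max_missed=1, min_len=5, max_len=53)
        cfg = SearchConfig(ptm_set=MCRA_PTM_SET, max_ptms_per_peptide=1)
        idx = SearchIndex(space, cfg)
        sp = make_self_spectrum("LSAMPERK", 0.0)
        psm = search_spectrum(sp, idx)
        assert psm.peptide == "LSAMPERK"
        assert psm.ptm_assignment == ()


class TestPTMVariants:
    def test_enumeration_counts_and_uniqueness(self):
        cfg = SearchConfig(ptm_set=MCRA_PTM_SET, max_ptms_per_peptide=2)
        variants = enumerate_ptm_variants("KAYK", cfg)
        assert () in variants
        assert len(variants) == len(set(variants))
        for v in variants:
            assert len(v) <= 2
            assert len({pos for pos, _, _ in v}) == len(v)

    def test_no_ptms_configured(self):
        assert enumerate_ptm_variants("KAYK", SearchConfig()) == [()]

    def test_invalid_ptm_spec(self):
        with pytest.raises(ValueError):
            PTMSpec("null", frozenset("K"), 0.0)
        with pytest.raises(ValueError):
            PTMSpec("none", frozenset(), 14.0)


class TestMgfIO:
    def test_round_trip_and_determinism(self, tmp_path):
        spectra = [make_self_spectrum("LSAMPERK", 30.0, scan_id="scan=1"),
                   make_self_spectrum("TAYIAEK", 0.0, scan_id="scan=2")]
        p1, p2 = tmp_path / "a.mgf", tmp_path / "b.mgf"
        write_mgf(spectra, p1)
        write_mgf(spectra, p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = read_mgf(p1)
        assert [s.id for s in back] == ["scan=1", "scan=2"]
        assert back[0].charge == 2
        assert back[0].precursor_mz == pytest.approx(spectra[0].precursor_mz, abs=1e-5)
        assert back[0].mz == pytest.approx(spectra[0].mz, abs=1e-4)
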