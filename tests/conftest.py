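"""Shared fixtures: small helper datasets and the two session-scoped
benchmark runs used by the acceptance-level tests."""

from __future__ import annotations

import numpy as np
import pytest

from protsip.database import build_search_space, deduplicate_records, make_decoys
from protsip.identification import best_psm_per_peptide, estimate_fdr, filter_at_fdr
from protsip.sip_search import SearchConfig, SearchIndex, search_spectra
from protsip.synthetic_data import SimulationConfig, simulate_dataset


def run_search_pipeline(sim: SimulationConfig, search: SearchConfig | None = None) -> dict:
    """Simulate, search, and FDR-filter one dataset; return all artefacts."""
    records, spectra, ledger = simulate_dataset(sim)
    space = build_search_space(make_decoys(deduplicate_records(records)))
    index = SearchIndex(space, search or SearchConfig())
    psms = search_spectra(spectra, index)
    peptide_records = best_psm_per_peptide(psms)
    accepted, threshold = filter_at_fdr(peptide_records, 0.01)
    return {
        "config": sim,
        "records": records,
        "spectra": spectra,
        "ledger": ledger,
        "space": space,
        "index": index,
        "psms": psms,
        "peptide_records": peptide_records,
        "accepted": accepted,
        "threshold": threshold,
        "decoy_fdr": estimate_fdr(peptide_records, threshold),
    }


@pytest.fixture(scope="session")
def benchmark_run() -> dict:
    """The standard synthetic benchmark: 300 proteins, 2000 spectra, 30% of
    proteins labelled with the enriched mode at 49 atom%."""
    return run_search_pipeline(
        SimulationConfig(n_proteins=300, n_spectra=2000, enriched_fraction=0.3,
                         theta_peak=49.0, seed=17)
    )


@pytest.fixture(scope="session")
def bimodal_run() -> dict:
    """Bimodal-recovery benchmark: both labelling arms equally represented so
    the enriched-pool histogram is well populated."""
    return run_search_pipeline(
        SimulationConfig(n_proteins=120, n_spectra=2000, enriched_fraction=0.5,
                         theta_peak=49.0, seed=17)
    )


@pytest.fixture(scope="session")
def small_run() -> dict:
    """A quick noisy dataset shared by ranking/FDR sanity tests."""
    return run_search_pipeline(SimulationConfig(n_proteins=30, n_spectra=100, seed=3))
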