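"""Pipeline orchestration: simulate → search → filter → enrich → bins.

``run_pipeline`` wires the stages together, writes every intermediate table
as TSV, and records a run manifest (config snapshot, seed, package version,
input digests, per-stage row counts and the thresholds actually applied) so
a run can be traced and reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bin_contrasts import (
    contrasts_frame,
    relative_abundances,
    report_major_bins,
    variance_contributions,
)
from .database import (
    ProteinRecord,
    build_search_space,
    deduplicate_records,
    make_decoys,
    write_fasta,
)
from .enrichment_stats import (
    EnrichmentConfig,
    classify,
    histogram,
    histogram_modes,
    pool_summary,
    protein_enrichment,
    write_enrichment_table,
)
from .identification import (
    IdentificationConfig,
    best_psm_per_peptide,
    filter_at_fdr,
    infer_proteins,
    write_accepted_peptides,
)
from .sip_search import (
    SearchConfig,
    SearchIndex,
    search_spectra,
    write_mgf,
    write_psms,
)
from .synthetic_data import SimulationConfig, simulate_dataset, write_annotations

logger = logging.getLogger("protsip")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    identification: IdentificationConfig = field(default_factory=IdentificationConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    enrichment_rule: str = "fixed"
    bin_min_fraction: float = 0.01

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "simulation" in raw:
            kwargs["simulation"] = SimulationConfig(**raw["simulation"])
        if "search" in raw:
            sr = dict(raw["search"])
            if "theta_grid" in sr:
                sr["theta_grid"] = tuple(sr["theta_grid"])
            if "window_offsets" in sr:
                sr["window_offsets"] = tuple(sr["window_offsets"])
            kwargs["search"] = SearchConfig(**sr)
        if "identification" in raw:
            kwargs["identification"] = IdentificationConfig(**raw["identification"])
        if "enrichment" in raw:
            kwargs["enrichment"] = EnrichmentConfig(**raw["enrichment"])
        for key in ("enrichment_rule", "bin_min_fraction"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """In-memory view of one run: the tables every stage produced."""

    records: list[ProteinRecord]
    ledger: "object"
    psms: list
    peptide_records: list
    accepted: list
    score_threshold: float
    calls: list
    groups_1tp: list
    groups_2tp: list
    protein_report: pd.DataFrame
    summary: dict
    contrasts: dict[str, pd.DataFrame]
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _asdict_config(cfg) -> dict:
    d = dataclasses.asdict(cfg)

    def clean(x):
        if isinstance(x, dict):
            return {str(k): clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, frozenset):
            return sorted(x)
        if isinstance(x, (np.integer, np.floating)):
            return x.item()
        return x

    return clean(d)


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    write_spectra: bool = False,
) -> PipelineResult:
    """Execute the full analysis on a simulated dataset and write reports.

    Outputs under ``outdir``: the simulated database (FASTA + annotations),
    truth ledger, PSMs, accepted peptides, protein report under both
    reporting criteria, per-peptide enrichment calls, the atom% histogram,
    taxonomy/function bin contrasts, a per-sample summary, and
    ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.simulation.seed,
        "config": {
            "simulation": _asdict_config(config.simulation),
            "search": _asdict_config(config.search),
            "identification": _asdict_config(config.identification),
            "enrichment": _asdict_config(config.enrichment),
            "enrichment_rule": config.enrichment_rule,
            "bin_min_fraction": config.bin_min_fraction,
        },
        "stages": {},
    }

    stage = "simulate"
    try:
        records, spectra, ledger = simulate_dataset(config.simulation)
        write_fasta(records, outdir / "database.fasta")
        write_annotations(records, outdir / "annotations.tsv")
        ledger.write(outdir)
        if write_spectra:
            write_mgf(spectra, outdir / "spectra.mgf")
        manifest["stages"][stage] = {
            "n_proteins": len(records),
            "n_spectra": len(spectra),
        }
        manifest["inputs"] = {
            "database.fasta": _sha256(outdir / "database.fasta"),
            "annotations.tsv": _sha256(outdir / "annotations.tsv"),
        }
        logger.info("simulated %d proteins, %d spectra", len(records), len(spectra))

        stage = "search"
        targets = deduplicate_records(records)
        space = build_search_space(make_decoys(targets))
        index = SearchIndex(space, config.search)
        psms = search_spectra(spectra, index)
        write_psms(psms, outdir / "psms.tsv")
        manifest["stages"][stage] = {
            "n_search_peptides": len(space),
            "n_psms": len(psms),
        }
        logger.info("search space %d peptides; %d PSMs", len(space), len(psms))

        stage = "filter"
        peptide_records = best_psm_per_peptide(psms)
        accepted, threshold = filter_at_fdr(
            peptide_records, config.identification.fdr_level
        )
        write_accepted_peptides(accepted, space, outdir / "accepted_peptides.tsv")
        from .identification import estimate_fdr

        fdr_at_cut = estimate_fdr(peptide_records, threshold)
        manifest["stages"][stage] = {
            "n_peptide_records": len(peptide_records),
            "n_accepted": len(accepted),
            "score_threshold": threshold,
            "decoy_fdr_estimate": fdr_at_cut,
            "fdr_level": config.identification.fdr_level,
        }
        logger.info(
            "accepted %d peptides at score >= %.4f (decoy FDR %.4f)",
            len(accepted), threshold, fdr_at_cut,
        )

        stage = "infer"
        id_cfg = config.identification
        groups_1tp = infer_proteins(
            accepted, space,
            IdentificationConfig(id_cfg.fdr_level, 1, id_cfg.unique_peptide_min),
        )
        groups_2tp = infer_proteins(
            accepted, space,
            IdentificationConfig(id_cfg.fdr_level, 2, id_cfg.unique_peptide_min),
        )
        manifest["stages"][stage] = {
            "n_groups_1tp1up": len(groups_1tp),
            "n_groups_2tp1up": len(groups_2tp),
        }

        stage = "enrich"
        calls = classify(accepted, config.enrichment, rule=config.enrichment_rule)
        write_enrichment_table(calls, outdir / "enrichment.tsv")
        mean_atom, pct_enriched = pool_summary(calls)
        lowers, counts = histogram(calls, config.enrichment.histogram_bin)
        pd.DataFrame({"bin_lower": lowers, "count": counts}).to_csv(
            outdir / "histogram.csv", index=False
        )
        unenriched_mode, enriched_mode = histogram_modes(
            calls, config.enrichment.histogram_bin, config.enrichment.enriched_threshold
        )
        summary = {
            "mean_atom_percent": round(mean_atom, 1),
            "percent_enriched_peptides": round(pct_enriched, 1),
            "unenriched_mode": unenriched_mode,
            "enriched_mode": enriched_mode,
            "enrichment_threshold": config.enrichment.enriched_threshold,
        }
        pd.DataFrame([summary]).to_csv(outdir / "summary.tsv", sep="\t", index=False)
        manifest["stages"][stage] = dict(summary)
        logger.info(
            "mean atom%% %.1f, %.1f%% enriched peptides",
            mean_atom, pct_enriched,
        )

        stage = "proteins"
        calls_by_pep = {c.peptide: c for c in calls}
        rec_by_id = {r.id: r for r in records}
        rows = []
        for g in groups_1tp:
            member_calls = [calls_by_pep[p] for p in g.peptides if p in calls_by_pep]
            rec = rec_by_id.get(g.group_id)
            rows.append(
                {
                    "group_id": g.group_id,
                    "members": ";".join(g.members),
                    "taxonomy_bin": getattr(rec, "taxonomy_bin", "unassigned"),
                    "function_bin": getattr(rec, "function_bin", "unassigned"),
                    "n_total_peptides": g.n_total_peptides,
                    "n_unique_peptides": g.n_unique_peptides,
                    "enriched": protein_enrichment(member_calls) if member_calls else False,
                    "passes_1tp1up": True,
                    "passes_2tp1up": g.group_id in {x.group_id for x in groups_2tp},
                }
            )
        protein_report = pd.DataFrame(
            rows,
            columns=[
                "group_id", "members", "taxonomy_bin", "function_bin",
                "n_total_peptides", "n_unique_peptides", "enriched",
                "passes_1tp1up", "passes_2tp1up",
            ],
        )
        protein_report.to_csv(outdir / "protein_report.tsv", sep="\t", index=False)

        stage = "bins"
        contrasts: dict[str, pd.DataFrame] = {}
        for key in ("taxonomy", "function"):
            report_2tp = protein_report[protein_report["passes_2tp1up"]]
            if (
                len(report_2tp) == 0
                or report_2tp["enriched"].all()
                or not report_2tp["enriched"].any()
            ):
                logger.info("skipping %s contrasts: one pool is empty", key)
                continue
            ra_e = relative_abundances(report_2tp, key, "enriched")
            ra_u = relative_abundances(report_2tp, key, "unenriched")
            cons = variance_contributions(ra_e, ra_u)
            major, cumulative = report_major_bins(cons, config.bin_min_fraction)
            df = contrasts_frame(cons)
            df.to_csv(outdir / f"bin_contrasts_{key}.tsv", sep="\t", index=False)
            contrasts[key] = df
            manifest["stages"].setdefault(stage, {})[key] = {
                "n_major_bins": len(major),
                "cumulative_variance_fraction": round(cumulative, 4),
            }

        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return PipelineResult(
            records=records,
            ledger=ledger,
            psms=psms,
            peptide_records=peptide_records,
            accepted=accepted,
            score_threshold=threshold,
            calls=calls,
            groups_1tp=groups_1tp,
            groups_2tp=groups_2tp,
            protein_report=protein_report,
            summary=summary,
            contrasts=contrasts,
            manifest=manifest,
        )
    except Exception:
        logger.error("pipeline failed in stage %r; partial outputs kept in %s", stage, outdir)
        raise
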