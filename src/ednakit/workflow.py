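"""End-to-end orchestration of the downstream pipeline.

Chains the per-module operations in the canonical order — screen hits,
calibrate thresholds, assign, collapse, merge barcodes, decontaminate,
rarefy, aggregate — so analyses, the CLI and the test bed all run the exact
same path. Each step stays individually importable from its own module;
this is glue, not logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import assignment, community, decontam
from .io import AuditLog, Checklist, Lineage, PipelineConfig, ReadCountTable, taxon_lineages
from .synthetic_data import SimulationConfig, simulate_study

__all__ = ["PipelineResult", "run_pipeline", "run_synthetic_pipeline"]


@dataclass
class PipelineResult:
    """Artifacts of one dataset's run, in processing order."""

    thresholds: dict[str, assignment.ThresholdSet]
    assignments: dict[str, dict[str, assignment.Assignment]]
    collapsed: dict[str, ReadCountTable]
    merged: ReadCountTable
    filtered: ReadCountTable
    rarefied: ReadCountTable
    sites: community.CommunityMatrix
    samples: community.CommunityMatrix
    audit: AuditLog = field(default_factory=AuditLog)


def run_pipeline(
    hits_by_barcode: dict[str, list],
    counts_by_barcode: dict[str, ReadCountTable],
    lineages: dict[str, Lineage],
    checklist: Checklist | None,
    blacklist: set[str],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run screening through aggregation for one season's datasets.

    ``hits_by_barcode`` and ``counts_by_barcode`` share barcode keys; count
    tables must share replicate columns so merged taxa can be summed
    per replicate.
    """
    cfg = config or PipelineConfig()
    audit = AuditLog()
    by_name = taxon_lineages(lineages)

    thresholds: dict[str, assignment.ThresholdSet] = {}
    assignments: dict[str, dict[str, assignment.Assignment]] = {}
    collapsed: dict[str, ReadCountTable] = {}
    defaults = assignment.ThresholdSet(
        species_band=(cfg.species_band_low, cfg.species_band_high),
        genus_min=cfg.default_genus_min,
        family_min=cfg.default_family_min,
    )
    for barcode, hits in hits_by_barcode.items():
        screened = assignment.screen_hits(
            hits, cfg.min_coverage, cfg.min_identity, cfg.max_hits_per_query
        )
        thresholds[barcode] = assignment.calibrate_thresholds(
            screened, lineages,
            percentile=cfg.calibration_percentile,
            mapping=cfg.calibration_mapping,
            min_per_level=cfg.calibration_min_n,
            defaults=defaults,
            barcode_id=barcode,
        )
        assignments[barcode] = assignment.assign_all(
            screened, thresholds[barcode], checklist, lineages, barcode
        )
        collapsed[barcode] = assignment.collapse_taxa(
            counts_by_barcode[barcode], assignments[barcode], audit=audit
        )
    merged = assignment.merge_count_tables(list(collapsed.values()))

    filtered = decontam.blacklist_filter(merged, blacklist, by_name, audit=audit)
    filtered = decontam.control_frequency_filter(filtered, audit=audit,
                                                 mode=cfg.frequency_mode)
    filtered = decontam.replicate_support_filter(
        filtered, min_reps=cfg.min_replicates, scope=cfg.replicate_scope, audit=audit
    )

    rarefied = community.rarefy_replicates(
        filtered, depth=cfg.rarefaction_depth, seed=cfg.seed,
        drop_below=cfg.drop_below_depth,
    )
    sites = community.aggregate(rarefied, "site")
    samples = community.aggregate(rarefied, "water_sample")
    return PipelineResult(
        thresholds=thresholds, assignments=assignments, collapsed=collapsed,
        merged=merged, filtered=filtered, rarefied=rarefied,
        sites=sites, samples=samples, audit=audit,
    )


def run_synthetic_pipeline(
    cfg: SimulationConfig,
    config: PipelineConfig | None = None,
    barcodes: tuple[str, ...] = ("mifish", "riaz"),
    season: str = "2016",
) -> tuple[PipelineResult, dict]:
    """Simulate a study under ``cfg`` and run the full pipeline on it.

    Returns the pipeline result and the simulation bundle (including ground
    truth) so callers can score recovery against what was generated.
    """
    study = simulate_study(cfg, barcodes=barcodes, season=season)
    lineages = study["truth"].lineages
    pipeline_cfg = config or PipelineConfig(seed=cfg.seed)
    result = run_pipeline(
        hits_by_barcode=study["hits"],
        counts_by_barcode=study["counts"],
        lineages=lineages,
        checklist=study["checklist"],
        blacklist=study["blacklist"],
        config=pipeline_cfg,
    )
    return result, study
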