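"""Taxonomic assignment of query sequences from BLAST hit tables.

The workflow: screen hits on coverage/identity, calibrate rank-specific
identity thresholds from the screened hits themselves, assign each query to
species, genus or family via a tie-aware cascade with regional-checklist
tie-breaking, consolidate assignments across barcodes, and collapse the
read-count table to assigned taxa.

Threshold calibration follows the data-driven recipe: for each query the
mean percent identity of its hits at each relationship level (congeneric,
confamilial non-congeneric, ordinal non-confamilial) is computed against the
best-hit anchor taxon, the per-query means are pooled across queries, and a
percentile (default the 95th) of each pooled distribution becomes a
threshold. Under the default ``mapping="adjacent"`` the threshold for
assigning at rank *r* is taken from the distribution one level broader:
congeneric identities bound the species call (the species band itself stays
fixed at [99, 100]), confamilial identities set ``genus_min`` and ordinal
identities set ``family_min``. ``mapping="direct"`` instead reads
``genus_min`` off the congeneric and ``family_min`` off the confamilial
distribution.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AuditLog, BlastHit, Checklist, FormatError, Lineage, ReadCountTable

__all__ = [
    "ThresholdSet",
    "Assignment",
    "AssignmentError",
    "screen_hits",
    "calibrate_thresholds",
    "assign_query",
    "assign_all",
    "merge_across_barcodes",
    "merge_count_tables",
    "collapse_taxa",
]

RANK_ORDER = {"species": 0, "genus": 1, "family": 2, "unassigned": 3}


class AssignmentError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdSet:
    """Rank-specific identity thresholds for one barcode.

    The species band is a closed interval; genus and family minima are strict
    (">") lower bounds, following the convention thresholds are printed in.
    """

    barcode_id: str = ""
    species_band: tuple[float, float] = (99.0, 100.0)
    genus_min: float = 93.0
    family_min: float = 89.0
    calibrated: bool = False
    diagnostics: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (self.family_min < self.genus_min < self.species_band[0] <= 100.0):
            raise AssignmentError(
                f"thresholds must satisfy family_min < genus_min < species floor <= 100; "
                f"got {self.family_min}, {self.genus_min}, {self.species_band}"
            )


@dataclass(frozen=True)
class Assignment:
    query_id: str
    assigned_rank: str  # species | genus | family | unassigned
    assigned_taxon: str
    best_identity: float
    tie_broken_by_checklist: bool = False
    supporting_barcodes: frozenset = frozenset()

    def __post_init__(self) -> None:
        if (self.assigned_rank == "unassigned") != (self.assigned_taxon == ""):
            raise AssignmentError("assigned_taxon must be empty iff rank is unassigned")


# ---------------------------------------------------------------------------
# Hit screening
# ---------------------------------------------------------------------------

def screen_hits(
    hits: list[BlastHit],
    min_coverage: float = 90.0,
    min_identity: float = 80.0,
    max_hits_per_query: int = 40,
) -> list[BlastHit]:
    """Keep hits with coverage >= ``min_coverage`` and identity >= ``min_identity``,
    at most ``max_hits_per_query`` per query by descending bitscore.

    Ties in bitscore are broken by descending identity, then subject
    accession, so the kept set is deterministic.
    """
    by_query: dict[str, list[BlastHit]] = defaultdict(list)
    order: list[str] = []
    for h in hits:
        if h.query_coverage >= min_coverage and h.percent_identity >= min_identity:
            if h.query_id not in by_query:
                order.append(h.query_id)
            by_query[h.query_id].append(h)
    kept: list[BlastHit] = []
    for q in order:
        ranked = sorted(
            by_query[q],
            key=lambda h: (-h.bitscore, -h.percent_identity, h.subject_accession),
        )
        kept.extend(ranked[:max_hits_per_query])
    return kept


# ---------------------------------------------------------------------------
# Threshold calibration
# ---------------------------------------------------------------------------

def _relationship(anchor: Lineage, other: Lineage) -> str | None:
    """Relationship of ``other`` to the anchor taxon, or None if incomparable."""
    if anchor.species and other.species and anchor.species == other.species:
        return "same_species"
    if anchor.genus and other.genus and anchor.genus == other.genus:
        return "same_genus"
    if anchor.family and other.family and anchor.family == other.family:
        return "same_family"
    if anchor.order and other.order and anchor.order == other.order:
        return "same_order"
    return None


def pooled_level_means(
    hits: list[BlastHit], lineages: dict[str, Lineage]
) -> dict[str, list[float]]:
    """Per-query mean identities at each relationship level, pooled across queries.

    The anchor for each query is the taxon of its best hit (highest identity,
    ties broken by bitscore).
    """
    by_query: dict[str, list[BlastHit]] = defaultdict(list)
    for h in hits:
        by_query[h.query_id].append(h)
    pooled: dict[str, list[float]] = {"same_genus": [], "same_family": [], "same_order": []}
    for q, qhits in by_query.items():
        best = max(qhits, key=lambda h: (h.percent_identity, h.bitscore))
        try:
            anchor = lineages[best.subject_accession]
        except KeyError:
            raise AssignmentError(
                f"no lineage for subject accession {best.subject_accession!r}"
            ) from None
        level_vals: dict[str, list[float]] = defaultdict(list)
        for h in qhits:
            try:
                lin = lineages[h.subject_accession]
            except KeyError:
                raise AssignmentError(
                    f"no lineage for subject accession {h.subject_accession!r}"
                ) from None
            rel = _relationship(anchor, lin)
            if rel in pooled:
                level_vals[rel].append(h.percent_identity)
        for level, vals in level_vals.items():
            pooled[level].append(float(np.mean(vals)))
    return pooled


def calibrate_thresholds(
    hits: list[BlastHit],
    lineages: dict[str, Lineage],
    percentile: float = 95.0,
    mapping: str = "adjacent",
    min_per_level: int = 5,
    defaults: ThresholdSet | None = None,
    barcode_id: str = "",
) -> ThresholdSet:
    """Calibrate genus/family thresholds from pooled per-query level means.

    Percentiles use linear interpolation between order statistics (position
    ``1 + p (n - 1)``). Levels with fewer than ``min_per_level`` pooled means
    fall back to the configured defaults with a warning. The species band is
    fixed at [99, 100] and is not calibrated.
    """
    if mapping not in ("adjacent", "direct"):
        raise AssignmentError(f"unknown calibration mapping {mapping!r}")
    defaults = defaults or ThresholdSet(barcode_id=barcode_id)
    pooled = pooled_level_means(hits, lineages)

    def pct(level: str) -> float | None:
        vals = pooled[level]
        if len(vals) < min_per_level:
            warnings.warn(
                f"only {len(vals)} pooled means at level {level}; "
                f"falling back to configured default",
                stacklevel=2,
            )
            return None
        return float(np.percentile(vals, percentile))

    if mapping == "adjacent":
        genus_src, family_src, floor_src = "same_family", "same_order", "same_genus"
    else:
        genus_src, family_src, floor_src = "same_genus", "same_family", "same_order"

    genus_min = pct(genus_src)
    family_min = pct(family_src)
    diagnostics = {
        "pooled_n": {k: len(v) for k, v in pooled.items()},
        "percentiles": {
            k: (float(np.percentile(v, percentile)) if v else None)
            for k, v in pooled.items()
        },
        "mapping": mapping,
    }
    if genus_min is None:
        genus_min = defaults.genus_min
    if family_min is None:
        family_min = defaults.family_min
    if not (family_min < genus_min < defaults.species_band[0]):
        warnings.warn(
            f"calibrated thresholds out of order (family {family_min:.2f}, "
            f"genus {genus_min:.2f}); falling back to defaults",
            stacklevel=2,
        )
        genus_min, family_min = defaults.genus_min, defaults.family_min
    floor = diagnostics["percentiles"][floor_src]
    if mapping == "adjacent" and floor is not None and floor < defaults.species_band[0]:
        diagnostics["species_floor_estimate"] = floor
    if mapping == "direct" and floor is not None and family_min <= floor:
        warnings.warn(
            f"family_min {family_min:.2f} does not exceed the {percentile:g}th "
            f"percentile of ordinal identities ({floor:.2f}); family calls may "
            "be unreliable",
            stacklevel=2,
        )
    return ThresholdSet(
        barcode_id=barcode_id,
        species_band=defaults.species_band,
        genus_min=genus_min,
        family_min=family_min,
        calibrated=True,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Per-query assignment cascade
# ---------------------------------------------------------------------------

def _unique_or_checklist(candidates: list[str], rank: str, checklist: Checklist | None):
    """Resolve a candidate set: unique -> it; else a unique checklist member."""
    uniq = sorted(set(candidates))
    if len(uniq) == 1:
        return uniq[0], False
    if checklist is not None:
        on_list = [c for c in uniq if checklist.has(c, rank)]
        if len(on_list) == 1:
            return on_list[0], True
    return None, False


def assign_query(
    hits: list[BlastHit],
    thresholds: ThresholdSet,
    checklist: Checklist | None,
    lineages: dict[str, Lineage],
    barcode_id: str = "",
) -> Assignment:
    """Assign one query's screened hits to species, genus or family.

    Cascade: if the best identity lies in the species band and the best-tied
    hits resolve to a single species (directly or via the regional checklist)
    the query is species-level; otherwise, above ``genus_min``, the shared
    genus of the best-tied hits (same tie-break); otherwise, above
    ``family_min``, the shared family; otherwise unassigned.
    """
    if not hits:
        raise AssignmentError("assign_query needs at least one hit")
    qid = hits[0].query_id
    for h in hits:
        if h.subject_accession not in lineages:
            raise AssignmentError(f"no lineage for subject accession {h.subject_accession!r}")
    best = max(h.percent_identity for h in hits)
    tied = [h for h in hits if h.percent_identity == best]
    tied_lineages = [lineages[h.subject_accession] for h in tied]

    lo, hi = thresholds.species_band
    if lo <= best <= hi:
        species = [l.species for l in tied_lineages if l.species]
        if species:
            taxon, by_list = _unique_or_checklist(species, "species", checklist)
            if taxon is not None:
                return Assignment(qid, "species", taxon, best, by_list,
                                  frozenset({barcode_id} if barcode_id else ()))
    if best > thresholds.genus_min:
        genera = [l.genus for l in tied_lineages if l.genus]
        if genera:
            taxon, by_list = _unique_or_checklist(genera, "genus", checklist)
            if taxon is not None:
                return Assignment(qid, "genus", taxon, best, by_list,
                                  frozenset({barcode_id} if barcode_id else ()))
    if best > thresholds.family_min:
        families = sorted({l.family for l in tied_lineages if l.family})
        if len(families) == 1:
            return Assignment(qid, "family", families[0], best, False,
                              frozenset({barcode_id} if barcode_id else ()))
    return Assignment(qid, "unassigned", "", best, False,
                      frozenset({barcode_id} if barcode_id else ()))


def assign_all(
    hits: list[BlastHit],
    thresholds: ThresholdSet,
    checklist: Checklist | None,
    lineages: dict[str, Lineage],
    barcode_id: str = "",
) -> dict[str, Assignment]:
    by_query: dict[str, list[BlastHit]] = defaultdict(list)
    for h in hits:
        by_query[h.query_id].append(h)
    return {
        q: assign_query(qhits, thresholds, checklist, lineages, barcode_id)
        for q, qhits in by_query.items()
    }


# ---------------------------------------------------------------------------
# Cross-barcode consolidation
# ---------------------------------------------------------------------------

def merge_across_barcodes(
    per_barcode: dict[str, dict[str, Assignment]],
    groups: dict[str, str],
    lineages_by_name: dict[str, Lineage] | None = None,
    audit: AuditLog | None = None,
) -> dict[str, Assignment]:
    """Consolidate per-barcode assignments of the same sequence-variant group.

    ``groups`` maps each query id to a cross-barcode variant-group label. A
    group detected at species level by either barcode is species-level in the
    union. Conflicting species assignments within a group are logged and
    resolved to the lowest common rank their lineages share (genus, then
    family, else unassigned).
    """
    lineages_by_name = lineages_by_name or {}
    grouped: dict[str, list[tuple[str, Assignment]]] = defaultdict(list)
    for barcode, assignments in per_barcode.items():
        for q, a in assignments.items():
            grouped[groups.get(q, q)].append((barcode, a))

    out: dict[str, Assignment] = {}
    for gid, members in grouped.items():
        assigned = [(b, a) for b, a in members if a.assigned_rank != "unassigned"]
        if not assigned:
            a0 = members[0][1]
            out[gid] = replace(
                a0, query_id=gid,
                supporting_barcodes=frozenset(b for b, _ in members),
            )
            continue
        best_rank = min(RANK_ORDER[a.assigned_rank] for _, a in assigned)
        finest = [(b, a) for b, a in assigned if RANK_ORDER[a.assigned_rank] == best_rank]
        taxa = sorted({a.assigned_taxon for _, a in finest})
        rank_name = finest[0][1].assigned_rank
        best_identity = max(a.best_identity for _, a in assigned)
        tie_flag = any(a.tie_broken_by_checklist for _, a in assigned)
        if len(taxa) == 1:
            support = frozenset(b for b, a in finest)
            out[gid] = Assignment(gid, rank_name, taxa[0], best_identity, tie_flag, support)
            continue
        # Conflict: distinct taxa at the finest rank. Resolve to the lowest
        # common ancestor rank of the conflicting lineages.
        lins = [lineages_by_name.get(t) for t in taxa]
        resolved_rank, resolved_taxon = "unassigned", ""
        if all(l is not None for l in lins):
            for rank in ("genus", "family", "order"):
                names = {getattr(l, rank) for l in lins}
                if len(names) == 1 and names != {""}:
                    if rank == "order":
                        break  # coarser than the table retains
                    resolved_rank, resolved_taxon = rank, names.pop()
                    break
        if audit is not None:
            audit.add(
                "merge_across_barcodes", gid, "conflict",
                "conflicting_assignments",
                f"taxa={taxa} resolved_to={resolved_rank}:{resolved_taxon or '-'}",
            )
        out[gid] = Assignment(
            gid, resolved_rank, resolved_taxon, best_identity, tie_flag,
            frozenset(b for b, a in assigned),
        )
    return out


def merge_count_tables(tables: list[ReadCountTable]) -> ReadCountTable:
    """Sum read counts of identical taxa across barcode tables (same columns)."""
    if not tables:
        raise AssignmentError("no tables to merge")
    base = tables[0]
    for t in tables[1:]:
        if list(t.counts.columns) != list(base.counts.columns):
            raise FormatError("tables to merge must share replicate columns")
    summed = (
        pd.concat([t.counts for t in tables])
        .groupby(level=0, sort=True)
        .sum()
    )
    depths = sum(t.depths for t in tables)
    metas = [t.row_meta for t in tables if t.row_meta is not None]
    row_meta = None
    if metas:
        row_meta = pd.concat(metas)
        row_meta = row_meta[~row_meta.index.duplicated()].reindex(summed.index)
    return ReadCountTable(summed, base.sheet, depths=depths, row_meta=row_meta)


# ---------------------------------------------------------------------------
# Collapse to assigned taxa
# ---------------------------------------------------------------------------

def collapse_taxa(
    table: ReadCountTable,
    assignments: dict[str, Assignment],
    audit: AuditLog | None = None,
) -> ReadCountTable:
    """Collapse variant rows to distinct assigned taxa by summing counts.

    Rows not identified to at least family are dropped (and logged). Column
    sums are conserved exactly, minus the dropped rows.
    """
    missing = [r for r in table.taxa if r not in assignments]
    if missing:
        raise AssignmentError(f"rows without an assignment: {missing[:5]}")
    keep_label: dict[str, str] = {}
    rank_of: dict[str, str] = {}
    for row in table.taxa:
        a = assignments[row]
        if a.assigned_rank == "unassigned":
            if audit is not None:
                audit.add("collapse_taxa", row, "dropped", "unassigned",
                          f"best_identity={a.best_identity}")
            continue
        keep_label[row] = a.assigned_taxon
        rank_of[a.assigned_taxon] = a.assigned_rank
    kept = table.counts.loc[list(keep_label)]
    collapsed = kept.groupby([keep_label[r] for r in kept.index], sort=True).sum()
    collapsed.index.name = "taxon"
    row_meta = pd.DataFrame(
        {"rank": [rank_of[t] for t in collapsed.index]}, index=collapsed.index
    )
    return ReadCountTable(collapsed, table.sheet, depths=table.depths, row_meta=row_meta)
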