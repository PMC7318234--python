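"""Contamination filtering of collapsed taxon tables.

Three filters, applied per dataset (barcode x season) in the order
blacklist -> control frequency -> replicate support by default:

* :func:`blacklist_filter` removes taxa (or descendants of taxa) on a
  contaminant blacklist, e.g. domestic animals;
* :func:`control_frequency_filter` removes taxa whose maximum relative
  abundance in a negative-control replicate reaches or exceeds their maximum
  in any water-sample replicate;
* :func:`replicate_support_filter` removes taxa seen in too few PCR
  replicates, either dataset-wide (default: present in at least 2) or within
  each water sample (e.g. at least 3 of 4).

"Frequency" means relative abundance within a replicate, computed against
the replicate's original sequencing depth (carried on the table), so each
filter is idempotent and depth differences between replicates do not
confound the comparison. Every removal is logged to the audit ledger with a
reason code and the numbers behind the decision.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import AuditLog, Lineage, ReadCountTable

__all__ = [
    "control_frequency_filter",
    "blacklist_filter",
    "replicate_support_filter",
]


def control_frequency_filter(
    table: ReadCountTable,
    audit: AuditLog | None = None,
    mode: str = "relative",
) -> ReadCountTable:
    """Remove taxa at least as frequent in a negative control as in any water sample.

    A taxon is removed iff its maximum frequency across control replicates is
    >= its maximum across water-sample replicates and it actually occurs in a
    control. With ``mode="relative"`` (default) frequency is counts divided
    by the replicate's original depth; ``mode="raw"`` compares raw counts.
    """
    if mode not in ("relative", "raw"):
        raise ValueError(f"unknown frequency mode {mode!r}")
    ctrl_ids = table.sheet.control_ids
    if not ctrl_ids:
        warnings.warn("no control columns in table; control-frequency filter is a no-op")
        return table
    freq = table.relative_abundance() if mode == "relative" else table.counts.astype(float)
    max_ctrl = freq[ctrl_ids].max(axis=1)
    sample_ids = table.sheet.sample_ids
    max_sample = (
        freq[sample_ids].max(axis=1) if sample_ids
        else pd.Series(0.0, index=freq.index)
    )
    remove = (max_ctrl >= max_sample) & (max_ctrl > 0)
    if audit is not None:
        for taxon in freq.index[remove]:
            audit.add(
                "control_frequency_filter", taxon, "removed", "control_frequency",
                f"max_control={max_ctrl[taxon]:.6g} max_sample={max_sample[taxon]:.6g}",
            )
    return table.drop_rows(freq.index[remove])


def blacklist_filter(
    table: ReadCountTable,
    blacklist: set[str],
    lineages_by_name: dict[str, Lineage] | None = None,
    audit: AuditLog | None = None,
) -> ReadCountTable:
    """Remove rows whose taxon, or any ancestor of it, is blacklisted.

    Ancestry is resolved through ``lineages_by_name`` (taxon name -> lineage,
    see :func:`ednakit.io.taxon_lineages`). Open nomenclature labels such as
    ``"Bos sp."`` also match a blacklisted genus ``"Bos"``.
    """
    blacklist = set(blacklist)
    if not blacklist:
        return table
    lineages_by_name = lineages_by_name or {}
    remove: list[str] = []
    for taxon in table.taxa:
        names = {taxon}
        if taxon.endswith(" sp."):
            names.add(taxon[: -len(" sp.")])
        lin = lineages_by_name.get(taxon)
        if lin is None and taxon.endswith(" sp."):
            lin = lineages_by_name.get(taxon[: -len(" sp.")])
        if lin is not None:
            names.update(n for n in (lin.species, lin.genus, lin.family, lin.order,
                                     lin.class_) if n)
        matched = names & blacklist
        if matched:
            remove.append(taxon)
            if audit is not None:
                audit.add(
                    "blacklist_filter", taxon, "removed", "blacklisted",
                    f"matched={sorted(matched)}",
                )
    return table.drop_rows(remove)


def replicate_support_filter(
    table: ReadCountTable,
    min_reps: int = 2,
    scope: str = "dataset",
    audit: AuditLog | None = None,
) -> ReadCountTable:
    """Remove taxa supported by too few PCR replicates.

    ``scope="dataset"``: a taxon with nonzero counts in fewer than
    ``min_reps`` water-sample replicates overall is removed (controls do not
    count as support). ``scope="within_sample"``: within each water sample, a
    taxon's counts are zeroed unless nonzero in at least ``min_reps`` of that
    sample's replicates; rows left all-zero are dropped.
    """
    if min_reps < 1:
        raise ValueError("min_reps must be >= 1")
    if scope not in ("dataset", "within_sample"):
        raise ValueError(f"unknown scope {scope!r}")
    sample_ids = table.sheet.sample_ids

    if scope == "dataset":
        support = (table.counts[sample_ids] > 0).sum(axis=1)
        remove = support.index[support < min_reps]
        if audit is not None:
            for taxon in remove:
                audit.add(
                    "replicate_support_filter", taxon, "removed", "single_replicate"
                    if min_reps == 2 else "replicate_support",
                    f"n_replicates={int(support[taxon])} min={min_reps}",
                )
        return table.drop_rows(remove)

    sheet = table.sheet.frame.loc[sample_ids]
    counts = table.counts.copy()
    for ws, cols in sheet.groupby("water_sample_id").groups.items():
        cols = list(cols)
        if min_reps > len(cols):
            raise ValueError(
                f"min_reps={min_reps} exceeds the {len(cols)} replicates of "
                f"water sample {ws!r}"
            )
        block = counts[cols]
        unsupported = (block > 0).sum(axis=1) < min_reps
        zeroed = unsupported & (block.sum(axis=1) > 0)
        counts.loc[unsupported, cols] = 0
        if audit is not None:
            for taxon in block.index[zeroed]:
                audit.add(
                    "replicate_support_filter", taxon, "zeroed", "replicate_support",
                    f"water_sample={ws} min={min_reps}",
                )
    empty = counts.index[(counts[sample_ids].sum(axis=1) == 0)]
    if audit is not None:
        for taxon in empty:
            audit.add(
                "replicate_support_filter", taxon, "removed", "replicate_support",
                "all water-sample counts zeroed",
            )
    return table.with_counts(counts.drop(index=empty))
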