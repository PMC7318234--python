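"""Analysis-ready community matrices.

Rarefies PCR replicates to a common depth (default: the median per-replicate
total, the depth the study design standardises on), aggregates replicates to
water samples or sites, and computes richness summaries including the
surface-versus-deep Welch t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ReadCountTable

__all__ = [
    "CommunityMatrix",
    "median_depth",
    "rarefy_replicates",
    "aggregate",
    "richness_summary",
    "welch_t_test",
]


@dataclass
class CommunityMatrix:
    """Units (sites or water samples) by taxa matrix with unit metadata.

    ``data`` holds counts; ``presence()`` gives the boolean form. ``meta``
    carries habitat and season per unit.
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    level: str  # "water_sample" | "site"

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise ValueError("community matrix must be non-negative")
        self.meta = self.meta.loc[self.data.index]

    def presence(self) -> pd.DataFrame:
        return self.data > 0

    @property
    def units(self) -> list[str]:
        return list(self.data.index)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def median_depth(table: ReadCountTable) -> int:
    """Median of per-replicate totals over water-sample columns, rounded half up.

    With an even number of replicates the two central values are averaged
    before rounding.
    """
    totals = np.sort(table.sample_columns.sum(axis=0).to_numpy())
    if totals.size == 0:
        raise ValueError("no water-sample columns")
    n = totals.size
    if n % 2 == 1:
        med = float(totals[n // 2])
    else:
        med = (float(totals[n // 2 - 1]) + float(totals[n // 2])) / 2.0
    return _round_half_up(med)


def rarefy_replicates(
    table: ReadCountTable,
    depth: int | str = "median",
    seed: int | np.random.Generator = 0,
    drop_below: bool = False,
    log: list | None = None,
) -> ReadCountTable:
    """Subsample each replicate column without replacement to a common depth.

    Columns whose total exceeds ``depth`` are drawn down to exactly ``depth``
    reads (multivariate hypergeometric, i.e. classical rarefaction); columns
    at or below ``depth`` pass unchanged (or are dropped if ``drop_below``),
    and the decision is logged. Deterministic under ``seed``. Depths recorded
    on the result are the post-rarefaction totals.
    """
    if depth == "median":
        depth = median_depth(table)
    depth = int(depth)
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = table.counts.copy()
    dropped: list[str] = []
    for col in counts.columns:
        vec = counts[col].to_numpy()
        total = int(vec.sum())
        if total == 0:
            warnings.warn(f"replicate {col!r} has zero reads; passed unchanged")
            if log is not None:
                log.append((col, total, "all_zero"))
            continue
        if total <= depth:
            if drop_below:
                dropped.append(col)
            if log is not None:
                log.append((col, total, "below_depth"))
            continue
        counts[col] = rng.multivariate_hypergeometric(vec, depth)
    if dropped:
        counts = counts.drop(columns=dropped)
        sheet = table.sheet.subset(counts.columns)
        return ReadCountTable(counts, sheet, row_meta=table.row_meta)
    return ReadCountTable(counts, table.sheet, row_meta=table.row_meta)


def aggregate(table: ReadCountTable, level: str = "site") -> CommunityMatrix:
    """Sum replicate columns to water samples or sites.

    Only water-sample columns (role ``sample``) enter the matrix; a taxon is
    present in a unit if any member replicate has a nonzero count.
    """
    key = {"water_sample": "water_sample_id", "site": "site_id"}.get(level)
    if key is None:
        raise ValueError(f"unknown aggregation level {level!r}")
    sample_ids = table.sheet.sample_ids
    sheet = table.sheet.frame.loc[sample_ids]
    groups = sheet.groupby(key).groups
    data = pd.DataFrame(
        {unit: table.counts[list(cols)].sum(axis=1) for unit, cols in groups.items()}
    ).T
    data = data.sort_index()
    meta_rows = {}
    for unit in data.index:
        block = sheet.loc[groups[unit]]
        meta_rows[unit] = {
            "habitat": block["habitat"].iloc[0],
            "season": block["season"].iloc[0],
            "site_id": block["site_id"].iloc[0],
            "n_replicates": len(block),
        }
    meta = pd.DataFrame.from_dict(meta_rows, orient="index").loc[data.index]
    return CommunityMatrix(data=data, meta=meta, level=level)


def richness_summary(table: ReadCountTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site and per-habitat richness totals, with mean and SE over water samples.

    Totals are union richness over the unit's replicates; the mean and SE are
    taken over the per-water-sample ("filter replicate") richnesses within
    the unit. SE is undefined (NaN) for a single water sample.
    """
    per_sample = aggregate(table, "water_sample")
    pres = per_sample.presence()
    sample_rich = pres.sum(axis=1)

    def summarise(group_key: str) -> pd.DataFrame:
        rows = {}
        for unit, samples in per_sample.meta.groupby(group_key).groups.items():
            samples = list(samples)
            rich = sample_rich[samples]
            total = int(pres.loc[samples].any(axis=0).sum())
            mean = float(rich.mean())
            se = float(rich.std(ddof=1) / math.sqrt(len(rich))) if len(rich) > 1 else float("nan")
            rows[unit] = {
                "total_richness": total,
                "mean_richness": mean,
                "se_richness": se,
                "n_water_samples": len(samples),
            }
        return pd.DataFrame.from_dict(rows, orient="index")

    return summarise("site_id"), summarise("habitat")


def welch_t_test(group_a, group_b) -> tuple[float, float, float]:
    """Two-sided Welch t-test (unequal variances) on per-filter richness.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom.
    Both groups having zero variance is an error.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
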