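"""Beta-diversity indices and clustering.

The centrepiece is the Raup-Crick null-model dissimilarity: for every pair
of sites, pairs of null communities are simulated preserving each site's
richness, species being drawn without replacement either with probability
proportional to their occurrence frequency across sites (the default null)
or equiprobably. The dissimilarity is the probability-scaled position of the
observed shared-species count in the null distribution,

    RC(j, k) = 1 - [ #(s_null < s_obs) + 0.5 #(s_null = s_obs) ] / n_sim,

so sites sharing more species than expected score near 0 and sites sharing
fewer score near 1. Under the equiprobable null the shared count is
hypergeometric, which gives a closed form used for verification.

Also here: Bray-Curtis dissimilarity, UPGMA (average-linkage) clustering
with a pinned lexicographic tie-break, and the rank-based inverse normal
transformation applied before PERMANOVA when group dispersions are
heterogeneous.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode
from skbio.stats.distance import DistanceMatrix

__all__ = [
    "raup_crick",
    "raup_crick_exact_equiprobable",
    "bray_curtis",
    "upgma",
    "clusters_at",
    "inverse_normal_transform",
]


# ---------------------------------------------------------------------------
# Raup-Crick
# ---------------------------------------------------------------------------

def _null_membership(
    rng: np.random.Generator, n_sim: int, weights: np.ndarray, richness: int
) -> np.ndarray:
    """Boolean (n_sim, S) membership of null communities of fixed richness.

    Species are drawn without replacement with inclusion order proportional
    to ``weights`` via exponential-race keys (Gumbel top-k); uniform weights
    reduce to simple random subsets.
    """
    S = weights.size
    if richness >= S:
        return np.ones((n_sim, S), dtype=bool)
    keys = np.log(weights)[None, :] + rng.gumbel(size=(n_sim, S))
    top = np.argpartition(-keys, richness, axis=1)[:, :richness]
    member = np.zeros((n_sim, S), dtype=bool)
    np.put_along_axis(member, top, True, axis=1)
    return member


def raup_crick(
    matrix: pd.DataFrame,
    n_sim: int = 9999,
    null_model: str = "frequency_weighted",
    seed: int | np.random.Generator = 0,
) -> DistanceMatrix:
    """Raup-Crick dissimilarity among the rows of a presence/absence matrix.

    ``matrix``: units x taxa, truthy = present. The null preserves each
    unit's richness; per pair, ``n_sim`` independent pairs of null
    communities are drawn. Deterministic under ``seed``; the taxon axis is
    canonicalised by sorted label first, so the result is exactly invariant
    to taxon-column permutation. Units with zero taxa get dissimilarity 1 to
    every other unit, with a warning.
    """
    if null_model not in ("frequency_weighted", "equiprobable"):
        raise ValueError(f"unknown null model {null_model!r}")
    pres = matrix.astype(bool)
    if pres.shape[0] < 2:
        raise ValueError("need at least 2 units")
    pres = pres[sorted(pres.columns)]
    X = pres.to_numpy()
    n_units, S = X.shape
    occ = X.sum(axis=0).astype(float)
    if null_model == "frequency_weighted":
        weights = np.where(occ > 0, occ, 1e-12)
    else:
        weights = np.ones(S)
    richness = X.sum(axis=1)
    empty = richness == 0
    if empty.any():
        import warnings

        warnings.warn(
            f"{int(empty.sum())} unit(s) with zero taxa; their dissimilarities set to 1"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    D = np.zeros((n_units, n_units))
    for j in range(n_units):
        for k in range(j + 1, n_units):
            if empty[j] or empty[k]:
                D[j, k] = D[k, j] = 1.0
                continue
            s_obs = int(np.sum(X[j] & X[k]))
            a = _null_membership(rng, n_sim, weights, int(richness[j]))
            b = _null_membership(rng, n_sim, weights, int(richness[k]))
            s_null = np.sum(a & b, axis=1)
            less = np.count_nonzero(s_null < s_obs)
            equal = np.count_nonzero(s_null == s_obs)
            D[j, k] = D[k, j] = 1.0 - (less + 0.5 * equal) / n_sim
    return DistanceMatrix(D, ids=[str(i) for i in matrix.index])


def raup_crick_exact_equiprobable(S: int, a: int, b: int, s_obs: int) -> float:
    """Closed-form Raup-Crick value under the equiprobable null.

    With a taxon pool of size ``S`` and fixed richnesses ``a`` and ``b``, the
    null shared count K is hypergeometric; the index is
    ``1 - [P(K < s_obs) + 0.5 P(K = s_obs)]``.
    """
    K = stats.hypergeom(S, a, b)
    return 1.0 - (K.cdf(s_obs - 1) + 0.5 * K.pmf(s_obs))


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity among rows of a non-negative count matrix.

    d(j, k) = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik). A pair of all-zero
    rows has no defined dissimilarity and raises ``ValueError``.
    """
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("Bray-Curtis needs non-negative counts")
    n = X.shape[0]
    D = np.zeros((n, n))
    for j in range(n):
        diff = np.abs(X[j] - X[j + 1:]).sum(axis=1)
        denom = (X[j] + X[j + 1:]).sum(axis=1)
        if np.any(denom == 0):
            k = j + 1 + int(np.flatnonzero(denom == 0)[0])
            raise ValueError(
                f"Bray-Curtis undefined for all-zero pair "
                f"({matrix.index[j]!r}, {matrix.index[k]!r})"
            )
        D[j, j + 1:] = D[j + 1:, j] = diff / denom
    return DistanceMatrix(D, ids=[str(i) for i in matrix.index])


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(dist: DistanceMatrix) -> tuple[TreeNode, list[tuple[str, str, float]]]:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    Clusters merge at the size-weighted mean of all between-cluster pairwise
    distances; ties between candidate merges are broken by the
    lexicographically smallest pair of cluster labels (a cluster is labelled
    by its smallest leaf). Returns an ultrametric tree (node height = merge
    distance / 2, so cophenetic distances reproduce merge distances) and the
    merge list ``(label_a, label_b, merge_distance)``.
    """
    D = np.asarray(dist.data, dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN")
    labels = list(dist.ids)
    n = len(labels)
    # active clusters: label -> (index set into D, height, TreeNode)
    active: dict[str, tuple[list[int], float, TreeNode]] = {
        lab: ([i], 0.0, TreeNode(name=lab, length=None)) for i, lab in enumerate(labels)
    }
    merges: list[tuple[str, str, float]] = []
    while len(active) > 1:
        best: tuple[float, str, str] | None = None
        labs = sorted(active)
        for i, la in enumerate(labs):
            ia = active[la][0]
            for lb in labs[i + 1:]:
                ib = active[lb][0]
                d = float(D[np.ix_(ia, ib)].mean())
                if best is None or d < best[0] or (d == best[0] and (la, lb) < best[1:]):
                    best = (d, la, lb)
        d, la, lb = best
        (ia, ha, ta), (ib, hb, tb) = active.pop(la), active.pop(lb)
        height = d / 2.0
        ta.length = height - ha
        tb.length = height - hb
        parent = TreeNode(children=[ta, tb], length=None)
        active[min(la, lb)] = (ia + ib, height, parent)
        merges.append((la, lb, d))
    (_, _, root) = next(iter(active.values()))
    return root, merges


def clusters_at(merges: list[tuple[str, str, float]], leaves: list[str], k: int) -> list[set[str]]:
    """Cut an agglomeration into ``k`` clusters by replaying the first n-k merges."""
    if not (1 <= k <= len(leaves)):
        raise ValueError("k out of range")
    parent = {lab: {lab} for lab in leaves}
    for la, lb, _ in merges[: len(leaves) - k]:
        merged = parent.pop(la) | parent.pop(lb)
        parent[min(la, lb)] = merged
    return list(parent.values())


# ---------------------------------------------------------------------------
# Inverse normal transformation
# ---------------------------------------------------------------------------

def inverse_normal_transform(dist: DistanceMatrix) -> DistanceMatrix:
    """Blom-score inverse normal transformation of the off-diagonal entries.

    Upper-triangle entries are ranked (ties averaged), mapped to standard
    normal quantiles at (r - 3/8)/(m + 1/4), and shifted by the minimum so
    the result is a non-negative dissimilarity with zero diagonal.
    """
    D = np.asarray(dist.data, dtype=float)
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = D[iu]
    m = vals.size
    if m < 2:
        raise ValueError("need at least 2 off-diagonal entries")
    ranks = stats.rankdata(vals)
    quantiles = stats.norm.ppf((ranks - 0.375) / (m + 0.25))
    shifted = quantiles - quantiles.min()
    out = np.zeros_like(D)
    out[iu] = shifted
    out.T[iu] = shifted
    return DistanceMatrix(out, ids=dist.ids)
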