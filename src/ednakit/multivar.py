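"""Multivariate habitat-discrimination statistics on distance matrices.

PERMANOVA partitions squared dissimilarities among groups directly from the
distance matrix (no embedding):

    SS_total = (1/N) sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2
    F = [SS_among / (g - 1)] / [SS_within / (N - g)],  R^2 = SS_among / SS_total

with a permutation p-value using the (1 + exceedances) / (1 + n_perm)
convention. The dispersion-homogeneity test embeds the matrix by principal
coordinates (positive-eigenvalue axes), measures each unit's distance to its
group centroid, and permutes group labels over those distances. CAP runs a
linear discriminant analysis (equal priors, pooled covariance) on the
leading PCoA axes and scores it by leave-one-out allocation success.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.distance import DistanceMatrix
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "permanova",
    "dispersion_test",
    "pcoa",
    "cap",
    "PermanovaResult",
    "CapResult",
]


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int


@dataclass(frozen=True)
class CapResult:
    m_axes: int
    loo_success: float
    loo_success_by_axes: dict[int, float]
    assignments: pd.Series = field(compare=False, default=None)

    @property
    def success_m1(self) -> float:
        return self.loo_success_by_axes.get(1, float("nan"))

    @property
    def success_m2(self) -> float:
        return self.loo_success_by_axes.get(2, float("nan"))


def _group_array(dist: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, (pd.Series, dict)):
        g = pd.Series(groups)
        return g.loc[list(dist.ids)].to_numpy()
    arr = np.asarray(groups)
    if arr.size != len(dist.ids):
        raise ValueError("groups length must match distance matrix")
    return arr


def _permanova_F(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    N = d2.shape[0]
    iu = np.triu_indices(N, k=1)
    ss_total = d2[iu].sum() / N
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += np.triu(sub, k=1).sum() / idx.size
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = N - n_groups
    if df_within <= 0:
        raise ValueError("PERMANOVA needs N > number of groups")
    F = (ss_among / df_among) / (ss_within / df_within) if ss_within > 0 else np.inf
    R2 = ss_among / ss_total if ss_total > 0 else 0.0
    return F, R2


def permanova(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> PermanovaResult:
    """One-way PERMANOVA of a distance matrix against group labels."""
    labels = _group_array(dist, groups)
    uniq, codes = np.unique(labels, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    d2 = np.asarray(dist.data, dtype=float) ** 2
    F_obs, R2 = _permanova_F(d2, codes, uniq.size)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        F_perm, _ = _permanova_F(d2, perm, uniq.size)
        if F_perm >= F_obs - 1e-10:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(float(F_obs), float(R2), float(p), n_perm)


def pcoa(dist: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinates of a distance matrix.

    Eigendecomposition of the double-centred Gower matrix; coordinates span
    the positive-eigenvalue axes, ordered by descending eigenvalue. Returns
    (coordinates, all eigenvalues).
    """
    D2 = np.asarray(dist.data, dtype=float) ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-10
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    frame = pd.DataFrame(
        coords, index=list(dist.ids),
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    return frame, eigvals


def dispersion_test(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Permutation test of multivariate homogeneity of group dispersions.

    Units are embedded by PCoA (positive axes); each unit's Euclidean
    distance to its group centroid is the dispersion; the one-way ANOVA F on
    those distances is compared with its distribution under group-label
    permutation. Groups of size 1 are excluded with a warning. All-identical
    points give F = 0.
    """
    labels = _group_array(dist, groups)
    coords, _ = pcoa(dist)
    X = coords.to_numpy()
    uniq, counts = np.unique(labels, return_counts=True)
    singletons = set(uniq[counts < 2])
    if singletons:
        warnings.warn(f"excluding singleton groups from dispersion test: {sorted(singletons)}")
        keep = ~np.isin(labels, list(singletons))
        labels, X = labels[keep], X[keep]
        uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 non-singleton groups")
    dists = np.empty(len(labels))
    for g in uniq:
        idx = labels == g
        centroid = X[idx].mean(axis=0)
        dists[idx] = np.linalg.norm(X[idx] - centroid, axis=1)

    def anova_F(vals: np.ndarray, labs: np.ndarray) -> float:
        grand = vals.mean()
        ssb = sum(
            (labs == g).sum() * (vals[labs == g].mean() - grand) ** 2 for g in uniq
        )
        ssw = sum(((vals[labs == g] - vals[labs == g].mean()) ** 2).sum() for g in uniq)
        if ssw == 0:
            return 0.0 if ssb == 0 else np.inf
        return (ssb / (uniq.size - 1)) / (ssw / (len(vals) - uniq.size))

    F_obs = anova_F(dists, labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        F_perm = anova_F(dists, rng.permutation(labels))
        if F_perm >= F_obs - 1e-10:
            exceed += 1
    return float(F_obs), (1 + exceed) / (1 + n_perm)


def cap(
    dist: DistanceMatrix,
    groups,
    m_axes: int | str = "auto",
) -> CapResult:
    """Canonical analysis of principal coordinates with LOO classification.

    PCoA axes are fed to a linear discriminant analysis (equal priors,
    pooled covariance); for each number of leading axes m the leave-one-out
    allocation success is computed. ``m_axes="auto"`` keeps the m maximising
    LOO success (smallest m on ties).
    """
    labels = _group_array(dist, groups)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    coords, eigvals = pcoa(dist)
    X = coords.to_numpy()
    n, n_axes = X.shape
    max_m = min(n_axes, n - uniq.size)
    if isinstance(m_axes, int):
        if m_axes > n_axes:
            raise ValueError(
                f"m_axes={m_axes} exceeds the {n_axes} positive-eigenvalue axes"
            )
        max_m = max(max_m, m_axes)

    def loo_success(m: int) -> tuple[float, np.ndarray]:
        Xm = X[:, :m]
        preds = np.empty(n, dtype=object)
        priors = np.full(uniq.size, 1.0 / uniq.size)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            if np.unique(labels[mask]).size < uniq.size:
                preds[i] = None
                continue
            lda = LinearDiscriminantAnalysis(solver="lsqr", priors=priors)
            lda.fit(Xm[mask], labels[mask])
            preds[i] = lda.predict(Xm[i:i + 1])[0]
        ok = np.array([p == t for p, t in zip(preds, labels)])
        return float(ok.mean()), preds

    by_axes: dict[int, float] = {}
    preds_by_m: dict[int, np.ndarray] = {}
    for m in range(1, max(max_m, 1) + 1):
        try:
            by_axes[m], preds_by_m[m] = loo_success(m)
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate fit
            break
    if m_axes == "auto":
        chosen = max(by_axes, key=lambda m: (by_axes[m], -m))
    else:
        chosen = int(m_axes)
        if chosen not in by_axes:
            by_axes[chosen], preds_by_m[chosen] = loo_success(chosen)
    return CapResult(
        m_axes=chosen,
        loo_success=by_axes[chosen],
        loo_success_by_axes=by_axes,
        assignments=pd.Series(preds_by_m[chosen], index=list(dist.ids)),
    )
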