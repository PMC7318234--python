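"""Species-accumulation curves, species-area model fitting, and extrapolation.

The exact analytic accumulation mean is the classical hypergeometric form

    E[S(n)] = sum_i [ 1 - C(N - f_i, n) / C(N, n) ]

where f_i is the number of the N sampling units occupied by taxon i. The
standard deviation is estimated by permutation of unit orderings (the
resampling analogue of the unconditional SD). Four species-area models are
fitted by multi-start least squares:

    arrhenius:  S = k n^z
    gleason:    S = k + slope * log n
    gitay:      S = (k + slope * log n)^2
    lomolino:   S = Smax / (1 + slope^(log(xmid / n)))      (natural log)

and the model with the lowest Gaussian AIC, n log(RSS/n) + 2 (p + 1), is
used to extrapolate richness to a target number of sites and to express the
observed richness as a fraction of the fitted asymptote (defined for the
Lomolino model only).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "AccumulationCurve",
    "SARFit",
    "accumulation_curve",
    "fit_sar",
    "select_and_extrapolate",
    "sar_predict",
    "percent_of",
    "SAR_MODELS",
]


@dataclass(frozen=True)
class AccumulationCurve:
    n_units: np.ndarray
    mean_richness: np.ndarray
    sd_richness: np.ndarray
    method: str  # "exact_analytic" | "permutation"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.mean_richness) < -1e-9):
            raise ValueError("mean richness must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_units": self.n_units,
                "mean_richness": self.mean_richness,
                "sd_richness": self.sd_richness,
            }
        )


@dataclass(frozen=True)
class SARFit:
    model: str
    parameters: dict[str, float]
    rss: float
    aic: float
    n_points: int
    asymptote: float | None = None

    @property
    def is_asymptotic(self) -> bool:
        return self.asymptote is not None


def accumulation_curve(
    presence: pd.DataFrame,
    method: str = "exact_analytic",
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> AccumulationCurve:
    """Accumulation curve over the rows (sampling units) of a presence matrix.

    ``exact_analytic`` computes the hypergeometric mean exactly and falls
    back to permutation for the SD; ``permutation`` estimates both from
    ``n_perm`` random unit orderings.
    """
    X = presence.to_numpy(dtype=bool)
    N, S = X.shape
    if N < 1:
        raise ValueError("need at least one unit")
    ns = np.arange(1, N + 1)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # permutation richness trajectories (used for SD in both methods)
    rich = np.empty((n_perm, N))
    for r in range(n_perm):
        order = rng.permutation(N)
        seen = np.cumsum(X[order], axis=0) > 0
        rich[r] = seen.sum(axis=1)
    sd = rich.std(axis=0, ddof=1) if n_perm > 1 else np.zeros(N)

    if method == "permutation":
        mean = rich.mean(axis=0)
    elif method == "exact_analytic":
        f = X.sum(axis=0)  # occurrence frequency per taxon
        mean = np.empty(N)
        for i, n in enumerate(ns):
            # C(N - f, n) / C(N, n) as a stable product
            absent = np.ones(S)
            for j in range(n):
                absent *= np.clip((N - f - j), 0, None) / (N - j)
            mean[i] = np.sum(1.0 - absent)
    else:
        raise ValueError(f"unknown method {method!r}")
    return AccumulationCurve(ns, mean, sd, method)


# ---------------------------------------------------------------------------
# Species-area models
# ---------------------------------------------------------------------------

def _arrhenius(n, k, z):
    return k * np.power(n, z)


def _gleason(n, k, slope):
    return k + slope * np.log(n)


def _gitay(n, k, slope):
    return (k + slope * np.log(n)) ** 2


def _lomolino(n, smax, slope, xmid):
    return smax / (1.0 + np.power(slope, np.log(xmid / n)))


SAR_MODELS = {
    "arrhenius": (_arrhenius, ("k", "z")),
    "gleason": (_gleason, ("k", "slope")),
    "gitay": (_gitay, ("k", "slope")),
    "lomolino": (_lomolino, ("smax", "slope", "xmid")),
}


def _aic(rss: float, n: int, n_params: int) -> float:
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + 2 * (n_params + 1)


def _starts(model: str, n: np.ndarray, s: np.ndarray) -> list[np.ndarray]:
    smax_grid = [f * s.max() for f in (1.0, 1.5, 2.0)]
    if model == "lomolino":
        xmids = np.quantile(n, [0.25, 0.5, 0.75])
        return [
            np.array([sm, sl, xm])
            for sm in smax_grid
            for sl in (1.5, 2.0, 4.0)
            for xm in xmids
        ]
    if model == "arrhenius":
        # log-log regression start plus a coarse grid
        z0, logk0 = np.polyfit(np.log(n), np.log(np.clip(s, 1e-6, None)), 1)
        return [np.array([math.exp(logk0), z0])] + [
            np.array([k, z]) for k in (s.max() / 2, s.max()) for z in (0.25, 0.5)
        ]
    # gleason / gitay: linear in (k, slope) after transform; one start suffices
    target = s if model == "gleason" else np.sqrt(np.clip(s, 0, None))
    slope0, k0 = np.polyfit(np.log(n), target, 1)
    return [np.array([k0, slope0])]


_BOUNDS = {
    "arrhenius": ([1e-9, -np.inf], np.inf),
    "gleason": (-np.inf, np.inf),
    "gitay": (-np.inf, np.inf),
    "lomolino": ([1e-9, 1.0 + 1e-9, 1e-9], np.inf),
}


def fit_sar(curve: AccumulationCurve, model: str) -> SARFit:
    """Least-squares fit of one species-area model to an accumulation curve.

    Multi-start over a deterministic grid of initial values; the best
    converged start by RSS wins. Raises ``RuntimeError`` (carrying the best
    residual seen) if no start converges.
    """
    if model not in SAR_MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(SAR_MODELS)}")
    func, names = SAR_MODELS[model]
    n = np.asarray(curve.n_units, dtype=float)
    s = np.asarray(curve.mean_richness, dtype=float)
    if n.size < len(names):
        raise ValueError(f"{model} needs at least {len(names)} points")

    best_params, best_rss = None, np.inf
    for x0 in _starts(model, n, s):
        try:
            res = least_squares(
                lambda p: func(n, *p) - s, x0,
                bounds=_BOUNDS[model], xtol=1e-15, ftol=1e-15, gtol=1e-15,
                max_nfev=20000,
            )
        except (ValueError, FloatingPointError):
            continue
        rss = float(np.sum(res.fun**2))
        if np.isfinite(rss) and np.all(np.isfinite(res.x)) and rss < best_rss:
            best_rss, best_params = rss, res.x
    if best_params is None:
        raise RuntimeError(f"no start converged for {model}; best RSS {best_rss}")
    params = dict(zip(names, (float(v) for v in best_params)))
    asymptote = params["smax"] if model == "lomolino" else None
    return SARFit(
        model=model,
        parameters=params,
        rss=best_rss,
        aic=_aic(best_rss, n.size, len(names)),
        n_points=n.size,
        asymptote=asymptote,
    )


def sar_predict(fit: SARFit, n) -> np.ndarray:
    func, names = SAR_MODELS[fit.model]
    return func(np.asarray(n, dtype=float), *(fit.parameters[p] for p in names))


def percent_of(part: float, whole: float) -> int:
    """Percentage of ``part`` in ``whole``, rounded to the nearest integer.

    The convention used for every reported detection overlap and
    fraction-of-asymptote figure.
    """
    if whole <= 0:
        raise ValueError("whole must be positive")
    return int(round(100.0 * part / whole))


@dataclass(frozen=True)
class Extrapolation:
    best: SARFit
    all_fits: dict[str, SARFit]
    n_target: int
    predicted_richness: float
    observed_richness: float
    fraction_detected: float | None  # observed / asymptote, None if non-asymptotic

    @property
    def fraction_detected_pct(self) -> int | None:
        if self.fraction_detected is None:
            return None
        return int(round(100 * self.fraction_detected))


def select_and_extrapolate(
    curve: AccumulationCurve,
    models: tuple[str, ...] = ("arrhenius", "gleason", "gitay", "lomolino"),
    n_target: int = 200,
) -> Extrapolation:
    """Fit the candidate models, pick the lowest AIC, extrapolate to ``n_target``.

    The fraction of the asymptote already detected is observed richness at N
    over the fitted asymptote; it is undefined (None) when the winning model
    has no asymptote.
    """
    fits = {}
    for m in models:
        try:
            fits[m] = fit_sar(curve, m)
        except RuntimeError as exc:
            warnings.warn(f"model {m} failed to fit: {exc}")
    if not fits:
        raise RuntimeError("no species-area model could be fitted")
    best = min(fits.values(), key=lambda f: f.aic)
    observed = float(curve.mean_richness[-1])
    predicted = float(sar_predict(best, [n_target])[0])
    fraction = observed / best.asymptote if best.is_asymptotic else None
    return Extrapolation(
        best=best, all_fits=fits, n_target=n_target,
        predicted_richness=predicted, observed_richness=observed,
        fraction_detected=fraction,
    )
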