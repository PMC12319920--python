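"""Diffusion-time-dependence models for MD(Delta) and MK(Delta) curves.

Five candidate models describe how the orientation-averaged diffusivity and
kurtosis vary with diffusion time Delta:

=================  =====================================================  ==
model id           functional form                                         k
=================  =====================================================  ==
disorder1d_md      MD = D_inf + 2 A Delta^(-1/2)                           2
disorder2d3d_md    MD = D_inf + A ln(Delta / t_c) / Delta                  3
disorder1d_mk      MK = K_inf + 2 A Delta^(-1/2)                           2
disorder2d3d_mk    MK = K_inf + A ln(Delta / t_c) / Delta                  3
karger_mk          MK = K0 (2 t_ex/Delta) [1 - (t_ex/Delta)(1 - e^(-Delta/t_ex))]  2
=================  =====================================================  ==

The Delta^(-1/2) tail is the one-dimensional structural-disorder
universality class (intracellular water along processes); the ln(Delta)/Delta
tail is the 2D-3D class (extracellular geometry); the exchange form follows
from the two-compartment model with barrier-limited water exchange. Fits are
unweighted nonlinear least squares on the mean curve with a multi-start
grid; candidates are ranked by the small-sample-corrected Akaike criterion
AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1), ties broken toward fewer
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .synth import karger_mk

__all__ = [
    "MODELS",
    "TimeDependenceCurve",
    "TimeDependenceFit",
    "ModelComparison",
    "eval_model",
    "fit_timedep",
    "aicc",
    "compare_models",
    "models_for_metric",
]


@dataclass(frozen=True)
class ModelDef:
    model_id: str
    metric: str  # "MD" or "MK"
    param_names: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]


MODELS: dict[str, ModelDef] = {
    "disorder1d_md": ModelDef(
        "disorder1d_md", "MD", ("A", "D_inf"), (-np.inf, -np.inf), (np.inf, np.inf)
    ),
    "disorder2d3d_md": ModelDef(
        "disorder2d3d_md", "MD", ("A", "t_c", "D_inf"),
        (-np.inf, 1e-3, -np.inf), (np.inf, 1e3, np.inf),
    ),
    "disorder1d_mk": ModelDef(
        "disorder1d_mk", "MK", ("A", "K_inf"), (-np.inf, -np.inf), (np.inf, np.inf)
    ),
    "disorder2d3d_mk": ModelDef(
        "disorder2d3d_mk", "MK", ("A", "t_c", "K_inf"),
        (-np.inf, 1e-3, -np.inf), (np.inf, 1e3, np.inf),
    ),
    "karger_mk": ModelDef(
        "karger_mk", "MK", ("K0", "t_ex"), (0.0, 1.0), (10.0, 1e3)
    ),
}


def models_for_metric(metric: str) -> list[str]:
    """Applicable candidates: both disorder classes for MD, both plus the
    exchange model for MK."""
    return [m for m, d in MODELS.items() if d.metric == metric.upper()]


def eval_model(model: str, params, delta_big):
    """Evaluate a time-dependence model at diffusion time(s) ``delta_big`` (ms)."""
    delta = np.asarray(delta_big, dtype=float)
    if np.any(delta <= 0):
        raise ValueError("diffusion time must be positive")
    p = np.asarray(params, dtype=float)
    mdef = MODELS[model]
    if p.size != len(mdef.param_names):
        raise ValueError(f"{model} takes {len(mdef.param_names)} parameters")
    if model in ("disorder1d_md", "disorder1d_mk"):
        a, c_inf = p
        out = c_inf + 2.0 * a / np.sqrt(delta)
    elif model in ("disorder2d3d_md", "disorder2d3d_mk"):
        a, t_c, c_inf = p
        if t_c <= 0:
            raise ValueError("correlation time t_c must be positive")
        out = c_inf + a * np.log(delta / t_c) / delta
    elif model == "karger_mk":
        k0, t_ex = p
        if t_ex <= 0:
            raise ValueError("exchange time t_ex must be positive")
        out = karger_mk(k0, t_ex, delta)
    else:  # pragma: no cover
        raise KeyError(model)
    out = np.asarray(out)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TimeDependenceCurve:
    """A mean MD(Delta) or MK(Delta) curve with optional standard errors."""

    delta: np.ndarray
    values: np.ndarray
    se: np.ndarray | None = None
    metric: str = "MK"
    condition: str = "rest"
    laterality: str = "contralateral"

    def __post_init__(self) -> None:
        delta = np.asarray(self.delta, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if delta.ndim != 1 or delta.shape != values.shape:
            raise ValueError("delta and values must be matching 1D arrays")
        if np.any(np.diff(delta) <= 0):
            raise ValueError("delta must be strictly increasing")
        object.__setattr__(self, "delta", delta)
        object.__setattr__(self, "values", values)
        if self.se is not None:
            se = np.asarray(self.se, dtype=float)
            if se.shape != delta.shape:
                raise ValueError("se must match delta")
            object.__setattr__(self, "se", se)

    @property
    def n(self) -> int:
        return self.delta.size

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.metric, self.condition, self.laterality)


@dataclass
class TimeDependenceFit:
    """One fitted model on one curve."""

    model: str
    params: dict[str, float]
    se: dict[str, float]
    rss: float
    n: int
    k: int
    aicc: float | None
    converged: bool = True
    message: str = ""
    covariance: np.ndarray | None = None

    @property
    def undefined_aicc(self) -> bool:
        return self.aicc is None


def aicc(rss: float, n: int, k: int) -> float:
    """Corrected Akaike criterion for a Gaussian-likelihood least-squares fit.

    AIC = n ln(RSS/n) + 2k; AICc = AIC + 2k(k+1)/(n-k-1). Undefined (raises)
    when n <= k + 1; such fits are excluded from model comparison.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (n must exceed k+1)")
    if rss <= 0:
        raise ValueError("AICc requires a positive residual sum of squares")
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _starts(curve: TimeDependenceCurve, model: str) -> list[np.ndarray]:
    """Multi-start initialization grid (documented defaults)."""
    d, y = curve.delta, curve.values
    if model == "karger_mk":
        k0 = max(float(np.max(y)), 1e-3)
        return [np.array([k0, t]) for t in (10.0, 25.0, 50.0, 100.0, 200.0)]
    c_inf = float(np.min(y))
    if model in ("disorder1d_md", "disorder1d_mk"):
        a = (y[0] - y[1]) / (2.0 * (d[0] ** -0.5 - d[1] ** -0.5))
        return [np.array([a, c_inf]), np.array([0.1 * a if a else 0.01, c_inf])]
    # 2D-3D: t_c grid, amplitude from the first point
    starts = []
    for t_c in (0.1, 1.0, 5.0, 10.0, 20.0):
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = np.log(d[0] / t_c) / d[0]
        a = (y[0] - c_inf) / denom if denom != 0 else 0.01
        starts.append(np.array([a, t_c, c_inf]))
    return starts


def fit_timedep(
    curve: TimeDependenceCurve,
    model: str,
    *,
    weighted: bool = False,
) -> TimeDependenceFit:
    """Nonlinear least squares of one model on a mean curve.

    Unweighted by default; ``weighted=True`` scales residuals by 1/SE.
    The best of a fixed multi-start grid wins; parameter covariance comes
    from the Jacobian at the optimum scaled by RSS/(n-k). Deterministic.
    """
    mdef = MODELS[model]
    k = len(mdef.param_names)
    min_points = k + 2  # need n > k + 1 for AICc; >= k+1 to fit at all
    if curve.n < k + 1:
        raise ValueError(f"{model} needs at least {k + 1} points, curve has {curve.n}")
    w = np.ones(curve.n)
    if weighted:
        if curve.se is None or np.any(curve.se <= 0):
            raise ValueError("weighted fit needs positive standard errors")
        w = 1.0 / curve.se

    def residuals(p):
        return (eval_model(model, p, curve.delta) - curve.values) * w

    best = None
    for x0 in _starts(curve, model):
        x0 = np.clip(x0, mdef.lower, mdef.upper)
        try:
            res = least_squares(
                residuals, x0, bounds=(mdef.lower, mdef.upper),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=5000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        return TimeDependenceFit(
            model=model, params={}, se={}, rss=np.nan, n=curve.n, k=k,
            aicc=None, converged=False,
            message="no start converged" if best is None else best.message,
        )

    rss = float(np.sum((eval_model(model, best.x, curve.delta) - curve.values) ** 2))
    jac = best.jac
    dof = max(curve.n - k, 1)
    try:
        cov = np.linalg.inv(jac.T @ jac) * rss / dof
        ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        cov = None
        ses = np.full(k, np.nan)
    try:
        crit = aicc(rss, curve.n, k) if curve.n >= min_points else None
    except ValueError:
        crit = None
    return TimeDependenceFit(
        model=model,
        params=dict(zip(mdef.param_names, map(float, best.x))),
        se=dict(zip(mdef.param_names, map(float, ses))),
        rss=rss,
        n=curve.n,
        k=k,
        aicc=crit,
        converged=True,
        covariance=cov,
    )


@dataclass
class ModelComparison:
    """All candidate fits per curve and the AICc winner for each."""

    fits: dict[tuple[str, str, str], dict[str, TimeDependenceFit]] = field(
        default_factory=dict
    )
    winners: dict[tuple[str, str, str], str] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for key, model_fits in self.fits.items():
            metric, condition, laterality = key
            for model, fit in model_fits.items():
                row = {
                    "metric": metric,
                    "condition": condition,
                    "laterality": laterality,
                    "model": model,
                    "rss": fit.rss,
                    "aicc": fit.aicc,
                    "k": fit.k,
                    "n": fit.n,
                    "converged": fit.converged,
                    "winner": self.winners.get(key) == model,
                }
                for name, val in fit.params.items():
                    row[name] = val
                    row[f"{name}_se"] = fit.se.get(name, np.nan)
                rows.append(row)
        return pd.DataFrame(rows)


def compare_models(
    curves, *, weighted: bool = False
) -> ModelComparison:
    """Fit every applicable model to every curve and flag the AICc winner.

    Fits with undefined AICc or failed convergence are excluded from the
    ranking; exact AICc ties go to the model with fewer parameters.
    """
    comparison = ModelComparison()
    for curve in curves:
        model_fits: dict[str, TimeDependenceFit] = {}
        for model in models_for_metric(curve.metric):
            if curve.n < len(MODELS[model].param_names) + 1:
                continue
            model_fits[model] = fit_timedep(curve, model, weighted=weighted)
        comparison.fits[curve.key] = model_fits
        ranked = [
            (fit.aicc, fit.k, model)
            for model, fit in model_fits.items()
            if fit.converged and fit.aicc is not None
        ]
        if ranked:
            comparison.winners[curve.key] = min(ranked)[2]
    return comparison
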