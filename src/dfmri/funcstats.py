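"""ROI-level rest-vs-stimulus statistics and the BOLD arm.

The diffusion arm aggregates voxel-wise MD/MK maps over anatomical ROIs
(valid voxels only), computes percent changes stimulus vs. rest per
diffusion time, reports the maximum-magnitude change across diffusion
times, and tests the condition effect with a linear mixed model (condition
and diffusion time fixed; run and subject random intercepts, runs nested in
subjects) via a likelihood-ratio test. Benjamini-Hochberg FDR is applied
separately per metric family. The BOLD arm normalizes each epoch by its
14 s pre-stimulus baseline, averages a response function, averages rest and
stimulus timepoints into one amplitude per condition, and runs a voxel-wise
boxcar GLM with discrete-cosine high-pass filtering and Bonferroni
family-wise voxel thresholding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .acquisition import REST, STIMULUS, BlockDesign, schedule_block

__all__ = [
    "GLMResult",
    "roi_aggregate",
    "percent_change",
    "max_abs_change",
    "condition_mixed_test",
    "fdr_adjust",
    "significance_stars",
    "bold_epoch_normalize",
    "bold_condition_average",
    "bold_glm",
]


def roi_aggregate(
    volume: np.ndarray,
    labels: np.ndarray,
    valid_mask: np.ndarray | None = None,
    region_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-ROI mean/SD/SE of a scalar volume over valid voxels.

    Empty ROIs (all voxels masked out) are dropped with a warning. Caller
    attaches metadata columns (metric, condition, diffusion time, run,
    subject, laterality) before pooling into the study-level table.
    """
    volume = np.asarray(volume)
    labels = np.asarray(labels)
    if labels.shape != volume.shape:
        raise ValueError("label volume must align with the data grid")
    if valid_mask is None:
        valid_mask = np.ones_like(labels, dtype=bool)
    rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        sel = (labels == lab) & valid_mask
        n = int(sel.sum())
        if n == 0:
            warnings.warn(f"ROI {lab} empty after masking; row dropped", stacklevel=2)
            continue
        vals = volume[sel]
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        rows.append(
            {
                "roi": region_names.get(int(lab), str(int(lab)))
                if region_names
                else str(int(lab)),
                "label": int(lab),
                "mean": float(vals.mean()),
                "sd": sd,
                "se": sd / np.sqrt(n),
                "n_voxels": n,
            }
        )
    return pd.DataFrame(rows)


def percent_change(rest_mean: float, stim_mean: float) -> float:
    """100 (stimulus - rest) / rest. Undefined (NaN) for a zero rest mean."""
    if rest_mean == 0:
        warnings.warn("zero rest mean: percent change undefined", stacklevel=2)
        return float("nan")
    return 100.0 * (stim_mean - rest_mean) / rest_mean


def max_abs_change(changes, deltas) -> tuple[float, float]:
    """Maximum-magnitude percent change across diffusion times, sign kept.

    Returns ``(change, delta)`` where ``change`` is the element of
    ``changes`` with the largest absolute value.
    """
    changes = np.asarray(changes, dtype=float)
    deltas = np.asarray(deltas, dtype=float)
    i = int(np.nanargmax(np.abs(changes)))
    return float(changes[i]), float(deltas[i])


@dataclass
class MixedTestResult:
    p_value: float
    statistic: float
    fallback: bool
    message: str = ""


def _fit_lmm(df: pd.DataFrame, formula: str, vc: dict | None) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            formula, groups="subject", re_formula="1", vc_formula=vc, data=df
        )
        fit = model.fit(reml=False, method="lbfgs", maxiter=200)
    return float(fit.llf)


def condition_mixed_test(rows: pd.DataFrame) -> MixedTestResult:
    """Likelihood-ratio test of the condition effect in a mixed model.

    Fixed effects: condition plus diffusion time (categorical, when more
    than one diffusion time is present). Random effects: subject intercept
    and run-within-subject intercepts (variance component). The p-value is
    the chi-square(1) tail of twice the ML log-likelihood difference between
    the full model and the model without condition. On a singular or failed
    fit, falls back to a condition-only fixed effect with a subject random
    intercept and flags the result.
    """
    df = rows.copy()
    required = {"value", "condition", "subject", "run"}
    if not required <= set(df.columns):
        raise ValueError(f"rows need columns {sorted(required)}")
    if df["subject"].nunique() < 2:
        raise ValueError("mixed condition test needs at least 2 subjects")
    if df["run"].nunique() < 2:
        raise ValueError("mixed condition test needs at least 2 runs")
    if df["condition"].nunique() != 2:
        raise ValueError("both conditions must be present")
    df["condition"] = pd.Categorical(df["condition"], categories=[REST, STIMULUS])

    fixed = "C(condition)"
    base = "1"
    if "delta" in df.columns and df["delta"].nunique() > 1:
        fixed += " + C(delta)"
        base += " + C(delta)"
    vc = {"run": "0 + C(run)"}
    try:
        llf_full = _fit_lmm(df, f"value ~ {fixed}", vc)
        llf_null = _fit_lmm(df, f"value ~ {base}", vc)
        lr = max(2.0 * (llf_full - llf_null), 0.0)
        if not np.isfinite(lr):
            raise ValueError("non-finite likelihood ratio")
        return MixedTestResult(
            p_value=float(stats.chi2.sf(lr, df=1)), statistic=lr, fallback=False
        )
    except Exception as exc:  # singular fit, convergence failure
        llf_full = _fit_lmm(df, "value ~ C(condition)", None)
        llf_null = _fit_lmm(df, "value ~ 1", None)
        lr = max(2.0 * (llf_full - llf_null), 0.0)
        return MixedTestResult(
            p_value=float(stats.chi2.sf(lr, df=1)),
            statistic=lr,
            fallback=True,
            message=f"fell back to condition-only model: {exc}",
        )


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for one metric family."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def significance_stars(q: float) -> str:
    """Star convention after FDR: * <0.05, ** <0.01, *** <0.001."""
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return ""


# --- BOLD arm -----------------------------------------------------------------

def bold_epoch_normalize(
    series: np.ndarray,
    design: BlockDesign,
    baseline_s: float = 14.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize each epoch by its pre-stimulus baseline and average.

    Each epoch (rest interval then stimulus interval) is divided by the mean
    signal over the ``baseline_s`` seconds immediately preceding stimulation
    onset. Returns ``(epochs, response)`` where ``epochs`` is
    (n_epochs, samples/epoch) and ``response`` the pointwise mean across
    epochs. Epochs whose baseline window is degenerate are dropped with a
    warning.
    """
    series = np.asarray(series, dtype=float)
    per_epoch = design.rest_volumes + design.stim_volumes
    if series.size != design.n_epochs * per_epoch:
        raise ValueError("series length does not cover all epochs")
    n_base = int(round(baseline_s / design.tr))
    if n_base < 1 or n_base > design.rest_volumes:
        raise ValueError("baseline window must fit inside the rest interval")
    epochs = series.reshape(design.n_epochs, per_epoch)
    base = epochs[:, design.rest_volumes - n_base : design.rest_volumes].mean(axis=1)
    keep = base != 0
    if not np.all(keep):
        warnings.warn("epoch with zero baseline dropped", stacklevel=2)
    epochs = epochs[keep] / base[keep, None]
    return epochs, epochs.mean(axis=0)


@dataclass
class ConditionAverage:
    rest_mean: float
    rest_se: float
    stim_mean: float
    stim_se: float
    percent_change: float
    p_value: float


def bold_condition_average(series: np.ndarray, design: BlockDesign) -> ConditionAverage:
    """One amplitude estimate per condition from all interval timepoints.

    Mirrors the sensitivity of the diffusion metrics, which also pool every
    timepoint of each condition into a single per-condition estimate. The
    p-value is a two-sided Welch t-test between rest and stimulus samples.
    """
    series = np.asarray(series, dtype=float)
    schedule = schedule_block(design)
    if series.size != schedule.n_volumes:
        raise ValueError("series length does not match the design")
    rest = series[schedule.labels == REST]
    stim = series[schedule.labels == STIMULUS]
    t = stats.ttest_ind(stim, rest, equal_var=False)
    return ConditionAverage(
        rest_mean=float(rest.mean()),
        rest_se=float(rest.std(ddof=1) / np.sqrt(rest.size)),
        stim_mean=float(stim.mean()),
        stim_se=float(stim.std(ddof=1) / np.sqrt(stim.size)),
        percent_change=percent_change(rest.mean(), stim.mean()),
        p_value=float(t.pvalue),
    )


@dataclass
class GLMResult:
    """Voxel-wise boxcar GLM output."""

    beta: np.ndarray
    tstat: np.ndarray
    activation_mask: np.ndarray
    analysis_mask: np.ndarray
    cluster_sizes: list[int]
    p_threshold: float
    dof: int


def _dct_basis(n: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine high-pass regressors with frequency below cutoff."""
    total_s = n * tr
    n_comp = int(np.floor(2.0 * total_s * cutoff_hz))
    t = np.arange(n)
    cols = [
        np.sqrt(2.0 / n) * np.cos(np.pi * (2 * t + 1) * k / (2 * n))
        for k in range(1, n_comp + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n, 0))


def bold_glm(
    series4d: np.ndarray,
    design: BlockDesign,
    mask: np.ndarray,
    *,
    cortex_mask: np.ndarray | None = None,
    alpha: float = 0.05,
    highpass_hz: float = 0.01,
    depth_fraction: float = 0.10,
) -> GLMResult:
    """Boxcar GLM with DCT high-pass filtering and Bonferroni FWE at ``alpha``.

    The design matrix is [intercept, DCT high-pass regressors, boxcar];
    activation is one-sided (positive response). No cluster-size threshold
    is applied. When ``cortex_mask`` is given, voxels with mean signal below
    ``depth_fraction`` of the mean cortical signal are removed from the
    analysis mask (surface-coil depth cutoff).
    """
    series4d = np.asarray(series4d, dtype=float)
    n_t = series4d.shape[-1]
    schedule = schedule_block(design)
    if n_t != schedule.n_volumes:
        raise ValueError(
            f"series has {n_t} volumes but the design implies {schedule.n_volumes}"
        )
    mask = np.asarray(mask, dtype=bool).copy()
    mean_img = series4d.mean(axis=-1)
    if cortex_mask is not None:
        cortex_level = float(mean_img[np.asarray(cortex_mask, dtype=bool)].mean())
        mask &= mean_img >= depth_fraction * cortex_level

    boxcar = (schedule.labels == STIMULUS).astype(float)
    X = np.column_stack(
        [np.ones(n_t), _dct_basis(n_t, design.tr, highpass_hz), boxcar]
    )
    y = series4d[mask].T  # (time, voxels)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n_t - np.linalg.matrix_rank(X)
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[-1, -1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta[-1] / se, np.inf * np.sign(beta[-1]))

    n_vox = int(mask.sum())
    p_thr = alpha / max(n_vox, 1)
    t_thr = stats.t.isf(p_thr, dof)

    beta_map = np.zeros(mask.shape)
    t_map = np.zeros(mask.shape)
    beta_map[mask] = beta[-1]
    t_map[mask] = tvals
    activation = np.zeros(mask.shape, dtype=bool)
    activation[mask] = tvals > t_thr

    labeled, n_clusters = ndimage.label(activation)
    sizes = sorted(
        (int(s) for s in ndimage.sum_labels(activation, labeled, range(1, n_clusters + 1))),
        reverse=True,
    )
    return GLMResult(
        beta=beta_map,
        tstat=t_map,
        activation_mask=activation,
        analysis_mask=mask,
        cluster_sizes=sizes,
        p_threshold=p_thr,
        dof=int(dof),
    )
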