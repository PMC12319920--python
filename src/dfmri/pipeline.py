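"""Study-level orchestration: estimate maps, aggregate ROIs, build reports.

Ties the stages together on a study directory produced by
:func:`dfmri.synth.make_study` (or any directory following the same layout
and manifest): condition averaging, fast MD/MK estimation with unphysical
masking, ROI aggregation into the study table, rest-vs-stimulus change
report with mixed-model tests and FDR, time-dependence model comparison in
the primary somatosensory ROI, and the BOLD arm.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import (
    REST,
    STIMULUS,
    BlockDesign,
    average_conditions,
    read_gradient_table,
    read_schedule_tsv,
)
from .fastdki import estimate_md_mk, mask_unphysical
from .funcstats import (
    bold_condition_average,
    bold_epoch_normalize,
    bold_glm,
    condition_mixed_test,
    fdr_adjust,
    max_abs_change,
    roi_aggregate,
    significance_stars,
)
from .timedep import TimeDependenceCurve, compare_models

__all__ = [
    "load_manifest",
    "estimate_study",
    "build_roi_table",
    "change_report",
    "timedep_report",
    "bold_report",
    "analyze_study",
]


def load_manifest(study_dir: str | Path) -> dict:
    study_dir = Path(study_dir)
    path = study_dir / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"no manifest.json under {study_dir}")
    return json.loads(path.read_text())


def _region_names(manifest: dict) -> dict[int, str]:
    return {r["label"]: r["name"] for r in manifest["regions"]}


def estimate_study(
    study_dir: str | Path,
    out_dir: str | Path | None = None,
    *,
    convention: str = "tensor-mean",
    signal_floor: float = 1e-6,
) -> dict:
    """Per run and diffusion time, estimate MD/MK maps for both conditions.

    Writes ``md``/``mk``/``valid`` NIfTI volumes with a JSON sidecar
    recording condition and diffusion time; returns a maps manifest.
    """
    study_dir = Path(study_dir)
    out_dir = Path(out_dir) if out_dir else study_dir / "maps"
    manifest = load_manifest(study_dir)
    affine = np.eye(4)
    entries = []
    for run in manifest["runs"]:
        for delta_key, rel in run["dwi"].items():
            nii = study_dir / rel
            prefix = nii.with_suffix("")
            scheme = read_gradient_table(prefix)
            schedule = read_schedule_tsv(Path(str(prefix) + "_schedule.tsv"))
            series = np.asarray(nib.load(nii).dataobj, dtype=float)
            rest_set, stim_set = average_conditions(series, schedule, scheme)
            for cond_set in (rest_set, stim_set):
                pmap = mask_unphysical(
                    estimate_md_mk(
                        cond_set, scheme,
                        convention=convention, signal_floor=signal_floor,
                    )
                )
                dest = out_dir / f"rat{run['rat']:02d}" / f"run{run['run']}"
                dest.mkdir(parents=True, exist_ok=True)
                stem = f"delta{delta_key}_{cond_set.condition}"
                nib.save(nib.Nifti1Image(pmap.md.astype(np.float32), affine),
                         dest / f"{stem}_md.nii")
                nib.save(nib.Nifti1Image(pmap.mk.astype(np.float32), affine),
                         dest / f"{stem}_mk.nii")
                nib.save(
                    nib.Nifti1Image(pmap.valid_mask.astype(np.uint8), affine),
                    dest / f"{stem}_valid.nii",
                )
                sidecar = {
                    "condition": cond_set.condition,
                    "delta_big_ms": float(delta_key),
                    "mk_convention": convention,
                }
                (dest / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
                entries.append(
                    {
                        "rat": run["rat"],
                        "run": run["run"],
                        "laterality": run["laterality"],
                        "delta": float(delta_key),
                        "condition": cond_set.condition,
                        "md": str((dest / f"{stem}_md.nii").relative_to(out_dir)),
                        "mk": str((dest / f"{stem}_mk.nii").relative_to(out_dir)),
                        "valid": str((dest / f"{stem}_valid.nii").relative_to(out_dir)),
                    }
                )
    maps_manifest = {"study": str(study_dir), "maps": entries}
    (out_dir / "maps_manifest.json").write_text(
        json.dumps(maps_manifest, indent=1, sort_keys=True)
    )
    return maps_manifest


def build_roi_table(
    study_dir: str | Path,
    maps_manifest: dict,
    *,
    maps_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Pool per-map ROI means into the study-level table.

    One row per (roi, metric, condition, diffusion time, run, subject):
    for the full-size protocol this realizes the 240-measurements-per-ROI
    bookkeeping (24 runs x 5 diffusion times x 2 conditions).
    """
    study_dir = Path(study_dir)
    maps_dir = Path(maps_dir) if maps_dir else study_dir / "maps"
    manifest = load_manifest(study_dir)
    labels = np.asarray(nib.load(study_dir / manifest["labels"]).dataobj).astype(int)
    names = _region_names(manifest)
    frames = []
    for entry in maps_manifest["maps"]:
        valid = np.asarray(
            nib.load(maps_dir / entry["valid"]).dataobj
        ).astype(bool)
        for metric in ("md", "mk"):
            vol = np.asarray(nib.load(maps_dir / entry[metric]).dataobj, dtype=float)
            df = roi_aggregate(vol, labels, valid, names)
            df["metric"] = metric.upper()
            df["condition"] = entry["condition"]
            df["delta"] = entry["delta"]
            df["run"] = entry["run"]
            df["subject"] = entry["rat"]
            df["laterality"] = entry["laterality"]
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def change_report(
    roi_table: pd.DataFrame, alpha: float = 0.05, with_tests: bool = True
) -> pd.DataFrame:
    """Rest-vs-stimulus percent changes, mixed-model p-values and FDR.

    Per (roi, laterality, metric): the percent change of the across-run mean
    at each diffusion time, the maximum-magnitude change and its diffusion
    time, the mixed-model condition p-value, and the BH q-value computed
    separately within each metric family.
    """
    rows = []
    for (roi, lat, metric), grp in roi_table.groupby(["roi", "laterality", "metric"]):
        changes, deltas = [], []
        for delta, dgrp in grp.groupby("delta"):
            rest = dgrp.loc[dgrp.condition == REST, "mean"].mean()
            stim = dgrp.loc[dgrp.condition == STIMULUS, "mean"].mean()
            changes.append(100.0 * (stim - rest) / rest if rest else np.nan)
            deltas.append(delta)
        max_chg, max_delta = max_abs_change(changes, deltas)
        p, fallback = np.nan, False
        if with_tests:
            test_df = grp.rename(columns={"mean": "value"})[
                ["value", "condition", "delta", "run", "subject"]
            ]
            try:
                res = condition_mixed_test(test_df)
                p, fallback = res.p_value, res.fallback
            except ValueError as exc:
                p, fallback = np.nan, True
                warnings.warn(f"{roi}/{lat}/{metric}: {exc}", stacklevel=2)
        rows.append(
            {
                "roi": roi,
                "laterality": lat,
                "metric": metric,
                **{f"change_pct_delta{d:g}": c for d, c in zip(deltas, changes)},
                "max_change_pct": max_chg,
                "max_change_delta": max_delta,
                "p_value": p,
                "fallback": fallback,
            }
        )
    report = pd.DataFrame(rows)
    report["q_value"] = np.nan
    for metric, grp in report.groupby("metric"):
        ok = grp["p_value"].notna()
        if ok.any():
            report.loc[grp.index[ok], "q_value"] = fdr_adjust(
                grp.loc[ok, "p_value"].to_numpy()
            )
    report["stars"] = [
        significance_stars(q) if np.isfinite(q) else "" for q in report["q_value"]
    ]
    return report


def timedep_report(
    roi_table: pd.DataFrame,
    *,
    roi: str = "S1FL",
    weighted: bool = False,
):
    """Model comparison on the ROI's MD(Delta) and MK(Delta) mean curves.

    Builds one curve per (metric, condition, laterality): the across-run
    mean at each diffusion time with its standard error, then fits all
    applicable time-dependence models and ranks them by AICc.
    """
    sub = roi_table[roi_table.roi == roi]
    curves = []
    for (metric, cond, lat), grp in sub.groupby(["metric", "condition", "laterality"]):
        agg = grp.groupby("delta")["mean"].agg(["mean", "sem", "count"]).reset_index()
        if len(agg) < 4:
            continue
        se = agg["sem"].to_numpy()
        curves.append(
            TimeDependenceCurve(
                delta=agg["delta"].to_numpy(),
                values=agg["mean"].to_numpy(),
                se=se if np.all(np.isfinite(se) & (se > 0)) else None,
                metric=metric,
                condition=cond,
                laterality=lat,
            )
        )
    return compare_models(curves, weighted=weighted)


def bold_report(
    study_dir: str | Path,
    *,
    run_glm: bool = True,
    alpha: float = 0.05,
) -> dict:
    """BOLD arm: per-run per-ROI condition averages, pooled response
    functions, mixed-model condition tests with FDR, and (optionally) the
    voxel-wise boxcar GLM of each run."""
    study_dir = Path(study_dir)
    manifest = load_manifest(study_dir)
    d = manifest["bold_design"]
    design = BlockDesign(
        n_epochs=d["n_epochs"], rest_s=d["rest_s"], stim_s=d["stim_s"], tr=d["tr"]
    )
    labels = np.asarray(nib.load(study_dir / manifest["labels"]).dataobj).astype(int)
    names = _region_names(manifest)
    # regions at cortical depth serve as the reference for the 10% depth mask
    cortical = [
        r["label"] for r in manifest["regions"] if r.get("snr", 20) >= 18
    ] or [manifest["regions"][0]["label"]]
    cortex_mask = np.isin(labels, cortical)

    rows = []
    responses: dict[str, list[np.ndarray]] = {}
    glm_summaries = []
    for run in manifest["runs"]:
        if "bold" not in run:
            continue
        series4d = np.asarray(
            nib.load(study_dir / run["bold"]).dataobj, dtype=float
        )
        for lab in np.unique(labels):
            if lab == 0:
                continue
            roi_series = series4d[labels == lab].mean(axis=0)
            avg = bold_condition_average(roi_series, design)
            rows.append(
                {
                    "roi": names[int(lab)],
                    "metric": "BOLD",
                    "run": run["run"],
                    "subject": run["rat"],
                    "laterality": run["laterality"],
                    "rest_mean": avg.rest_mean,
                    "stim_mean": avg.stim_mean,
                    "percent_change": avg.percent_change,
                    "p_within_run": avg.p_value,
                }
            )
            key = f"{names[int(lab)]}|{run['laterality']}"
            _, resp = bold_epoch_normalize(roi_series, design)
            responses.setdefault(key, []).append(resp)
        if run_glm:
            glm = bold_glm(
                series4d, design, labels > 0,
                cortex_mask=cortex_mask, alpha=alpha,
            )
            glm_summaries.append(
                {
                    "rat": run["rat"],
                    "run": run["run"],
                    "n_active": int(glm.activation_mask.sum()),
                    "n_clusters": len(glm.cluster_sizes),
                    "largest_cluster": glm.cluster_sizes[0] if glm.cluster_sizes else 0,
                }
            )

    table = pd.DataFrame(rows)
    if table.empty:
        return {
            "per_run": table,
            "tests": pd.DataFrame(
                columns=["roi", "laterality", "metric", "percent_change",
                         "p_value", "q_value", "stars"]
            ),
            "response_functions": {},
            "glm": [],
        }
    tests = []
    for (roi, lat), grp in table.groupby(["roi", "laterality"]):
        rest = grp["rest_mean"].mean()
        stim = grp["stim_mean"].mean()
        long = pd.concat(
            [
                grp.assign(condition=REST, value=grp["rest_mean"]),
                grp.assign(condition=STIMULUS, value=grp["stim_mean"]),
            ]
        )
        try:
            res = condition_mixed_test(long[["value", "condition", "run", "subject"]])
            p = res.p_value
        except ValueError:
            p = np.nan
        tests.append(
            {
                "roi": roi,
                "laterality": lat,
                "metric": "BOLD",
                "percent_change": 100.0 * (stim - rest) / rest if rest else np.nan,
                "p_value": p,
            }
        )
    test_df = pd.DataFrame(tests)
    ok = test_df["p_value"].notna()
    test_df["q_value"] = np.nan
    if ok.any():
        test_df.loc[ok, "q_value"] = fdr_adjust(test_df.loc[ok, "p_value"].to_numpy())
    test_df["stars"] = [
        significance_stars(q) if np.isfinite(q) else "" for q in test_df["q_value"]
    ]
    return {
        "per_run": table,
        "tests": test_df,
        "response_functions": {k: np.mean(v, axis=0) for k, v in responses.items()},
        "glm": glm_summaries,
    }


def _render_change_table(report: pd.DataFrame) -> str:
    """Plain-text table of maximum percent changes with significance stars."""
    lines = [f"{'ROI':<8}{'laterality':<15}{'metric':<7}{'max change %':>13}  sig"]
    for _, row in report.sort_values(["metric", "roi", "laterality"]).iterrows():
        lines.append(
            f"{row.roi:<8}{row.laterality:<15}{row.metric:<7}"
            f"{row.max_change_pct:>13.2f}  {row.stars}"
        )
    return "\n".join(lines)


def analyze_study(
    study_dir: str | Path,
    out_dir: str | Path | None = None,
    *,
    maps_dir: str | Path | None = None,
    roi_subset: list[str] | None = None,
    timedep_roi: str = "S1FL",
    weighted: bool = False,
    run_glm: bool = True,
    alpha: float = 0.05,
) -> dict:
    """Full analysis pass over an estimated study; writes TSV/JSON reports."""
    study_dir = Path(study_dir)
    out_dir = Path(out_dir) if out_dir else study_dir / "reports"
    out_dir.mkdir(parents=True, exist_ok=True)
    maps_dir = Path(maps_dir) if maps_dir else study_dir / "maps"
    maps_manifest = json.loads((maps_dir / "maps_manifest.json").read_text())

    roi_table = build_roi_table(study_dir, maps_manifest, maps_dir=maps_dir)
    if roi_subset:
        roi_table = roi_table[roi_table.roi.isin(roi_subset)]
    roi_table.to_csv(out_dir / "roi_table.tsv", sep="\t", index=False)

    changes = change_report(roi_table, alpha=alpha)
    changes.to_csv(out_dir / "change_report.tsv", sep="\t", index=False)
    (out_dir / "change_report.txt").write_text(_render_change_table(changes) + "\n")

    comparison = None
    if timedep_roi in set(roi_table.roi):
        comparison = timedep_report(roi_table, roi=timedep_roi, weighted=weighted)
        comparison.to_dataframe().to_csv(
            out_dir / "timedep_comparison.tsv", sep="\t", index=False
        )

    bold = bold_report(study_dir, run_glm=run_glm, alpha=alpha)
    bold["per_run"].to_csv(out_dir / "bold_per_run.tsv", sep="\t", index=False)
    bold["tests"].to_csv(out_dir / "bold_tests.tsv", sep="\t", index=False)

    summary = {
        "n_roi_rows": int(len(roi_table)),
        "change_report": changes.drop(columns=["fallback"]).to_dict("records"),
        "bold_tests": bold["tests"].to_dict("records"),
        "glm": bold["glm"],
        "timedep_winners": (
            {"|".join(k): v for k, v in comparison.winners.items()}
            if comparison
            else {}
        ),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return {
        "roi_table": roi_table,
        "change_report": changes,
        "timedep": comparison,
        "bold": bold,
        "out_dir": out_dir,
    }
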