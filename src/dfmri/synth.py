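"""Synthetic ground truth: exchange substrates, DWI phantoms, BOLD series.

The ground truth for diffusion signals is a two-compartment substrate with
inter-compartmental exchange. Its mean diffusivity is the fraction-weighted
mean of the compartment diffusivities (time-independent); its mean kurtosis
decays with diffusion time Delta following the two-compartment exchange
closed form

    MK(Delta) = K0 * (2 t_ex / Delta) * [1 - (t_ex / Delta) (1 - exp(-Delta / t_ex))]

with K0 = 3 Var_f(D) / MD^2 the zero-time kurtosis and t_ex the exchange
time. Noise-free diffusion-weighted signals use the second-order cumulant
form (the same truncation the fast estimator inverts) so that estimator
round-trips are exact and fitting behaviour is isolated from model bias;
Rician noise is added on two Gaussian channels of the complex signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pydantic import BaseModel

from .acquisition import (
    REST,
    STIMULUS,
    AcquisitionScheme,
    BlockDesign,
    VolumeSchedule,
    build_default_scheme,
    schedule_block,
    write_gradient_table,
    write_schedule_tsv,
)

__all__ = [
    "KargerSubstrate",
    "RegionSpec",
    "PhantomSpec",
    "BOLDSeriesSpec",
    "StudyConfig",
    "UndefinedKurtosisError",
    "karger_mk",
    "karger_ground_truth",
    "substrate_from_moments",
    "cumulant_signal",
    "cumulant_signal_tensor",
    "add_rician_noise",
    "synthesize_dwi",
    "synthesize_bold",
    "make_study",
    "PROTOCOL_DELTAS",
]

#: The five diffusion times of the default protocol (ms).
PROTOCOL_DELTAS = (9.5, 15.0, 20.0, 25.0, 30.0)


class UndefinedKurtosisError(ZeroDivisionError):
    """Kurtosis is undefined for a substrate with MD = 0 but nonzero variance."""


@dataclass(frozen=True)
class KargerSubstrate:
    """Two-(or more-)compartment exchange substrate: the simulator's truth.

    fractions: compartment water fractions, sum to 1.
    diffusivities: compartment diffusivities, um^2/ms.
    t_ex: exchange time, ms.
    """

    fractions: tuple[float, ...]
    diffusivities: tuple[float, ...]
    t_ex: float

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        d = np.asarray(self.diffusivities, dtype=float)
        if f.shape != d.shape:
            raise ValueError("fractions and diffusivities must align")
        if abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1 within 1e-12")
        if np.any(d < 0):
            raise ValueError("diffusivities must be nonnegative")
        if not self.t_ex > 0:
            raise ValueError("exchange time must be positive")

    @property
    def md(self) -> float:
        f = np.asarray(self.fractions)
        return float(f @ np.asarray(self.diffusivities))

    @property
    def k0(self) -> float:
        """Zero-time kurtosis 3 Var_f(D) / MD^2."""
        f = np.asarray(self.fractions)
        d = np.asarray(self.diffusivities)
        md = self.md
        var = float(f @ d**2 - md**2)
        if md == 0.0:
            if var > 0:
                raise UndefinedKurtosisError("MD = 0 with nonzero diffusivity variance")
            return 0.0
        return 3.0 * var / md**2


def karger_mk(k0: float, t_ex: float, delta_big) -> np.ndarray | float:
    """Time-dependent mean kurtosis of the two-compartment exchange model.

    Series-expanded near Delta/t_ex -> 0 to avoid cancellation; there
    MK -> K0. For Delta >> t_ex, MK ~ 2 K0 t_ex / Delta.
    """
    if not t_ex > 0:
        raise ValueError("t_ex must be positive")
    delta_big = np.asarray(delta_big, dtype=float)
    if np.any(delta_big <= 0):
        raise ValueError("diffusion time must be positive")
    x = delta_big / t_ex
    small = x < 1e-3
    with np.errstate(all="ignore"):
        exact = (2.0 / x) * (1.0 - (1.0 / x) * (-np.expm1(-x)))
    series = 1.0 - x / 3.0 + x**2 / 12.0 - x**3 / 60.0
    out = k0 * np.where(small, series, exact)
    return out if out.ndim else float(out)


def karger_ground_truth(
    substrate: KargerSubstrate, delta_big
) -> tuple[float, np.ndarray | float]:
    """(MD, MK(Delta)) of a substrate at diffusion time ``delta_big`` (ms)."""
    return substrate.md, karger_mk(substrate.k0, substrate.t_ex, delta_big)


def substrate_from_moments(md: float, k0: float, t_ex: float) -> KargerSubstrate:
    """Equal-fraction two-compartment substrate realizing (MD, K0, t_ex).

    With f = (1/2, 1/2), K0 = 3 ((D1 - D2)/2)^2 / MD^2, so
    D_{1,2} = MD (1 +/- sqrt(K0 / 3)). Requires K0 < 3 for D2 >= 0.
    """
    if not 0 <= k0 < 3:
        raise ValueError("equal-fraction construction needs 0 <= K0 < 3")
    s = np.sqrt(k0 / 3.0)
    return KargerSubstrate(
        fractions=(0.5, 0.5),
        diffusivities=(md * (1.0 + s), md * (1.0 - s)),
        t_ex=t_ex,
    )


# --- signal forms -------------------------------------------------------------

def cumulant_signal(s0, b, md, mk):
    """Isotropic second-order cumulant signal S = S0 exp(-b MD + b^2 MD^2 MK / 6)."""
    b = np.asarray(b, dtype=float)
    return s0 * np.exp(-b * md + b**2 * md**2 * mk / 6.0)


def cumulant_signal_tensor(s0, bvals, bvecs, dtensor, wtensor):
    """Directional cumulant signal for a (D, W) tensor pair.

    ``ln S = ln S0 - b n.D.n + (1/6) b^2 MD^2 W(n)`` with MD = trace(D)/3 and
    W(n) the full contraction of the kurtosis tensor with n x n x n x n.
    Used by the anisotropic phantom mode and the estimator cross-checks.
    """
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    md = np.trace(dtensor) / 3.0
    d_n = np.einsum("ia,ab,ib->i", bvecs, dtensor, bvecs)
    w_n = np.einsum("ia,ib,ic,id,abcd->i", bvecs, bvecs, bvecs, bvecs, wtensor)
    return s0 * np.exp(-bvals * d_n + bvals**2 * md**2 * w_n / 6.0)


def add_rician_noise(signal, sigma, rng: np.random.Generator):
    """Magnitude of the complex signal after adding independent Gaussian noise
    of standard deviation ``sigma`` on each channel."""
    signal = np.asarray(signal, dtype=float)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), signal.shape)
    re = signal + rng.normal(scale=1.0, size=signal.shape) * sigma
    im = rng.normal(scale=1.0, size=signal.shape) * sigma
    return np.hypot(re, im)


# --- phantom ------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSpec:
    """Per-region ground truth: substrates for both conditions plus the local
    b0 SNR (surface-coil profile: ~20 cortically down to ~10 at depth)."""

    name: str
    rest: KargerSubstrate
    stimulus: KargerSubstrate
    snr: float = 20.0
    bold_amplitude_pct: float = 0.0

    def substrate(self, condition: str) -> KargerSubstrate:
        return self.rest if condition == REST else self.stimulus


@dataclass(frozen=True)
class PhantomSpec:
    """Labelled grid with per-region rest/stimulus substrates.

    labels: integer volume, 0 = background (no signal).
    regions: label -> RegionSpec; every nonzero label must be present.
    s0: b0 signal level (arbitrary units); snr values are S0 / sigma.
    """

    labels: np.ndarray
    regions: dict[int, RegionSpec]
    s0: float = 100.0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        object.__setattr__(self, "labels", labels)
        present = set(np.unique(labels).tolist()) - {0}
        missing = present - set(self.regions)
        if missing:
            raise ValueError(f"labels {sorted(missing)} have no region spec")
        for lab, reg in self.regions.items():
            if not reg.snr > 0:
                raise ValueError(f"region {lab}: SNR must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape


def synthesize_dwi(
    phantom: PhantomSpec,
    scheme: AcquisitionScheme,
    schedule: VolumeSchedule,
    seed: int | np.random.SeedSequence | None = 0,
    *,
    noise: bool = True,
) -> np.ndarray:
    """4D diffusion series (grid + time) for one acquisition.

    Each volume's noise-free signal is the isotropic cumulant form evaluated
    with the condition-appropriate substrate of the voxel's region at the
    scheme's diffusion time. Rician noise uses sigma = S0 / SNR(region).
    With ``noise=False`` the output is seed-independent.
    """
    if schedule.measurement_ids is None:
        raise ValueError("diffusion synthesis needs a measurement-id schedule")
    labels = phantom.labels
    n_t = schedule.n_volumes
    out = np.zeros(labels.shape + (n_t,), dtype=float)
    bvals = scheme.bvalues

    for lab, reg in phantom.regions.items():
        vox = labels == lab
        if not np.any(vox):
            continue
        for cond in (REST, STIMULUS):
            md, mk = karger_ground_truth(reg.substrate(cond), scheme.delta_big)
            idx = schedule.condition_index(cond)
            b_t = bvals[schedule.measurement_ids[idx]]
            sig = cumulant_signal(phantom.s0, b_t, md, mk)  # (len(idx),)
            flat = out[vox]
            flat[:, idx] = sig
            out[vox] = flat

    if noise:
        rng = np.random.default_rng(seed)
        sigma = np.zeros(labels.shape)
        for lab, reg in phantom.regions.items():
            sigma[labels == lab] = phantom.s0 / reg.snr
        noisy = add_rician_noise(out, sigma[..., None], rng)
        noisy[labels == 0] = 0.0
        return noisy
    return out


# --- BOLD ---------------------------------------------------------------------

@dataclass(frozen=True)
class BOLDSeriesSpec:
    """One BOLD time series: baseline + boxcar response + drift + noise.

    amplitude_pct: response during stimulus intervals, % of baseline.
    drift_pct_per_min: linear drift slope, % of baseline per minute.
    noise_pct: Gaussian noise standard deviation, % of baseline.
    """

    design: BlockDesign
    baseline: float = 100.0
    amplitude_pct: float = 1.2
    drift_pct_per_min: float = 0.0
    noise_pct: float = 0.0
    seed: int | np.random.SeedSequence | None = 0

    def __post_init__(self) -> None:
        for name in ("amplitude_pct", "drift_pct_per_min", "noise_pct"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def synthesize_bold(spec: BOLDSeriesSpec) -> np.ndarray:
    """1D BOLD series following the spec's block design; seeded, reproducible."""
    design = spec.design
    schedule = schedule_block(design)
    boxcar = (schedule.labels == STIMULUS).astype(float)
    t_min = np.arange(schedule.n_volumes) * design.tr / 60.0
    series = spec.baseline * (
        1.0
        + spec.amplitude_pct / 100.0 * boxcar
        + spec.drift_pct_per_min / 100.0 * t_min
    )
    if spec.noise_pct > 0:
        rng = np.random.default_rng(spec.seed)
        series = series + rng.normal(
            scale=spec.baseline * spec.noise_pct / 100.0, size=series.shape
        )
    return series


# --- whole-study generation ---------------------------------------------------

# Default per-region effects. Signs follow the in-vivo pattern: MD and MK
# decrease in the S1FL-like primary somatosensory region, increase in the
# secondary-somatosensory-like and subcortical-like regions, and are null in
# the control regions. Percent changes and exchange times are calibration
# targets expressed directly as substrate modifications; depth sets the
# surface-coil SNR profile (snr = 20 - 10 * depth); size_weight sets the
# relative ROI volume (subcortical structures are the largest, mirroring the
# spread of ROI sizes the analysis averages over).
DEFAULT_REGIONS: tuple[dict, ...] = (
    dict(name="S1FL", md_pct=-1.1, mk_pct=-4.9, t_ex_stim=45.1, depth=0.0,
         bold_pct=1.2, size_weight=2.0),
    dict(name="M1", md_pct=-1.2, mk_pct=0.0, t_ex_stim=53.8, depth=0.05,
         bold_pct=0.2, size_weight=1.5),
    dict(name="S2", md_pct=1.5, mk_pct=3.1, t_ex_stim=53.8, depth=0.15,
         bold_pct=0.3, size_weight=1.5),
    dict(name="CPu", md_pct=1.3, mk_pct=1.5, t_ex_stim=53.8, depth=0.5,
         bold_pct=-0.1, size_weight=3.0),
    dict(name="Hip", md_pct=1.4, mk_pct=2.0, t_ex_stim=53.8, depth=0.6,
         bold_pct=0.0, size_weight=2.5),
    dict(name="Tha", md_pct=1.9, mk_pct=2.4, t_ex_stim=53.8, depth=1.0,
         bold_pct=0.0, size_weight=3.5),
    dict(name="M2", md_pct=0.0, mk_pct=0.0, t_ex_stim=53.8, depth=0.05,
         bold_pct=0.0, size_weight=1.0),
    dict(name="RSC", md_pct=0.0, mk_pct=0.0, t_ex_stim=53.8, depth=0.1,
         bold_pct=0.0, size_weight=1.0),
)

# Baseline (rest) microstructure shared by all regions: MD near the cortical
# long-time diffusivity, zero-time kurtosis and exchange time of gray matter.
DEFAULT_REST_MD = 0.70  # um^2/ms
DEFAULT_REST_K0 = 0.86
DEFAULT_REST_TEX = 53.8  # ms


class StudyConfig(BaseModel):
    """Configuration of a full synthetic study.

    Defaults mirror the in-vivo protocol: 10 subjects with 5 functional runs
    each except two subjects with 4 (48 runs), forepaw alternating run to
    run, 5 diffusion times, 3-epoch 28 s / 28 s diffusion blocks at TR = 2 s
    and 6-epoch BOLD blocks at TR = 1 s.
    """

    n_rats: int = 10
    runs_per_rat: int = 5
    rats_with_fewer: int = 2
    deltas: tuple[float, ...] = PROTOCOL_DELTAS
    grid: tuple[int, int, int] = (12, 12, 6)
    s0: float = 100.0
    snr_cortex: float = 20.0
    snr_deep: float = 10.0
    rest_md: float = DEFAULT_REST_MD
    rest_k0: float = DEFAULT_REST_K0
    rest_t_ex: float = DEFAULT_REST_TEX
    regions: tuple[dict, ...] = DEFAULT_REGIONS
    bold_noise_pct: float = 0.5
    bold_drift_pct_per_min: float = 0.1
    include_bold: bool = True
    noise: bool = True
    seed: int = 0
    model_config = dict(frozen=True)

    def runs_for_rat(self, rat: int) -> int:
        if rat < self.rats_with_fewer:
            return self.runs_per_rat - 1
        return self.runs_per_rat


def _build_phantom(config: StudyConfig, forepaw: str) -> PhantomSpec:
    """Label volume: regions as equal slabs along x. Effects are applied only
    when the stimulated forepaw is contralateral to the measured (left)
    hemisphere, i.e. the right forepaw; ipsilateral runs carry null effects."""
    nx, ny, nz = config.grid
    labels = np.zeros(config.grid, dtype=np.int16)
    n_reg = len(config.regions)
    weights = np.array([r.get("size_weight", 1.0) for r in config.regions])
    edges = np.concatenate([[0.0], np.cumsum(weights)]) / weights.sum() * nx
    bounds = np.round(edges).astype(int)
    if np.any(np.diff(bounds) < 1):  # tiny grids: fall back to equal slabs
        bounds = np.linspace(0, nx, n_reg + 1).astype(int)
    regions: dict[int, RegionSpec] = {}
    contralateral = forepaw == "right"
    for i, spec in enumerate(config.regions, start=1):
        labels[bounds[i - 1]:bounds[i]] = i
        rest = substrate_from_moments(config.rest_md, config.rest_k0, config.rest_t_ex)
        if contralateral:
            md_s = config.rest_md * (1.0 + spec["md_pct"] / 100.0)
            k0_s = config.rest_k0 * (1.0 + spec["mk_pct"] / 100.0)
            stim = substrate_from_moments(md_s, k0_s, spec["t_ex_stim"])
            bold_amp = spec["bold_pct"]
        else:
            stim = rest
            bold_amp = 0.0
        snr = config.snr_cortex - (config.snr_cortex - config.snr_deep) * spec["depth"]
        regions[i] = RegionSpec(
            name=spec["name"], rest=rest, stimulus=stim, snr=snr,
            bold_amplitude_pct=bold_amp,
        )
    return PhantomSpec(labels=labels, regions=regions, s0=config.s0)


def _series_seed(master: int, rat: int, run: int, delta_idx: int, kind: int):
    """Seed-splitting rule: SeedSequence(master) with a per-series spawn key
    (rat, run, delta index, stream kind) so any series is reproducible alone."""
    return np.random.SeedSequence(entropy=master, spawn_key=(rat, run, delta_idx, kind))


def make_study(config: StudyConfig, out_dir: str | Path) -> dict:
    """Write a full synthetic study tree and return its manifest.

    Layout: ``labels.nii.gz``-free — everything is uncompressed NIfTI:
    ``labels.nii``, and per run ``rat<r>/run<k>/dwi_delta<d>.nii`` with
    gradient-table triple and schedule TSV, plus ``bold.nii`` and its
    schedule. The manifest (``manifest.json``) records seeds, forepaw
    alternation, region table and file paths.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)

    dwi_design = BlockDesign(n_epochs=3, rest_s=28.0, stim_s=28.0, tr=2.0)
    bold_design = BlockDesign(n_epochs=6, rest_s=28.0, stim_s=28.0, tr=1.0)

    # label volume and region table are forepaw-independent
    ref_phantom = _build_phantom(config, forepaw="right")
    nib.save(
        nib.Nifti1Image(ref_phantom.labels.astype(np.int16), affine),
        out_dir / "labels.nii",
    )
    region_table = [
        {
            "label": lab,
            "name": reg.name,
            "snr": reg.snr,
            "bold_amplitude_pct": reg.bold_amplitude_pct,
            "md_pct": config.regions[lab - 1]["md_pct"],
            "mk_pct": config.regions[lab - 1]["mk_pct"],
        }
        for lab, reg in sorted(ref_phantom.regions.items())
    ]

    runs = []
    for rat in range(config.n_rats):
        for run in range(config.runs_for_rat(rat)):
            forepaw = "right" if (run % 2 == 0) else "left"
            phantom = _build_phantom(config, forepaw=forepaw)
            run_dir = out_dir / f"rat{rat:02d}" / f"run{run}"
            run_dir.mkdir(parents=True, exist_ok=True)
            entry = {
                "rat": rat,
                "run": run,
                "forepaw": forepaw,
                "laterality": "contralateral" if forepaw == "right" else "ipsilateral",
                "dwi": {},
            }
            for di, delta in enumerate(config.deltas):
                scheme = build_default_scheme(delta)
                schedule = schedule_block(dwi_design, scheme)
                series = synthesize_dwi(
                    phantom,
                    scheme,
                    schedule,
                    seed=_series_seed(config.seed, rat, run, di, 0),
                    noise=config.noise,
                )
                stem = f"dwi_delta{delta:g}"
                nib.save(
                    nib.Nifti1Image(series.astype(np.float32), affine),
                    run_dir / f"{stem}.nii",
                )
                write_gradient_table(scheme, run_dir / stem)
                write_schedule_tsv(schedule, run_dir / f"{stem}_schedule.tsv")
                entry["dwi"][f"{delta:g}"] = str(
                    (run_dir / f"{stem}.nii").relative_to(out_dir)
                )
            if not config.include_bold:
                runs.append(entry)
                continue
            # BOLD: per-voxel series with region-specific boxcar amplitudes
            rng = np.random.default_rng(_series_seed(config.seed, rat, run, 0, 1))
            schedule_b = schedule_block(bold_design)
            boxcar = (schedule_b.labels == STIMULUS).astype(float)
            t_min = np.arange(schedule_b.n_volumes) * bold_design.tr / 60.0
            bold = np.zeros(phantom.shape + (schedule_b.n_volumes,), dtype=float)
            for lab, reg in phantom.regions.items():
                vox = phantom.labels == lab
                base = config.s0 * (
                    1.0
                    + reg.bold_amplitude_pct / 100.0 * boxcar
                    + config.bold_drift_pct_per_min / 100.0 * t_min
                )
                bold[vox] = base
            if config.noise and config.bold_noise_pct > 0:
                bold += rng.normal(
                    scale=config.s0 * config.bold_noise_pct / 100.0, size=bold.shape
                )
                bold[phantom.labels == 0] = 0.0
            nib.save(
                nib.Nifti1Image(bold.astype(np.float32), affine),
                run_dir / "bold.nii",
            )
            write_schedule_tsv(schedule_b, run_dir / "bold_schedule.tsv")
            entry["bold"] = str((run_dir / "bold.nii").relative_to(out_dir))
            runs.append(entry)

    manifest = {
        "seed": config.seed,
        "n_rats": config.n_rats,
        "deltas": list(config.deltas),
        "grid": list(config.grid),
        "s0": config.s0,
        "noise": config.noise,
        "labels": "labels.nii",
        "regions": region_table,
        "dwi_design": {"n_epochs": 3, "rest_s": 28.0, "stim_s": 28.0, "tr": 2.0},
        "bold_design": {"n_epochs": 6, "rest_s": 28.0, "stim_s": 28.0, "tr": 1.0},
        "n_runs": len(runs),
        "runs": runs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
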