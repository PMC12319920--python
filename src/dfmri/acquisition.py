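"""Acquisition protocol and block-paradigm bookkeeping.

Encodes a two-shell diffusion acquisition (3 b0 + 9 directions x 2 b-values
per repetition, 2 repetitions per condition) and the alternating
rest/stimulus block design, labels every acquired volume with its condition,
and collapses a labelled 4D series into one averaged image per unique
diffusion weighting and condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "BlockDesign",
    "VolumeSchedule",
    "ConditionSignalSet",
    "InvalidGeometryError",
    "ConfigurationError",
    "IncompleteScheduleError",
    "build_default_scheme",
    "schedule_block",
    "average_conditions",
    "write_gradient_table",
    "read_gradient_table",
    "write_schedule_tsv",
    "read_schedule_tsv",
]

REST = "rest"
STIMULUS = "stimulus"

_DIR_TOL = 1e-9


class InvalidGeometryError(ValueError):
    """Pulse-sequence timing that cannot be realized (e.g. delta > Delta)."""


class ConfigurationError(ValueError):
    """Block design / scheme combination that does not tile into volumes."""


class IncompleteScheduleError(ValueError):
    """A condition is missing measurements required for averaging."""


@dataclass(frozen=True)
class AcquisitionScheme:
    """One diffusion acquisition: timing, b-values and gradient directions.

    ``bvalues`` has one entry per measurement (b0 entries are exactly 0);
    ``directions`` has one unit row per nonzero-b measurement, in measurement
    order. Units: ms for Delta/delta/TE, s for TR, ms/um^2 for b.
    """

    delta_big: float
    delta_small: float
    te: float
    tr: float
    bvalues: np.ndarray
    directions: np.ndarray
    n_b0: int
    n_reps: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "bvalues", np.asarray(self.bvalues, dtype=float))
        object.__setattr__(self, "directions", np.asarray(self.directions, dtype=float))
        if self.delta_big < self.delta_small:
            raise InvalidGeometryError(
                f"diffusion time Delta={self.delta_big} ms shorter than "
                f"gradient pulse delta={self.delta_small} ms"
            )
        if np.any(self.bvalues < 0):
            raise ValueError("b-values must be nonnegative")
        n_dw = int(np.count_nonzero(self.bvalues))
        if self.directions.shape != (n_dw, 3):
            raise ValueError(
                f"expected {n_dw} direction rows for {n_dw} nonzero-b "
                f"measurements, got shape {self.directions.shape}"
            )
        norms = np.linalg.norm(self.directions, axis=1)
        if n_dw and np.any(np.abs(norms - 1.0) > _DIR_TOL):
            raise ValueError("directions must be unit vectors (|n| = 1 within 1e-9)")
        if int(np.sum(self.bvalues == 0)) != self.n_b0:
            raise ValueError("n_b0 inconsistent with zero entries of bvalues")

    @property
    def n_measurements(self) -> int:
        """Measurements per repetition (b0s included)."""
        return self.bvalues.size

    @property
    def volumes_per_condition(self) -> int:
        return self.n_measurements * self.n_reps

    @property
    def nonzero_index(self) -> np.ndarray:
        """Indices of diffusion-weighted measurements within the scheme."""
        return np.flatnonzero(self.bvalues > 0)

    def measurement_bvecs(self) -> np.ndarray:
        """Per-measurement direction table with zero rows at b0 positions."""
        out = np.zeros((self.n_measurements, 3))
        out[self.nonzero_index] = self.directions
        return out


@dataclass(frozen=True)
class BlockDesign:
    """Alternating rest/stimulus block paradigm (each interval starts at rest)."""

    n_epochs: int
    rest_s: float = 28.0
    stim_s: float = 28.0
    tr: float = 2.0

    def __post_init__(self) -> None:
        if self.n_epochs < 1:
            raise ConfigurationError("need at least one epoch")
        if self.tr <= 0:
            raise ConfigurationError("TR must be positive")
        for name, length in (("rest_s", self.rest_s), ("stim_s", self.stim_s)):
            k = length / self.tr
            if abs(k - round(k)) > 1e-9 or round(k) < 1:
                raise ConfigurationError(
                    f"{name}={length} s is not a positive integer multiple of TR={self.tr} s"
                )

    @property
    def rest_volumes(self) -> int:
        return int(round(self.rest_s / self.tr))

    @property
    def stim_volumes(self) -> int:
        return int(round(self.stim_s / self.tr))

    @property
    def total_volumes(self) -> int:
        return self.n_epochs * (self.rest_volumes + self.stim_volumes)


@dataclass(frozen=True)
class VolumeSchedule:
    """Per-volume condition labels and the scheme measurement each realizes.

    ``measurement_ids`` is None for non-diffusion (e.g. BOLD) series where
    every volume realizes the same measurement.
    """

    labels: np.ndarray
    measurement_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels))
        n_rest = int(np.sum(self.labels == REST))
        n_stim = int(np.sum(self.labels == STIMULUS))
        if n_rest + n_stim != self.labels.size:
            raise ValueError("labels must be 'rest' or 'stimulus'")
        if n_rest != n_stim:
            raise ValueError("rest and stimulus volume counts must be equal")
        if self.measurement_ids is not None:
            mids = np.asarray(self.measurement_ids, dtype=int)
            if mids.size != self.labels.size:
                raise ValueError("measurement_ids length must match labels")
            object.__setattr__(self, "measurement_ids", mids)

    @property
    def n_volumes(self) -> int:
        return self.labels.size

    def condition_index(self, condition: str) -> np.ndarray:
        return np.flatnonzero(self.labels == condition)


@dataclass(frozen=True)
class ConditionSignalSet:
    """Condition-averaged signals: one mean b0 plus one mean image per
    unique (b, direction).

    ``signals`` has the averaged images stacked on the last axis, b0 first
    then diffusion-weighted measurements in scheme order; ``bvalues`` and
    ``directions`` describe that axis (``directions`` excludes the b0 slot).
    """

    condition: str
    signals: np.ndarray
    bvalues: np.ndarray
    directions: np.ndarray
    provenance: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_images(self) -> int:
        return self.signals.shape[-1]

    @property
    def b0(self) -> np.ndarray:
        return self.signals[..., 0]

    @property
    def dwi(self) -> np.ndarray:
        return self.signals[..., 1:]


def build_default_scheme(
    delta_big: float,
    *,
    delta_small: float = 4.0,
    te: float = 48.0,
    tr: float = 2.0,
    bvalues: tuple[float, float] = (1.0, 2.0),
    directions: np.ndarray | None = None,
    n_b0: int = 3,
    n_reps: int = 2,
) -> AcquisitionScheme:
    """Two-shell fast-kurtosis scheme: ``n_b0`` b0s followed by each of nine
    directions at both shells (direction-major, b-minor ordering).

    The shipped nine-direction set satisfies the second- and fourth-order
    isotropic averaging identities (see :func:`dfmri.fastdki.verify_direction_set`).
    """
    from .fastdki import DEFAULT_DIRECTIONS  # local import to avoid cycle

    if directions is None:
        directions = DEFAULT_DIRECTIONS
    directions = np.asarray(directions, dtype=float)
    b_lo, b_hi = sorted(bvalues)
    if b_lo <= 0:
        raise ValueError("both shells must have positive b")
    n_dirs = directions.shape[0]
    bvals = np.concatenate(
        [np.zeros(n_b0), np.tile([b_lo, b_hi], n_dirs)]
    )
    dir_rows = np.repeat(directions, 2, axis=0)
    return AcquisitionScheme(
        delta_big=delta_big,
        delta_small=delta_small,
        te=te,
        tr=tr,
        bvalues=bvals,
        directions=dir_rows,
        n_b0=n_b0,
        n_reps=n_reps,
    )


def schedule_block(
    design: BlockDesign,
    scheme_or_tr: AcquisitionScheme | float | None = None,
) -> VolumeSchedule:
    """Label every acquired volume with its condition.

    Volumes fall into half-open time bins [t, t + TR); a volume belongs to
    the interval containing its start time. Each epoch is rest first, then
    stimulus. For a diffusion scheme, measurement ids cycle through the
    scheme in order within each condition so that every measurement is
    realized ``n_reps`` times per condition across the whole run.
    """
    scheme: AcquisitionScheme | None = None
    if isinstance(scheme_or_tr, AcquisitionScheme):
        scheme = scheme_or_tr
        if abs(scheme.tr - design.tr) > 1e-12:
            raise ConfigurationError("scheme TR and design TR disagree")
    elif scheme_or_tr is not None:
        if abs(float(scheme_or_tr) - design.tr) > 1e-12:
            raise ConfigurationError("TR argument and design TR disagree")

    per_epoch = [REST] * design.rest_volumes + [STIMULUS] * design.stim_volumes
    labels = np.array(per_epoch * design.n_epochs)

    measurement_ids = None
    if scheme is not None:
        per_cond = labels.size // 2
        expected = scheme.volumes_per_condition
        if per_cond != expected:
            raise ConfigurationError(
                f"design yields {per_cond} volumes per condition but the scheme "
                f"requires {expected} ({scheme.n_measurements} measurements x "
                f"{scheme.n_reps} repetitions)"
            )
        measurement_ids = np.empty(labels.size, dtype=int)
        for cond in (REST, STIMULUS):
            idx = np.flatnonzero(labels == cond)
            measurement_ids[idx] = np.arange(idx.size) % scheme.n_measurements
    return VolumeSchedule(labels=labels, measurement_ids=measurement_ids)


def average_conditions(
    series: np.ndarray,
    schedule: VolumeSchedule,
    scheme: AcquisitionScheme,
) -> tuple[ConditionSignalSet, ConditionSignalSet]:
    """Average repeated measurements voxel-wise within each condition.

    All b0 volumes of a condition are pooled into a single mean image; each
    diffusion-weighted measurement is averaged over its repetitions. For the
    default scheme this yields 19 images per condition (1 b0 + 18 DWI).
    """
    series = np.asarray(series)
    if series.shape[-1] != schedule.n_volumes:
        raise ValueError(
            f"series has {series.shape[-1]} volumes, schedule expects {schedule.n_volumes}"
        )
    if schedule.measurement_ids is None:
        raise ValueError("schedule carries no measurement ids (not a diffusion schedule)")

    b0_ids = np.flatnonzero(scheme.bvalues == 0)
    dw_ids = scheme.nonzero_index
    out = []
    for cond in (REST, STIMULUS):
        vol_idx = schedule.condition_index(cond)
        mids = schedule.measurement_ids[vol_idx]
        images = np.empty(series.shape[:-1] + (1 + dw_ids.size,), dtype=float)
        counts = np.empty(1 + dw_ids.size, dtype=int)
        b0_vols = vol_idx[np.isin(mids, b0_ids)]
        if b0_vols.size == 0:
            raise IncompleteScheduleError(f"no b0 volumes for condition {cond!r}")
        images[..., 0] = series[..., b0_vols].mean(axis=-1)
        counts[0] = b0_vols.size
        for j, mid in enumerate(dw_ids, start=1):
            vols = vol_idx[mids == mid]
            if vols.size != scheme.n_reps:
                raise IncompleteScheduleError(
                    f"measurement {mid} appears {vols.size} times for condition "
                    f"{cond!r}, expected {scheme.n_reps}"
                )
            images[..., j] = series[..., vols].mean(axis=-1)
            counts[j] = vols.size
        out.append(
            ConditionSignalSet(
                condition=cond,
                signals=images,
                bvalues=np.concatenate([[0.0], scheme.bvalues[dw_ids]]),
                directions=scheme.directions,
                provenance=counts,
            )
        )
    return out[0], out[1]


# --- plain-text serialization -------------------------------------------------

def write_gradient_table(scheme: AcquisitionScheme, prefix: str | Path) -> None:
    """Write ``<prefix>.bval`` (one row), ``<prefix>.bvec`` (three rows, one
    column per measurement) and ``<prefix>.json`` (Delta/delta/TE/TR and
    repetition counts)."""
    prefix = Path(prefix)
    bvecs = scheme.measurement_bvecs().T
    np.savetxt(prefix.with_suffix(".bval"), scheme.bvalues[None, :], fmt="%.6g")
    np.savetxt(prefix.with_suffix(".bvec"), bvecs, fmt="%.17g")
    sidecar = {
        "delta_big_ms": scheme.delta_big,
        "delta_small_ms": scheme.delta_small,
        "te_ms": scheme.te,
        "tr_s": scheme.tr,
        "n_b0": scheme.n_b0,
        "n_reps": scheme.n_reps,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_gradient_table(prefix: str | Path) -> AcquisitionScheme:
    prefix = Path(prefix)
    for ext in (".bval", ".bvec", ".json"):
        if not prefix.with_suffix(ext).exists():
            raise FileNotFoundError(
                f"gradient table component {prefix.with_suffix(ext)} is missing; "
                "expected a .bval/.bvec/.json triple"
            )
    bvals = np.atleast_1d(np.loadtxt(prefix.with_suffix(".bval")))
    bvecs = np.loadtxt(prefix.with_suffix(".bvec"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    nz = bvals > 0
    return AcquisitionScheme(
        delta_big=meta["delta_big_ms"],
        delta_small=meta["delta_small_ms"],
        te=meta["te_ms"],
        tr=meta["tr_s"],
        bvalues=bvals,
        directions=bvecs.T[nz],
        n_b0=int(np.sum(~nz)),
        n_reps=int(meta["n_reps"]),
    )


def write_schedule_tsv(schedule: VolumeSchedule, path: str | Path) -> None:
    """One-column TSV of condition labels, plus a measurement-id column for
    diffusion schedules."""
    path = Path(path)
    lines = ["label\tmeasurement_id"]
    mids = schedule.measurement_ids
    for i, lab in enumerate(schedule.labels):
        mid = "" if mids is None else str(int(mids[i]))
        lines.append(f"{lab}\t{mid}")
    path.write_text("\n".join(lines) + "\n")


def read_schedule_tsv(path: str | Path) -> VolumeSchedule:
    rows = Path(path).read_text().strip().splitlines()[1:]
    labels, mids = [], []
    for row in rows:
        parts = row.split("\t")
        labels.append(parts[0])
        mids.append(parts[1] if len(parts) > 1 else "")
    measurement_ids = None
    if all(m != "" for m in mids) and mids:
        measurement_ids = np.array([int(m) for m in mids])
    return VolumeSchedule(labels=np.array(labels), measurement_ids=measurement_ids)
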