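"""Quantification of calibrated emission images (PET/SPECT).

Implements the chain used to quantify brown-adipose-tissue uptake on small
animal scans: SPECT count calibration, smoothing/resampling to coarse
isotropic voxels, dynamic-frame selection, and iso-contour segmentation of a
hand-drawn VOI followed by SUV_mean, metabolic volume and total metabolic
activity.

The iso-contour rule thresholds the VOI at ``min + cutoff * (max - min)``
(cutoff 30% by default) and keeps every voxel at or above the threshold,
interpreting the surviving voxels as metabolically active tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

__all__ = [
    "EmissionImage",
    "VOIBox",
    "VOIResult",
    "NotQuantifiableError",
    "calibrate_spect",
    "resample_isotropic",
    "select_uptake_frame",
    "IsoContourQuantifier",
    "quantify_voi",
    "PET_FRAME_SCHEDULE",
    "SPECT_FRAME_SCHEDULE",
    "SPECT_BQ_PER_COUNT",
]

#: Phantom-based SPECT calibration, Bq per count (Tc-99m and I-123 alike).
SPECT_BQ_PER_COUNT = 635.0

#: Dynamic PET schedule: 8x15 s, 6x30 s, 5x60 s, 3x300 s (25 min total).
PET_FRAME_SCHEDULE: list[tuple[float, float]] = []
_t = 0.0
for _n, _d in [(8, 15.0), (6, 30.0), (5, 60.0), (3, 300.0)]:
    for _ in range(_n):
        PET_FRAME_SCHEDULE.append((_t, _d))
        _t += _d

#: Dynamic SPECT schedule: 15 frames of 3 min.
SPECT_FRAME_SCHEDULE: list[tuple[float, float]] = [
    (i * 180.0, 180.0) for i in range(15)
]
del _t, _n, _d


class NotQuantifiableError(ValueError):
    """VOI uptake too low to delineate (reported as NQ in tables)."""


@dataclass(frozen=True)
class EmissionImage:
    """A 3-D (x, y, z) or 4-D (x, y, z, frame) emission volume.

    Values are concentrations — Bq/cc for calibrated images, counts/cc for
    raw SPECT output — together with the acquisition metadata needed for
    SUV computation.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    value_unit: str  # "Bq_per_cc" | "counts_per_cc"
    modality: str  # "PET" | "SPECT"
    injected_dose_Bq: float
    body_weight_g: float
    isotope: str  # "F18" | "Tc99m" | "I123"
    injection_time_s: float = 0.0
    frame_schedule: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim not in (3, 4):
            raise ValueError(f"voxels must be 3-D or 4-D, got {vox.ndim}-D")
        if not np.all(np.isfinite(vox)):
            raise ValueError("voxel values must be finite")
        if vox.min() < 0:
            raise ValueError("voxel values must be non-negative")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("spacing_mm must be 3 strictly positive lengths")
        if self.value_unit not in ("Bq_per_cc", "counts_per_cc"):
            raise ValueError(f"unknown value_unit {self.value_unit!r}")
        if self.modality not in ("PET", "SPECT"):
            raise ValueError(f"unknown modality {self.modality!r}")
        schedule = tuple((float(a), float(b)) for a, b in self.frame_schedule)
        n_frames = vox.shape[3] if vox.ndim == 4 else 1
        if schedule:
            if len(schedule) != n_frames:
                raise ValueError(
                    f"frame_schedule has {len(schedule)} entries for "
                    f"{n_frames} frame(s)"
                )
            for (s0, d0), (s1, _) in zip(schedule, schedule[1:]):
                if d0 <= 0 or abs(s0 + d0 - s1) > 1e-9:
                    raise ValueError("frames must be contiguous, non-overlapping")
            if schedule[-1][1] <= 0:
                raise ValueError("frame durations must be positive")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "frame_schedule", schedule)

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[3] if self.voxels.ndim == 4 else 1

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0


@dataclass(frozen=True)
class VOIBox:
    """Axis-aligned voxel-index box (half-open, 0-based) delimiting a VOI."""

    bounds: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def __post_init__(self):
        bounds = tuple((int(a), int(b)) for a, b in self.bounds)
        if len(bounds) != 3:
            raise ValueError("bounds must give (lo, hi) for three axes")
        for lo, hi in bounds:
            if hi <= lo or lo < 0:
                raise ValueError(f"empty or negative bound ({lo}, {hi})")
        object.__setattr__(self, "bounds", bounds)

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in self.bounds)

    def check_within(self, shape: Sequence[int]) -> None:
        for (lo, hi), n in zip(self.bounds, shape[:3]):
            if hi > n:
                raise ValueError(f"VOI bound ({lo}, {hi}) exceeds image extent {n}")


@dataclass(frozen=True)
class VOIResult:
    """Iso-contour quantification of one VOI.

    ``total_metabolic_activity`` is SUV_mean x metabolic volume, the
    composite activity index. When the VOI cannot be delineated
    (``quantifiable`` False) the numeric fields are NaN.
    """

    suv_mean: float  # g/cm^3
    metabolic_volume_cm3: float
    total_metabolic_activity: float
    threshold_value: float
    n_voxels: int
    cutoff_fraction: float
    quantifiable: bool = True
    mask: np.ndarray | None = field(default=None, repr=False, compare=False)

    @classmethod
    def not_quantifiable(cls, threshold: float, cutoff: float) -> "VOIResult":
        return cls(
            suv_mean=float("nan"),
            metabolic_volume_cm3=float("nan"),
            total_metabolic_activity=float("nan"),
            threshold_value=threshold,
            n_voxels=0,
            cutoff_fraction=cutoff,
            quantifiable=False,
        )


def calibrate_spect(
    image: EmissionImage, factor: float = SPECT_BQ_PER_COUNT
) -> EmissionImage:
    """Convert a counts/cc SPECT image to Bq/cc with a phantom-derived factor.

    Parameters
    ----------
    image : raw SPECT image in counts_per_cc.
    factor : calibration in Bq per count; default 635 (valid for Tc-99m and
        I-123 on the calibrated system).
    """
    if image.value_unit != "counts_per_cc":
        raise ValueError(
            "image is already calibrated (Bq_per_cc); refusing double calibration"
        )
    if factor <= 0:
        raise ValueError("calibration factor must be positive")
    return replace(image, voxels=image.voxels * float(factor), value_unit="Bq_per_cc")


def _overlap_matrix(n_in: int, s_in: float, s_out: float) -> np.ndarray:
    """Row-stochastic 1-D mean-pooling weights from n_in voxels of length
    s_in onto output voxels of length s_out (half-open intervals from 0)."""
    extent = n_in * s_in
    n_out = int(np.ceil(extent / s_out - 1e-9))
    w = np.zeros((n_out, n_in))
    edges_in = np.arange(n_in + 1) * s_in
    for j in range(n_out):
        lo, hi = j * s_out, min((j + 1) * s_out, extent)
        a = np.clip(edges_in[1:], lo, hi) - np.clip(edges_in[:-1], lo, hi)
        w[j] = a
    return w / w.sum(axis=1, keepdims=True)


def resample_isotropic(
    image: EmissionImage, target_spacing_mm: float = 3.0
) -> EmissionImage:
    """Smooth an image to coarse isotropic voxels (default 3x3x3 mm).

    Mean-pooling over the footprint of each output voxel: concentrations are
    intensive, so a constant image stays constant and total activity is
    conserved wherever output voxels tile the input exactly.
    """
    target = float(target_spacing_mm)
    if target < max(image.spacing_mm) - 1e-9:
        raise ValueError(
            f"target spacing {target} mm is finer than native "
            f"{image.spacing_mm}; refusing to upsample"
        )
    if all(abs(s - target) < 1e-9 for s in image.spacing_mm):
        return image
    vox = image.voxels
    for axis in range(3):
        w = _overlap_matrix(vox.shape[axis], image.spacing_mm[axis], target)
        vox = np.moveaxis(np.tensordot(w, vox, axes=([1], [axis])), 0, axis)
    return replace(image, voxels=vox, spacing_mm=(target, target, target))


def select_uptake_frame(image: EmissionImage, policy: str | int = "last") -> EmissionImage:
    """Collapse a dynamic series to the static frame fed into SUV analysis.

    ``last`` keeps the final frame (latest, most trapped uptake); ``sum``
    returns the duration-weighted mean concentration over all frames; an
    integer selects frame k.
    """
    if image.voxels.ndim == 3:
        return image
    vox = image.voxels
    n = vox.shape[3]
    if policy == "last":
        out = vox[..., n - 1]
        schedule = image.frame_schedule[-1:] if image.frame_schedule else ()
    elif policy == "sum":
        if image.frame_schedule:
            durations = np.array([d for _, d in image.frame_schedule])
        else:
            durations = np.ones(n)
        out = (vox * durations).sum(axis=3) / durations.sum()
        if image.frame_schedule:
            start = image.frame_schedule[0][0]
            schedule = ((start, float(durations.sum())),)
        else:
            schedule = ()
    elif isinstance(policy, (int, np.integer)) and not isinstance(policy, bool):
        if not 0 <= policy < n:
            raise ValueError(f"frame index {policy} out of range [0, {n})")
        out = vox[..., policy]
        schedule = (image.frame_schedule[policy],) if image.frame_schedule else ()
    else:
        raise ValueError(f"unknown frame policy {policy!r}")
    return replace(image, voxels=out, frame_schedule=schedule)


class IsoContourQuantifier(BaseEstimator):
    """Iso-contour VOI quantifier (SUV_mean, metabolic volume, activity).

    Thresholds the drawn VOI at ``min + cutoff_fraction * (max - min)``
    (min/max over the VOI only) and retains voxels >= threshold; the
    retained set defines the metabolically active volume.

    Parameters
    ----------
    cutoff_fraction : float, default 0.30
        Fraction of the VOI's (max - min) dynamic range added to the
        minimum to form the absolute threshold.
    min_voxels : int, default 1
        Below this retained-voxel count the VOI is flagged not quantifiable.
    raise_on_nq : bool, default False
        Raise :class:`NotQuantifiableError` instead of returning a flagged
        :class:`VOIResult`.

    Attributes
    ----------
    result_ : VOIResult
    mask_ : boolean array over the full image grid (True = retained)
    threshold_value_, suv_mean_, metabolic_volume_cm3_,
    total_metabolic_activity_, n_voxels_ : scalars mirroring ``result_``.
    """

    def __init__(self, cutoff_fraction: float = 0.30, min_voxels: int = 1,
                 raise_on_nq: bool = False):
        self.cutoff_fraction = cutoff_fraction
        self.min_voxels = min_voxels
        self.raise_on_nq = raise_on_nq

    def fit(self, image: EmissionImage, box: VOIBox) -> "IsoContourQuantifier":
        if not 0.0 <= self.cutoff_fraction <= 1.0:
            raise ValueError("cutoff_fraction must lie in [0, 1]")
        if image.value_unit != "Bq_per_cc":
            raise ValueError(
                "image is in counts_per_cc; run calibrate_spect() first"
            )
        if image.voxels.ndim != 3:
            raise ValueError(
                "image is dynamic; run select_uptake_frame() first"
            )
        if image.injected_dose_Bq <= 0:
            raise ValueError("injected_dose_Bq must be positive")
        if image.body_weight_g <= 0:
            raise ValueError("body_weight_g must be positive")
        box.check_within(image.voxels.shape)

        roi = image.voxels[box.slices()]
        vmin, vmax = float(roi.min()), float(roi.max())
        threshold = vmin + self.cutoff_fraction * (vmax - vmin)
        retained = roi >= threshold
        n = int(retained.sum())

        if vmax <= 0 or n < self.min_voxels:
            if self.raise_on_nq:
                raise NotQuantifiableError(
                    "VOI uptake too low to delineate (NQ)"
                )
            self.result_ = VOIResult.not_quantifiable(threshold, self.cutoff_fraction)
        else:
            dose_per_g = image.injected_dose_Bq / image.body_weight_g
            suv = float(roi[retained].mean()) / dose_per_g
            vol = n * image.voxel_volume_cm3
            mask = np.zeros(image.voxels.shape, dtype=bool)
            mask[box.slices()] = retained
            self.result_ = VOIResult(
                suv_mean=suv,
                metabolic_volume_cm3=vol,
                total_metabolic_activity=suv * vol,
                threshold_value=threshold,
                n_voxels=n,
                cutoff_fraction=self.cutoff_fraction,
                mask=mask,
            )
        r = self.result_
        self.mask_ = r.mask
        self.threshold_value_ = r.threshold_value
        self.suv_mean_ = r.suv_mean
        self.metabolic_volume_cm3_ = r.metabolic_volume_cm3
        self.total_metabolic_activity_ = r.total_metabolic_activity
        self.n_voxels_ = r.n_voxels
        return self


def quantify_voi(
    image: EmissionImage,
    box: VOIBox,
    cutoff_fraction: float = 0.30,
    min_voxels: int = 1,
) -> VOIResult:
    """Quantify a VOI on a static calibrated image. See IsoContourQuantifier."""
    return IsoContourQuantifier(
        cutoff_fraction=cutoff_fraction, min_voxels=min_voxels
    ).fit(image, box).result_
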