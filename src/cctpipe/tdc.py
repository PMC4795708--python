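"""Time–density curves and time-to-peak measurement.

A dynamic contrast acquisition (CT perfusion or digital subtraction
angiography) is reduced to one baseline-corrected time–density curve (TDC)
per region of interest, from which the time to peak (TTP) is read.  TTP is
the time at which contrast attenuation reaches its maximum along the frame
axis; for DSA the reference time t = 0 is the pre-contrast mask frame, for
CTP it is the start of the acquisition, with the first few pre-arrival
frames serving as the baseline estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

MODALITY_CTP = "CTP"
MODALITY_DSA = "DSA"

#: ROI labels required by each phantom placement convention.
DSA_LATERAL_LABELS = ("RA2", "LA2", "RM2", "LM2", "SSS_right", "SSS_left")
CTP_AXIAL_LABELS = ("A2", "RM2", "LM2", "SSS")

FLAG_CONSTANT_SERIES = "constant_series"
FLAG_PEAK_AT_BOUNDARY = "peak_at_boundary"
FLAG_LOW_CONTRAST = "low_contrast"

#: peak must exceed this multiple of the robust noise level, else flagged.
LOW_CONTRAST_SNR = 5.0


class ROIError(ValueError):
    """Raised for empty or out-of-grid regions of interest."""


class LabelError(ValueError):
    """Raised when a label map lacks a label required by a convention."""


@dataclass
class DynamicSeries:
    """A dynamic contrast acquisition; the last axis of ``data`` is time.

    Parameters
    ----------
    data : ndarray
        ``(x, y, z, t)`` for CTP or ``(x, y, t)`` for DSA.
    frame_interval : float
        Seconds between frames.
    modality : str
        ``"CTP"`` or ``"DSA"``.
    mask_frame_index : int
        DSA: index of the mask frame that defines t = 0.  CTP: number of
        leading pre-contrast frames used as the baseline.
    """

    data: np.ndarray
    frame_interval: float
    modality: str
    mask_frame_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.modality not in (MODALITY_CTP, MODALITY_DSA):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.data.ndim < 2 or self.data.shape[-1] < 2:
            raise ValueError("series needs at least 2 frames")
        if not 0 <= self.mask_frame_index < self.data.shape[-1]:
            raise ValueError("mask_frame_index outside frame range")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:-1]

    @property
    def times(self) -> np.ndarray:
        """Frame times (s).  DSA: t = 0 at the mask frame; CTP: at frame 0."""
        idx = np.arange(self.n_frames, dtype=float)
        if self.modality == MODALITY_DSA:
            idx -= self.mask_frame_index
        return idx * self.frame_interval


@dataclass
class ROISpec:
    """A labelled region of interest as a boolean mask on the spatial grid."""

    label: str
    mask: np.ndarray
    caliber_note: str = ""
    clipped: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ROIError(f"ROI {self.label!r} has an empty mask")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class LabeledMasks:
    """Integer-labelled ROI image plus the name → label-value map."""

    data: np.ndarray
    labels: dict
    clipped: set = field(default_factory=set)

    def mask_for(self, label: str) -> np.ndarray:
        if label not in self.labels:
            raise LabelError(f"label {label!r} not present in label map")
        return self.data == self.labels[label]

    def roi(self, label: str) -> ROISpec:
        return ROISpec(label=label, mask=self.mask_for(label),
                       clipped=label in self.clipped)


@dataclass
class TimeDensityCurve:
    """Baseline-corrected mean ROI intensity versus time."""

    times: np.ndarray
    values: np.ndarray
    roi_label: str = ""
    n_voxels: int = 0
    quality_flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("times must be strictly increasing")


@dataclass
class TTPMeasurement:
    roi_label: str
    ttp: float
    peak_value: float
    method: str
    quality_flags: set = field(default_factory=set)


def _validate_roi(series: DynamicSeries, roi: ROISpec) -> None:
    if roi.mask.shape != series.spatial_shape:
        raise ROIError(
            f"ROI {roi.label!r} grid {roi.mask.shape} does not match series "
            f"grid {series.spatial_shape}")
    if not roi.mask.any():
        raise ROIError(f"ROI {roi.label!r} has an empty mask")


def extract_tdc(series: DynamicSeries, roi: ROISpec) -> TimeDensityCurve:
    """Mean ROI intensity per frame, baseline-corrected.

    DSA: the mask frame's mean is subtracted.  CTP: the mean of the first
    ``mask_frame_index`` pre-contrast frames is subtracted (no subtraction
    when that count is zero).
    """
    _validate_roi(series, roi)
    raw = series.data[roi.mask].mean(axis=0).astype(float)
    flags: set = set()
    if series.modality == MODALITY_DSA:
        baseline = raw[series.mask_frame_index]
    else:
        nb = series.mask_frame_index
        baseline = raw[:nb].mean() if nb > 0 else 0.0
    values = raw - baseline
    if np.ptp(raw) == 0:
        values = np.zeros_like(values)
        flags.add(FLAG_CONSTANT_SERIES)
    return TimeDensityCurve(times=series.times, values=values,
                            roi_label=roi.label, n_voxels=roi.n_voxels,
                            quality_flags=flags)


def robust_noise_estimate(values: np.ndarray) -> float:
    """Noise level from the median absolute successive difference.

    For i.i.d. noise on a slowly varying curve, successive differences have
    standard deviation sigma * sqrt(2); 1.4826 * MAD estimates their SD.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        return 0.0
    d = np.diff(values)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def time_to_peak(curve: TimeDensityCurve, method: str = "argmax") -> TTPMeasurement:
    """Time at which the curve reaches its maximum.

    ``argmax`` takes the earliest frame of maximum value (deterministic tie
    rule).  ``parabolic`` refines the discrete argmax with a three-point
    parabola through the neighbouring frames; at the boundary it falls back
    to the discrete value, and the refinement never moves the peak by more
    than one frame interval.
    """
    if method not in ("argmax", "parabolic"):
        raise ValueError(f"unknown TTP method {method!r}")
    values = curve.values
    if len(values) == 0:
        raise ValueError("empty curve")
    i = int(np.argmax(values))          # np.argmax returns the earliest tie
    peak = float(values[i])
    ttp = float(curve.times[i])
    flags = set(curve.quality_flags)
    if i == 0 or i == len(values) - 1:
        flags.add(FLAG_PEAK_AT_BOUNDARY)
    elif method == "parabolic":
        y0, y1, y2 = values[i - 1], values[i], values[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:                   # strict local max; vertex is defined
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -1.0, 1.0))
            step = float(curve.times[i] - curve.times[i - 1])
            ttp = float(curve.times[i] + delta * step)
    noise = robust_noise_estimate(values)
    if peak < LOW_CONTRAST_SNR * noise or peak <= 0:
        flags.add(FLAG_LOW_CONTRAST)
    return TTPMeasurement(roi_label=curve.roi_label, ttp=ttp, peak_value=peak,
                          method=method, quality_flags=flags)


def locate_phantom_rois(masks: LabeledMasks, convention: str) -> list:
    """ROISpec list for every label a placement convention requires.

    ``dsa_lateral`` expects both carotid territories and both superior
    sagittal sinus measurements on the lateral view; ``ctp_axial`` expects
    the dominant A2, both insular M2 branches and a single SSS on the axial
    slice.  ROIs come from phantom metadata; no image analysis is done.
    """
    conventions = {"dsa_lateral": DSA_LATERAL_LABELS,
                   "ctp_axial": CTP_AXIAL_LABELS}
    if convention not in conventions:
        raise ValueError(f"unknown convention {convention!r}")
    required: Iterable[str] = conventions[convention]
    missing = [lab for lab in required if lab not in masks.labels]
    if missing:
        raise LabelError(f"label map is missing required labels: {missing}")
    return [masks.roi(lab) for lab in required]
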