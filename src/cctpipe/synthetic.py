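"""Synthetic dynamic-contrast cohort generator.

Emulates the data structure of a post-SAH vasospasm imaging study: every
subject gets a CT-perfusion acquisition (3D+t, 1 s frames for 1 min), a
lateral-view DSA acquisition (2D+t with a pre-contrast mask frame), labelled
vessel ROI masks, and a ground-truth record.  Vessel time–density curves are
peak-normalized gamma-variate boluses; brain tissue carries the arterial
input convolved with an exponential residue function scaled by the true
cerebral blood flow; the arterial→venous delay between paired ROIs is the
ground-truth cerebral circulation time (CCT).

Group-level CCT calibration defaults are the control/vasospasm means and SDs
of the study population this generator emulates; true CCTs are drawn from
those normals truncated below at a physiologic floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import stats

from .tdc import (
    DynamicSeries, LabeledMasks, MODALITY_CTP, MODALITY_DSA,
)

# ---------------------------------------------------------------------------
# index bookkeeping

XA_INDEXES = ("XA-CCT_RA2", "XA-CCT_LA2", "XA-CCT_RM2", "XA-CCT_LM2")
CT_INDEXES = ("CT-CCT_A2", "CT-CCT_RM2", "CT-CCT_LM2")
ALL_INDEXES = XA_INDEXES + CT_INDEXES

GROUP_CONTROL = "control"
GROUP_VASOSPASM = "vasospasm"

#: (control mean, control SD, vasospasm mean, vasospasm SD) in seconds.
DEFAULT_GROUP_CCT: Dict[str, Tuple[float, float, float, float]] = {
    "XA-CCT_RA2": (4.9, 0.9, 6.0, 1.3),
    "XA-CCT_LA2": (4.6, 1.0, 5.8, 2.4),
    "XA-CCT_RM2": (4.7, 1.3, 5.8, 2.1),
    "XA-CCT_LM2": (4.9, 0.8, 5.9, 2.1),
    "CT-CCT_A2": (5.0, 2.6, 6.4, 2.2),
    "CT-CCT_RM2": (4.9, 2.2, 6.4, 2.2),
    "CT-CCT_LM2": (5.2, 2.1, 6.7, 1.7),
}

# perfusion-truth calibration: (control mean, control SD, vaso mean, vaso SD)
DEFAULT_GROUP_MTT = (5.5, 1.1, 6.3, 2.1)     # s
DEFAULT_GROUP_CBV = (4.0, 1.6, 3.3, 1.0)     # ml/100 g
DEFAULT_GROUP_GCS = (12.3, 3.9, 10.3, 4.5)
FISHER_GRADES = ("I", "II", "III", "IV")
DEFAULT_FISHER_P = {
    GROUP_CONTROL: (6 / 19, 6 / 19, 1 / 19, 6 / 19),
    GROUP_VASOSPASM: (5 / 22, 2 / 22, 2 / 22, 13 / 22),
}

MTT_FLOOR = 2.0      # s; keeps transit physiologic
CBV_FLOOR = 0.5      # ml/100 g

# intensity model (arbitrary HU-like units)
CTP_BASELINE = 40.0
ARTERIAL_AMPLITUDE = 100.0
CTP_VENOUS_AMPLITUDE = 70.0
DSA_VENOUS_AMPLITUDE = 60.0

# curve-shape constants: arterial curves are narrower than venous ones
CTP_ARTERIAL_AB = 6.0        # alpha*beta (s); alpha fixed below
CTP_VENOUS_AB = 9.0
DSA_ARTERIAL_AB = 2.0
DSA_VENOUS_AB = 3.5
GV_ALPHA = 3.0
T0_MIN = 0.5                 # earliest permissible bolus arrival (s)

# default venous peak times (s), jittered per subject
CTP_SSS_MODE = 19.5
DSA_RSSS_MODE = 9.5
DSA_LSSS_MODE = 9.1

# hematocrit correction and brain tissue density for ml/100 g scaling
K_H = 0.73
RHO = 1.04   # g/ml

# fractional in-plane ROI centre positions
CTP_POSITIONS = {"A2": (0.50, 0.22), "RM2": (0.72, 0.50),
                 "LM2": (0.28, 0.50), "SSS": (0.50, 0.82),
                 "TISSUE": (0.42, 0.66)}
DSA_POSITIONS = {"RA2": (0.33, 0.22), "LA2": (0.28, 0.38),
                 "RM2": (0.55, 0.40), "LM2": (0.50, 0.56),
                 "SSS_right": (0.80, 0.28), "SSS_left": (0.76, 0.48)}
# ROI sizing follows vessel caliber: 3x3 for the small A2/M2 arteries, 5x5
# for the much larger superior sagittal sinus, and a cm^2-scale parenchymal
# block (15x15 on the default grid) for the tissue ROI.
VESSEL_HALF = 1
SSS_HALF = 2
TISSUE_HALF = 7
DOMINANT_A2_SHIFT = 0.05   # fractional x shift of the A2 ROI by side


def _label_half(name: str) -> int:
    if name.startswith("SSS"):
        return SSS_HALF
    if name == "TISSUE":
        return TISSUE_HALF
    return VESSEL_HALF


class GenerationError(RuntimeError):
    """Raised when a phantom cannot be assembled on the requested grid."""


# ---------------------------------------------------------------------------
# gamma-variate bolus model


@dataclass(frozen=True)
class GammaVariateParams:
    """Peak-normalized gamma-variate bolus: arrival t0, shape alpha, time
    scale beta (s), peak amplitude; the analytic mode is ``t0 + alpha*beta``.
    """

    t0: float
    alpha: float
    beta: float
    amplitude: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"gamma-variate parameter {name} must be > 0")
        if self.t0 < 0:
            raise ValueError("gamma-variate parameter t0 must be >= 0")

    @property
    def mode(self) -> float:
        return self.t0 + self.alpha * self.beta


def gamma_variate(t, params: GammaVariateParams):
    """Evaluate the peak-normalized gamma-variate at times ``t`` (s).

    Zero up to arrival; ``amplitude * ((t-t0)/(alpha*beta))**alpha *
    exp(alpha - (t-t0)/beta)`` after, so the global maximum equals
    ``amplitude`` at ``t0 + alpha*beta``.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros(t.shape)
    m = t > params.t0
    x = (t[m] - params.t0) / (params.alpha * params.beta)
    out[m] = params.amplitude * x ** params.alpha * np.exp(
        params.alpha - (t[m] - params.t0) / params.beta)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# configuration and ground truth


@dataclass
class CohortConfig:
    n_control: int = 19
    n_vasospasm: int = 22
    frame_interval_ctp: float = 1.0
    n_frames_ctp: int = 60
    frame_interval_dsa: float = 0.5
    n_frames_dsa: int = 50
    grid_ctp: Tuple[int, int, int] = (64, 64, 4)
    grid_dsa: Tuple[int, int] = (128, 128)
    group_cct: Dict[str, Tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_CCT))
    noise_sd: float = 5.0          # SNR 20 against the arterial amplitude
    reader_jitter_voxels: float = 0.5   # sub-voxel; reproduces ICC ~0.95+
    cct_floor: float = 0.5         # lower truncation of sampled true CCTs (s)
    n_baseline_frames: int = 3     # CTP pre-contrast frames
    seed: int = 0

    def validate(self) -> None:
        if self.n_control < 0 or self.n_vasospasm < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_control + self.n_vasospasm < 1:
            raise ValueError("cohort must contain at least one subject")
        if self.frame_interval_ctp <= 0 or self.frame_interval_dsa <= 0:
            raise ValueError("frame intervals must be > 0")
        if self.n_frames_ctp < 2 or self.n_frames_dsa < 2:
            raise ValueError("each series needs at least 2 frames")
        if self.noise_sd < 0 or self.reader_jitter_voxels < 0:
            raise ValueError("noise_sd and reader_jitter_voxels must be >= 0")
        for name, (m0, s0, m1, s1) in self.group_cct.items():
            if s0 < 0 or s1 < 0:
                raise ValueError(f"negative SD configured for {name}")
        if min(self.grid_ctp[:2]) < 48 or min(self.grid_dsa) < 48:
            raise GenerationError(
                "grid too small to place all ROIs disjointly")


@dataclass
class SubjectTruth:
    """Ground truth for one synthetic subject.

    ``true_cct_per_index`` holds the arterial→venous delay (s) for each of
    the seven circulation-time indices; by construction it equals the
    difference of the analytic gamma-variate modes of the paired venous and
    arterial ROIs.  MTT, CBF and CBV satisfy the central-volume identity
    ``mtt = 60 * cbv / cbf``.
    """

    subject_id: str
    group: str
    true_cct_per_index: Dict[str, float]
    ctp_params: Dict[str, GammaVariateParams]
    dsa_params: Dict[str, GammaVariateParams]
    residue_model: str
    true_mtt: float
    true_cbf: float
    true_cbv: float
    dominant_aca_side: str
    gcs: int
    fisher_grade: str


@dataclass
class SubjectData:
    truth: SubjectTruth
    ctp: DynamicSeries
    dsa: DynamicSeries
    masks_ctp: LabeledMasks
    masks_dsa: LabeledMasks


def derive_subject_seed(master_seed: int, subject_index: int) -> int:
    """Fixed arithmetic so any cohort subset regenerates identically."""
    return (master_seed * 1_000_003 + 7_919 * subject_index + 1) % (2 ** 31)


def derive_reader_seed(master_seed: int, subject_index: int,
                       reader_index: int) -> int:
    return (master_seed * 2_000_003 + 104_729 * subject_index
            + 613 * (reader_index + 1)) % (2 ** 31)


def _truncated_normal(rng, mean, sd, low):
    if sd == 0:
        return max(mean, low)
    a = (low - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                     random_state=rng))


def truncated_cct_moments(mean: float, sd: float,
                          floor: float = 0.5) -> Tuple[float, float]:
    """Analytic mean and SD of the lower-truncated normal the generator
    actually draws true CCTs from."""
    a = (floor - mean) / sd
    return (float(stats.truncnorm.mean(a, np.inf, loc=mean, scale=sd)),
            float(stats.truncnorm.std(a, np.inf, loc=mean, scale=sd)))


def _gv_for_mode(mode: float, ab: float, amplitude: float) -> GammaVariateParams:
    """Gamma-variate with a prescribed analytic mode and dispersion alpha*beta."""
    t0 = mode - ab
    if t0 < 0:
        raise GenerationError(f"bolus arrival {t0:.2f}s < 0 for mode {mode:.2f}s")
    return GammaVariateParams(t0=t0, alpha=GV_ALPHA, beta=ab / GV_ALPHA,
                              amplitude=amplitude)


def _sample_one_truth(rng: np.random.Generator, subject_id: str, group: str,
                      config: CohortConfig) -> SubjectTruth:
    g = 0 if group == GROUP_CONTROL else 2
    ccts = {}
    for name in ALL_INDEXES:
        mean, sd = config.group_cct[name][g], config.group_cct[name][g + 1]
        ccts[name] = _truncated_normal(rng, mean, sd, config.cct_floor)

    # CTP: one shared venous (SSS) peak; arterial peaks are earlier by the
    # per-index CCT.  The venous peak is raised if needed so every arterial
    # arrival stays >= T0_MIN.
    max_ct = max(ccts[n] for n in CT_INDEXES)
    v_ctp = max(CTP_SSS_MODE + rng.normal(0.0, 1.0),
                max_ct + CTP_ARTERIAL_AB + T0_MIN)
    ctp_params = {
        "SSS": _gv_for_mode(v_ctp, CTP_VENOUS_AB, CTP_VENOUS_AMPLITUDE),
        "A2": _gv_for_mode(v_ctp - ccts["CT-CCT_A2"], CTP_ARTERIAL_AB,
                           ARTERIAL_AMPLITUDE),
        "RM2": _gv_for_mode(v_ctp - ccts["CT-CCT_RM2"], CTP_ARTERIAL_AB,
                            ARTERIAL_AMPLITUDE),
        "LM2": _gv_for_mode(v_ctp - ccts["CT-CCT_LM2"], CTP_ARTERIAL_AB,
                            ARTERIAL_AMPLITUDE),
    }

    # DSA: each carotid injection has its own SSS measurement.
    max_r = max(ccts["XA-CCT_RA2"], ccts["XA-CCT_RM2"])
    max_l = max(ccts["XA-CCT_LA2"], ccts["XA-CCT_LM2"])
    v_r = max(DSA_RSSS_MODE + rng.normal(0.0, 0.8),
              max_r + DSA_ARTERIAL_AB + T0_MIN)
    v_l = max(DSA_LSSS_MODE + rng.normal(0.0, 0.8),
              max_l + DSA_ARTERIAL_AB + T0_MIN)
    dsa_params = {
        "SSS_right": _gv_for_mode(v_r, DSA_VENOUS_AB, DSA_VENOUS_AMPLITUDE),
        "SSS_left": _gv_for_mode(v_l, DSA_VENOUS_AB, DSA_VENOUS_AMPLITUDE),
        "RA2": _gv_for_mode(v_r - ccts["XA-CCT_RA2"], DSA_ARTERIAL_AB,
                            ARTERIAL_AMPLITUDE),
        "RM2": _gv_for_mode(v_r - ccts["XA-CCT_RM2"], DSA_ARTERIAL_AB,
                            ARTERIAL_AMPLITUDE),
        "LA2": _gv_for_mode(v_l - ccts["XA-CCT_LA2"], DSA_ARTERIAL_AB,
                            ARTERIAL_AMPLITUDE),
        "LM2": _gv_for_mode(v_l - ccts["XA-CCT_LM2"], DSA_ARTERIAL_AB,
                            ARTERIAL_AMPLITUDE),
    }

    mtt = _truncated_normal(rng, DEFAULT_GROUP_MTT[g], DEFAULT_GROUP_MTT[g + 1],
                            MTT_FLOOR)
    cbv = _truncated_normal(rng, DEFAULT_GROUP_CBV[g], DEFAULT_GROUP_CBV[g + 1],
                            CBV_FLOOR)
    cbf = 60.0 * cbv / mtt
    gcs = int(np.clip(round(rng.normal(DEFAULT_GROUP_GCS[g],
                                       DEFAULT_GROUP_GCS[g + 1])), 3, 15))
    fisher = str(rng.choice(FISHER_GRADES, p=DEFAULT_FISHER_P[group]))
    side = "right" if rng.random() < 0.5 else "left"
    return SubjectTruth(subject_id=subject_id, group=group,
                        true_cct_per_index=ccts, ctp_params=ctp_params,
                        dsa_params=dsa_params, residue_model="exponential",
                        true_mtt=mtt, true_cbf=cbf, true_cbv=cbv,
                        dominant_aca_side=side, gcs=gcs, fisher_grade=fisher)


def sample_truths(config: CohortConfig) -> List[SubjectTruth]:
    """Draw ground truth for the whole cohort (controls first)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truths = []
    for i in range(config.n_control + config.n_vasospasm):
        group = GROUP_CONTROL if i < config.n_control else GROUP_VASOSPASM
        truths.append(_sample_one_truth(rng, f"S{i + 1:03d}", group, config))
    return truths


# ---------------------------------------------------------------------------
# image synthesis


def discrete_residue_decay(mtt: float, dt: float) -> float:
    """Decay constant of the sampled exponential residue, calibrated so the
    rectangle-rule area ``dt * sum(exp(-k*dt/tau))`` equals ``mtt`` exactly.
    """
    if dt >= mtt:
        raise GenerationError("frame interval must be shorter than MTT")
    return -dt / np.log(1.0 - dt / mtt)


def tissue_curve(aif_values: np.ndarray, mtt: float, cbf: float,
                 dt: float) -> np.ndarray:
    """Tissue enhancement = (CBF-scaled) AIF ⊛ exponential residue.

    Scaling: with CBV = 100*(k_H/rho)*area(tissue)/area(AIF) (ml/100 g) and
    the central-volume identity MTT = 60*CBV/CBF, the convolution carries the
    factor ``cbf / (60 * 100 * k_H / rho)``.
    """
    n = len(aif_values)
    t = np.arange(n) * dt
    residue = np.exp(-t / discrete_residue_decay(mtt, dt))
    conv = np.convolve(aif_values, residue)[:n] * dt
    k = 100.0 * K_H / RHO
    return cbf / (60.0 * k) * conv


def _block_mask(shape, centre, half=VESSEL_HALF):
    sl = []
    for dim, c in zip(shape, centre):
        lo, hi = c - half, c + half + 1
        if lo < 0 or hi > dim:
            raise GenerationError("grid too small to place all ROIs disjointly")
        sl.append(slice(lo, hi))
    return tuple(sl)


def _place_labels(grid, positions, z: Optional[int] = None):
    """Integer label image; raises if any two blocks would overlap."""
    data = np.zeros(grid, dtype=np.int16)
    labels = {}
    for value, (name, frac) in enumerate(sorted(positions.items()), start=1):
        centre = [int(round(f * (dim - 1))) for f, dim in zip(frac, grid[:2])]
        sl = _block_mask(grid[:2], centre, half=_label_half(name))
        if z is not None:
            sl = sl + (z,)
        if np.any(data[sl] != 0):
            raise GenerationError("grid too small to place all ROIs disjointly")
        data[sl] = value
        labels[name] = value
    return LabeledMasks(data=data, labels=labels)


def _ctp_positions(truth: SubjectTruth):
    pos = dict(CTP_POSITIONS)
    dx = DOMINANT_A2_SHIFT if truth.dominant_aca_side == "right" else -DOMINANT_A2_SHIFT
    pos["A2"] = (pos["A2"][0] + dx, pos["A2"][1])
    return pos


def synthesize_ctp(truth: SubjectTruth, config: CohortConfig,
                   rng: np.random.Generator) -> Tuple[DynamicSeries, LabeledMasks]:
    grid = tuple(config.grid_ctp)
    dt = config.frame_interval_ctp
    t = np.arange(config.n_frames_ctp) * dt
    aif = gamma_variate(t, truth.ctp_params["A2"])
    parenchyma = tissue_curve(aif, truth.true_mtt, truth.true_cbf, dt)

    data = np.empty(grid + (config.n_frames_ctp,), dtype=float)
    data[...] = CTP_BASELINE + parenchyma          # brain everywhere ...
    masks = _place_labels(grid, _ctp_positions(truth), z=grid[2] // 2)
    for name in ("A2", "RM2", "LM2", "SSS"):       # ... vessels overwrite it
        curve = CTP_BASELINE + gamma_variate(t, truth.ctp_params[name])
        data[masks.mask_for(name)] = curve
    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=data.shape)
    series = DynamicSeries(data=data, frame_interval=dt, modality=MODALITY_CTP,
                           mask_frame_index=config.n_baseline_frames)
    return series, masks


def synthesize_dsa(truth: SubjectTruth, config: CohortConfig,
                   rng: np.random.Generator) -> Tuple[DynamicSeries, LabeledMasks]:
    grid = tuple(config.grid_dsa)
    dt = config.frame_interval_dsa
    # frame 0 is the mask frame (t = 0); contrast is zero there by model.
    t = np.arange(config.n_frames_dsa) * dt
    data = np.zeros(grid + (config.n_frames_dsa,), dtype=float)
    masks = _place_labels(grid, DSA_POSITIONS)
    for name, params in truth.dsa_params.items():
        data[masks.mask_for(name)] = gamma_variate(t, params)
    if config.noise_sd > 0:
        data += rng.normal(0.0, config.noise_sd, size=data.shape)
        data[..., 0] = 0.0     # subtracted mask frame is identically zero
    series = DynamicSeries(data=data, frame_interval=dt, modality=MODALITY_DSA,
                           mask_frame_index=0)
    return series, masks


def synthesize_subject(truth: SubjectTruth, config: CohortConfig,
                       seed: int) -> SubjectData:
    """Render one subject's CTP and DSA acquisitions plus ROI masks.

    Pure function of (truth, config, seed): the same seed reproduces the
    series bit for bit.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    ctp, masks_ctp = synthesize_ctp(truth, config, rng)
    dsa, masks_dsa = synthesize_dsa(truth, config, rng)
    return SubjectData(truth=truth, ctp=ctp, dsa=dsa,
                       masks_ctp=masks_ctp, masks_dsa=masks_dsa)


def synthesize_cohort(config: CohortConfig) -> List[SubjectData]:
    """Full synthetic cohort; per-subject seeds derive from ``config.seed``."""
    return [synthesize_subject(truth, config,
                               derive_subject_seed(config.seed, i))
            for i, truth in enumerate(sample_truths(config))]


# ---------------------------------------------------------------------------
# reader simulation


def simulate_reader(masks: LabeledMasks, jitter: float,
                    seed: int) -> LabeledMasks:
    """A reader's ROI placement: each labelled mask is translated by an
    integer in-plane displacement drawn as round(N(0, jitter)) per axis.

    Displacements that would push a mask over the grid edge are clamped so
    the mask stays whole, and the label is recorded in ``clipped``.  With
    ``jitter == 0`` the masks are returned unchanged.
    """
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    data = np.zeros_like(masks.data)
    clipped = set(masks.clipped)
    shape = masks.data.shape
    displacements = {name: np.rint(rng.normal(0.0, jitter, size=2)).astype(int)
                     for name in sorted(masks.labels)}
    # displaced ROIs may overlap; paint the largest first so that a small
    # vessel ROI keeps its voxels when a big tissue block drifts onto it
    sizes = {name: int((masks.data == v).sum())
             for name, v in masks.labels.items()}
    for name in sorted(masks.labels, key=lambda n: (-sizes[n], n)):
        value = masks.labels[name]
        disp = displacements[name]
        idx = np.argwhere(masks.data == value)
        for axis in range(2):          # in-plane axes only
            lo, hi = idx[:, axis].min(), idx[:, axis].max()
            allowed = np.clip(disp[axis], -lo, shape[axis] - 1 - hi)
            if allowed != disp[axis]:
                clipped.add(name)
            idx[:, axis] += allowed
        data[tuple(idx.T)] = value
    return LabeledMasks(data=data, labels=dict(masks.labels), clipped=clipped)
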