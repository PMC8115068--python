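"""Synthetic dynamic PET cohorts with known kinetic ground truth.

Reference curves are gamma-variates (smooth, positive, single early peak —
qualitatively like a cerebellar FDOPA curve); tissue curves are built from
the reference by the irreversible-uptake construction

    C_T(t) = ki_true * int_0^t C_R dtau + v_prime * C_R(t)

evaluated with the *same* midpoint-trapezoid rule the estimator uses, so the
noiseless generator is exactly invertible by the graphical fit. Noise is
multiplicative Gaussian with variance inversely proportional to frame
duration, calibrated so the longest frames have the requested CV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    FrameSchedule,
    KineticGroundTruth,
    MaskVolume,
    ReferenceTAC,
    SubjectScan,
    TissueTAC,
)
from .patlak import reference_integral_min

__all__ = [
    "CohortDesign",
    "make_reference_tac",
    "make_tissue_tac",
    "make_mask",
    "simulate_cohort",
    "simulate_test_retest",
    "draw_cohort_truths",
]

SUBDIVISIONS = ("limbic", "associative", "sensorimotor")

#: striatal label sizes summing to the default 2847-voxel feature dimension
DEFAULT_STRIATAL_COUNTS = {"limbic": 600, "associative": 1447, "sensorimotor": 800}


# ---------------------------------------------------------------------------
# curves


def make_reference_tac(
    schedule: FrameSchedule,
    peak_time_min: float = 5.0,
    amplitude: float = 20.0,
    washout_min: float = 40.0,
    fine_step_s: float = 1.0,
) -> ReferenceTAC:
    """Frame-averaged gamma-variate reference curve.

    ``g(t) = amplitude * (t/tp)^(tp/tau) * exp((tp - t) / tau)`` with peak at
    ``tp = peak_time_min`` and washout timescale ``tau = washout_min``, so the
    curve rises to a single early peak and then decays slowly over the scan.
    Evaluated on a fine grid (<= 1 s step) and averaged within each frame;
    deterministic given its inputs.
    """
    if peak_time_min <= 0 or amplitude <= 0 or washout_min <= 0:
        raise ValueError("peak_time_min, amplitude and washout_min must be > 0")
    if fine_step_s <= 0 or fine_step_s > 1.0:
        raise ValueError("fine_step_s must be in (0, 1] seconds")
    if peak_time_min * 60.0 >= schedule.end_s:
        raise ValueError("peak_time_min must fall within the scan duration")
    tp = peak_time_min
    alpha = tp / washout_min
    activity = np.empty(schedule.n_frames)
    for k in range(schedule.n_frames):
        t = np.arange(schedule.starts_s[k], schedule.starts_s[k] + schedule.durations_s[k]
                      + 0.5 * fine_step_s, fine_step_s) / 60.0
        with np.errstate(divide="ignore"):
            curve = amplitude * (t / tp) ** alpha * np.exp((tp - t) / washout_min)
        curve[t == 0] = 0.0
        activity[k] = float(np.mean(curve))
    return ReferenceTAC(schedule, activity)


def _noise_sigma(schedule: FrameSchedule, noise_cv: float) -> np.ndarray:
    """Per-frame multiplicative noise SD; equals ``noise_cv`` on the longest
    frames and grows as 1/sqrt(duration) for shorter ones."""
    d = schedule.durations_s
    return noise_cv * np.sqrt(d.max() / d)


def make_tissue_tac(
    ref: ReferenceTAC,
    truth: KineticGroundTruth,
    noise_cv: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> TissueTAC:
    """Tissue curve with influx slope ``truth.ki_true`` against ``ref``."""
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    xint = reference_integral_min(ref)
    clean = truth.ki_true * xint + truth.v_prime * ref.activity
    if noise_cv == 0:
        return TissueTAC(ref.schedule, clean)
    rng = np.random.default_rng(rng)
    sigma = _noise_sigma(ref.schedule, noise_cv)
    noisy = clean * (1.0 + sigma * rng.standard_normal(clean.size))
    return TissueTAC(ref.schedule, np.clip(noisy, 0.0, None))


# ---------------------------------------------------------------------------
# atlas


def make_mask(
    shape: tuple[int, int, int] = (24, 24, 12),
    striatal_counts: dict[str, int] | None = None,
    n_cerebellum: int = 500,
    n_extra_striatal: int = 1500,
    voxel_size_mm: float = 2.0,
) -> MaskVolume:
    """Synthetic box atlas with disjoint labels; striatal labels default to a
    2847-voxel total. Geometry is a flat fill — anatomical realism is a
    non-goal."""
    counts = dict(DEFAULT_STRIATAL_COUNTS if striatal_counts is None else striatal_counts)
    sizes = [counts["limbic"], counts["associative"], counts["sensorimotor"],
             n_cerebellum, n_extra_striatal]
    if any(s <= 0 for s in sizes):
        raise ValueError("all region sizes must be > 0")
    total = int(np.prod(shape))
    if sum(sizes) > total:
        raise ValueError(f"regions need {sum(sizes)} voxels; volume has {total}")
    flat = np.zeros(total, dtype=np.int16)
    pos = 0
    for label, size in zip((1, 2, 3, 4, 5), sizes):
        flat[pos:pos + size] = label
        pos += size
    return MaskVolume(flat.reshape(shape), voxel_size_mm=voxel_size_mm)


# ---------------------------------------------------------------------------
# cohort design


def _default_means() -> dict:
    base = {"limbic": 0.0120, "associative": 0.0125, "sensorimotor": 0.0118}
    sd = 0.0015
    d = {"limbic": 0.6, "associative": 0.8, "sensorimotor": 0.4}
    responder = {r: base[r] + d[r] * sd for r in SUBDIVISIONS}
    return {
        "non_responder": base,
        "responder": responder,
        "control": dict(responder),
    }


@dataclass(frozen=True)
class CohortDesign:
    """Generating parameters of a synthetic cohort.

    ``mean_ki[group][subdivision]`` (1/min) and a shared per-subdivision
    between-subject SD define the subject-level truth distribution;
    ``noise_cv`` is the per-voxel multiplicative CV on the longest frames.
    """

    n_per_group: dict = field(
        default_factory=lambda: {"control": 12, "responder": 13, "non_responder": 13}
    )
    mean_ki: dict = field(default_factory=_default_means)
    between_sd: dict = field(
        default_factory=lambda: {r: 0.0015 for r in SUBDIVISIONS}
    )
    within_cv: float = 0.02
    noise_cv: float = 0.05
    v_prime: float = 0.5
    v_prime_extra: float = 0.8
    voxel_jitter_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_group or any(n < 1 for n in self.n_per_group.values()):
            raise ValueError("every listed group must have n >= 1")
        for g, means in self.mean_ki.items():
            if any(m <= 0 for m in means.values()):
                raise ValueError(f"group {g!r} mean Ki must be positive")
        if any(s < 0 for s in self.between_sd.values()):
            raise ValueError("between-subject SDs must be >= 0")
        for cv in (self.within_cv, self.noise_cv):
            if not 0 <= cv < 1:
                raise ValueError("CVs must lie in [0, 1)")
        if self.voxel_jitter_sd < 0:
            raise ValueError("voxel_jitter_sd must be >= 0")

    def with_effect_size(self, d_by_subdivision: dict[str, float]) -> "CohortDesign":
        """Set responder means = non-responder means + d * between-SD."""
        means = {g: dict(v) for g, v in self.mean_ki.items()}
        for r, d in d_by_subdivision.items():
            means["responder"][r] = means["non_responder"][r] + d * self.between_sd[r]
        return replace(self, mean_ki=means)


def draw_cohort_truths(design: CohortDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Subject-level true Ki per subdivision, drawn from the group
    distributions. One row per subject; used by the cohort builder and
    directly testable without building any image."""
    rows = []
    for group, n in design.n_per_group.items():
        for i in range(n):
            row = {"subject_id": f"{group}_{i:03d}", "group": group}
            for r in SUBDIVISIONS:
                ki = rng.normal(design.mean_ki[group][r], design.between_sd[r])
                row[r] = max(ki, 1e-5)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scan assembly


def _voxel_truth(
    sub_ki: dict[str, float],
    design: CohortDesign,
    mask: MaskVolume,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel (ki, v_prime) arrays for one subject; the voxel-scale jitter
    is drawn here once so paired sessions can share it."""
    n_vox = mask.data.size
    ki_flat = np.zeros(n_vox)
    vp_flat = np.zeros(n_vox)
    for r in SUBDIVISIONS:
        idx = mask.region_indices(r)
        jitter = rng.normal(0.0, design.voxel_jitter_sd, idx.size)
        ki_flat[idx] = np.clip(sub_ki[r] * (1.0 + jitter), 0.0, None)
        vp_flat[idx] = design.v_prime
    vp_flat[mask.region_indices("cerebellum")] = 1.0  # follows the reference
    vp_flat[mask.region_indices("extra_striatal")] = design.v_prime_extra
    return ki_flat, vp_flat


def _build_scan(
    subject_id: str,
    group: str,
    session: str,
    ki_flat: np.ndarray,
    vp_flat: np.ndarray,
    design: CohortDesign,
    ref: ReferenceTAC,
    mask: MaskVolume,
    rng: np.random.Generator,
) -> SubjectScan:
    schedule = ref.schedule
    n_vox = mask.data.size
    labelled = np.flatnonzero(vp_flat > 0)
    xint = reference_integral_min(ref)
    act = ki_flat[labelled, None] * xint[None, :] + vp_flat[labelled, None] * ref.activity[None, :]
    if design.noise_cv > 0:
        sigma = _noise_sigma(schedule, design.noise_cv)
        act = act * (1.0 + sigma[None, :] * rng.standard_normal(act.shape))
        act = np.clip(act, 0.0, None)

    data = np.zeros((n_vox, schedule.n_frames))
    data[labelled] = act
    return SubjectScan(
        subject_id=subject_id,
        group=group,
        session=session,
        data=data.reshape(mask.data.shape + (schedule.n_frames,)),
        schedule=schedule,
        mask=mask,
        truth_ki=ki_flat.reshape(mask.data.shape),
        truth_vprime=vp_flat.reshape(mask.data.shape),
    )


def simulate_cohort(
    design: CohortDesign,
    schedule: FrameSchedule,
    mask: MaskVolume | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[SubjectScan]:
    """One single-session scan per subject; all randomness flows from one
    generator (``design.seed`` unless an rng is given)."""
    mask = make_mask() if mask is None else mask
    rng = np.random.default_rng(design.seed if rng is None else rng)
    ref = make_reference_tac(schedule)
    truths = draw_cohort_truths(design, rng)
    scans = []
    for row in truths.itertuples(index=False):
        sub_ki = {r: getattr(row, r) for r in SUBDIVISIONS}
        ki_flat, vp_flat = _voxel_truth(sub_ki, design, mask, rng)
        scans.append(
            _build_scan(row.subject_id, row.group, "test", ki_flat, vp_flat,
                        design, ref, mask, rng)
        )
    return scans


def simulate_test_retest(
    design: CohortDesign,
    schedule: FrameSchedule,
    mask: MaskVolume | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[SubjectScan, SubjectScan]]:
    """Paired sessions: retest subject Ki = test Ki * (1 + within-subject
    perturbation with SD ``design.within_cv``); noise independent per
    session."""
    mask = make_mask() if mask is None else mask
    rng = np.random.default_rng(design.seed if rng is None else rng)
    ref = make_reference_tac(schedule)
    truths = draw_cohort_truths(design, rng)
    pairs = []
    for row in truths.itertuples(index=False):
        test_ki = {r: getattr(row, r) for r in SUBDIVISIONS}
        ki_flat, vp_flat = _voxel_truth(test_ki, design, mask, rng)
        # retest scales each subdivision's voxels by the same within-subject
        # factor, keeping the voxel-scale jitter pattern shared across sessions
        retest_flat = ki_flat.copy()
        for r in SUBDIVISIONS:
            factor = max(1.0 + rng.normal(0.0, design.within_cv), 1e-3)
            retest_flat[mask.region_indices(r)] *= factor
        test = _build_scan(row.subject_id, row.group, "test", ki_flat, vp_flat,
                           design, ref, mask, rng)
        retest = _build_scan(row.subject_id, row.group, "retest", retest_flat, vp_flat,
                             design, ref, mask, rng)
        pairs.append((test, retest))
    return pairs
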