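"""Shared domain types: frame schedules, time-activity curves, masks and scans.

Internal time unit is the minute (influx constants are reported in 1/min);
frame schedules are *stored* in seconds, as acquired, and converted once via
properties. All activities are assumed decay-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameSchedule",
    "ReferenceTAC",
    "TissueTAC",
    "KineticGroundTruth",
    "MaskVolume",
    "SubjectScan",
    "STRIATAL_LABELS",
    "LABEL_NAMES",
]

#: canonical integer labels of the synthetic atlas
LABEL_NAMES = {
    0: "background",
    1: "limbic",
    2: "associative",
    3: "sensorimotor",
    4: "cerebellum",
    5: "extra_striatal",
}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}
STRIATAL_LABELS = (1, 2, 3)


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition frames as (start, duration) pairs in seconds post-injection.

    Frames must be contiguous: ``starts[i + 1] == starts[i] + durations[i]``.
    """

    starts_s: np.ndarray
    durations_s: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts_s, dtype=float)
        durs = np.asarray(self.durations_s, dtype=float)
        object.__setattr__(self, "starts_s", starts)
        object.__setattr__(self, "durations_s", durs)
        if starts.ndim != 1 or starts.shape != durs.shape:
            raise ValueError("starts and durations must be 1-D and equal length")
        if starts.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if np.any(durs <= 0):
            raise ValueError("all frame durations must be > 0")
        if starts.size > 1 and np.any(np.diff(starts) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if not np.allclose(starts[1:], starts[:-1] + durs[:-1]):
            raise ValueError("frames must be contiguous (start[i+1] = start[i] + dur[i])")

    @classmethod
    def from_blocks(cls, blocks: list[tuple[int, float]]) -> "FrameSchedule":
        """Build a schedule from ``(count, duration_s)`` blocks."""
        durs = np.concatenate([np.full(n, d, dtype=float) for n, d in blocks])
        starts = np.concatenate([[0.0], np.cumsum(durs)[:-1]])
        return cls(starts, durs)

    @classmethod
    def dataset1(cls) -> "FrameSchedule":
        """32-frame schedule: 8x15 s, 3x60 s, 5x120 s, 16x300 s (95 min)."""
        return cls.from_blocks([(8, 15), (3, 60), (5, 120), (16, 300)])

    @classmethod
    def dataset2(cls) -> "FrameSchedule":
        """26-frame schedule: 1x30 s, 4x60 s, 3x120 s, 3x180 s, 15x300 s."""
        return cls.from_blocks([(1, 30), (4, 60), (3, 120), (3, 180), (15, 300)])

    @property
    def n_frames(self) -> int:
        return int(self.starts_s.size)

    @property
    def mid_min(self) -> np.ndarray:
        """Frame midpoints in minutes."""
        return (self.starts_s + 0.5 * self.durations_s) / 60.0

    @property
    def durations_min(self) -> np.ndarray:
        return self.durations_s / 60.0

    @property
    def end_s(self) -> float:
        return float(self.starts_s[-1] + self.durations_s[-1])

    @property
    def total_min(self) -> float:
        return self.end_s / 60.0


def _check_activity(schedule: FrameSchedule, activity: np.ndarray) -> np.ndarray:
    act = np.asarray(activity, dtype=float)
    if act.shape != (schedule.n_frames,):
        raise ValueError(
            f"activity length {act.shape} does not match schedule "
            f"({schedule.n_frames} frames)"
        )
    if np.any(act < 0):
        raise ValueError("activity must be non-negative")
    return act


@dataclass(frozen=True)
class ReferenceTAC:
    """Per-frame decay-corrected activity (kBq/mL) of the reference region."""

    schedule: FrameSchedule
    activity: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "activity", _check_activity(self.schedule, self.activity))


@dataclass(frozen=True)
class TissueTAC:
    """Per-frame decay-corrected activity (kBq/mL) of a target tissue."""

    schedule: FrameSchedule
    activity: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "activity", _check_activity(self.schedule, self.activity))


@dataclass(frozen=True)
class KineticGroundTruth:
    """Generating parameters of an irreversible-uptake tissue curve.

    ``ki_true`` is the influx slope (1/min); ``v_prime`` the effective
    distribution volume (the intercept of the graphical-analysis line).
    """

    ki_true: float
    v_prime: float

    def __post_init__(self) -> None:
        if self.ki_true < 0:
            raise ValueError("ki_true must be >= 0")
        if self.v_prime < 0:
            raise ValueError("v_prime must be >= 0")


@dataclass(frozen=True)
class MaskVolume:
    """Integer-labelled 3-D atlas volume with a fixed label map."""

    data: np.ndarray
    voxel_size_mm: float = 2.0
    label_names: dict = field(default_factory=lambda: dict(LABEL_NAMES))

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError("mask must be an integer volume")
        object.__setattr__(self, "data", data)

    def label_of(self, region: int | str) -> int:
        if isinstance(region, str):
            try:
                return NAME_TO_LABEL[region] if region != "striatum" else -1
            except KeyError:
                raise KeyError(
                    f"unknown region {region!r}; known: "
                    f"{sorted(NAME_TO_LABEL)} + ['striatum']"
                ) from None
        return int(region)

    def region_indices(self, region: int | str) -> np.ndarray:
        """Flat voxel indices of a region; ``'striatum'`` is the union of
        the three striatal subdivision labels."""
        flat = self.data.ravel()
        label = self.label_of(region)
        if label == -1:  # whole striatum
            sel = np.isin(flat, STRIATAL_LABELS)
        else:
            sel = flat == label
        idx = np.flatnonzero(sel)
        if idx.size == 0:
            raise ValueError(
                f"region {region!r} is empty; labels present: "
                f"{sorted(np.unique(flat).tolist())}"
            )
        return idx

    def count(self, region: int | str) -> int:
        return int(self.region_indices(region).size)


@dataclass
class SubjectScan:
    """A subject's 4-D dynamic acquisition plus cohort metadata.

    ``data`` has shape ``mask.shape + (n_frames,)``. Ground-truth influx per
    voxel (``truth_ki``, same 3-D shape) is carried for every generated scan
    so downstream estimates can be scored against it.
    """

    subject_id: str
    group: str
    session: str
    data: np.ndarray
    schedule: FrameSchedule
    mask: MaskVolume
    truth_ki: np.ndarray | None = None
    truth_vprime: np.ndarray | None = None

    GROUPS = ("control", "responder", "non_responder")
    SESSIONS = ("test", "retest")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.group not in self.GROUPS:
            raise ValueError(f"group must be one of {self.GROUPS}")
        if self.session not in self.SESSIONS:
            raise ValueError(f"session must be one of {self.SESSIONS}")
        expected = self.mask.data.shape + (self.schedule.n_frames,)
        if self.data.shape != expected:
            raise ValueError(
                f"scan shape {self.data.shape} does not match mask+schedule {expected}"
            )
        if np.any(self.data < 0):
            raise ValueError("scan activity must be non-negative")

    def region_tac(self, region: int | str) -> TissueTAC:
        """Mean time-activity curve over a region's voxels."""
        idx = self.mask.region_indices(region)
        flat = self.data.reshape(-1, self.schedule.n_frames)
        return TissueTAC(self.schedule, flat[idx].mean(axis=0))

    def reference_tac(self) -> ReferenceTAC:
        """Mean cerebellar curve used as the reference input."""
        idx = self.mask.region_indices("cerebellum")
        flat = self.data.reshape(-1, self.schedule.n_frames)
        return ReferenceTAC(self.schedule, flat[idx].mean(axis=0))
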