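"""Windowed static-uptake metrics: SUVRc and static-image SNR.

SUVRc is the mean activity of a (striatal) region over a short late window
divided by the mean cerebellar activity over the same window. Window start
times are minutes post-injection; frames partially covered by the window
contribute in proportion to their overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MaskVolume, SubjectScan

__all__ = ["SuvrResult", "SnrResult", "static_frame", "compute_suvrc", "compute_snr"]

DEFAULT_WINDOW_STARTS_MIN = (60.0, 75.0, 90.0)
DEFAULT_WINDOW_LENGTH_MIN = 10.0


@dataclass(frozen=True)
class SuvrResult:
    region: str
    window_start_min: float
    window_length_min: float
    suvrc: float


@dataclass(frozen=True)
class SnrResult:
    window_start_min: float
    window_length_min: float
    snr: float


def static_frame(
    scan: SubjectScan, window_start_min: float, window_length_min: float
) -> np.ndarray:
    """Duration-weighted mean 3-D volume over a post-injection window."""
    if window_length_min <= 0:
        raise ValueError("window length must be > 0")
    w0 = window_start_min * 60.0
    w1 = w0 + window_length_min * 60.0
    sched = scan.schedule
    if w0 < sched.starts_s[0] - 1e-9 or w1 > sched.end_s + 1e-9:
        raise ValueError(
            f"window [{window_start_min}, {window_start_min + window_length_min}] min "
            f"outside acquisition [0, {sched.total_min:g}] min"
        )
    f0, f1 = sched.starts_s, sched.starts_s + sched.durations_s
    overlap = np.clip(np.minimum(f1, w1) - np.maximum(f0, w0), 0.0, None)
    total = overlap.sum()
    if total <= 0:
        raise ValueError("window overlaps no frames")
    return np.tensordot(scan.data, overlap / total, axes=([-1], [0]))


def compute_suvrc(
    scan: SubjectScan,
    region: int | str,
    window_start_min: float,
    window_length_min: float,
) -> SuvrResult:
    """Region-to-cerebellum uptake ratio over a static window.

    Window length is a required explicit argument: the acquisition protocol
    admits both 10- and 15-min static frames.
    """
    vol = static_frame(scan, window_start_min, window_length_min)
    flat = vol.ravel()
    region_mean = float(flat[scan.mask.region_indices(region)].mean())
    cere_mean = float(flat[scan.mask.region_indices("cerebellum")].mean())
    if cere_mean <= 0:
        raise ValueError("cerebellar mean activity is non-positive")
    name = region if isinstance(region, str) else scan.mask.label_names[int(region)]
    return SuvrResult(str(name), float(window_start_min), float(window_length_min),
                      region_mean / cere_mean)


def compute_snr(
    static_volume: np.ndarray,
    mask: MaskVolume,
    window_start_min: float = float("nan"),
    window_length_min: float = float("nan"),
) -> SnrResult:
    """Striatal mean divided by the SD of the brain signal outside the
    striatum (extra-striatal label)."""
    flat = np.asarray(static_volume, dtype=float).ravel()
    if flat.size != mask.data.size:
        raise ValueError("static volume does not match mask shape")
    striatal_mean = float(flat[mask.region_indices("striatum")].mean())
    outside = flat[mask.region_indices("extra_striatal")]
    sd = float(outside.std(ddof=1))
    if sd == 0:
        raise ValueError("extra-striatal SD is zero (degenerate noiseless input)")
    return SnrResult(float(window_start_min), float(window_length_min), striatal_mean / sd)
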