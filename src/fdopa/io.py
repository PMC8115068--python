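"""Readers and writers: NIfTI-1 volumes, frame-schedule CSVs, cohort
manifests, ground-truth tables and plain key-value configs.

CSV conventions: comma-separated, UTF-8, header row, '.' decimal, units in
column names. Voxel coordinates are 0-based; mask labels are small integers
with a sidecar label-map text file.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import LABEL_NAMES, FrameSchedule, MaskVolume, SubjectScan

__all__ = [
    "write_schedule",
    "read_schedule",
    "write_mask",
    "read_mask",
    "write_scan",
    "read_dynamic_scan",
    "write_cohort",
    "write_label_map",
    "read_config",
    "write_config",
]


def write_schedule(schedule: FrameSchedule, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"start_s": schedule.starts_s, "duration_s": schedule.durations_s}
    ).to_csv(path, index=False)
    return path


def read_schedule(path) -> FrameSchedule:
    df = pd.read_csv(path)
    missing = {"start_s", "duration_s"} - set(df.columns)
    if missing:
        raise ValueError(f"schedule CSV missing columns: {sorted(missing)}")
    return FrameSchedule(df["start_s"].to_numpy(float), df["duration_s"].to_numpy(float))


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def write_mask(mask: MaskVolume, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.data.astype(np.int16), _affine(mask.voxel_size_mm))
    nib.save(img, path)
    write_label_map(path.parent / (path.name.split(".")[0] + "_labels.txt"))
    return path


def write_label_map(path) -> Path:
    path = Path(path)
    path.write_text(
        "".join(f"{label},{name}\n" for label, name in sorted(LABEL_NAMES.items())),
        encoding="utf-8",
    )
    return path


def read_mask(path) -> MaskVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.int16)
    voxel = float(img.header.get_zooms()[0])
    return MaskVolume(data, voxel_size_mm=voxel)


def write_scan(scan: SubjectScan, out_dir) -> dict:
    """Write one subject's 4-D volume (+ per-voxel truth if present); returns
    the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{scan.subject_id}_{scan.session}"
    aff = _affine(scan.mask.voxel_size_mm)
    paths = {"scan": out_dir / f"{stem}_dyn.nii"}
    nib.save(nib.Nifti1Image(scan.data.astype(np.float64), aff), paths["scan"])
    if scan.truth_ki is not None:
        paths["truth"] = out_dir / f"{stem}_truth_ki_per_min.csv"
        idx = np.flatnonzero(scan.truth_ki.ravel() > 0)
        pd.DataFrame(
            {"voxel_flat_index": idx, "ki_true_per_min": scan.truth_ki.ravel()[idx]}
        ).to_csv(paths["truth"], index=False)
    return paths


def read_dynamic_scan(
    path_image,
    path_frames,
    path_mask,
    subject_id: str = "subject",
    group: str = "control",
    session: str = "test",
) -> SubjectScan:
    """Assemble a 4-D NIfTI + frame-schedule CSV + integer NIfTI mask."""
    img = nib.load(str(path_image))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected 4-D dynamic image, got {data.ndim}-D")
    schedule = read_schedule(path_frames)
    if data.shape[-1] != schedule.n_frames:
        raise ValueError(
            f"image has {data.shape[-1]} frames but schedule lists {schedule.n_frames}"
        )
    mask = read_mask(path_mask)
    if mask.data.shape != data.shape[:3]:
        raise ValueError(
            f"mask shape {mask.data.shape} does not match image {data.shape[:3]}"
        )
    present = sorted(np.unique(mask.data).tolist())
    if 4 not in present:  # cerebellum label, required as the reference region
        raise ValueError(f"mask has no cerebellum label (4); labels present: {present}")
    return SubjectScan(subject_id, group, session, data, schedule, mask)


def write_cohort(scans: list[SubjectScan], out_dir) -> Path:
    """Write every scan plus schedule, mask and a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_schedule(scans[0].schedule, out_dir / "frames.csv")
    nib.save(
        nib.Nifti1Image(scans[0].mask.data.astype(np.int16),
                        _affine(scans[0].mask.voxel_size_mm)),
        out_dir / "mask.nii",
    )
    write_label_map(out_dir / "mask_labels.txt")
    rows = []
    for scan in scans:
        paths = write_scan(scan, out_dir)
        rows.append(
            {
                "subject_id": scan.subject_id,
                "group": scan.group,
                "session": scan.session,
                "scan_path": paths["scan"].name,
                "truth_path": paths.get("truth", Path("")).name,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def _coerce(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            pass
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    return text


def read_config(path) -> dict:
    """Plain ``key = value`` config; '#' starts a comment."""
    out = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = _coerce(value)
    return out


def write_config(config: dict, path) -> Path:
    path = Path(path)
    path.write_text(
        "".join(f"{k} = {v}\n" for k, v in config.items()), encoding="utf-8"
    )
    return path
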