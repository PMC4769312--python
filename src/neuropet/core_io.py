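"""Volume, frame-schedule and blood-curve containers plus NIfTI/TSV readers and writers.

All volumes move through the package as plain :class:`numpy.ndarray` data
attached to a :class:`VolumeGeometry`.  NIfTI-1 is the single on-disk volume
format; frame timing and blood samples travel in TSV sidecars so that every
input stays diff-able text.  Dynamic PET activity concentrations are in
kBq/mL; frame schedules are stored in seconds while every kinetic time axis
is in minutes (conversion happens exactly once, here).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGeometry",
    "FrameSchedule",
    "DynamicImage",
    "BloodCurve",
    "ParametricMap",
    "load_dynamic_image",
    "load_blood_curve",
    "save_blood_curve",
    "integrate_frames",
    "save_volume",
    "load_volume",
    "save_frame_schedule",
    "load_frame_schedule",
    "WATER_FRAME_SCHEDULE",
    "FDDNP_FRAME_SCHEDULE",
    "ARTERIAL_SAMPLE_TIMES_S",
]

SEC_PER_MIN = 60.0


@dataclass(frozen=True)
class VolumeGeometry:
    """Voxel grid geometry: shape, physical voxel size (mm) and voxel→world affine.

    2-D slices and 3-D volumes are both supported; the affine is always the
    homogeneous 4×4 map NIfTI uses (a 2-D image occupies the first two axes).
    """

    shape: tuple
    voxel_size: tuple
    affine: np.ndarray = field(default=None)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(shape) not in (2, 3):
            raise ValueError("geometry must be 2-D or 3-D")
        if len(voxel_size) != len(shape):
            raise ValueError("voxel_size must match shape dimensionality")
        if any(s <= 0 for s in shape):
            raise ValueError("shape entries must be positive")
        if any(v <= 0 for v in voxel_size):
            raise ValueError("voxel sizes must be strictly positive")
        affine = self.affine
        if affine is None:
            affine = np.eye(4)
            for i, v in enumerate(voxel_size):
                affine[i, i] = v
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", voxel_size)
        object.__setattr__(self, "affine", affine)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    def matches(self, other: "VolumeGeometry", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=atol)
            and np.allclose(self.affine, other.affine, atol=atol)
        )


@dataclass(frozen=True)
class FrameSchedule:
    """Dynamic-scan frame timing: per-frame start and duration, in seconds."""

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start_s, dtype=float)
        dur = np.asarray(self.duration_s, dtype=float)
        if start.ndim != 1 or start.shape != dur.shape or start.size == 0:
            raise ValueError("start and duration must be equal-length 1-D arrays")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(start) < 0):
            raise ValueError("frame starts must be non-decreasing")
        ends = start + dur
        if np.any(start[1:] < ends[:-1] - 1e-9):
            raise ValueError("frames must not overlap")
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "duration_s", dur)

    def __len__(self) -> int:
        return int(self.start_s.size)

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def mid_times_min(self) -> np.ndarray:
        """Frame mid-times in minutes — the kinetic time axis of frame data."""
        return (self.start_s + self.duration_s / 2.0) / SEC_PER_MIN

    @property
    def total_span_s(self) -> float:
        return float(self.end_s[-1] - self.start_s[0])

    @classmethod
    def from_blocks(cls, blocks) -> "FrameSchedule":
        """Build a contiguous schedule from ``[(n_frames, duration_s), ...]`` blocks."""
        durs = np.concatenate([np.full(int(n), float(d)) for n, d in blocks])
        starts = np.concatenate([[0.0], np.cumsum(durs)[:-1]])
        return cls(starts, durs)


#: 10-min dynamic water protocol: 6 x 5 s, 9 x 10 s, 6 x 30 s, 5 x 60 s (26 frames).
WATER_FRAME_SCHEDULE = FrameSchedule.from_blocks([(6, 5), (9, 10), (6, 30), (5, 60)])

#: 65-min dynamic FDDNP protocol: 6 x 30 s, 4 x 180 s, 10 x 300 s (20 frames).
FDDNP_FRAME_SCHEDULE = FrameSchedule.from_blocks([(6, 30), (4, 180), (10, 300)])

#: Arterial sampling schedule (s): 0, 5 x 12, 3 x 20, 2 x 30, 2 x 60, 2 x 150 — 15 draws over 10 min.
ARTERIAL_SAMPLE_TIMES_S = np.concatenate(
    [[0.0], np.cumsum(np.repeat([12.0, 20.0, 30.0, 60.0, 150.0], [5, 3, 2, 2, 2]))]
)


@dataclass
class DynamicImage:
    """4-D (frame-stacked) activity-concentration image with its frame schedule."""

    data: np.ndarray  # shape (*spatial, n_frames), kBq/mL
    geometry: VolumeGeometry
    schedule: FrameSchedule

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape[:-1] != self.geometry.shape:
            raise ValueError("spatial shape does not match geometry")
        if self.data.shape[-1] != len(self.schedule):
            raise ValueError(
                f"frame count mismatch: image has {self.data.shape[-1]} frames, "
                f"schedule has {len(self.schedule)}"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]


@dataclass
class BloodCurve:
    """Sampled arterial input: time (min) vs activity concentration (kBq/mL)."""

    time_min: np.ndarray
    value: np.ndarray
    decay_corrected: bool = True

    def __post_init__(self):
        t = np.asarray(self.time_min, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("time and value must be equal-length 1-D arrays")
        if t.size < 3:
            raise ValueError("a blood curve needs at least 3 samples")
        if t[0] < 0:
            raise ValueError("blood sample times must start at or after 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("blood sample times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("blood activity values must be finite")
        self.time_min = t
        self.value = v


@dataclass
class ParametricMap:
    """Per-voxel estimate volume for one named kinetic parameter."""

    name: str
    data: np.ndarray
    units: str
    geometry: VolumeGeometry
    missing_value: float = np.nan

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.geometry.shape:
            raise ValueError("map shape does not match geometry")


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def _nifti_shape(data: np.ndarray, geometry: VolumeGeometry) -> np.ndarray:
    """nibabel wants >= 3 spatial axes; pad 2-D data with a singleton plane."""
    if geometry.ndim == 2:
        return data[..., np.newaxis] if data.shape == geometry.shape else data.reshape(
            geometry.shape + (1,) + data.shape[len(geometry.shape):]
        )
    return data


def save_volume(data: np.ndarray, geometry: VolumeGeometry, path) -> Path:
    """Write a volume (3-D, or 4-D dynamic) as NIfTI-1, preserving the affine.

    Integer arrays are stored as int32 so labels round-trip bit-exactly.
    """
    data = np.asarray(data)
    spatial = data.shape[: geometry.ndim]
    if spatial != geometry.shape:
        raise ValueError(f"data shape {data.shape} does not match geometry {geometry.shape}")
    if np.issubdtype(data.dtype, np.integer) or np.issubdtype(data.dtype, np.bool_):
        out = data.astype(np.int32)
    else:
        out = data.astype(np.float64)
    if geometry.ndim == 2:
        out = out.reshape(geometry.shape + (1,) + data.shape[2:])
    img = nib.Nifti1Image(out, geometry.affine)
    zooms = list(geometry.voxel_size) + [1.0] * (len(out.shape) - geometry.ndim)
    img.header.set_zooms(tuple(zooms[: len(out.shape)]))
    path = Path(path)
    nib.save(img, str(path))
    return path


def load_volume(path, ndim: int | None = None):
    """Load a NIfTI volume → (data, VolumeGeometry).

    ``ndim=2`` squeezes a singleton third axis back out (the convention
    :func:`save_volume` uses for planar images).
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()
    if ndim == 2 or (ndim is None and data.ndim >= 3 and data.shape[2] == 1):
        data = data.reshape(data.shape[:2] + data.shape[3:])
        geom = VolumeGeometry(data.shape[:2], zooms[:2], img.affine)
    else:
        geom = VolumeGeometry(data.shape[:3], zooms[:3], img.affine)
    return data, geom


# ---------------------------------------------------------------------------
# Frame timing sidecars
# ---------------------------------------------------------------------------

def save_frame_schedule(schedule: FrameSchedule, path) -> Path:
    df = pd.DataFrame(
        {"frame_start_s": schedule.start_s, "frame_duration_s": schedule.duration_s}
    )
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def load_frame_schedule(path) -> FrameSchedule:
    df = pd.read_csv(path, sep="\t")
    for col in ("frame_start_s", "frame_duration_s"):
        if col not in df.columns:
            raise ValueError(f"timing table missing column {col!r}")
    return FrameSchedule(df["frame_start_s"].to_numpy(), df["frame_duration_s"].to_numpy())


def load_dynamic_image(image_path, timing_path) -> DynamicImage:
    """Load a 4-D NIfTI plus its TSV frame-timing sidecar."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D dynamic image, got shape {data.shape}")
    schedule = load_frame_schedule(timing_path)
    if data.shape[-1] != len(schedule):
        raise ValueError(
            f"frame-count mismatch: image has {data.shape[-1]} frames, "
            f"timing table has {len(schedule)} rows"
        )
    zooms = img.header.get_zooms()
    if data.shape[2] == 1:  # planar convention
        data = data[:, :, 0, :]
        geom = VolumeGeometry(data.shape[:2], zooms[:2], img.affine)
    else:
        geom = VolumeGeometry(data.shape[:3], zooms[:3], img.affine)
    return DynamicImage(data, geom, schedule)


# ---------------------------------------------------------------------------
# Blood curves
# ---------------------------------------------------------------------------

def load_blood_curve(path) -> BloodCurve:
    """Read an arterial blood TSV.

    The time column declares its unit in the header: ``time_s`` or
    ``time_min``.  The activity column is ``activity_kbq_ml``.  Times are
    converted to minutes and sorted; duplicates and negative activities are
    rejected.
    """
    df = pd.read_csv(path, sep="\t")
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(dtype=float) / SEC_PER_MIN
    elif "time_min" in df.columns:
        t = df["time_min"].to_numpy(dtype=float)
    else:
        raise ValueError("blood TSV must declare 'time_s' or 'time_min'")
    if "activity_kbq_ml" not in df.columns:
        raise ValueError("blood TSV must have an 'activity_kbq_ml' column")
    v = df["activity_kbq_ml"].to_numpy(dtype=float)
    if np.any(v < 0):
        raise ValueError("negative blood activity")
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    if np.any(np.diff(t) == 0):
        raise ValueError("duplicate blood sample times")
    return BloodCurve(t, v)


def save_blood_curve(curve: BloodCurve, path, unit: str = "s") -> Path:
    if unit == "s":
        df = pd.DataFrame({"time_s": curve.time_min * SEC_PER_MIN, "activity_kbq_ml": curve.value})
    elif unit == "min":
        df = pd.DataFrame({"time_min": curve.time_min, "activity_kbq_ml": curve.value})
    else:
        raise ValueError("unit must be 's' or 'min'")
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


# ---------------------------------------------------------------------------
# Frame integration
# ---------------------------------------------------------------------------

def integrate_frames(img: DynamicImage, window_start_min: float, window_end_min: float) -> np.ndarray:
    """Duration-weighted sum (time integral, kBq·min/mL) of frames in a window.

    A frame contributes iff its mid-time lies in ``[start, end)``; partially
    covered frames are included whole on that rule.  Used to build the summed
    0–10 min water and 0–6 min FDDNP images that drive rigid co-registration.
    """
    if not window_end_min > window_start_min:
        raise ValueError("window must have positive length")
    mid = img.schedule.mid_times_min
    sel = (mid >= window_start_min) & (mid < window_end_min)
    if not np.any(sel):
        raise ValueError("integration window contains no frame mid-times")
    dur_min = img.schedule.duration_s[sel] / SEC_PER_MIN
    return np.tensordot(img.data[..., sel], dur_min, axes=([-1], [0]))
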