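"""Digital brain phantom: every input the workflow consumes, synthesized.

A labelled 2-D (default 128²) or small 3-D brain-like geometry — cortical
shell split into lobar sectors, subcortical blobs, ventricle, cerebellar
patch and a white-matter core — with per-region kinetic parameters for both
tracers; a gamma-variate arterial input with a recirculation tail; dynamic
PET frames produced by the same forward models the estimators later invert,
with duration-scaled proportional Gaussian noise; smooth invertible
deformations with grid landmarks; focal lesions; and degraded (delayed,
dispersed, noisy) blood curves.  All randomness is controlled by a seed.

Default kinetic parameters encode gray-matter flow 33, cerebellar gray 38.4
and white-matter flow 20 mL/100 g/min (extraction fraction 0.85), so the
generating gray/white flow ratio is 1.65 with a whole-brain gray mean of 33.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage

from ._kinetics import expconv, fine_grid, sample_curve
from .core_io import (
    BloodCurve,
    DynamicImage,
    FrameSchedule,
    SEC_PER_MIN,
    VolumeGeometry,
)
from .registration import DeformationField, jacobian_determinant
from .water_kinetics import DelayDispersion, frame_weights
from ._kinetics import frame_average_fine

__all__ = [
    "RegionSpec",
    "PhantomSpec",
    "default_spec",
    "make_phantom",
    "synth_input",
    "default_input",
    "degrade_input",
    "simulate_dynamic",
    "make_deformation",
    "insert_lesion",
]


@dataclass(frozen=True)
class RegionSpec:
    """One phantom region: geometry primitive, intensity and kinetics.

    ``kind`` is one of ``shell_sector`` (angular sector of the cortical
    shell; params ``angle_deg=(lo, hi)``), ``ellipse`` (params ``center``
    and ``radii`` in fractions of the image half-extent, center relative to
    the image middle) or ``core`` (white-matter remainder of the inner
    brain).  ``water`` is (K1, k2, Vb); ``fddnp`` is (R_I, k2, BP).
    """

    label: int
    kind: str
    params: dict
    intensity: float
    water: Tuple[float, float, float]
    fddnp: Tuple[float, float, float]


@dataclass
class PhantomSpec:
    shape: Tuple[int, ...]
    regions: Dict[str, RegionSpec]
    noise_percent: float = 5.0
    bias_percent: float = 5.0
    seed: int = 0
    brain_outer: Tuple[float, float] = (0.84, 0.88)
    brain_inner: Tuple[float, float] = (0.56, 0.62)
    #: one-tissue parameters generating the FDDNP reference-region curve
    fddnp_ref: Tuple[float, float, float] = (0.5, 0.25, 0.0)
    voxel_size_mm: float = 2.0


def _gray(F_ml100g_min, Vb, E=0.85, part=0.9):
    """(K1, k2, Vb) for a target flow in mL/100 g/min."""
    K1 = F_ml100g_min * E / 100.0
    return (K1, K1 / part, Vb)


def default_spec(shape=(128, 128), noise_percent: float = 5.0, seed: int = 0) -> PhantomSpec:
    """Default phantom: gray flow 33, CGM 38.4, white 20 mL/100 g/min."""
    g = lambda F, Vb=0.04: _gray(F, Vb)  # noqa: E731
    regions = {
        # cortical shell sectors (angles measured in the x-y plane)
        "FRT": RegionSpec(1, "shell_sector", {"angle_deg": (45, 135)}, 100.0,
                          g(33.0), (0.86, 0.38, 0.15)),
        "PAR": RegionSpec(2, "shell_sector", {"angle_deg": (135, 225)}, 100.0,
                          g(33.0), (0.90, 0.40, 0.12)),
        "OCC": RegionSpec(3, "shell_sector", {"angle_deg": (225, 315)}, 100.0,
                          g(33.0), (0.95, 0.42, 0.10)),
        "TEMP": RegionSpec(4, "shell_sector", {"angle_deg": (315, 45)}, 100.0,
                           g(33.0), (0.88, 0.39, 0.18)),
        # subcortical gray blobs
        "CAU": RegionSpec(5, "ellipse", {"center": (-0.16, 0.16), "radii": (0.11, 0.09)},
                          100.0, g(33.0), (0.83, 0.36, 0.20)),
        "THAL": RegionSpec(6, "ellipse", {"center": (0.14, 0.14), "radii": (0.11, 0.10)},
                           100.0, g(33.0, Vb=0.05), (0.86, 0.37, 0.16)),
        # ventricle
        "VENT": RegionSpec(7, "ellipse", {"center": (0.02, -0.14), "radii": (0.10, 0.085)},
                           30.0, (0.005, 0.01, 0.0), (0.05, 0.10, 0.0)),
        # cerebellar gray patch (the FDDNP reference region)
        "CGM": RegionSpec(8, "ellipse", {"center": (0.0, -0.70), "radii": (0.26, 0.14)},
                          100.0, _gray(38.4, 0.05), (1.0, 0.35, 0.0)),
        # white-matter core (centrum semiovale stand-in)
        "SWM": RegionSpec(9, "core", {}, 140.0, _gray(20.0, 0.03), (0.55, 0.25, 0.05)),
    }
    return PhantomSpec(tuple(shape), regions, noise_percent=noise_percent, seed=seed)


def _ellipse_mask(shape, center_frac, radii_frac) -> np.ndarray:
    half = (np.asarray(shape, dtype=float) - 1) / 2.0
    coords = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij"))
    d = len(shape)
    center = half + np.asarray(center_frac[:d]) * half
    radii = np.asarray(radii_frac[:d]) * half
    q = sum(((coords[i] - center[i]) / radii[i]) ** 2 for i in range(d))
    return q <= 1.0


def make_phantom(spec: PhantomSpec):
    """Build the labelled geometry and a structural image.

    Returns ``(LabelVolume, structural ndarray)``.  The structural image is
    per-region constant intensity modulated by a smooth multiplicative bias
    field plus seeded Gaussian noise.  Interior primitives (blobs,
    ventricle, cerebellar patch) must not overlap one another.
    """
    from .atlas_roi import LabelVolume  # local import avoids a cycle

    shape = spec.shape
    d = len(shape)
    outer = _ellipse_mask(shape, (0.0,) * d, spec.brain_outer + (0.8,) * (d - 2))
    inner = _ellipse_mask(shape, (0.0,) * d, spec.brain_inner + (0.55,) * (d - 2))
    shell = outer & ~inner

    half = (np.asarray(shape, dtype=float) - 1) / 2.0
    coords = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij"))
    angle = np.degrees(np.arctan2(coords[1] - half[1], coords[0] - half[0])) % 360.0

    labels = np.zeros(shape, dtype=np.int32)
    core_region = None
    ellipse_masks = {}
    for name, r in spec.regions.items():
        if r.kind == "shell_sector":
            lo, hi = r.params["angle_deg"]
            sect = (angle >= lo) & (angle < hi) if lo < hi else (angle >= lo) | (angle < hi)
            labels[shell & sect] = r.label
        elif r.kind == "ellipse":
            m = _ellipse_mask(shape, tuple(r.params["center"]) + (0.0,) * (d - 2),
                              tuple(r.params["radii"]) + (0.3,) * (d - 2))
            if not np.any(m & outer):
                raise ValueError(f"region {name!r} lies outside the brain")
            ellipse_masks[name] = m & outer
        elif r.kind == "core":
            core_region = r
        else:
            raise ValueError(f"unknown region kind {r.kind!r}")
    names = list(ellipse_masks)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.any(ellipse_masks[a] & ellipse_masks[b]):
                raise ValueError(f"overlapping primitives: {a!r} and {b!r}")
    if core_region is not None:
        core = inner.copy()
        for m in ellipse_masks.values():
            core &= ~m
        labels[core] = core_region.label
    for name, m in ellipse_masks.items():
        labels[m] = spec.regions[name].label

    table = {r.label: name for name, r in spec.regions.items()}
    for lab in np.unique(labels):
        if lab != 0 and int(np.count_nonzero(labels == lab)) == 0:
            raise ValueError(f"region {table[lab]} has no voxels")

    rng = np.random.default_rng(spec.seed)
    structural = np.zeros(shape, dtype=float)
    for name, r in spec.regions.items():
        structural[labels == r.label] = r.intensity
    if spec.bias_percent > 0:
        bias = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=min(shape) / 4)
        bias = bias / (np.abs(bias).max() + 1e-12) * spec.bias_percent / 100.0
        structural *= 1.0 + bias
    if spec.noise_percent > 0:
        structural += (spec.noise_percent / 100.0) * structural * rng.standard_normal(shape)

    geom = VolumeGeometry(shape, (spec.voxel_size_mm,) * d)
    return LabelVolume(labels, geom, table), structural


# ---------------------------------------------------------------------------
# Arterial input
# ---------------------------------------------------------------------------

def synth_input(
    A: float,
    alpha: float,
    beta_min: float,
    t0_min: float,
    recirc_fraction: float = 0.0,
    times_min: Optional[np.ndarray] = None,
) -> BloodCurve:
    """Gamma-variate bolus A·(t−t0)^α·e^{−(t−t0)/β} with optional recirculation.

    The peak sits at t0 + α·β.  The recirculation tail adds
    ``recirc_fraction`` of the peak value, rising on the bolus time scale
    and washing out slowly.  Sampled on ``times_min`` or, by default, a fine
    0.01-min grid over 10 minutes.
    """
    if A <= 0 or alpha <= 0 or beta_min <= 0:
        raise ValueError("shape parameters must be positive")
    if times_min is None:
        times_min = fine_grid(10.0)
    t = np.asarray(times_min, dtype=float)
    s = np.maximum(t - t0_min, 0.0)
    v = A * s**alpha * np.exp(-s / beta_min)
    if recirc_fraction > 0:
        peak = A * (alpha * beta_min) ** alpha * np.exp(-alpha)
        v = v + recirc_fraction * peak * (1.0 - np.exp(-s / (alpha * beta_min))) * np.exp(-s / 8.0)
    v = np.where(t <= t0_min, 0.0, v)
    return BloodCurve(t, v)


def default_input(peak_kbq_ml: float = 100.0, times_min: Optional[np.ndarray] = None) -> BloodCurve:
    """Bolus-shaped default input, peak normalized to ``peak_kbq_ml``."""
    alpha, beta, t0 = 2.5, 0.18, 0.25
    A = peak_kbq_ml / ((alpha * beta) ** alpha * np.exp(-alpha))
    return synth_input(A, alpha, beta, t0, recirc_fraction=0.15, times_min=times_min)


def degrade_input(
    true: BloodCurve, dd: DelayDispersion, noise_percent: float = 0.0, seed: int = 0
) -> BloodCurve:
    """Forward-degrade an input curve: delay, monoexponential dispersion, noise.

    The curve is shifted by +Δt, convolved with (1/τ)·e^{−t/τ} (unit area,
    so the total activity integral is preserved) and proportional Gaussian
    noise is added.  Samples are returned on the input curve's own times.
    """
    if dd.tau_s < 0:
        raise ValueError("tau must be non-negative")
    t_end = true.time_min[-1] + dd.delta_t_s / SEC_PER_MIN + 1e-9
    grid = fine_grid(t_end)
    shifted = np.interp(grid - dd.delta_t_s / SEC_PER_MIN, true.time_min, true.value,
                        left=0.0, right=true.value[-1])
    if dd.tau_s > 0:
        rate = SEC_PER_MIN / dd.tau_s
        dispersed = rate * expconv(shifted, rate)
    else:
        dispersed = shifted
    out = np.interp(true.time_min, grid, dispersed)
    if noise_percent > 0:
        rng = np.random.default_rng(seed)
        out = out + (noise_percent / 100.0) * out * rng.standard_normal(out.shape)
        out = np.maximum(out, 0.0)
    return BloodCurve(true.time_min, out, true.decay_corrected)


# ---------------------------------------------------------------------------
# Dynamic PET simulation
# ---------------------------------------------------------------------------

def region_model_curves(spec: PhantomSpec, tracer: str, input_curve: BloodCurve,
                        schedule: FrameSchedule):
    """Noise-free frame-averaged model TAC per region label.

    Water regions follow the one-tissue model against the arterial input;
    FDDNP regions follow the SRTM forward model against the reference-region
    curve, itself generated from the spec's reference one-tissue parameters.
    Returns ``(curves: {label: (F,) array}, ref_fine or cb_fine, grid)``.
    """
    end_min = schedule.end_s[-1] / SEC_PER_MIN
    grid = fine_grid(max(end_min, input_curve.time_min[-1]))
    start = schedule.start_s / SEC_PER_MIN
    end = schedule.end_s / SEC_PER_MIN
    cb = sample_curve(input_curve.time_min, input_curve.value, grid)
    step = grid[1] - grid[0]
    curves = {}
    if tracer == "water":
        for name, r in spec.regions.items():
            K1, k2, Vb = r.water
            c = K1 * expconv(cb, k2, step) + Vb * cb
            curves[r.label] = frame_average_fine(c, grid, start, end)
        return curves, cb, grid
    if tracer == "fddnp":
        K1r, k2r, Vbr = spec.fddnp_ref
        cr = K1r * expconv(cb, k2r, step) + Vbr * cb
        for name, r in spec.regions.items():
            R_I, k2, BP = r.fddnp
            theta = k2 / (1.0 + BP)
            c = R_I * cr + (k2 - R_I * theta) * expconv(cr, theta, step)
            curves[r.label] = frame_average_fine(c, grid, start, end)
        return curves, cr, grid
    raise ValueError("tracer must be 'water' or 'fddnp'")


def simulate_dynamic(
    labels,
    spec: PhantomSpec,
    tracer: str,
    input_curve: BloodCurve,
    schedule: FrameSchedule,
    noise_percent: Optional[float] = None,
    seed: Optional[int] = None,
) -> DynamicImage:
    """Frame-averaged noisy dynamic PET on the phantom labels.

    Noise is zero-mean Gaussian with σ = noise% · value · √(d_max/d_f):
    shorter frames collect fewer counts and are proportionally noisier, the
    first-order behavior of reconstructed PET images.
    """
    if noise_percent is None:
        noise_percent = spec.noise_percent
    if seed is None:
        seed = spec.seed
    curves, _, _ = region_model_curves(spec, tracer, input_curve, schedule)
    lab = labels.labels
    shape = lab.shape
    n_frames = len(schedule)
    data = np.zeros(shape + (n_frames,))
    for label_id, curve in curves.items():
        data[lab == label_id] = curve
    if noise_percent > 0:
        rng = np.random.default_rng(seed)
        scale = np.sqrt(schedule.duration_s.max() / schedule.duration_s)
        sigma = (noise_percent / 100.0) * data * scale
        data = data + sigma * rng.standard_normal(data.shape)
    return DynamicImage(data, labels.geometry, schedule)


# ---------------------------------------------------------------------------
# Deformations and lesions
# ---------------------------------------------------------------------------

def make_deformation(
    geometry: VolumeGeometry,
    amplitude_voxels: float,
    smoothness_voxels: float = 12.0,
    seed: int = 0,
    n_landmarks_per_axis: int = 5,
):
    """Seeded random smooth deformation with a guaranteed positive Jacobian.

    White noise is smoothed to ``smoothness_voxels``, tapered to zero at the
    image border and scaled so the largest displacement equals
    ``amplitude_voxels``.  If that amplitude folds space the call fails,
    reporting the maximum feasible amplitude.  Returns
    ``(DeformationField, landmarks)`` with a regular interior grid of
    landmark points.
    """
    shape = geometry.shape
    d = geometry.ndim
    if amplitude_voxels < 0:
        raise ValueError("amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    disp = np.stack([
        ndimage.gaussian_filter(rng.standard_normal(shape), smoothness_voxels)
        for _ in range(d)
    ])
    # cosine taper: zero displacement on the border, full amplitude inside
    taper = np.ones(shape)
    for axis, s in enumerate(shape):
        x = np.arange(s)
        edge = np.minimum(x, s - 1 - x) / max(s * 0.15, 1.0)
        w = np.clip(edge, 0.0, 1.0)
        w = 0.5 - 0.5 * np.cos(np.pi * w)
        taper *= w.reshape([-1 if a == axis else 1 for a in range(d)])
    disp *= taper
    maxnorm = np.max(np.linalg.norm(disp, axis=0))
    if maxnorm > 0 and amplitude_voxels > 0:
        disp *= amplitude_voxels / maxnorm
    else:
        disp[:] = 0.0
    field = DeformationField(disp, geometry)
    if amplitude_voxels > 0:
        minjac = float(jacobian_determinant(field).min())
        if minjac <= 0:
            lo, hi = 0.0, amplitude_voxels
            for _ in range(20):
                mid = 0.5 * (lo + hi)
                test = DeformationField(disp * (mid / amplitude_voxels), geometry)
                if jacobian_determinant(test).min() > 0:
                    lo = mid
                else:
                    hi = mid
            raise ValueError(
                f"amplitude {amplitude_voxels} folds space at this smoothness; "
                f"maximum feasible ≈ {lo:.2f} voxels"
            )
    marks = np.stack(np.meshgrid(*[
        np.linspace(0.2 * (s - 1), 0.8 * (s - 1), n_landmarks_per_axis) for s in shape
    ], indexing="ij")).reshape(d, -1).T
    return field, marks


def insert_lesion(volume: np.ndarray, center, radii, intensity: float):
    """Set an ellipsoidal focal lesion to a fixed intensity.

    ``center`` and ``radii`` are in voxels.  Returns ``(volume, mask)``;
    voxels outside the mask are untouched.
    """
    volume = np.asarray(volume, dtype=float)
    shape = volume.shape
    center = np.asarray(center, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(center - radii < 0) or np.any(center + radii > np.asarray(shape) - 1):
        raise ValueError("lesion extends outside the volume")
    coords = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij"))
    q = sum(((coords[i] - center[i]) / radii[i]) ** 2 for i in range(len(shape)))
    mask = q <= 1.0
    out = volume.copy()
    out[mask] = intensity
    return out, mask
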