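"""Simplified reference tissue model (SRTM) with a basis-function estimator.

For a tracer whose reference region is devoid of specific binding, the
target-region curve is

    C_T(t) = R_I·C_R(t) + (k2 − R_I·k2/(1+BP)) · C_R(t) ⊗ e^{−θ t},
    θ = k2 / (1 + BP),

with R_I the target/reference delivery ratio (the relative-perfusion index
for early-phase ¹⁸F-FDDNP), k2 the target efflux rate and BP the binding
potential.  Fixing θ on a grid makes the model linear in (α1, α2) with
α1 = R_I and α2 = k2 − R_I·θ, so each voxel reduces to N small weighted
linear solves; the θ with minimal weighted residual sum of squares wins.
The default grid is 100 log-spaced values between 0.00636 and 1 min⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kinetics import expconv, fine_grid, frame_average_fine, sample_curve
from .core_io import DynamicImage, FrameSchedule, ParametricMap, SEC_PER_MIN, integrate_frames
from .water_kinetics import TissueCurve, frame_weights

__all__ = [
    "SRTMParams",
    "BasisSet",
    "theta_grid",
    "srtm_tac",
    "build_basis",
    "fit_srtm_voxel",
    "srtm_parametric_map",
    "early_sum_ratio",
]


@dataclass(frozen=True)
class SRTMParams:
    """SRTM parameters: R_I (unitless), k2 (1/min), BP (unitless)."""

    R_I: float
    k2: float
    BP: float

    def __post_init__(self):
        if not np.isfinite(self.R_I):
            raise ValueError("R_I must be finite")
        if self.k2 < 0:
            raise ValueError("k2 must be non-negative")
        if self.BP <= -1:
            raise ValueError("BP must exceed -1 (theta must stay positive)")

    @property
    def theta(self) -> float:
        return self.k2 / (1.0 + self.BP)


@dataclass
class BasisSet:
    """Precomputed SRTM basis: θ grid, frame-averaged basis curves, reference TAC."""

    thetas: np.ndarray          # (N,), 1/min, strictly increasing
    basis: np.ndarray           # (N, F) frame-averaged C_R ⊗ e^{−θ t}
    ref_frames: np.ndarray      # (F,) frame-averaged C_R
    ref_fine: np.ndarray        # C_R on the fine grid
    grid: np.ndarray            # fine time grid (min)
    schedule: FrameSchedule

    def __post_init__(self):
        if self.thetas.size < 2 or np.any(np.diff(self.thetas) <= 0):
            raise ValueError("thetas must be strictly increasing with N >= 2")


def theta_grid(n: int = 100, lo: float = 0.00636, hi: float = 1.0) -> np.ndarray:
    """Logarithmically spaced θ grid: θ_j = lo·(hi/lo)^{(j−1)/(n−1)}."""
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    if n < 2:
        raise ValueError("need at least 2 grid points")
    return lo * (hi / lo) ** (np.arange(n) / (n - 1))


def srtm_tac(p: SRTMParams, ref_fine: np.ndarray, grid: np.ndarray, times_min) -> np.ndarray:
    """Evaluate the SRTM forward model at arbitrary times.

    ``ref_fine`` is the reference TAC on the uniform fine grid ``grid``.
    """
    times_min = np.asarray(times_min, dtype=float)
    if np.any(times_min > grid[-1] + 1e-9) or np.any(times_min < 0):
        raise ValueError("requested times outside the reference curve span")
    theta = p.theta
    conv = expconv(ref_fine, theta, grid[1] - grid[0])
    ct = p.R_I * ref_fine + (p.k2 - p.R_I * theta) * conv
    return np.interp(times_min, grid, ct)


def build_basis(
    ref_tac: TissueCurve, schedule: FrameSchedule, thetas=None
) -> BasisSet:
    """Build frame-averaged basis curves B_i = C_R ⊗ e^{−θ_i t}.

    The reference TAC is linearly interpolated onto the fine grid (zero
    before the first sample); each basis curve is convolved exactly on that
    grid and then averaged over the frames.  A densely sampled reference is
    used as-is; when the reference is the frame-sampled TAC itself, its
    measured values serve directly as the reference column so the estimator
    stays exact on self-referential data.
    """
    if thetas is None:
        thetas = theta_grid()
    thetas = np.asarray(thetas, dtype=float)
    if thetas.size == 0:
        raise ValueError("empty theta grid")
    start = schedule.start_s / SEC_PER_MIN
    end = schedule.end_s / SEC_PER_MIN
    grid = fine_grid(end[-1])
    ref_fine = sample_curve(ref_tac.time_min, ref_tac.value, grid)
    step = grid[1] - grid[0]
    basis = np.empty((thetas.size, len(schedule)))
    for i, th in enumerate(thetas):
        basis[i] = frame_average_fine(expconv(ref_fine, th, step), grid, start, end)
    mids = schedule.mid_times_min
    if ref_tac.time_min.size == mids.size and np.allclose(ref_tac.time_min, mids):
        ref_frames = ref_tac.value.copy()
    else:
        ref_frames = frame_average_fine(ref_fine, grid, start, end)
    return BasisSet(thetas, basis, ref_frames, ref_fine, grid, schedule)


def _fit_matrix(tacs: np.ndarray, basis: BasisSet, weights: np.ndarray):
    """Vectorized per-θ linear fits for a (V, F) stack of TACs.

    Returns (alpha1, alpha2, wrss) each of shape (N, V).
    """
    w = weights
    cr = basis.ref_frames
    N, F = basis.basis.shape
    V = tacs.shape[0]
    a1 = np.empty((N, V))
    a2 = np.empty((N, V))
    wrss = np.empty((N, V))
    y = tacs  # (V, F)
    wy = y * w
    s_yy = np.einsum("vf,vf->v", wy, y)
    for i in range(N):
        b = basis.basis[i]
        # 2x2 weighted normal equations, closed form
        s_cc = np.sum(w * cr * cr)
        s_cb = np.sum(w * cr * b)
        s_bb = np.sum(w * b * b)
        det = s_cc * s_bb - s_cb * s_cb
        s_cy = wy @ cr
        s_by = wy @ b
        if abs(det) < 1e-12 * max(s_cc * s_bb, 1e-30):
            # basis collinear with reference at this θ — flag by +inf wrss
            a1[i] = np.nan
            a2[i] = np.nan
            wrss[i] = np.inf
            continue
        a1[i] = (s_bb * s_cy - s_cb * s_by) / det
        a2[i] = (s_cc * s_by - s_cb * s_cy) / det
        wrss[i] = s_yy - a1[i] * s_cy - a2[i] * s_by
    return a1, a2, np.maximum(wrss, 0.0)


def fit_srtm_voxel(tac: TissueCurve, basis: BasisSet):
    """Basis-function SRTM fit of one TAC.

    For every θ on the grid a weighted linear solve yields (α1, α2); the θ
    with the smallest weighted residual sum of squares is selected (ties go
    to the smaller θ for determinism) and mapped back to
    R_I = α1, k2 = α2 + α1·θ, BP = k2/θ − 1.

    Returns ``(SRTMParams, theta_index, wrss)``.
    """
    if tac.value.shape != basis.ref_frames.shape:
        raise ValueError("TAC not aligned with basis frame times")
    if np.all(tac.value == 0):
        return SRTMParams(0.0, 0.0, 0.0), 0, 0.0
    a1, a2, wrss = _fit_matrix(tac.value[None, :], basis, tac.weight)
    wrss = wrss[:, 0]
    if not np.any(np.isfinite(wrss)):
        raise ValueError("degenerate design: all basis curves collinear with reference")
    idx = int(np.argmin(wrss))  # argmin returns the first (smallest-θ) minimizer
    alpha1, alpha2 = float(a1[idx, 0]), float(a2[idx, 0])
    theta = float(basis.thetas[idx])
    k2 = alpha2 + alpha1 * theta
    bp = k2 / theta - 1.0 if k2 > 0 else 0.0
    # α2 is unconstrained: negative k2/BP estimates are reported, not clipped
    return SRTMParams(alpha1, max(k2, 0.0), max(bp, -0.999)), idx, float(wrss[idx])


def srtm_parametric_map(img: DynamicImage, ref_tac: TissueCurve, mask, thetas=None):
    """Voxel-wise basis-function SRTM over a mask; basis built once and reused.

    Returns a dict of ParametricMaps ``R_I``, ``k2``, ``BP`` plus ``wrss``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("mask is empty")
    basis = build_basis(ref_tac, img.schedule, thetas)
    w = frame_weights(img.schedule)
    y = img.data[mask]
    a1, a2, wrss = _fit_matrix(y, basis, w)
    idx = np.argmin(wrss, axis=0)
    cols = np.arange(y.shape[0])
    alpha1 = a1[idx, cols]
    alpha2 = a2[idx, cols]
    theta = basis.thetas[idx]
    k2 = alpha2 + alpha1 * theta
    bp = np.where(k2 > 0, k2 / theta - 1.0, 0.0)
    best_wrss = wrss[idx, cols]

    geometry = img.geometry

    def to_map(vals, name, units):
        vol = np.full(geometry.shape, np.nan)
        vol[mask] = vals
        return ParametricMap(name, vol, units, geometry)

    return {
        "R_I": to_map(alpha1, "R_I", "ratio"),
        "k2": to_map(np.maximum(k2, 0.0), "k2", "1/min"),
        "BP": to_map(bp, "BP", "unitless"),
        "wrss": to_map(best_wrss, "wrss", "(kBq/mL)^2"),
    }


def early_sum_ratio(
    img: DynamicImage, reference_mask, window=(0.0, 6.0)
) -> ParametricMap:
    """Early-summed image normalized by its reference-region mean (R_P).

    Integrates the dynamic image over ``window`` (minutes) and divides by the
    mean of the summed image inside the reference mask, yielding the
    relative-perfusion surrogate map.
    """
    summed = integrate_frames(img, window[0], window[1])
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not np.any(reference_mask):
        raise ValueError("reference mask is empty")
    ref_mean = float(summed[reference_mask].mean())
    if ref_mean <= 0:
        raise ValueError("reference-region mean of the summed image must be positive")
    return ParametricMap("R_P", summed / ref_mean, "ratio", img.geometry)
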