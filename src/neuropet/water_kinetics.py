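"""One-tissue kinetic modelling of dynamic ¹⁵O-water PET.

The tissue tracer concentration follows

    dC_T/dt = K1·C_b(t) − k2·C_T(t),       C_ROI(t) = C_T(t) + Vb·C_b(t)

with K1 (mL/mL/min) the delivery rate constant — proportional to cerebral
blood flow — k2 (1/min) the clearance rate and Vb the fractional vascular
volume contributing intravascular signal.  CBF in mL/100 g/min is obtained
from K1 through the first-pass extraction fraction E (default 0.85) assuming
unit tissue density.

The module provides the forward model, frame averaging, whole-brain delay
and dispersion correction of the measured arterial input, a bounded
non-linear voxel fit, and a fast linearized ridge estimator with a spatial
constraint for whole-image parametric mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import least_squares, minimize_scalar

from ._kinetics import (
    FINE_STEP_MIN,
    cumulative_integral,
    expconv,
    fine_grid,
    frame_average_fine,
    sample_curve,
)
from .core_io import BloodCurve, DynamicImage, FrameSchedule, ParametricMap, SEC_PER_MIN

__all__ = [
    "OneTissueParams",
    "DelayDispersion",
    "TissueCurve",
    "frame_weights",
    "one_tissue_tac",
    "frame_average",
    "fit_one_tissue",
    "correct_delay_dispersion",
    "ridge_parametric_fit",
    "flow_map",
    "normalize_map",
]

# optimizer bounds for (K1, k2, Vb); generous relative to physiology
_K1_MAX = 5.0
_K2_MAX = 10.0


@dataclass(frozen=True)
class OneTissueParams:
    """One-tissue model parameters: K1 (1/min), k2 (1/min), Vb (fraction)."""

    K1: float
    k2: float
    Vb: float

    def __post_init__(self):
        if self.K1 < 0 or self.k2 < 0:
            raise ValueError("K1 and k2 must be non-negative")
        if not 0 <= self.Vb <= 1:
            raise ValueError("Vb must lie in [0, 1]")


@dataclass(frozen=True)
class DelayDispersion:
    """Delay (s) and dispersion time constant (s) of the measured arterial input."""

    delta_t_s: float
    tau_s: float

    def __post_init__(self):
        if self.tau_s < 0:
            raise ValueError("dispersion time constant must be non-negative")


@dataclass
class TissueCurve:
    """Frame-sampled tissue activity: mid-times (min), values, fit weights."""

    time_min: np.ndarray
    value: np.ndarray
    weight: np.ndarray
    schedule: Optional[FrameSchedule] = None

    def __post_init__(self):
        t = np.asarray(self.time_min, dtype=float)
        v = np.asarray(self.value, dtype=float)
        w = np.asarray(self.weight, dtype=float)
        if not (t.shape == v.shape == w.shape) or t.ndim != 1:
            raise ValueError("time, value and weight must be equal-length 1-D arrays")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be non-negative and not all zero")
        self.time_min, self.value, self.weight = t, v, w


def frame_weights(schedule: FrameSchedule) -> np.ndarray:
    """Per-frame fit weights, proportional to frame duration (max-normalized).

    Longer frames accumulate more counts, so their values are less noisy;
    duration weighting is the standard first-order surrogate for count
    statistics when true variance estimates are unavailable.
    """
    d = schedule.duration_s
    return d / d.max()


def one_tissue_tac(p: OneTissueParams, input_curve: BloodCurve, times_min) -> np.ndarray:
    """Continuous C_ROI(t) = K1·(C_b ⊗ e^{−k2 t})(t) + Vb·C_b(t).

    The blood curve is linearly interpolated onto a uniform 0.01-min grid
    (zero before the first sample) and the convolution is evaluated exactly
    for that piecewise-linear input.
    """
    times_min = np.asarray(times_min, dtype=float)
    t_end = input_curve.time_min[-1]
    if np.any(times_min < 0) or np.any(times_min > t_end + 1e-9):
        raise ValueError("requested times fall outside the blood curve span")
    grid = fine_grid(t_end)
    cb = sample_curve(input_curve.time_min, input_curve.value, grid)
    c = p.K1 * expconv(cb, p.k2) + p.Vb * cb
    return np.interp(times_min, grid, c)


def frame_average(values: np.ndarray, grid: np.ndarray, schedule: FrameSchedule) -> TissueCurve:
    """Average a continuous fine-grid curve over each frame of a schedule.

    PET frames measure the time-averaged activity over their duration; this
    is the forward operator from model curves to frame data.
    """
    start = schedule.start_s / SEC_PER_MIN
    end = schedule.end_s / SEC_PER_MIN
    vals = frame_average_fine(values, grid, start, end)
    return TissueCurve(schedule.mid_times_min, vals, frame_weights(schedule), schedule)


def _model_frames(params, cb_fine, grid, schedule):
    K1, k2, Vb = params
    c = K1 * expconv(cb_fine, k2) + Vb * cb_fine
    return frame_average_fine(
        c, grid, schedule.start_s / SEC_PER_MIN, schedule.end_s / SEC_PER_MIN
    )


def fit_one_tissue(tac: TissueCurve, input_curve: BloodCurve):
    """Bounded weighted non-linear LS fit of (K1, k2, Vb) to a frame TAC.

    Because the model is linear in (K1, Vb) at fixed k2, the fit first
    profiles k2 over a coarse logarithmic grid with a non-negative linear
    solve at each node, then polishes the three best distinct candidates with
    bounded Levenberg–Marquardt (trust-region reflective) starts.  Returns
    ``(OneTissueParams, wrss)``.
    """
    if not np.all(np.isfinite(tac.value)):
        raise ValueError("non-finite values in tissue curve")
    if tac.time_min.size < 4:
        raise ValueError("need at least 4 frames to fit 3 parameters")
    if np.all(tac.value == 0):
        return OneTissueParams(0.0, 0.0, 0.0), 0.0
    if tac.schedule is None:
        raise ValueError("tissue curve must carry its frame schedule for fitting")
    schedule = tac.schedule
    grid = fine_grid(max(input_curve.time_min[-1], schedule.end_s[-1] / SEC_PER_MIN))
    cb_fine = sample_curve(input_curve.time_min, input_curve.value, grid)
    cb_frames = frame_average_fine(
        cb_fine, grid, schedule.start_s / SEC_PER_MIN, schedule.end_s / SEC_PER_MIN
    )
    w = tac.weight
    sw = np.sqrt(w)
    y = tac.value

    # ---- profile k2 on a coarse grid, linear (K1, Vb) at each node ----
    k2_grid = np.concatenate([[0.0], np.geomspace(1e-3, _K2_MAX, 40)])
    best = []
    for k2 in k2_grid:
        conv = frame_average_fine(
            expconv(cb_fine, k2), grid,
            schedule.start_s / SEC_PER_MIN, schedule.end_s / SEC_PER_MIN,
        )
        X = np.column_stack([conv, cb_frames]) * sw[:, None]
        coef, *_ = np.linalg.lstsq(X, y * sw, rcond=None)
        K1 = float(np.clip(coef[0], 0.0, _K1_MAX))
        Vb = float(np.clip(coef[1], 0.0, 1.0))
        r = (K1 * conv + Vb * cb_frames - y) * sw
        best.append((float(r @ r), K1, k2, Vb))
    best.sort(key=lambda t: t[0])

    def resid(p):
        return (_model_frames(p, cb_fine, grid, schedule) - y) * sw

    lb = [0.0, 0.0, 0.0]
    ub = [_K1_MAX, _K2_MAX, 1.0]
    solutions = []
    for wrss0, K1, k2, Vb in best[:3]:
        x0 = np.clip([max(K1, 1e-6), max(k2, 1e-6), Vb], lb, ub)
        sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if not sol.success:
            raise RuntimeError(f"one-tissue optimizer failed: {sol.message}")
        solutions.append((2 * sol.cost, sol.x))
    wrss, x = min(solutions, key=lambda t: t[0])
    return OneTissueParams(*x), float(wrss)


def correct_delay_dispersion(
    measured: BloodCurve,
    whole_brain: TissueCurve,
    delta_range_s=(-10.0, 20.0),
    delta_step_s=0.25,
    tau_max_s=20.0,
    tau_step_s=0.5,
):
    """Estimate and correct the delay and dispersion of the measured input.

    The arterial curve measured at the sampling site lags (delay Δt) and is
    smeared (monoexponential dispersion, time constant τ) relative to the
    input the brain sees.  Both are estimated by grid search: each candidate
    (Δt, τ) shifts the measured curve by −Δt and un-disperses it with the
    closed-form inverse of the monoexponential kernel, c(t) = m(t) + τ·m′(t)
    (no numerical deconvolution); the candidate-corrected input then enters
    the exact frame-averaged one-tissue model, whose weighted residual sum
    of squares against the whole-brain frame TAC — with k2 profiled out
    (the model is linear in K1 and Vb at fixed k2) — scores the candidate.
    The winner is polished with the full non-linear fit.

    Returns ``(corrected BloodCurve, DelayDispersion, OneTissueParams)``.
    """
    if np.all(whole_brain.value == 0) or np.ptp(whole_brain.value) == 0:
        raise ValueError("whole-brain TAC carries no signal")
    deltas = np.arange(delta_range_s[0], delta_range_s[1] + 1e-9, delta_step_s)
    taus = np.arange(0.0, tau_max_s + 1e-9, tau_step_s)
    if deltas.size == 0 or taus.size == 0:
        raise ValueError("empty delay/dispersion search grid")
    schedule = whole_brain.schedule
    if schedule is None:
        raise ValueError("whole-brain TAC must carry its frame schedule")
    t_end = min(measured.time_min[-1], schedule.end_s[-1] / SEC_PER_MIN)
    grid = fine_grid(t_end)
    fa = lambda v: frame_average_fine(  # noqa: E731 - local shorthand
        v, grid, schedule.start_s / SEC_PER_MIN,
        np.minimum(schedule.end_s / SEC_PER_MIN, grid[-1]),
    )
    w = whole_brain.weight
    sw = np.sqrt(w)
    y = whole_brain.value
    ysw = y * sw

    k2_coarse = np.concatenate([[0.0], np.geomspace(0.05, _K2_MAX, 9)])

    def candidate_wrss(c_fine):
        """Exact frame-averaged one-tissue wrss with k2 profiled out."""
        cb_frames = fa(c_fine)

        def at_k2(k2):
            conv = fa(expconv(c_fine, k2))
            X = np.column_stack([conv, cb_frames]) * sw[:, None]
            coef, *_ = np.linalg.lstsq(X, ysw, rcond=None)
            r = X @ coef - ysw
            return float(r @ r)

        vals = [at_k2(k2) for k2 in k2_coarse]
        i = int(np.argmin(vals))
        lo = k2_coarse[max(i - 1, 0)]
        hi = k2_coarse[min(i + 1, k2_coarse.size - 1)]
        if hi > lo:
            res = minimize_scalar(at_k2, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-4})
            return min(vals[i], float(res.fun))
        return vals[i]

    # shifted measured curves and their derivatives, shared across tau values
    best = (np.inf, 0.0, 0.0)
    for dt in deltas:
        m_s = np.interp(
            grid + dt / SEC_PER_MIN, measured.time_min, measured.value,
            left=0.0, right=measured.value[-1],
        )
        dm_s = np.gradient(m_s, FINE_STEP_MIN)
        for tau in taus:
            c = m_s + (tau / SEC_PER_MIN) * dm_s
            wrss = candidate_wrss(c)
            if wrss < best[0] - 1e-15:
                best = (wrss, dt, tau)
    _, dt_hat, tau_hat = best
    dd = DelayDispersion(float(dt_hat), float(tau_hat))

    m_s = np.interp(
        grid + dt_hat / SEC_PER_MIN, measured.time_min, measured.value,
        left=0.0, right=measured.value[-1],
    )
    dm_s = np.gradient(m_s, FINE_STEP_MIN)
    corrected_vals = np.maximum(m_s + (tau_hat / SEC_PER_MIN) * dm_s, 0.0)
    corrected = BloodCurve(grid, corrected_vals, measured.decay_corrected)

    # full non-linear whole-brain fit with the corrected input
    params, _ = fit_one_tissue(whole_brain, corrected)
    return corrected, dd, params


def _masked_gaussian(vol, mask, sigma):
    """Gaussian smoothing restricted to a mask (normalized convolution)."""
    m = mask.astype(float)
    num = gaussian_filter(np.where(mask, vol, 0.0), sigma)
    den = gaussian_filter(m, sigma)
    out = np.zeros_like(vol)
    good = den > 1e-8
    out[good] = num[good] / den[good]
    return out


def ridge_parametric_fit(
    img: DynamicImage,
    input_curve: BloodCurve,
    mask: np.ndarray,
    ridge: bool = True,
    smooth_fwhm_vox: float = 2.0,
    eps: float = 1e-6,
):
    """Voxel-wise linearized one-tissue fit with a spatially constrained ridge.

    Integrating the model equation from 0 to t gives the operational form

        C_ROI(t) = P1·∫C_b − P2·∫C_ROI + P3·C_b,
        P1 = K1 + k2·Vb,  P2 = k2,  P3 = Vb,

    linear in (P1, P2, P3).  All regressors are frame-averaged so they live
    on the same footing as the measured frame values; the voxel integral
    ∫C_ROI is computed from the piecewise-linear interpolant of the frame
    TAC.  A first unpenalized weighted LS pass produces raw maps; a second
    pass shrinks each voxel's estimate toward the Gaussian-smoothed
    first-pass maps with a data-driven per-voxel, per-parameter penalty
    h = wrss / (local variance of the first-pass estimate + eps), damping
    noisy voxels strongly while leaving well-determined ones untouched.

    Returns a dict with ParametricMaps ``K1``, ``k2``, ``Vb`` and ``wrss``.
    """
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        raise ValueError("fit mask is empty")
    schedule = img.schedule
    n_frames = len(schedule)
    if n_frames < 4:
        raise ValueError("need at least 4 frames")
    start = schedule.start_s / SEC_PER_MIN
    end = schedule.end_s / SEC_PER_MIN
    mid = schedule.mid_times_min
    grid = fine_grid(max(input_curve.time_min[-1], end[-1]))
    cb_fine = sample_curve(input_curve.time_min, input_curve.value, grid)
    x1 = frame_average_fine(cumulative_integral(cb_fine), grid, start, end)
    x3 = frame_average_fine(cb_fine, grid, start, end)

    # linear operator: frame values -> frame-averaged running integral of the
    # piecewise-linear frame TAC (zero before the first mid-time)
    A = np.empty((n_frames, n_frames))
    for j in range(n_frames):
        e = np.zeros(n_frames)
        e[j] = 1.0
        cont = np.interp(grid, mid, e, left=0.0, right=e[-1])
        A[:, j] = frame_average_fine(cumulative_integral(cont), grid, start, end)

    y = img.data[mask]  # (V, F)
    x2 = y @ A.T  # (V, F) per-voxel ∫C_ROI regressor
    w = frame_weights(schedule)

    V = y.shape[0]
    X = np.empty((V, n_frames, 3))
    X[:, :, 0] = x1
    X[:, :, 1] = -x2
    X[:, :, 2] = x3
    Xw = X * w[None, :, None]
    XtX = np.einsum("vfi,vfj->vij", Xw, X)
    Xty = np.einsum("vfi,vf->vi", Xw, y)
    theta = np.linalg.solve(XtX + 1e-12 * np.eye(3), Xty[..., None])[..., 0]
    resid = np.einsum("vfi,vi->vf", X, theta) - y
    wrss = np.einsum("vf,f->v", resid**2, w)

    if ridge:
        sigma = smooth_fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        theta_s = np.empty_like(theta)
        local_var = np.empty_like(theta)
        for j in range(3):
            vol = np.zeros(img.geometry.shape)
            vol[mask] = theta[:, j]
            sm = _masked_gaussian(vol, mask, sigma)
            sm2 = _masked_gaussian(vol**2, mask, sigma)
            theta_s[:, j] = sm[mask]
            local_var[:, j] = np.maximum(sm2[mask] - sm[mask] ** 2, 0.0)
        h = np.nan_to_num(wrss[:, None] / (local_var + eps), nan=0.0, posinf=0.0)
        H = np.zeros((V, 3, 3))
        H[:, [0, 1, 2], [0, 1, 2]] = h
        theta = np.linalg.solve(XtX + H + 1e-12 * np.eye(3),
                                (Xty + h * theta_s)[..., None])[..., 0]
        resid = np.einsum("vfi,vi->vf", X, theta) - y
        wrss = np.einsum("vf,f->v", resid**2, w)

    P1, P2, P3 = theta[:, 0], theta[:, 1], theta[:, 2]
    k2 = np.clip(P2, 0.0, _K2_MAX)
    Vb = np.clip(P3, 0.0, 1.0)
    K1 = np.clip(P1 - k2 * Vb, 0.0, _K1_MAX)

    def to_map(vals, name, units):
        vol = np.full(img.geometry.shape, np.nan)
        vol[mask] = vals
        return ParametricMap(name, vol, units, img.geometry)

    return {
        "K1": to_map(K1, "K1", "1/min"),
        "k2": to_map(k2, "k2", "1/min"),
        "Vb": to_map(Vb, "Vb", "fraction"),
        "wrss": to_map(wrss, "wrss", "(kBq/mL)^2"),
    }


def flow_map(K1_map: ParametricMap, extraction_fraction: float = 0.85) -> ParametricMap:
    """CBF (mL/100 g/min) = K1 / E × 100, assuming tissue density 1 g/mL."""
    if not 0 < extraction_fraction <= 1:
        raise ValueError("extraction fraction must lie in (0, 1]")
    data = K1_map.data / extraction_fraction * 100.0
    return ParametricMap("CBF", data, "mL/100g/min", K1_map.geometry)


def normalize_map(pmap: ParametricMap, reference_mean: float) -> ParametricMap:
    """Divide a map by its reference-region mean (e.g. cerebellar gray matter)."""
    if not reference_mean > 0:
        raise ValueError("reference mean must be positive")
    return ParametricMap(
        pmap.name + "_norm", pmap.data / reference_mean, "ratio", pmap.geometry
    )
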