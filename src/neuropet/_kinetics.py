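"""Shared numerics for compartment-model evaluation.

Every kinetic model in the package reduces to convolving an input curve with
a single decaying exponential.  On a uniform fine grid (default step 0.01
min) with the input taken as piecewise linear, that convolution has an exact
recursive solution, used here instead of quadrature so model curves agree
with a stiff ODE oracle to near machine precision.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

#: Fine-grid step for all convolutions and frame averaging (minutes).
FINE_STEP_MIN = 0.01


def fine_grid(t_end_min: float, step: float = FINE_STEP_MIN) -> np.ndarray:
    """Uniform grid 0..t_end (inclusive endpoint, minutes)."""
    n = int(np.ceil(t_end_min / step - 1e-9)) + 1
    return np.arange(n) * step


def sample_curve(time_min, value, grid) -> np.ndarray:
    """Linear interpolation of a sampled curve onto a grid.

    Zero before the first sample (tracer not yet arrived); the last sample
    value is held beyond the final time.
    """
    time_min = np.asarray(time_min, dtype=float)
    value = np.asarray(value, dtype=float)
    return np.interp(grid, time_min, value, left=0.0, right=value[-1])


def expconv(u: np.ndarray, rate: float, step: float = FINE_STEP_MIN) -> np.ndarray:
    """Exact convolution of a piecewise-linear curve with ``exp(-rate*t)``.

    Returns ``y(t) = ∫_0^t u(s) exp(-rate (t - s)) ds`` on the same uniform
    grid, i.e. the solution of ``y' = u - rate*y`` with ``y(0)=0`` for the
    piecewise-linear interpolant of ``u``.  ``rate = 0`` degenerates to the
    running (trapezoidal) integral.
    """
    u = np.asarray(u, dtype=float)
    if rate < 0:
        raise ValueError("rate must be non-negative")
    n = u.size
    y = np.empty(n)
    y[0] = 0.0
    dt = step
    if rate * dt < 1e-12:
        # running trapezoid integral
        y[1:] = np.cumsum(0.5 * dt * (u[1:] + u[:-1]))
        return y
    e = np.exp(-rate * dt)
    # over one step with u(s) = a + b s: contribution
    #   a (1-e)/rate + b (dt/rate - (1-e)/rate^2)
    c0 = (1.0 - e) / rate
    c1 = dt / rate - (1.0 - e) / rate**2
    a = u[:-1]
    b = (u[1:] - u[:-1]) / dt
    inc = a * c0 + b * c1
    # the recursion y[i] = e y[i-1] + inc[i-1] is a first-order IIR filter
    y[1:] = lfilter([1.0], [1.0, -e], inc)
    return y


def cumulative_integral(u: np.ndarray, step: float = FINE_STEP_MIN) -> np.ndarray:
    """Running trapezoidal integral on the fine grid."""
    return expconv(u, 0.0, step)


def frame_average_fine(values: np.ndarray, grid: np.ndarray, start_min, end_min) -> np.ndarray:
    """Mean of a fine-grid curve over each frame interval ``[start, end]``.

    Exact for the piecewise-linear interpolant: computed as differences of
    the running trapezoid integral, linearly interpolated at the frame edges.
    """
    values = np.asarray(values, dtype=float)
    start_min = np.atleast_1d(np.asarray(start_min, dtype=float))
    end_min = np.atleast_1d(np.asarray(end_min, dtype=float))
    if end_min[-1] > grid[-1] + 1e-9:
        raise ValueError("fine grid does not cover the frame schedule")
    step = grid[1] - grid[0]
    F = cumulative_integral(values, step)
    # the running integral of a piecewise-linear curve is piecewise quadratic;
    # interpolate it quadratically so frame edges off the grid stay exact
    f_lo = _quad_interp(F, values, grid, start_min)
    f_hi = _quad_interp(F, values, grid, end_min)
    return (f_hi - f_lo) / (end_min - start_min)


def _quad_interp(F, u, grid, t):
    """Evaluate the running integral F at arbitrary times (exact for linear u)."""
    step = grid[1] - grid[0]
    idx = np.clip(np.floor(t / step).astype(int), 0, grid.size - 2)
    s = t - grid[idx]
    a = u[idx]
    b = (u[idx + 1] - u[idx]) / step
    return F[idx] + a * s + 0.5 * b * s * s
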