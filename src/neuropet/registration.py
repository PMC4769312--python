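"""Rigid and symmetric diffeomorphic image registration.

Two registration layers feed the workflow:

* a 6-parameter (3 in 2-D) rigid-body alignment of summed PET to structural
  images, driven by mutual information on a multiresolution pyramid;
* a greedy symmetric diffeomorphic normalization ("SyN"-style) of structural
  images to a template, driven by a localized squared cross-correlation
  metric.  Two half-way warps φ1 (applied to the source S) and φ2 (applied
  to the target T) meet at a midpoint and are updated symmetrically, so the
  result is independent of the input order; the full forward map S→T is
  composed as φ2⁻¹∘φ1 and its exact inverse as φ1⁻¹∘φ2.

Focal lesions are handled as missing data (constrained cost-function
masking): lesion voxels are excluded from the similarity windows and their
velocity is inferred by smooth diffusion inpainting from the exterior.

All displacement fields are stored in voxel units of their grid; the
registration itself contains no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import List, Optional, Tuple, Union

import numpy as np
from scipy import ndimage

from .core_io import VolumeGeometry

__all__ = [
    "RigidTransform",
    "DeformationField",
    "DiffeoPair",
    "TransformChain",
    "mutual_information",
    "rigid_register",
    "local_cc",
    "syn_register",
    "apply_cost_mask",
    "invert_field",
    "compose_fields",
    "compose_chain",
    "warp_image",
    "jacobian_determinant",
]


# ---------------------------------------------------------------------------
# Transform containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """Rigid-body map in voxel coordinates of the fixed image.

    Acts as a pull-back: a point x on the fixed grid is sent to
    R(x − c) + c + t in the moving image, with c the grid center.  2-D uses
    one angle; 3-D uses three (intrinsic z-y-x order, degrees).
    """

    angles_deg: Tuple[float, ...]
    translation: Tuple[float, ...]

    def __post_init__(self):
        n_ang, n_tr = len(self.angles_deg), len(self.translation)
        if (n_ang, n_tr) not in ((1, 2), (3, 3)):
            raise ValueError("expected (1 angle, 2 translations) or (3, 3)")

    @property
    def ndim(self) -> int:
        return len(self.translation)

    def matrix(self) -> np.ndarray:
        a = np.deg2rad(self.angles_deg)
        if self.ndim == 2:
            c, s = np.cos(a[0]), np.sin(a[0])
            return np.array([[c, -s], [s, c]])
        rz = np.array(
            [[np.cos(a[0]), -np.sin(a[0]), 0], [np.sin(a[0]), np.cos(a[0]), 0], [0, 0, 1]]
        )
        ry = np.array(
            [[np.cos(a[1]), 0, np.sin(a[1])], [0, 1, 0], [-np.sin(a[1]), 0, np.cos(a[1])]]
        )
        rx = np.array(
            [[1, 0, 0], [0, np.cos(a[2]), -np.sin(a[2])], [0, np.sin(a[2]), np.cos(a[2])]]
        )
        return rz @ ry @ rx

    def apply_points(self, pts: np.ndarray, shape) -> np.ndarray:
        """Map points (N, d) on the fixed grid into the moving grid."""
        c = (np.asarray(shape, dtype=float) - 1) / 2.0
        return (pts - c) @ self.matrix().T + c + np.asarray(self.translation)

    def inverse(self) -> "RigidTransform":
        R = self.matrix()
        t = np.asarray(self.translation)
        # inverse of x -> R(x-c)+c+t is x -> R^T(x-c-t)+c, i.e. angles negated
        # and translation -R^T t
        inv_t = tuple((-R.T @ t).tolist())
        return RigidTransform(tuple(-a for a in self.angles_deg), inv_t)

    def to_field(self, geometry: VolumeGeometry) -> "DeformationField":
        grid = _identity_grid(geometry.shape)
        pts = grid.reshape(len(geometry.shape), -1).T
        mapped = self.apply_points(pts, geometry.shape)
        disp = (mapped - pts).T.reshape(grid.shape)
        return DeformationField(disp, geometry)


@dataclass
class DeformationField:
    """Dense displacement field, voxel units: point x maps to x + disp[:, x]."""

    disp: np.ndarray  # (d, *spatial)
    geometry: VolumeGeometry

    def __post_init__(self):
        self.disp = np.asarray(self.disp, dtype=float)
        d = self.geometry.ndim
        if self.disp.shape != (d,) + self.geometry.shape:
            raise ValueError("displacement shape must be (ndim, *spatial)")
        if not np.all(np.isfinite(self.disp)):
            raise ValueError("displacement field must be finite")

    @property
    def ndim(self) -> int:
        return self.geometry.ndim


@dataclass
class DiffeoPair:
    """Forward (S→T) and inverse (T→S) diffeomorphic maps plus the metric trace."""

    forward: DeformationField
    inverse: DeformationField
    metric_trace: List[float] = dataclass_field(default_factory=list)


#: chain element: a transform plus an "inverted" flag
ChainElement = Tuple[Union[RigidTransform, DeformationField], bool]


@dataclass
class TransformChain:
    """Ordered transforms applied to a point from the output grid inward.

    Warping an image through the chain samples the input image at
    Φn(…Φ1(x)…): the first element maps the output grid, the last lands on
    the input grid.  The chain inverts by reversing the order and inverting
    each element.
    """

    elements: List[ChainElement] = dataclass_field(default_factory=list)

    def add(self, transform, inverted: bool = False) -> "TransformChain":
        self.elements.append((transform, inverted))
        return self

    def inverted(self) -> "TransformChain":
        out = TransformChain()
        for tr, inv in reversed(self.elements):
            out.add(tr, not inv)
        return out


# ---------------------------------------------------------------------------
# Warping and field algebra
# ---------------------------------------------------------------------------

def _identity_grid(shape) -> np.ndarray:
    return np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij"))


def warp_image(img: np.ndarray, transform, interp: str = "linear") -> np.ndarray:
    """Pull-back resampling of an image through a transform.

    ``transform`` may be a DeformationField, a RigidTransform, a raw
    displacement array, or a TransformChain (composed first).  ``linear``
    interpolation for intensities, ``nearest`` for labels; samples falling
    outside the input grid become 0.
    """
    if interp not in ("linear", "nearest"):
        raise ValueError("interp must be 'linear' or 'nearest'")
    order = 1 if interp == "linear" else 0
    img = np.asarray(img)
    if isinstance(transform, TransformChain):
        geom = VolumeGeometry(img.shape, (1.0,) * img.ndim)
        transform = compose_chain(transform, geom)
    if isinstance(transform, RigidTransform):
        grid = _identity_grid(img.shape)
        pts = grid.reshape(img.ndim, -1).T
        coords = transform.apply_points(pts, img.shape).T.reshape(grid.shape)
    else:
        disp = transform.disp if isinstance(transform, DeformationField) else np.asarray(transform)
        coords = _identity_grid(img.shape[: disp.shape[0]]) + disp
    if interp == "nearest":
        out = ndimage.map_coordinates(img, coords, order=0, mode="constant", cval=0)
        return out.astype(img.dtype)
    return ndimage.map_coordinates(img.astype(float), coords, order=order, mode="constant", cval=0.0)


def _interp_field(disp: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Sample each displacement component at fractional coordinates."""
    # nearest-edge extension keeps composed fields well behaved at borders
    return np.stack(
        [ndimage.map_coordinates(c, coords, order=1, mode="nearest") for c in disp]
    )


def compose_fields(first: np.ndarray, second: np.ndarray) -> np.ndarray:
    """Displacement of 'apply first, then second' (pull-back order).

    warp(warp(img, first), second) == warp(img, compose_fields(first, second)):
    the composed map sends x to x + second(x) + first(x + second(x)).
    """
    grid = _identity_grid(second.shape[1:])
    coords = grid + second
    return second + _interp_field(first, coords)


def invert_field(f: DeformationField, max_iter: int = 50, tol_vox: float = 0.01) -> DeformationField:
    """Fixed-point inversion: iterate g ← −f(x + g(x)) until the mean update
    falls below ``tol_vox`` voxels.  Valid for diffeomorphic (positive-
    Jacobian) fields; non-convergence raises with the residual."""
    disp = f.disp if isinstance(f, DeformationField) else np.asarray(f)
    grid = _identity_grid(disp.shape[1:])
    g = -disp.copy()
    update = np.inf
    for _ in range(max_iter):
        g_new = -_interp_field(disp, grid + g)
        update = float(np.mean(np.linalg.norm(g_new - g, axis=0)))
        g = g_new
        if update < tol_vox:
            break
    if not np.all(np.isfinite(g)):
        raise RuntimeError("field inversion diverged")
    if isinstance(f, DeformationField):
        return DeformationField(g, f.geometry)
    return g


def compose_chain(chain: TransformChain, geometry: VolumeGeometry) -> DeformationField:
    """Collapse a transform chain into one displacement field on ``geometry``.

    Warping through the composed field equals sequential warping but incurs
    a single interpolation of the image.
    """
    total: Optional[np.ndarray] = None
    for tr, inv in chain.elements:
        if isinstance(tr, RigidTransform):
            tr = tr.inverse() if inv else tr
            disp = tr.to_field(geometry).disp
        elif isinstance(tr, DeformationField):
            disp = invert_field(tr).disp if inv else tr.disp
            if tr.geometry.shape != geometry.shape:
                raise ValueError("incompatible geometry in transform chain")
        else:
            raise TypeError(f"unsupported chain element {type(tr)}")
        # point-wise: after this element the map is Φ_new ∘ Φ_total
        total = disp if total is None else compose_fields(disp, total)
    if total is None:
        d = geometry.ndim
        total = np.zeros((d,) + geometry.shape)
    return DeformationField(total, geometry)


def jacobian_determinant(f: DeformationField) -> np.ndarray:
    """Determinant of ∇(id + f) by central differences (1 at zero field)."""
    disp = f.disp if isinstance(f, DeformationField) else np.asarray(f)
    d = disp.shape[0]
    J = np.empty(disp.shape[1:] + (d, d))
    for i in range(d):
        for j in range(d):
            J[..., i, j] = np.gradient(disp[i], axis=j)
        J[..., i, i] += 1.0
    return np.linalg.det(J)


# ---------------------------------------------------------------------------
# Mutual information and rigid registration
# ---------------------------------------------------------------------------

def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Mutual information (nats) from a joint intensity histogram."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("images must share shape")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("images must be finite")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    hist, _, _ = np.histogram2d(a, b, bins=bins)
    p = hist / hist.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    sm = ndimage.gaussian_filter(img.astype(float), sigma=factor / 2.0)
    sl = tuple(slice(None, None, factor) for _ in range(img.ndim))
    return sm[sl]


def rigid_register(moving: np.ndarray, fixed: np.ndarray, levels=(4, 2, 1),
                   bins: int = 32, fixed_mask: Optional[np.ndarray] = None) -> RigidTransform:
    """Rigid-body alignment maximizing mutual information.

    Derivative-free direction-set (Powell) optimization of −MI at each
    pyramid level, warm-started from the previous level.  Returns the
    moving→fixed transform (a pull-back on the fixed grid).

    ``fixed_mask`` marks fixed-image voxels (e.g. a focal lesion) to exclude
    from the joint histogram; the interior is zeroed before pyramid
    smoothing, so the result is independent of the intensities inside it.
    """
    from scipy.optimize import minimize

    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.ndim != fixed.ndim:
        raise ValueError("dimensionality mismatch")
    d = fixed.ndim
    n_ang = 1 if d == 2 else 3
    params = np.zeros(n_ang + d)
    if fixed_mask is not None:
        fixed_mask = np.asarray(fixed_mask, dtype=bool)
        fixed = np.where(fixed_mask, 0.0, fixed)

    for level in levels:
        mv = _downsample(moving, level)
        fx = _downsample(fixed, level)
        valid = None
        if fixed_mask is not None:
            valid = _downsample(fixed_mask.astype(float), level) <= 1e-6

        def neg_mi(p):
            tr = RigidTransform(tuple(p[:n_ang]), tuple(p[n_ang:]))
            warped = warp_image(mv, tr)
            if valid is not None:
                return -mutual_information(warped[valid], fx[valid], bins=bins)
            return -mutual_information(warped, fx, bins=bins)

        # translations shrink by the pyramid factor at this level
        x0 = params.copy()
        x0[n_ang:] /= level
        res = minimize(neg_mi, x0, method="Powell",
                       options={"xtol": 1e-4, "ftol": 1e-7, "maxiter": 400})
        if not np.isfinite(res.fun):
            raise RuntimeError("rigid registration failed to evaluate the metric")
        params = res.x.copy()
        params[n_ang:] *= level
    return RigidTransform(tuple(params[:n_ang]), tuple(params[n_ang:]))


# ---------------------------------------------------------------------------
# Localized cross-correlation
# ---------------------------------------------------------------------------

def _boxsum(x: np.ndarray, radius: int) -> np.ndarray:
    size = 2 * radius + 1
    return ndimage.uniform_filter(x, size=size, mode="constant", cval=0.0) * size ** x.ndim


def _cc_terms(S: np.ndarray, T: np.ndarray, radius: int, valid: np.ndarray):
    """Shared sums for the local CC metric and both intensity derivatives.

    Returns (score, dS, dT): the mean per-voxel squared correlation ρ over
    valid window centers and the derivatives of Σρ with respect to the S and
    T intensities (already divided by the number of valid centers so they
    are gradients of the mean score).
    """
    w = valid.astype(float)
    Sw, Tw = S * w, T * w
    n = _boxsum(w, radius)
    sS = _boxsum(Sw, radius)
    sT = _boxsum(Tw, radius)
    sSS = _boxsum(Sw * S, radius)
    sTT = _boxsum(Tw * T, radius)
    sST = _boxsum(Sw * T, radius)
    with np.errstate(invalid="ignore", divide="ignore"):
        muS = np.where(n > 0, sS / np.maximum(n, 1e-12), 0.0)
        muT = np.where(n > 0, sT / np.maximum(n, 1e-12), 0.0)
    A = sST - muS * sT
    B = sSS - muS * sS
    C = sTT - muT * sT
    eps = 1e-8 * (np.mean(np.abs(S)) + np.mean(np.abs(T)) + 1e-30) ** 2
    good = valid & (B > eps) & (C > eps) & (n >= 2)
    rho = np.zeros_like(A)
    rho[good] = A[good] ** 2 / (B[good] * C[good])
    n_valid = int(np.count_nonzero(good))
    score = float(rho[good].mean()) if n_valid else 0.0

    F1 = np.zeros_like(A)
    F2 = np.zeros_like(A)
    G1 = np.zeros_like(A)
    G2 = np.zeros_like(A)
    F1[good] = 2.0 * A[good] / (B[good] * C[good])
    F2[good] = 2.0 * A[good] ** 2 / (B[good] ** 2 * C[good])
    G1[good] = F1[good]
    G2[good] = 2.0 * A[good] ** 2 / (B[good] * C[good] ** 2)
    scale = 1.0 / max(n_valid, 1)
    dS = w * (T * _boxsum(F1, radius) - _boxsum(F1 * muT, radius)
              - S * _boxsum(F2, radius) + _boxsum(F2 * muS, radius)) * scale
    dT = w * (S * _boxsum(G1, radius) - _boxsum(G1 * muS, radius)
              - T * _boxsum(G2, radius) + _boxsum(G2 * muT, radius)) * scale
    return score, dS, dT


def local_cc(S: np.ndarray, T: np.ndarray, radius: int = 4, mask: Optional[np.ndarray] = None):
    """Localized squared cross-correlation metric and its gradient on S.

    At every voxel, ρ = ⟨S̄,T̄⟩² / (⟨S̄,S̄⟩·⟨T̄,T̄⟩) over a (2r+1)^d window with
    local means subtracted; the score is the mean ρ over valid window
    centers.  When a mask is given, masked voxels are excluded from all
    windows and from the score, and the gradient is forced to zero inside
    the mask.

    Returns ``(score, gradient)`` where the gradient is the vector field
    ∂score/∂(S displacement) = (∂score/∂S)·∇S, shape (d, *spatial).
    """
    S = np.asarray(S, dtype=float)
    T = np.asarray(T, dtype=float)
    if S.shape != T.shape:
        raise ValueError("images must share shape")
    if min(S.shape) < 2 * radius + 1:
        raise ValueError("correlation window larger than the image")
    valid = np.ones(S.shape, dtype=bool) if mask is None else ~np.asarray(mask, dtype=bool)
    score, dS, _ = _cc_terms(S, T, radius, valid)
    gradS = np.stack(np.gradient(S))
    return score, dS * gradS


def intensity_gradient(S: np.ndarray, T: np.ndarray, radius: int = 4,
                       mask: Optional[np.ndarray] = None) -> np.ndarray:
    """∂(mean local-CC score)/∂S(x) — the scalar intensity derivative.

    Exposed separately so the analytic gradient can be validated against
    finite differences without the geometric ∇S factor.
    """
    valid = np.ones(S.shape, dtype=bool) if mask is None else ~np.asarray(mask, dtype=bool)
    _, dS, _ = _cc_terms(np.asarray(S, float), np.asarray(T, float), radius, valid)
    return dS


# ---------------------------------------------------------------------------
# Cost-function masking
# ---------------------------------------------------------------------------

def apply_cost_mask(update: np.ndarray, mask: np.ndarray, sweeps: int = 50) -> np.ndarray:
    """Replace update-field values inside a lesion mask by diffusion inpainting.

    Iterative neighbor averaging with the exterior held fixed produces a
    smooth (approximately harmonic) extension of the exterior velocity into
    the lesion, realizing the missing-data treatment of focal lesions.
    """
    mask = np.asarray(mask, dtype=bool)
    if not np.any(mask):
        return update
    if np.all(mask):
        raise ValueError("mask covers the whole image")
    out = update.copy()
    footprint = ndimage.generate_binary_structure(mask.ndim, 1).astype(float)
    footprint[tuple(s // 2 for s in footprint.shape)] = 0.0  # neighbors only
    footprint /= footprint.sum()
    # seed the interior with the nearest exterior value, then relax
    _, nearest = ndimage.distance_transform_edt(mask, return_indices=True)
    fill_idx = tuple(ind[mask] for ind in nearest)
    for comp in range(out.shape[0]):
        c = out[comp]
        c[mask] = c[fill_idx]
        for _ in range(sweeps):
            avg = ndimage.correlate(c, footprint, mode="nearest")
            c[mask] = avg[mask]
        out[comp] = c
    return out


# ---------------------------------------------------------------------------
# Greedy symmetric diffeomorphic registration
# ---------------------------------------------------------------------------

def _resize_field(disp: np.ndarray, new_shape) -> np.ndarray:
    old_shape = disp.shape[1:]
    factors = [n / o for n, o in zip(new_shape, old_shape)]
    out = np.empty((disp.shape[0],) + tuple(new_shape))
    for i, c in enumerate(disp):
        out[i] = ndimage.zoom(c, factors, order=1, mode="nearest") * factors[i]
    return out


def syn_register(
    S: np.ndarray,
    T: np.ndarray,
    levels=(8, 4, 2, 1),
    max_iter: int = 250,
    radius: int = 4,
    mask: Optional[np.ndarray] = None,
    sigma_fluid: float = 3.0,
    sigma_elastic: float = 0.5,
    max_step_vox: float = 0.25,
    converge_tol: float = 1e-6,
    converge_window: int = 10,
) -> DiffeoPair:
    """Greedy symmetric diffeomorphic registration of S onto T.

    Half-warps φ1 (on S) and φ2 (on T) are advanced toward each other: per
    iteration the local-CC gradients between S∘φ1 and T∘φ2 are smoothed with
    a fluid Gaussian, scaled so the largest update is ``max_step_vox``,
    composed into the half-warps, and the totals are smoothed elastically.
    An iteration is accepted only if the metric does not decrease (otherwise
    the step is halved), so the recorded metric trace is non-decreasing.
    The scheme runs coarse→fine over ``levels`` with at most ``max_iter``
    iterations per level and stops early when the score improves by less
    than ``converge_tol`` over ``converge_window`` iterations.

    A lesion mask (in S's voxel space) activates constrained cost-function
    masking: S is treated as missing inside the mask — those voxels are
    zeroed, excluded from the metric, and the update field inside the
    (warped) mask is inpainted from its exterior — so the output is entirely
    independent of the original intensities inside the lesion.

    Returns a DiffeoPair with forward = φ2⁻¹∘φ1, inverse = φ1⁻¹∘φ2 and the
    per-iteration metric trace.
    """
    S = np.asarray(S, dtype=float)
    T = np.asarray(T, dtype=float)
    if S.shape != T.shape:
        raise ValueError("S and T must share shape")
    d = S.ndim
    full_shape = S.shape
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != full_shape:
            raise ValueError("mask must share the image shape")
        S = np.where(mask, 0.0, S)

    phi1 = phi2 = None
    trace: List[float] = []

    for level in levels:
        S_l = _downsample(S, level)
        T_l = _downsample(T, level)
        mask_l = None
        if mask is not None:
            mask_l = _downsample(mask.astype(float), level) > 0.25
        shape_l = S_l.shape
        r_l = max(2, int(round(radius / max(1, level // 2)))) if level > 1 else radius
        if min(shape_l) < 2 * r_l + 1:
            r_l = max(1, (min(shape_l) - 1) // 2)
        if phi1 is None:
            phi1 = np.zeros((d,) + shape_l)
            phi2 = np.zeros((d,) + shape_l)
        else:
            phi1 = _resize_field(phi1, shape_l)
            phi2 = _resize_field(phi2, shape_l)

        step = max_step_vox
        grid1 = _identity_grid(shape_l)

        def metric_at(p1, p2):
            S1 = _warp_disp(S_l, p1)
            T2 = _warp_disp(T_l, p2)
            m1 = None
            if mask_l is not None:
                m1 = _warp_disp(mask_l.astype(float), p1) > 0.5
            sc, dS_, dT_ = _cc_terms(S1, T2, r_l, np.ones(shape_l, bool) if m1 is None
                                     else ~m1)
            return sc, S1, T2, dS_, dT_, m1

        score, S1, T2, dS, dT, m1 = metric_at(phi1, phi2)
        best_scores = [score]
        for _ in range(max_iter):
            g1 = dS * np.stack(np.gradient(S1))
            g2 = dT * np.stack(np.gradient(T2))
            u1 = np.stack([ndimage.gaussian_filter(c, sigma_fluid) for c in g1])
            u2 = np.stack([ndimage.gaussian_filter(c, sigma_fluid) for c in g2])
            n1 = np.max(np.linalg.norm(u1, axis=0))
            n2 = np.max(np.linalg.norm(u2, axis=0))
            if max(n1, n2) < 1e-12:
                break
            accepted = False
            local_step = step
            for _try in range(8):
                c1 = u1 * (local_step / n1) if n1 > 0 else u1 * 0
                c2 = u2 * (local_step / n2) if n2 > 0 else u2 * 0
                if m1 is not None:
                    c1 = apply_cost_mask(c1, m1)
                p1 = compose_fields(phi1, c1)
                p2 = compose_fields(phi2, c2)
                p1 = np.stack([ndimage.gaussian_filter(c, sigma_elastic) for c in p1])
                p2 = np.stack([ndimage.gaussian_filter(c, sigma_elastic) for c in p2])
                if (jacobian_determinant(p1).min() <= 0
                        or jacobian_determinant(p2).min() <= 0):
                    local_step *= 0.5
                    continue
                new = metric_at(p1, p2)
                if new[0] >= score:
                    phi1, phi2 = p1, p2
                    score, S1, T2, dS, dT, m1 = new
                    accepted = True
                    break
                local_step *= 0.5
            if not accepted:
                break
            trace.append(score)
            best_scores.append(score)
            if (len(best_scores) > converge_window
                    and best_scores[-1] - best_scores[-1 - converge_window] < converge_tol):
                break

    if phi1 is None:  # no levels — degenerate call
        phi1 = np.zeros((d,) + full_shape)
        phi2 = np.zeros((d,) + full_shape)
    if phi1.shape[1:] != full_shape:
        phi1 = _resize_field(phi1, full_shape)
        phi2 = _resize_field(phi2, full_shape)

    geom = VolumeGeometry(full_shape, (1.0,) * d)
    phi1_f = DeformationField(phi1, geom)
    phi2_f = DeformationField(phi2, geom)
    phi1_inv = invert_field(phi1_f)
    phi2_inv = invert_field(phi2_f)
    forward = DeformationField(compose_fields(phi1, phi2_inv.disp), geom)
    inverse = DeformationField(compose_fields(phi2, phi1_inv.disp), geom)
    return DiffeoPair(forward, inverse, trace)


def _warp_disp(img: np.ndarray, disp: np.ndarray) -> np.ndarray:
    coords = _identity_grid(img.shape) + disp
    return ndimage.map_coordinates(img.astype(float), coords, order=1,
                                   mode="nearest")
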