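"""Mask-weighted affine and cosine-basis nonlinear spatial normalization.

Both registrations minimize a weighted sum of squared intensity differences
on the reference grid,

    E = sum_x w(x) (ref(x) - g * mov(phi(x)))^2 / sum_x w(x)  (+ penalty),

where ``w`` is the intracranial weighting image defined on the reference
grid, ``g`` a global intensity gain (solved in closed form at every
evaluation, so acquisitions with different scanner scaling can be mixed)
and ``phi`` either a 12-parameter affine map or an affine-normalized
identity plus a smooth displacement field expanded in a truncated 3D
cosine (DCT) basis.  Optimization is multi-resolution and fully
deterministic: Levenberg-Marquardt for the affine stage, L-BFGS with an
analytic separable gradient for the basis coefficients.

The deformation objects here double as the pipeline's T_i / T-bar maps:
``invert_deformation`` produces the reference-to-subject map from a fitted
subject-to-reference field, and ``average_deformation`` the unbiased group
mean used to remove the reference subject's geometric bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .core_image import ImageVolume
from .errors import InversionError, RegistrationError

__all__ = [
    "AffineParams",
    "DCTDeformation",
    "RegistrationResult",
    "affine_register",
    "apply_affine",
    "nonlinear_register",
    "invert_deformation",
    "average_deformation",
    "apply_deformation",
    "mirror_conjugate",
]


# ---------------------------------------------------------------------------
# Affine transform


@dataclass
class AffineParams:
    """12-parameter global transform: translation (mm), rotation (rad),
    scale and shear, composed as T @ Rz @ Ry @ Rx @ Scale @ Shear.

    The matrix maps reference world coordinates to moving-image world
    coordinates: the registered image is ``mov(A x)`` sampled on the
    reference grid.
    """

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: np.ndarray = field(default_factory=lambda: np.ones(3))
    shear: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3)
        self.scale = np.asarray(self.scale, dtype=float).reshape(3)
        self.shear = np.asarray(self.shear, dtype=float).reshape(3)
        if np.any(self.scale <= 0):
            raise ValueError("scales must be strictly positive")

    @classmethod
    def identity(cls) -> "AffineParams":
        return cls()

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "AffineParams":
        v = np.asarray(v, dtype=float)
        return cls(v[0:3], v[3:6], np.exp(v[6:9]), v[9:12])

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.translation, self.rotation, np.log(self.scale), self.shear]
        )

    def matrix(self) -> np.ndarray:
        cx, cy, cz = np.cos(self.rotation)
        sx, sy, sz = np.sin(self.rotation)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        S = np.diag(self.scale)
        H = np.array(
            [[1, self.shear[0], self.shear[1]], [0, 1, self.shear[2]], [0, 0, 1]]
        )
        M = np.eye(4)
        M[:3, :3] = Rz @ Ry @ Rx @ S @ H
        M[:3, 3] = self.translation
        return M

    def to_dict(self) -> dict:
        return {
            "translation": self.translation.tolist(),
            "rotation": self.rotation.tolist(),
            "scale": self.scale.tolist(),
            "shear": self.shear.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AffineParams":
        return cls(d["translation"], d["rotation"], d["scale"], d["shear"])


@dataclass
class RegistrationResult:
    """Transform plus the per-iteration weighted-SSD objective.

    ``objective_trace`` concatenates the accepted objective values of all
    multi-resolution levels (the objective is rescaled between levels, so
    the non-increase invariant holds within each entry of
    ``trace_by_level``, which is what tests audit).
    """

    transform: object
    objective_trace: list
    converged: bool
    trace_by_level: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Cosine-basis deformation


def _basis_matrix(coords: np.ndarray, lo: float, length: float, k: int) -> np.ndarray:
    """Sample the L2[0,1]-orthonormal cosine basis at world coords.

    beta_0 = 1, beta_l(s) = sqrt(2) cos(pi l s) with s = (x - lo)/length.
    When the coordinates are symmetric about the domain midpoint the sampled
    matrix is symmetrized exactly: B[n-1-i, l] = (-1)^l B[i, l], so mirror
    conjugation of a field is an exact sign flip of its coefficients.
    """
    s = (np.asarray(coords, dtype=float) - lo) / length
    n = s.shape[0] if s.ndim else 1
    B = np.empty((np.size(s), k))
    B[:, 0] = 1.0
    for l in range(1, k):
        B[:, l] = np.sqrt(2.0) * np.cos(np.pi * l * s.reshape(-1))
    # exact mirror symmetry when the sample points are symmetric in [0,1]
    sr = s.reshape(-1)
    lvals = np.arange(k)
    mid_row = np.where(lvals % 2 == 1, 0.0, np.sqrt(2.0) * (-1.0) ** (lvals // 2))
    mid_row[0] = 1.0  # cos(pi l / 2): exactly 0 for odd l, +-1 for even l
    if sr.size > 1 and abs((sr[0] + sr[-1]) - 1.0) < 1e-12:
        m = sr.size
        half = m // 2
        signs = (-1.0) ** np.arange(k)
        B[m - 1 - np.arange(half)] = B[:half] * signs
        if m % 2 == 1:
            B[half] = mid_row
    else:
        # samples landing exactly on the domain midpoint still get the
        # analytically exact values (odd terms vanish on the midplane)
        at_mid = np.abs(sr - 0.5) < 1e-9
        if at_mid.any():
            B[at_mid] = mid_row
    return B


@dataclass
class DCTDeformation:
    """Smooth displacement field u(x) (mm) on a truncated 3D cosine basis.

    ``coeffs`` has shape (3, kx, ky, kz): per world axis, the coefficients of
    the separable basis over the reference field of view.  ``domain_lo`` and
    ``domain_len`` define the normalized coordinate s = (x - lo)/len per axis
    (the domain spans the reference grid, half a voxel beyond the outer
    voxel centers, so voxel-center samples sit at s = (i + 1/2)/n).
    """

    coeffs: np.ndarray
    domain_lo: np.ndarray
    domain_len: np.ndarray
    grid_shape: tuple
    grid_affine: np.ndarray
    regularization: float = 0.0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.domain_lo = np.asarray(self.domain_lo, dtype=float).reshape(3)
        self.domain_len = np.asarray(self.domain_len, dtype=float).reshape(3)
        self.grid_affine = np.asarray(self.grid_affine, dtype=float)
        if self.coeffs.ndim != 4 or self.coeffs.shape[0] != 3:
            raise ValueError("coeffs must have shape (3, kx, ky, kz)")

    @property
    def order(self) -> tuple:
        return self.coeffs.shape[1:]

    @classmethod
    def zeros(cls, like: ImageVolume, k: int | tuple = 8, regularization: float = 0.0):
        ks = np.broadcast_to(np.asarray(k), (3,)).astype(int)
        lo, ln = _domain_from_grid(like)
        return cls(
            np.zeros((3, ks[0], ks[1], ks[2])),
            lo,
            ln,
            tuple(like.shape),
            like.affine.copy(),
            regularization,
        )

    def same_basis(self, other: "DCTDeformation", atol: float = 1e-9) -> bool:
        return (
            self.coeffs.shape == other.coeffs.shape
            and self.grid_shape == other.grid_shape
            and np.allclose(self.grid_affine, other.grid_affine, atol=atol)
            and np.allclose(self.domain_lo, other.domain_lo, atol=atol)
            and np.allclose(self.domain_len, other.domain_len, atol=atol)
        )

    def basis_matrices(self, coords_per_axis: Sequence[np.ndarray]) -> list:
        return [
            _basis_matrix(c, self.domain_lo[a], self.domain_len[a], self.coeffs.shape[1 + a])
            for a, c in enumerate(coords_per_axis)
        ]

    def displacement_on_axes(self, coords_per_axis: Sequence[np.ndarray]) -> np.ndarray:
        """Displacement (3, nx, ny, nz) on a separable set of sample coords."""
        Bx, By, Bz = self.basis_matrices(coords_per_axis)
        return _expand(self.coeffs, Bx, By, Bz)

    def displacement_at_points(self, pts: np.ndarray) -> np.ndarray:
        """Displacement (3, m) at arbitrary world points (3, m)."""
        pts = np.asarray(pts, dtype=float).reshape(3, -1)
        out = np.zeros_like(pts)
        k = self.coeffs.shape[1:]
        Bs = [
            _basis_matrix(pts[a], self.domain_lo[a], self.domain_len[a], k[a])
            for a in range(3)
        ]
        for a in range(3):
            # sum_lmn C[a,l,m,n] Bx[:,l] By[:,m] Bz[:,n], evaluated pointwise
            t = np.einsum("lmn,pl->pmn", self.coeffs[a], Bs[0])
            t = np.einsum("pmn,pm->pn", t, Bs[1])
            out[a] = np.einsum("pn,pn->p", t, Bs[2])
        return out

    def to_dict(self) -> dict:
        return {
            "coeffs": self.coeffs.tolist(),
            "domain_lo": self.domain_lo.tolist(),
            "domain_len": self.domain_len.tolist(),
            "grid_shape": list(self.grid_shape),
            "grid_affine": self.grid_affine.tolist(),
            "regularization": self.regularization,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DCTDeformation":
        return cls(
            np.asarray(d["coeffs"]),
            np.asarray(d["domain_lo"]),
            np.asarray(d["domain_len"]),
            tuple(d["grid_shape"]),
            np.asarray(d["grid_affine"]),
            d.get("regularization", 0.0),
        )

    def as_displacement_volumes(self) -> list:
        """Export as three ImageVolumes (mm displacement per world axis)."""
        coords = _axis_coords(self.grid_shape, self.grid_affine)
        u = self.displacement_on_axes(coords)
        return [
            ImageVolume(u[a].astype(np.float32), self.grid_affine.copy(), f"u_{'xyz'[a]} (mm)")
            for a in range(3)
        ]


def _axis_coords(shape, affine):
    return [affine[a, 3] + np.arange(shape[a]) * affine[a, a] for a in range(3)]


def _domain_from_grid(vol: ImageVolume):
    """Basis domain spanning the grid: from half a voxel before the first
    center to half a voxel after the last, so centers sit at (i+1/2)/n."""
    vs = np.diag(vol.affine[:3, :3])
    lo = vol.affine[:3, 3] - vs / 2.0
    ln = np.asarray(vol.shape) * vs
    return lo, ln


def _expand(coeffs: np.ndarray, Bx, By, Bz) -> np.ndarray:
    """Tensor expansion (3,kx,ky,kz) x basis -> (3,nx,ny,nz)."""
    t = np.tensordot(coeffs, Bz, axes=([3], [1]))  # (3,kx,ky,nz)
    t = np.tensordot(t, By, axes=([2], [1]))  # (3,kx,nz,ny)
    t = np.tensordot(t, Bx, axes=([1], [1]))  # (3,nz,ny,nx)
    return np.ascontiguousarray(np.moveaxis(t, (1, 2, 3), (3, 2, 1)))


def _project(field3: np.ndarray, Bx, By, Bz) -> np.ndarray:
    """Adjoint of _expand: (3,nx,ny,nz) x basis^T -> (3,kx,ky,kz)."""
    t = np.tensordot(field3, Bx, axes=([1], [0]))  # (3,ny,nz,kx)
    t = np.tensordot(t, By, axes=([1], [0]))  # (3,nz,kx,ky)
    t = np.tensordot(t, Bz, axes=([1], [0]))  # (3,kx,ky,kz)
    return t


# ---------------------------------------------------------------------------
# Shared sampling helpers


def _require_axis_aligned(vol: ImageVolume, who: str) -> None:
    if not vol.is_axis_aligned(atol=1e-6):
        raise RegistrationError(f"{who} requires axis-aligned grids; reslice first")


def _smoothed(data: np.ndarray, sigma_vox) -> np.ndarray:
    if np.all(np.asarray(sigma_vox) < 1e-3):
        return np.asarray(data, dtype=float)
    return ndimage.gaussian_filter(np.asarray(data, dtype=float), sigma=sigma_vox)


def _sample_with_gradient(vol_data, vox_coords, gradients):
    """Trilinear sample of an image and its precomputed gradient volumes."""
    m = ndimage.map_coordinates(vol_data, vox_coords, order=1, mode="constant", cval=0.0)
    g = [
        ndimage.map_coordinates(gr, vox_coords, order=1, mode="constant", cval=0.0)
        for gr in gradients
    ]
    return m, np.stack(g)


def _world_to_vox(affine):
    inv = np.linalg.inv(affine)
    return inv[:3, :3], inv[:3, 3]


class _Level:
    """One multi-resolution level: subsampled reference grid + smoothed
    moving image with gradients."""

    def __init__(self, moving, reference, weight, level_mm):
        ref_vs = reference.voxel_size
        stride = np.maximum(1, np.round(level_mm / ref_vs).astype(int))
        sigma_ref = np.maximum(level_mm / ref_vs / 2.0 - 0.5, 0.0)
        ref_s = _smoothed(reference.data, sigma_ref)
        w_s = _smoothed(weight.data, sigma_ref)
        sl = tuple(slice(None, None, int(s)) for s in stride)
        self.ref = ref_s[sl]
        self.w = np.maximum(w_s[sl], 0.0)
        if not np.any(self.w > 0):
            raise RegistrationError("weight image is empty at registration level")
        coords = _axis_coords(reference.shape, reference.affine)
        self.axis_coords = [c[s] for c, s in zip(coords, sl)]
        self.pts = np.stack(
            np.meshgrid(*self.axis_coords, indexing="ij"), axis=0
        ).reshape(3, -1)
        self.wf = self.w.reshape(-1)
        self.rf = self.ref.reshape(-1)
        self.wsum = float(self.wf.sum())
        mov_vs = moving.voxel_size
        sigma_mov = np.maximum(level_mm / mov_vs / 2.0 - 0.5, 0.0)
        self.mov = _smoothed(moving.data, sigma_mov)
        self.mov_grad = [
            g / v for g, v in zip(np.gradient(self.mov), mov_vs)
        ]  # d/d(world mm) on the moving grid
        self.mov_R, self.mov_t = _world_to_vox(moving.affine)

    def sample(self, world_pts):
        vox = self.mov_R @ world_pts + self.mov_t[:, None]
        return _sample_with_gradient(self.mov, vox, self.mov_grad)


def _intensity_centroid(vol: ImageVolume) -> np.ndarray:
    """Intensity-weighted center of mass in world mm."""
    data = np.maximum(np.asarray(vol.data, dtype=float), 0.0)
    tot = data.sum()
    if tot <= 0:
        return vol.affine[:3, :3] @ ((np.asarray(vol.shape) - 1) / 2.0) + vol.affine[:3, 3]
    com = np.array(ndimage.center_of_mass(data))
    return vol.affine[:3, :3] @ com + vol.affine[:3, 3]


def _gain(w, ref, m):
    """Closed-form least-squares intensity gain g minimizing
    sum w (ref - g m)^2."""
    den = float((w * m * m).sum())
    if den <= 0:
        return 1.0
    return float((w * ref * m).sum() / den)


# ---------------------------------------------------------------------------
# Affine registration


def affine_register(
    moving: ImageVolume,
    reference: ImageVolume,
    weight: ImageVolume,
    levels_mm: Sequence[float] = (4.0, 2.0, 1.0),
    max_iter: Sequence[int] = (40, 15, 5),
    tol: float = 1e-8,
) -> RegistrationResult:
    """Mask-weighted 12-parameter affine registration by multi-resolution
    Gauss-Newton descent with backtracking.

    The returned :class:`AffineParams` maps reference world coordinates into
    the moving image; intensities are globally rescaled between the images
    by a closed-form gain inside the objective.
    """
    _require_axis_aligned(moving, "affine_register")
    _require_axis_aligned(reference, "affine_register")
    if not np.any(np.asarray(weight.data) > 0):
        raise ValueError("affine_register: weight image is empty")
    if not weight.same_grid(reference):
        raise ValueError("weight must be defined on the reference grid")
    v = AffineParams.identity().to_vector()
    # initialize translation from intensity centroids (background is ~0);
    # pre-alignment keeps the coarse level out of rotation-compensated
    # local minima around nearly-symmetric heads
    v[0:3] = _intensity_centroid(moving) - _intensity_centroid(reference)
    by_level: list[list[float]] = []
    converged = False
    for level_mm, iters in zip(levels_mm, max_iter):
        lev = _Level(moving, reference, weight, level_mm)
        v, lvl_trace, converged = _affine_gn(lev, v, iters, tol)
        by_level.append(lvl_trace)
    if not np.all(np.isfinite(v)):
        raise RegistrationError("affine optimization produced non-finite parameters")
    flat = [e for lvl in by_level for e in lvl]
    return RegistrationResult(AffineParams.from_vector(v), flat, converged, by_level)


def _affine_objective(lev: _Level, v: np.ndarray):
    A = AffineParams.from_vector(v).matrix()
    pts = A[:3, :3] @ lev.pts + A[:3, 3:4]
    m, grad = lev.sample(pts)
    g = _gain(lev.wf, lev.rf, m)
    r = lev.rf - g * m
    E = float((lev.wf * r * r).sum() / lev.wsum)
    return E, m, grad, g, r

_EPS_FD = 1e-6


def _param_matrix_derivs(v: np.ndarray) -> np.ndarray:
    """dA/dp for the 12 parameters, by central differences on the matrix."""
    out = np.empty((12, 4, 4))
    for p in range(12):
        vp = v.copy()
        vp[p] += _EPS_FD
        vm = v.copy()
        vm[p] -= _EPS_FD
        out[p] = (
            AffineParams.from_vector(vp).matrix() - AffineParams.from_vector(vm).matrix()
        ) / (2 * _EPS_FD)
    return out


def _affine_gn(lev: _Level, v0: np.ndarray, max_iter: int, tol: float):
    """Levenberg-Marquardt descent on the weighted SSD; only improving
    steps are accepted, so the returned trace is non-increasing."""
    v = v0.copy()
    E, m, grad, g, r = _affine_objective(lev, v)
    if not np.isfinite(E):
        raise RegistrationError("non-finite registration objective")
    trace = [E]
    converged = False
    mu = 1e-6
    for _ in range(max_iter):
        dA = _param_matrix_derivs(v)
        # J[:, p] = -g * grad . (dA/dp @ [x; 1])
        dpts = np.einsum("pij,jn->pin", dA[:, :3, :3], lev.pts) + dA[:, :3, 3][:, :, None]
        J = -g * np.einsum("an,pan->np", grad, dpts)
        sw = np.sqrt(lev.wf / lev.wsum)
        Jw = J * sw[:, None]
        rw = r * sw
        JtJ = Jw.T @ Jw
        Jtr = Jw.T @ rw
        diag = np.diag(JtJ).copy()
        diag[diag <= 0] = 1.0
        accepted = False
        for _lm in range(12):
            try:
                step = np.linalg.solve(JtJ + mu * np.diag(diag), -Jtr)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            E2, m2, grad2, g2, r2 = _affine_objective(lev, v + step)
            if np.isfinite(E2) and E2 < E:
                v = v + step
                rel = (E - E2) / max(E, 1e-300)
                E, m, grad, g, r = E2, m2, grad2, g2, r2
                trace.append(E)
                accepted = True
                mu = max(mu * 0.3, 1e-10)
                if rel < tol:
                    converged = True
                break
            mu *= 10.0
            if mu > 1e8:
                break
        if not accepted or converged:
            converged = converged or not accepted
            break
    return v, trace, converged


def apply_affine(
    t: AffineParams | np.ndarray,
    vol: ImageVolume,
    like: ImageVolume | None = None,
    kind: str = "intensity",
    binarize: bool = False,
) -> ImageVolume:
    """Resample ``vol`` onto the grid of ``like`` through the affine map.

    ``kind='mask'`` keeps the trilinearly interpolated values continuous in
    [0, 1] unless ``binarize`` thresholds at 0.5.
    """
    A = t.matrix() if isinstance(t, AffineParams) else np.asarray(t, dtype=float)
    if abs(np.linalg.det(A[:3, :3])) < 1e-12:
        raise ValueError("singular affine transform")
    like = vol if like is None else like
    coords = _axis_coords(like.shape, like.affine)
    pts = np.stack(np.meshgrid(*coords, indexing="ij"), axis=0).reshape(3, -1)
    src = A[:3, :3] @ pts + A[:3, 3:4]
    R, tt = _world_to_vox(vol.affine)
    vox = R @ src + tt[:, None]
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float), vox, order=1, mode="constant", cval=0.0
    ).reshape(like.shape)
    if kind == "mask":
        out = np.clip(out, 0.0, 1.0)
        if binarize:
            out = (out > 0.5).astype(float)
    return ImageVolume(out.astype(np.float32), like.affine.copy(), vol.description)


# ---------------------------------------------------------------------------
# Nonlinear (cosine-basis) registration


def _bending_weights(d: DCTDeformation) -> np.ndarray:
    """Diagonal bending-energy weights omega^4 per coefficient: for basis
    term (l,m,n), omega^2 = (pi l/Lx)^2 + (pi m/Ly)^2 + (pi n/Lz)^2."""
    k = d.coeffs.shape[1:]
    w2 = [
        (np.pi * np.arange(k[a]) / d.domain_len[a]) ** 2 for a in range(3)
    ]
    om2 = w2[0][:, None, None] + w2[1][None, :, None] + w2[2][None, None, :]
    return (om2 ** 2)[None, :, :, :]  # broadcast over the 3 components


def nonlinear_register(
    moving: ImageVolume,
    reference: ImageVolume,
    weight: ImageVolume,
    k: int = 8,
    regularization: float = 0.01,
    levels_mm: Sequence[float] = (4.0, 2.0),
    max_iter: Sequence[int] = (60, 30),
) -> RegistrationResult:
    """Fit a cosine-basis displacement field normalizing ``moving`` (already
    affinely normalized, on any grid) to ``reference``.

    Minimizes the weighted SSD plus a bending-energy penalty
    ``lambda * sum c^2 omega^4`` (the analytic integral of the squared
    second derivatives of the separable cosine terms), by L-BFGS with an
    analytic gradient obtained from separable basis projections.
    """
    if k < 2:
        raise ValueError("basis order k must be >= 2")
    _require_axis_aligned(moving, "nonlinear_register")
    _require_axis_aligned(reference, "nonlinear_register")
    if not weight.same_grid(reference):
        raise ValueError("weight must be defined on the reference grid")
    if not np.any(np.asarray(weight.data) > 0):
        raise ValueError("nonlinear_register: weight image is empty")
    d = DCTDeformation.zeros(reference, k=k, regularization=regularization)
    pen_w = regularization * _bending_weights(d)
    # scale the quartic frequency weights so the penalty is comparable across
    # fields of view: normalize by the mean nonzero omega^4
    nz = pen_w[pen_w > 0]
    if nz.size:
        pen_w = pen_w / nz.mean()
    by_level: list[list[float]] = []
    converged = False
    shape = d.coeffs.shape
    c = d.coeffs.reshape(-1).copy()
    for level_mm, iters in zip(levels_mm, max_iter):
        lev = _Level(moving, reference, weight, level_mm)
        Bx, By, Bz = d.basis_matrices(lev.axis_coords)
        cache = {"x": None, "E": None}

        def fun(cvec):
            C = cvec.reshape(shape)
            u = _expand(C, Bx, By, Bz).reshape(3, -1)
            m, grad = lev.sample(lev.pts + u)
            g = _gain(lev.wf, lev.rf, m)
            r = lev.rf - g * m
            E = float((lev.wf * r * r).sum() / lev.wsum)
            pen = float((pen_w * C * C).sum())
            q = (-2.0 * g / lev.wsum) * (lev.wf * r) * grad  # (3, npts)
            gC = _project(q.reshape(3, *lev.ref.shape), Bx, By, Bz)
            gC += 2.0 * pen_w * C
            cache["x"], cache["E"] = cvec.copy(), E + pen
            return E + pen, gC.reshape(-1)

        hist: list[float] = []

        def cb(xk):
            # L-BFGS's last accepted evaluation is the new iterate
            if cache["x"] is not None and np.array_equal(xk, cache["x"]):
                hist.append(cache["E"])
            else:
                hist.append(fun(xk)[0])

        E0 = fun(c)[0]
        if not np.isfinite(E0):
            raise RegistrationError("non-finite registration objective")
        res = minimize(
            fun,
            c,
            jac=True,
            method="L-BFGS-B",
            callback=cb,
            options={"maxiter": int(iters), "ftol": 1e-10, "gtol": 1e-9},
        )
        c = res.x
        by_level.append([E0] + hist)
        converged = bool(res.success)
    d.coeffs = c.reshape(shape)
    flat = [e for lvl in by_level for e in lvl]
    return RegistrationResult(d, flat, converged, by_level)


def apply_deformation(
    d: DCTDeformation,
    vol: ImageVolume,
    like: ImageVolume | None = None,
    kind: str = "intensity",
    binarize: bool = False,
) -> ImageVolume:
    """Resample ``vol`` through x -> x + u(x) onto the grid of ``like``
    (default: the deformation's own grid)."""
    if like is None:
        like = ImageVolume(
            np.zeros(d.grid_shape, dtype=np.float32), d.grid_affine.copy()
        )
    coords = _axis_coords(like.shape, like.affine)
    u = d.displacement_on_axes(coords).reshape(3, -1)
    pts = np.stack(np.meshgrid(*coords, indexing="ij"), axis=0).reshape(3, -1)
    src = pts + u
    R, t = _world_to_vox(vol.affine)
    vox = R @ src + t[:, None]
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float), vox, order=1, mode="constant", cval=0.0
    ).reshape(like.shape)
    if kind == "mask":
        out = np.clip(out, 0.0, 1.0)
        if binarize:
            out = (out > 0.5).astype(float)
    return ImageVolume(out.astype(np.float32), like.affine.copy(), vol.description)


def invert_deformation(
    d: DCTDeformation,
    stride: int = 2,
    max_iter: int = 30,
    tol_mm: float = 1e-3,
) -> DCTDeformation:
    """Numerically invert x -> x + u(x) and re-project onto the same basis.

    Fixed-point iteration v <- -u(x + v) on a (optionally subsampled) grid,
    then a per-axis least-squares fit of v back onto the cosine basis.
    Raises :class:`InversionError` if the field folds (nonpositive Jacobian
    of the forward map on the grid).
    """
    coords = _axis_coords(d.grid_shape, d.grid_affine)
    sub = [c[::stride] for c in coords]
    _check_jacobian(d, sub)
    pts = np.stack(np.meshgrid(*sub, indexing="ij"), axis=0).reshape(3, -1)
    v = np.zeros_like(pts)
    for _ in range(max_iter):
        u_at = d.displacement_at_points(pts + v)
        v_new = -u_at
        delta = np.max(np.abs(v_new - v))
        v = v_new
        if delta < tol_mm:
            break
    shape_sub = tuple(len(c) for c in sub)
    Bs = [
        _basis_matrix(sub[a], d.domain_lo[a], d.domain_len[a], d.coeffs.shape[1 + a])
        for a in range(3)
    ]
    # least-squares projection: per-axis Gram systems (basis is only
    # near-orthogonal on a subsampled grid)
    grams = [np.linalg.inv(B.T @ B) for B in Bs]
    C = _project(v.reshape((3,) + shape_sub), *Bs)
    C = np.einsum("xabc,ad->xdbc", C, grams[0])
    C = np.einsum("xabc,bd->xadc", C, grams[1])
    C = np.einsum("xabc,cd->xabd", C, grams[2])
    return DCTDeformation(
        C, d.domain_lo.copy(), d.domain_len.copy(), d.grid_shape, d.grid_affine.copy(),
        d.regularization,
    )


def _check_jacobian(d: DCTDeformation, sub_coords) -> None:
    u = d.displacement_on_axes(sub_coords)
    spac = [c[1] - c[0] if len(c) > 1 else 1.0 for c in sub_coords]
    J = np.zeros(u.shape[1:])
    # det(I + grad u) via finite differences on the sampled field
    g = np.empty((3, 3) + u.shape[1:])
    for a in range(3):
        grads = np.gradient(u[a], *spac)
        for b in range(3):
            g[a, b] = grads[b]
    for i in range(3):
        g[i, i] += 1.0
    J = (
        g[0, 0] * (g[1, 1] * g[2, 2] - g[1, 2] * g[2, 1])
        - g[0, 1] * (g[1, 0] * g[2, 2] - g[1, 2] * g[2, 0])
        + g[0, 2] * (g[1, 0] * g[2, 1] - g[1, 1] * g[2, 0])
    )
    if np.min(J) <= 0.05:
        raise InversionError(
            f"deformation folds (min Jacobian {np.min(J):.3f}); cannot invert"
        )


def average_deformation(fields: Sequence[DCTDeformation]) -> DCTDeformation:
    """Coefficient-wise arithmetic mean of deformations sharing one basis:
    the spatially unbiased group transform T-bar = (1/2N) sum T_i."""
    fields = list(fields)
    if not fields:
        raise ValueError("average_deformation: empty list")
    first = fields[0]
    for f in fields[1:]:
        if not first.same_basis(f):
            raise ValueError("all deformations must share grid and basis order")
    if all(np.array_equal(f.coeffs, first.coeffs) for f in fields[1:]):
        C = first.coeffs.copy()  # mean of identical fields, without rounding
    else:
        C = np.mean([f.coeffs for f in fields], axis=0)
    return DCTDeformation(
        C,
        first.domain_lo.copy(),
        first.domain_len.copy(),
        first.grid_shape,
        first.grid_affine.copy(),
        first.regularization,
    )


def mirror_conjugate(d: DCTDeformation) -> DCTDeformation:
    """The sagittal mirror conjugate F d F of a deformation (F = flip about
    x = 0): exact coefficient sign flips, with the x displacement component
    additionally negated.

    Requires the basis domain to be symmetric about x = 0.
    """
    if abs(d.domain_lo[0] + (d.domain_lo[0] + d.domain_len[0])) > 1e-6:
        raise ValueError("mirror_conjugate requires an x domain symmetric about 0")
    kx = d.coeffs.shape[1]
    signs = (-1.0) ** np.arange(kx)
    C = d.coeffs * signs[None, :, None, None]
    C[0] = -C[0]
    return DCTDeformation(
        C, d.domain_lo.copy(), d.domain_len.copy(), d.grid_shape, d.grid_affine.copy(),
        d.regularization,
    )
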