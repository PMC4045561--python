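"""Volume container, NIfTI I/O, reslicing, AC-PC reorientation and
sagittal flipping.

The central convention of the whole package is the *grid-exact flip*: every
grid produced here is axis-aligned in RAS world coordinates with the
x voxel-center coordinates symmetric about the x = 0 midsagittal plane
(an odd count centered on 0, or an even count straddling it).  On such a
grid a left-right mirror image is a pure index reversal along the first
axis — no interpolation — which is what ultimately allows the symmetrized
atlas to equal its own mirror bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

from .errors import FormatError, GridError

__all__ = [
    "ImageVolume",
    "Landmarks",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "reslice_isotropic",
    "acpc_transform",
    "reorient_acpc",
    "flip_sagittal",
    "is_flip_exact",
    "make_symmetric_grid",
    "sample_at_world",
    "world_axis_coords",
]


@dataclass
class ImageVolume:
    """A 3D scalar grid with a world-coordinate mapping.

    Parameters
    ----------
    data
        3D array of intensities (arbitrary units) or mask/probability values.
    affine
        4x4 homogeneous ``world_from_voxel`` matrix, RAS-oriented, in mm,
        mapping 0-based voxel indices (voxel centers) to world coordinates.
    description
        Free-text provenance.
    """

    data: np.ndarray
    affine: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if not np.all(np.isfinite(self.affine)):
            raise ValueError("affine contains non-finite values")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel sizes must be strictly positive")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis (column norms of the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, description: str | None = None) -> "ImageVolume":
        """New volume on the same grid with different data."""
        return ImageVolume(
            data,
            self.affine.copy(),
            self.description if description is None else description,
        )

    def same_grid(self, other: "ImageVolume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def is_axis_aligned(self, atol: float = 1e-9) -> bool:
        """True if the rotation part of the affine is diagonal (RAS grid)."""
        off = self.affine[:3, :3] - np.diag(np.diag(self.affine[:3, :3]))
        return bool(np.all(np.abs(off) < atol) and np.all(np.diag(self.affine[:3, :3]) > 0))


@dataclass
class Landmarks:
    """AC, PC and an interhemispheric-fissure point, world mm coordinates."""

    AC: np.ndarray
    PC: np.ndarray
    IH: np.ndarray

    def __post_init__(self) -> None:
        self.AC = np.asarray(self.AC, dtype=float).reshape(3)
        self.PC = np.asarray(self.PC, dtype=float).reshape(3)
        self.IH = np.asarray(self.IH, dtype=float).reshape(3)
        if np.linalg.norm(self.AC - self.PC) < 1e-9:
            raise ValueError("AC and PC coincide")
        # IH must not be collinear with the AC-PC line
        y = self.PC - self.AC
        v = self.IH - self.AC
        cross = np.cross(y, v)
        if np.linalg.norm(cross) < 1e-9 * max(np.linalg.norm(y), 1.0):
            raise ValueError("IH is collinear with the AC-PC line")


# ---------------------------------------------------------------------------
# I/O


def read_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI-1 volume, reorienting axes to RAS."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        img = nib.as_closest_canonical(img)
        data = np.asarray(img.dataobj, dtype=np.float32)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return ImageVolume(data, np.asarray(img.affine), description=str(path))


def write_volume(vol: ImageVolume, path: str | Path, dtype=np.float32) -> None:
    """Write a volume as NIfTI-1; float output is unscaled (bit-exact)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), vol.affine)
    img.header.set_slope_inter(1.0, 0.0)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise OSError(f"cannot write NIfTI volume {path}: {exc}") from exc


def read_landmarks(path: str | Path) -> Landmarks:
    """Read AC/PC/IH landmarks from a JSON file of world-mm triplets."""
    with open(path) as fh:
        obj = json.load(fh)
    try:
        return Landmarks(obj["AC"], obj["PC"], obj["IH"])
    except KeyError as exc:
        raise FormatError(f"landmark file {path} missing key {exc}") from exc


def write_landmarks(lm: Landmarks, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"AC": lm.AC.tolist(), "PC": lm.PC.tolist(), "IH": lm.IH.tolist()}, fh, indent=1)


# ---------------------------------------------------------------------------
# Grid construction and sampling


def make_symmetric_grid(
    extent_mm: tuple[float, float, float],
    voxel_mm: float | tuple[float, float, float],
    center_yz: tuple[float, float] = (0.0, 0.0),
) -> tuple[tuple[int, int, int], np.ndarray]:
    """Build an axis-aligned grid whose x voxel centers are symmetric
    about x = 0 (odd count, one column exactly on the midplane).

    ``extent_mm`` gives half-extent in x and full extents in y, z.
    Returns (shape, affine).
    """
    vs = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (3,)).copy()
    if np.any(vs <= 0):
        raise ValueError("voxel size must be positive")
    hx, ey, ez = extent_mm
    nx = 2 * int(np.ceil(hx / vs[0])) + 1
    ny = int(np.ceil(ey / vs[1])) + 1
    nz = int(np.ceil(ez / vs[2])) + 1
    x0 = -(nx - 1) / 2.0 * vs[0]
    y0 = center_yz[0] - (ny - 1) / 2.0 * vs[1]
    z0 = center_yz[1] - (nz - 1) / 2.0 * vs[2]
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vs
    affine[:3, 3] = (x0, y0, z0)
    return (nx, ny, nz), affine


def world_axis_coords(vol: ImageVolume) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World coordinates of voxel centers along each axis.

    Requires an axis-aligned grid.
    """
    if not vol.is_axis_aligned(atol=1e-6):
        raise GridError("grid is not axis-aligned; reslice first")
    out = []
    for a in range(3):
        n = vol.shape[a]
        out.append(vol.affine[a, 3] + np.arange(n) * vol.affine[a, a])
    return tuple(out)  # type: ignore[return-value]


def sample_at_world(
    vol: ImageVolume, pts: np.ndarray, order: int = 1, cval: float = 0.0
) -> np.ndarray:
    """Sample a volume at world-mm points (3, ...) with trilinear (order=1)
    interpolation; out-of-field values are ``cval`` (air = 0 by default)."""
    pts = np.asarray(pts, dtype=float)
    inv = np.linalg.inv(vol.affine)
    flat = pts.reshape(3, -1)
    vox = inv[:3, :3] @ flat + inv[:3, 3:4]
    vals = map_coordinates(
        np.asarray(vol.data, dtype=np.float64), vox, order=order, mode="constant", cval=cval
    )
    return vals.reshape(pts.shape[1:])


def _grid_world_points(shape, affine) -> np.ndarray:
    """World coordinates (3, nx, ny, nz) of every voxel center."""
    idx = np.indices(shape, dtype=float)
    flat = idx.reshape(3, -1)
    wld = affine[:3, :3] @ flat + affine[:3, 3:4]
    return wld.reshape((3,) + tuple(shape))


# ---------------------------------------------------------------------------
# Operations


def reslice_isotropic(vol: ImageVolume, target_mm: float = 0.5) -> ImageVolume:
    """Reslice to cubic voxels of ``target_mm`` on a flip-exact grid.

    The output grid is axis-aligned with x centers symmetric about x = 0 and
    covers at least the input field of view (symmetrization may extend the
    x range; out-of-field samples are 0).
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    if not vol.is_axis_aligned(atol=1e-6):
        raise GridError("reslice_isotropic requires an axis-aligned input grid")
    xs, ys, zs = world_axis_coords(vol)
    hx = max(abs(xs[0]), abs(xs[-1]))
    shape, affine = make_symmetric_grid(
        (hx, ys[-1] - ys[0], zs[-1] - zs[0]),
        target_mm,
        center_yz=((ys[0] + ys[-1]) / 2.0, (zs[0] + zs[-1]) / 2.0),
    )
    pts = _grid_world_points(shape, affine)
    data = sample_at_world(vol, pts, order=1)
    return ImageVolume(data.astype(np.float32), affine, vol.description)


def acpc_transform(lm: Landmarks) -> np.ndarray:
    """Rigid 4x4 mapping from the AC-PC-aligned frame to the original
    world frame.

    In the aligned frame AC is the origin, the +y axis points from PC toward
    AC (anterior), the z axis lies in the AC-IH plane (superior), and
    x = y cross z (right), giving a right-handed RAS frame.
    """
    yhat = lm.AC - lm.PC
    yhat = yhat / np.linalg.norm(yhat)
    v = lm.IH - lm.AC
    z = v - (v @ yhat) * yhat
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise ValueError("IH is collinear with the AC-PC line")
    zhat = z / nz
    xhat = np.cross(yhat, zhat)
    T = np.eye(4)
    T[:3, 0], T[:3, 1], T[:3, 2] = xhat, yhat, zhat
    T[:3, 3] = lm.AC
    return T


def reorient_acpc(
    vol: ImageVolume, lm: Landmarks, margin_mm: float = 2.0
) -> ImageVolume:
    """Rigidly reorient a head volume to the AC-PC frame.

    After reorientation AC maps to the world origin, PC lies on the y axis,
    and IH lies in the x = 0 (midsagittal) plane.  The volume is resampled
    trilinearly onto a flip-exact grid at the input voxel size.
    """
    T = acpc_transform(lm)  # aligned -> original world
    if not vol.is_axis_aligned(atol=1e-6):
        raise GridError("reorient_acpc requires an axis-aligned input grid")
    xs, ys, zs = world_axis_coords(vol)
    # bounding box of the input FOV expressed in the aligned frame
    corners = np.array(
        [[x, y, z] for x in (xs[0], xs[-1]) for y in (ys[0], ys[-1]) for z in (zs[0], zs[-1])]
    )
    Tinv = np.linalg.inv(T)
    aligned = (Tinv[:3, :3] @ corners.T + Tinv[:3, 3:4]).T
    lo = aligned.min(axis=0) - margin_mm
    hi = aligned.max(axis=0) + margin_mm
    vs = vol.voxel_size
    hx = max(abs(lo[0]), abs(hi[0]))
    shape, affine = make_symmetric_grid(
        (hx, hi[1] - lo[1], hi[2] - lo[2]),
        tuple(vs),
        center_yz=((lo[1] + hi[1]) / 2.0, (lo[2] + hi[2]) / 2.0),
    )
    pts = _grid_world_points(shape, affine)
    flat = pts.reshape(3, -1)
    src = T[:3, :3] @ flat + T[:3, 3:4]
    data = sample_at_world(vol, src.reshape(pts.shape), order=1)
    return ImageVolume(data.astype(np.float32), affine, vol.description)


def is_flip_exact(vol: ImageVolume, atol: float = 1e-6) -> bool:
    """True if the grid supports an interpolation-free sagittal flip:
    axis-aligned and x voxel centers symmetric about x = 0."""
    if not vol.is_axis_aligned(atol=1e-6):
        return False
    xs = vol.affine[0, 3] + np.arange(vol.shape[0]) * vol.affine[0, 0]
    return bool(abs(xs[0] + xs[-1]) < atol)


def flip_sagittal(vol: ImageVolume) -> ImageVolume:
    """Mirror a volume across the midsagittal plane x = 0.

    Pure index reversal along x — no interpolation — so the operation is an
    exact involution.  Requires a flip-exact grid.
    """
    if not is_flip_exact(vol):
        raise GridError(
            "grid is not symmetric about x=0; reslice onto a symmetric grid "
            "(reslice_isotropic) before flipping"
        )
    return ImageVolume(vol.data[::-1, :, :].copy(), vol.affine.copy(), vol.description)
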