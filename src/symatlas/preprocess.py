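"""Bias-field reduction, simple tissue segmentation and intracranial mask.

Segmentation here is deliberately plain — background split by Otsu, a
three-class 1D intensity clustering inside the head, morphological cleanup
— because the atlas framework, not the segmenter, is the point; externally
produced brain/CSF masks are accepted everywhere downstream.

The bias model is the standard one: a smooth multiplicative field,
estimated as a Gaussian low-pass of log-intensity within a mask
(normalized convolution, so the estimate extends smoothly outside the
mask) and divided out, preserving the mean intensity within the mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core_image import ImageVolume, flip_sagittal
from .errors import SegmentationError

__all__ = ["TissueMasks", "bias_correct", "segment_tissues", "make_ic_mask"]


@dataclass
class TissueMasks:
    """Binary brain (B), CSF (C) and intracranial (IC = B or C) masks,
    all on the grid of the source image."""

    brain: ImageVolume
    csf: ImageVolume
    ic: ImageVolume

    def validate(self) -> None:
        if not (self.brain.same_grid(self.csf) and self.brain.same_grid(self.ic)):
            raise ValueError("tissue masks must share one grid")
        b = self.brain.data > 0.5
        c = self.csf.data > 0.5
        if np.any(b & c):
            raise ValueError("brain and CSF masks overlap")
        if np.any((self.ic.data > 0.5) != (b | c)):
            raise ValueError("IC mask is not the union of brain and CSF")

    def flipped(self) -> "TissueMasks":
        return TissueMasks(
            brain=flip_sagittal(self.brain),
            csf=flip_sagittal(self.csf),
            ic=flip_sagittal(self.ic),
        )


def bias_correct(
    vol: ImageVolume,
    mask: ImageVolume,
    fwhm_mm: float = 40.0,
    n_iter: int = 3,
    band: float = 0.25,
    max_samples: int = 30000,
    smoothness: float = 1e-3,
    edge_thr: float = 0.05,
) -> ImageVolume:
    """Divide out a smooth multiplicative intensity nonuniformity.

    The log-bias is modeled on a low-order separable 3D cosine basis (order
    per axis chosen so the finest basis scale matches ``fwhm_mm``) and fit
    by bending-energy-regularized least squares to the log-intensities of
    the voxels of ``mask`` that (a) lie within ``band`` log-units of the
    in-mask median — restricting the fit to the modal tissue class keeps
    anatomical contrast (CSF vs brain) out of the field estimate — and (b)
    have local log-intensity standard deviation below ``edge_thr``, which
    drops partial-volume voxels at tissue boundaries.  A few fit/divide
    iterations refine the selection.  The fitted field extends smoothly
    over the whole volume by basis evaluation; the output is rescaled so
    the mask mean is preserved.
    """
    from .registration import _basis_matrix

    m = np.asarray(mask.data, dtype=float) > 0.5
    if not m.any():
        raise ValueError("bias_correct: mask is empty")
    data = np.asarray(vol.data, dtype=float)
    if np.any(data[m] <= 0):
        raise ValueError("bias_correct: nonpositive intensities inside mask")
    vs = vol.voxel_size
    shape = vol.shape
    lo = vol.affine[:3, 3] - vs / 2.0
    ln = np.asarray(shape) * vs
    order = np.clip(np.ceil(2.0 * ln / fwhm_mm).astype(int) + 3, 4, 8)
    axes = [vol.affine[a, 3] + np.arange(shape[a]) * vol.affine[a, a] for a in range(3)]
    Bax = [_basis_matrix(axes[a], lo[a], ln[a], order[a]) for a in range(3)]
    w2 = [(np.pi * np.arange(order[a]) / ln[a]) ** 2 for a in range(3)]
    om2 = w2[0][:, None, None] + w2[1][None, :, None] + w2[2][None, None, :]
    pen = (om2**2).reshape(-1)
    if (pen > 0).any():
        pen = pen / pen[pen > 0].mean()
    idx_all = np.indices(shape).reshape(3, -1)
    work = data.copy()
    total_log = np.zeros_like(data)
    for _ in range(n_iter):
        wl = np.where(work > 0, np.log(np.maximum(work, 1e-12)), 0.0)
        mu = ndimage.uniform_filter(wl, size=3)
        mu2 = ndimage.uniform_filter(wl * wl, size=3)
        lstd = np.sqrt(np.maximum(mu2 - mu * mu, 0.0))
        med = np.median(wl[m])
        sel = np.zeros_like(data, dtype=bool)
        sel[m] = np.abs(wl[m] - med) < band
        sel &= lstd < edge_thr
        nsel = int(sel.sum())
        if nsel < 64:
            break
        flat = np.flatnonzero(sel.reshape(-1))
        flat = flat[:: max(1, nsel // max_samples)]
        iv = idx_all[:, flat]
        rows = [Bax[a][iv[a]] for a in range(3)]
        design = np.einsum("pl,pm,pn->plmn", rows[0], rows[1], rows[2]).reshape(
            len(flat), -1
        )
        y = wl.reshape(-1)[flat]
        AtA = design.T @ design
        AtA[np.diag_indices_from(AtA)] += (
            smoothness * len(flat) * pen + 1e-9 * np.trace(AtA) / AtA.shape[0]
        )
        coef = np.linalg.solve(AtA, design.T @ y)
        C = coef.reshape(tuple(order))
        # separable evaluation of the fitted log field on the full grid
        t = np.tensordot(C, Bax[2], axes=([2], [1]))  # (kx,ky,nz)
        t = np.tensordot(t, Bax[1], axes=([1], [1]))  # (kx,nz,ny)
        fld = np.transpose(np.tensordot(t, Bax[0], axes=([0], [1])), (2, 1, 0))
        fld = fld - fld[m].mean()
        work = work / np.exp(fld)
        total_log += fld
    out = data / np.exp(total_log)
    out *= data[m].mean() / out[m].mean()
    return vol.with_data(out.astype(np.float32), vol.description + " [bias corrected]")


def _kmeans_1d(values: np.ndarray, k: int = 3, iters: int = 50) -> np.ndarray:
    """Deterministic 1D Lloyd clustering, initialized from multi-Otsu
    thresholds (robust to very unequal class sizes, e.g. the thin CSF shell
    against large brain/scalp classes).

    Scale-equivariant, so segmentation is invariant to a global intensity
    gain.  Returns sorted class centers.
    """
    from skimage.filters import threshold_multiotsu

    try:
        thr = threshold_multiotsu(values, classes=k)
        parts = np.split(np.sort(values), np.searchsorted(np.sort(values), thr))
        centers = np.array([p.mean() if p.size else np.nan for p in parts])
    except ValueError:
        centers = np.full(k, np.nan)
    if np.any(~np.isfinite(centers)) or np.any(np.diff(centers) <= 0):
        lo, hi = values.min(), values.max()
        centers = np.linspace(lo, hi, k + 2)[1:-1]
    for _ in range(iters):
        edges = (centers[:-1] + centers[1:]) / 2.0
        labels = np.searchsorted(edges, values)
        new = centers.copy()
        for j in range(k):
            sel = labels == j
            if sel.any():
                new[j] = values[sel].mean()
        if np.allclose(new, centers, rtol=1e-10, atol=0.0):
            centers = new
            break
        centers = new
    return np.sort(centers)


def segment_tissues(
    vol: ImageVolume, csf_bright: bool = False, min_component_voxels: int = 8
) -> TissueMasks:
    """Three-class intensity segmentation of a head volume into brain / CSF.

    Steps: Otsu split of background vs head, largest connected above-background
    component as head region, 1D k-means (k=3) inside the head, class
    assignment by mean intensity (with T1 newborn contrast, CSF is the lowest
    non-background class and brain the highest; ``csf_bright=True`` swaps
    them for T2-like contrast), then morphological cleanup: largest brain
    component with hole filling, CSF restricted to components adjacent to
    the brain.
    """
    data = np.asarray(vol.data, dtype=float)
    finite_range = data.max() - data.min()
    if finite_range <= 0:
        raise SegmentationError("constant image: no intensity classes")
    try:
        thr = threshold_otsu(data)
    except ValueError as exc:
        raise SegmentationError(f"Otsu thresholding failed: {exc}") from exc
    above = data > thr
    if not above.any():
        raise SegmentationError("no voxels above background threshold")
    filled = ndimage.binary_fill_holes(above)
    lab, nlab = ndimage.label(filled)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, nlab + 1))
    head = lab == (1 + int(np.argmax(sizes)))
    vals = data[head]
    centers = _kmeans_1d(vals, k=3)
    if centers[-1] - centers[0] < 1e-6 * max(abs(centers[-1]), 1.0):
        raise SegmentationError("fewer than 3 distinguishable intensity classes")
    edges = (centers[:-1] + centers[1:]) / 2.0
    labels = np.zeros(data.shape, dtype=np.int8)
    labels[head] = np.searchsorted(edges, vals) + 1  # 1..3 in ascending intensity
    csf_class, brain_class = (3, 1) if csf_bright else (1, 3)
    brain = labels == brain_class
    # keep the largest brain component, fill internal holes
    lab_b, nb = ndimage.label(brain)
    if nb == 0:
        raise SegmentationError("no brain-class voxels found")
    sizes_b = ndimage.sum_labels(np.ones_like(lab_b), lab_b, index=np.arange(1, nb + 1))
    brain = lab_b == (1 + int(np.argmax(sizes_b)))
    brain = ndimage.binary_fill_holes(brain)
    csf = (labels == csf_class) & ~brain
    # CSF must be adjacent to brain; drops partial-volume rims at the scalp edge
    lab_c, nc = ndimage.label(csf)
    if nc:
        near_brain = ndimage.binary_dilation(brain, iterations=2)
        keep = np.unique(lab_c[near_brain & (lab_c > 0)])
        csf = np.isin(lab_c, keep[keep > 0])
    small = ndimage.binary_opening(csf)
    if small.sum() >= min_component_voxels:
        csf = small
    csf &= ~brain
    ic = brain | csf
    masks = TissueMasks(
        brain=vol.with_data(brain.astype(np.float32), "brain mask"),
        csf=vol.with_data(csf.astype(np.float32), "csf mask"),
        ic=vol.with_data(ic.astype(np.float32), "ic mask"),
    )
    masks.validate()
    return masks


def make_ic_mask(masks: TissueMasks, smooth_mm: float = 1.0) -> tuple[ImageVolume, ImageVolume]:
    """Union of brain and CSF as intracranial mask.

    Returns ``(ic, ic_smooth)``: the binary union and a Gaussian-smoothed
    (sigma ``smooth_mm``) version suitable as a registration weighting mask.
    """
    b = np.asarray(masks.brain.data) > 0.5
    c = np.asarray(masks.csf.data) > 0.5
    union = (b | c).astype(np.float32)
    if not union.any():
        raise ValueError("make_ic_mask: empty brain+CSF union")
    if smooth_mm > 0:
        sigma = smooth_mm / masks.brain.voxel_size
        sm = ndimage.gaussian_filter(union.astype(float), sigma=sigma, mode="constant")
    else:
        sm = union.astype(float)
    return (
        masks.brain.with_data(union, "ic mask"),
        masks.brain.with_data(sm.astype(np.float32), "ic weight (smoothed)"),
    )
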