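"""Two-pass symmetric atlas construction.

The pipeline mirrors the classic unbiased-template recipe for building a
left-right symmetric average of a cohort: the N preprocessed heads are
augmented with their sagittal mirror images (2N inputs), every input is
affinely and then nonlinearly normalized to a reference with an
intracranial weighting mask, the average reference-to-subject deformation
T-bar is applied to all normalized images to remove the geometric bias of
the reference choice, and the 2N results are averaged into an intensity
template plus probabilistic brain and CSF models.  A second pass repeats
the procedure with the first-pass template as reference, and the final
atlas is the average of the second-pass atlas and its mirror image — an
operation that is interpolation-free on the flip-exact grid, so the result
equals its own mirror bit for bit.

The asymmetric control atlas runs the identical pipeline on the N
originals only, without mirror augmentation or final flip-averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_image import ImageVolume, flip_sagittal, is_flip_exact
from .errors import RegistrationError
from .preprocess import TissueMasks, make_ic_mask
from .registration import (
    AffineParams,
    DCTDeformation,
    affine_register,
    apply_affine,
    apply_deformation,
    average_deformation,
    invert_deformation,
    nonlinear_register,
)

log = logging.getLogger(__name__)

__all__ = [
    "SubjectRecord",
    "Atlas",
    "AtlasConfig",
    "augment_with_flips",
    "select_reference",
    "run_pass",
    "build_symmetric_atlas",
    "build_asymmetric_atlas",
]


@dataclass
class SubjectRecord:
    """One (possibly mirrored) input: image I_i with masks B_i, C_i, IC_i."""

    image: ImageVolume
    masks: TissueMasks
    flipped: bool = False
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def flip(self) -> "SubjectRecord":
        return SubjectRecord(
            image=flip_sagittal(self.image),
            masks=self.masks.flipped(),
            flipped=not self.flipped,
            subject_id=self.subject_id,
            meta=dict(self.meta),
        )


@dataclass
class Atlas:
    """Intensity template plus probabilistic brain and CSF models."""

    template: ImageVolume
    brain_prob: ImageVolume
    csf_prob: ImageVolume
    pass_index: object = "final"  # 1 | 2 | ... | "final"
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        for v in (self.brain_prob, self.csf_prob):
            if not self.template.same_grid(v):
                raise ValueError("atlas volumes must share one grid")
            if v.data.min() < -1e-6 or v.data.max() > 1.0 + 1e-6:
                raise ValueError("probability map out of [0, 1]")
        if np.any(self.brain_prob.data + self.csf_prob.data > 1.0 + 1e-6):
            raise ValueError("brain_prob + csf_prob exceeds 1")

    def flipped(self) -> "Atlas":
        return Atlas(
            template=flip_sagittal(self.template),
            brain_prob=flip_sagittal(self.brain_prob),
            csf_prob=flip_sagittal(self.csf_prob),
            pass_index=self.pass_index,
            provenance=dict(self.provenance),
        )


@dataclass
class AtlasConfig:
    """Registration and averaging settings for atlas construction."""

    affine_levels_mm: tuple = (4.0, 2.0)
    affine_max_iter: tuple = (40, 15)
    nonlinear_levels_mm: tuple = (4.0, 2.0)
    nonlinear_max_iter: tuple = (60, 30)
    basis_order: int = 8
    regularization: float = 0.01
    ic_smooth_mm: float = 1.0
    pass2_support_threshold: float = 0.5
    binarize_masks: bool = False  # False: average continuous warped masks
    invert_stride: int = 2
    passes: int = 2


def augment_with_flips(subjects: Sequence[SubjectRecord]) -> list:
    """Return the 2N records: originals followed by their exact mirrors."""
    subjects = list(subjects)
    if not subjects:
        raise ValueError("augment_with_flips: empty cohort")
    return subjects + [s.flip() for s in subjects]


def select_reference(
    subjects: Sequence[SubjectRecord],
    subject_id: str | None = None,
    cfg: AtlasConfig | None = None,
) -> SubjectRecord:
    """Choose the reference subject I_R.

    With ``subject_id`` the choice is explicit (the subject with minimal
    head deformation, as judged by the operator).  Otherwise an automatic
    fallback picks the subject with the smallest mean affine distance
    (sum |log scale| + sum |shear| of the pairwise affine registrations) to
    all others; ties break on lowest subject_id.
    """
    subjects = list(subjects)
    if not subjects:
        raise ValueError("select_reference: empty cohort")
    if subject_id is not None:
        for s in subjects:
            if s.subject_id == subject_id:
                return s
        raise ValueError(f"no subject with id {subject_id!r}")
    if len(subjects) == 1:
        return subjects[0]
    cfg = cfg or AtlasConfig()
    n = len(subjects)
    dist = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            ref = subjects[b]
            _, w = make_ic_mask(ref.masks, smooth_mm=cfg.ic_smooth_mm)
            res = affine_register(
                subjects[a].image,
                ref.image,
                w,
                levels_mm=cfg.affine_levels_mm[:1],
                max_iter=cfg.affine_max_iter[:1],
            )
            p: AffineParams = res.transform
            dist[a, b] = float(np.abs(np.log(p.scale)).sum() + np.abs(p.shear).sum())
    mean_dist = dist.sum(axis=1) / (n - 1)
    # deterministic tie-break on subject_id
    best = min(range(n), key=lambda i: (round(mean_dist[i], 12), subjects[i].subject_id))
    return subjects[best]


def _normalize_record(
    rec: SubjectRecord,
    reference: ImageVolume,
    weight: ImageVolume,
    cfg: AtlasConfig,
):
    """Affine + nonlinear normalization of one record onto the reference
    grid; returns (warped volumes dict, D_i, T_i, log info)."""
    kind = "mask"
    try:
        ares = affine_register(
            rec.image, reference, weight,
            levels_mm=cfg.affine_levels_mm, max_iter=cfg.affine_max_iter,
        )
        aff: AffineParams = ares.transform
        img1 = apply_affine(aff, rec.image, like=reference)
        brain1 = apply_affine(aff, rec.masks.brain, like=reference, kind=kind,
                              binarize=cfg.binarize_masks)
        csf1 = apply_affine(aff, rec.masks.csf, like=reference, kind=kind,
                            binarize=cfg.binarize_masks)
        ic1 = apply_affine(aff, rec.masks.ic, like=reference, kind=kind,
                           binarize=cfg.binarize_masks)
        nres = nonlinear_register(
            img1, reference, weight,
            k=cfg.basis_order, regularization=cfg.regularization,
            levels_mm=cfg.nonlinear_levels_mm, max_iter=cfg.nonlinear_max_iter,
        )
        D: DCTDeformation = nres.transform
        img2 = apply_deformation(D, img1, like=reference)
        brain2 = apply_deformation(D, brain1, like=reference, kind=kind)
        csf2 = apply_deformation(D, csf1, like=reference, kind=kind)
        ic2 = apply_deformation(D, ic1, like=reference, kind=kind)
        T = invert_deformation(D, stride=cfg.invert_stride)
    except (RegistrationError, ValueError) as exc:
        raise RegistrationError(
            f"normalization failed for subject "
            f"{rec.subject_id}{' (flipped)' if rec.flipped else ''}: {exc}"
        ) from exc
    info = {
        "subject_id": rec.subject_id,
        "flipped": rec.flipped,
        "affine": aff.to_dict(),
        "affine_objective": ares.objective_trace[-1] if ares.objective_trace else None,
        "affine_trace_by_level": ares.trace_by_level,
        "nonlinear_objective": nres.objective_trace[-1] if nres.objective_trace else None,
        "nonlinear_trace_by_level": nres.trace_by_level,
    }
    return {"image": img2, "brain": brain2, "csf": csf2, "ic": ic2}, D, T, info


def run_pass(
    records: Sequence[SubjectRecord],
    reference: ImageVolume,
    ref_ic_weight: ImageVolume,
    cfg: AtlasConfig | None = None,
    pass_index: int = 1,
) -> Atlas:
    """One normalization pass over the (flip-augmented) records.

    Each record is affinely then nonlinearly normalized to the reference;
    the average of the inverted deformations T-bar is applied to every
    normalized image and mask; the arithmetic means over all records form
    the template and the probabilistic brain / CSF models.  Subjects are
    processed in a canonical (subject_id, flipped) order so the result is
    independent of input ordering, bit for bit.
    """
    cfg = cfg or AtlasConfig()
    records = sorted(records, key=lambda r: (r.subject_id, r.flipped))
    if not records:
        raise ValueError("run_pass: no records")
    if not is_flip_exact(reference):
        raise ValueError("reference grid must be symmetric about x=0")
    warped = []
    inverses = []
    infos = []
    for rec in records:
        vols, D, T, info = _normalize_record(rec, reference, ref_ic_weight, cfg)
        warped.append(vols)
        inverses.append(T)
        infos.append(info)
        log.info(
            "pass %d: normalized %s%s (affine SSD %.4g, nonlinear SSD %.4g)",
            pass_index, rec.subject_id, " (flipped)" if rec.flipped else "",
            info["affine_objective"], info["nonlinear_objective"],
        )
    tbar = average_deformation(inverses)
    n = len(records)
    sums = {k: np.zeros(reference.shape, dtype=np.float64) for k in ("image", "brain", "csf")}
    for vols in warped:
        for k in sums:
            kind = "intensity" if k == "image" else "mask"
            out = apply_deformation(tbar, vols[k], like=reference, kind=kind)
            sums[k] += out.data
    template = ImageVolume(
        (sums["image"] / n).astype(np.float32), reference.affine.copy(),
        f"pass-{pass_index} template",
    )
    brain_p = ImageVolume(
        np.clip(sums["brain"] / n, 0.0, 1.0).astype(np.float32),
        reference.affine.copy(), f"pass-{pass_index} brain probability",
    )
    csf_p = ImageVolume(
        np.clip(sums["csf"] / n, 0.0, 1.0).astype(np.float32),
        reference.affine.copy(), f"pass-{pass_index} csf probability",
    )
    atlas = Atlas(
        template=template, brain_prob=brain_p, csf_prob=csf_p, pass_index=pass_index,
        provenance={"n_records": n, "subjects": infos, "tbar": tbar.to_dict()},
    )
    atlas.validate()
    return atlas


def _pass2_weight(atlas: Atlas, cfg: AtlasConfig) -> ImageVolume:
    """IC support of a pass atlas: brain+CSF probability thresholded then
    smoothed, used as the weighting mask of the next pass."""
    support = (
        atlas.brain_prob.data + atlas.csf_prob.data > cfg.pass2_support_threshold
    ).astype(np.float32)
    from scipy import ndimage as ndi

    sigma = cfg.ic_smooth_mm / atlas.template.voxel_size
    sm = ndi.gaussian_filter(support.astype(float), sigma=sigma, mode="constant")
    return atlas.template.with_data(sm.astype(np.float32), "pass IC weight")


def _multi_pass(
    records: Sequence[SubjectRecord],
    reference_rec: SubjectRecord,
    cfg: AtlasConfig,
) -> Atlas:
    _, weight = make_ic_mask(reference_rec.masks, smooth_mm=cfg.ic_smooth_mm)
    reference = reference_rec.image
    atlas = None
    history = []
    for p in range(1, cfg.passes + 1):
        new = run_pass(records, reference, weight, cfg, pass_index=p)
        if atlas is not None:
            rms = float(
                np.sqrt(np.mean((new.template.data - atlas.template.data) ** 2))
            )
            history.append(rms)
            log.info("pass %d template RMS change: %.5g", p, rms)
        atlas = new
        reference = atlas.template
        weight = _pass2_weight(atlas, cfg)
    atlas.provenance["template_rms_change"] = history
    return atlas


def build_symmetric_atlas(
    subjects: Sequence[SubjectRecord],
    reference_id: str | None = None,
    cfg: AtlasConfig | None = None,
) -> Atlas:
    """Build the final symmetric atlas from N original subjects.

    Mirror-augments to 2N records, runs the configured number of passes
    (default 2: subject reference, then pass-1 template reference), and
    flip-averages the last pass.  The returned template and probability
    maps are bit-exactly invariant under sagittal flipping.
    """
    cfg = cfg or AtlasConfig()
    subjects = list(subjects)
    if not subjects:
        raise ValueError("build_symmetric_atlas: empty cohort")
    records = augment_with_flips(subjects)
    ref = select_reference(subjects, reference_id, cfg)
    last = _multi_pass(records, ref, cfg)
    half = np.float32(0.5)

    def symmetrize(v: ImageVolume, desc: str) -> ImageVolume:
        f = flip_sagittal(v)
        return ImageVolume(half * (v.data + f.data), v.affine.copy(), desc)

    final = Atlas(
        template=symmetrize(last.template, "symmetric template"),
        brain_prob=symmetrize(last.brain_prob, "symmetric brain probability"),
        csf_prob=symmetrize(last.csf_prob, "symmetric csf probability"),
        pass_index="final",
        provenance={
            "mode": "symmetric",
            "reference_id": ref.subject_id,
            "passes": cfg.passes,
            "last_pass": last.provenance,
        },
    )
    final.validate()
    return final


def build_asymmetric_atlas(
    subjects: Sequence[SubjectRecord],
    reference_id: str | None = None,
    cfg: AtlasConfig | None = None,
) -> Atlas:
    """Control pipeline: identical passes on the N originals only — no
    mirror augmentation and no final flip-averaging."""
    cfg = cfg or AtlasConfig()
    subjects = list(subjects)
    if not subjects:
        raise ValueError("build_asymmetric_atlas: empty cohort")
    ref = select_reference(subjects, reference_id, cfg)
    last = _multi_pass(subjects, ref, cfg)
    last.pass_index = "final"
    last.provenance = {
        "mode": "asymmetric",
        "reference_id": ref.subject_id,
        "passes": cfg.passes,
        "last_pass": dict(last.provenance),
    }
    return last
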