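"""Cohort manifests and the end-to-end pipeline driver.

A manifest is a YAML document describing a cohort::

    seed: 7
    voxel_mm: 0.5
    reference: S01          # optional; automatic selection if omitted
    passes: 2
    registration: {basis_order: 8, regularization: 0.01}
    subjects:
      - id: S01
        image: sub01.nii.gz
        landmarks: sub01_landmarks.json    # optional (skip reorientation)
        brain_mask: sub01_brain.nii.gz     # optional (skip segmentation)
        csf_mask: sub01_csf.nii.gz

Every referenced file must exist at load time; validation happens before
any computation so a typo fails fast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .atlas import (
    Atlas,
    AtlasConfig,
    SubjectRecord,
    build_asymmetric_atlas,
    build_symmetric_atlas,
)
from .core_image import read_landmarks, read_volume, reorient_acpc, reslice_isotropic
from .errors import ManifestError
from .evaluation import asymmetry_index, hemisphere_volume_report
from .preprocess import TissueMasks, bias_correct, segment_tissues

log = logging.getLogger(__name__)

__all__ = ["SubjectEntry", "CohortManifest", "load_manifest", "run_pipeline"]


@dataclass
class SubjectEntry:
    subject_id: str
    image: Path
    landmarks: Path | None = None
    brain_mask: Path | None = None
    csf_mask: Path | None = None


@dataclass
class CohortManifest:
    subjects: list
    voxel_mm: float = 0.5
    reference: str | None = None
    passes: int = 2
    seed: int = 0
    csf_bright: bool = False
    registration: dict = field(default_factory=dict)
    base_dir: Path = Path(".")

    def validate(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if not ids:
            raise ManifestError("manifest lists no subjects")
        if len(set(ids)) != len(ids):
            raise ManifestError("subject ids are not unique")
        if self.voxel_mm <= 0:
            raise ManifestError("voxel_mm must be positive")
        if self.reference is not None and self.reference not in ids:
            raise ManifestError(f"reference {self.reference!r} is not a subject id")
        for s in self.subjects:
            for p in (s.image, s.landmarks, s.brain_mask, s.csf_mask):
                if p is not None and not Path(p).exists():
                    raise ManifestError(f"subject {s.subject_id}: missing file {p}")
            if (s.brain_mask is None) != (s.csf_mask is None):
                raise ManifestError(
                    f"subject {s.subject_id}: brain and CSF masks must be "
                    "supplied together"
                )

    def atlas_config(self) -> AtlasConfig:
        cfg = AtlasConfig(passes=self.passes)
        allowed = {
            "basis_order", "regularization", "affine_levels_mm", "affine_max_iter",
            "nonlinear_levels_mm", "nonlinear_max_iter", "ic_smooth_mm",
            "binarize_masks", "invert_stride",
        }
        for k, v in self.registration.items():
            if k not in allowed:
                raise ManifestError(f"unknown registration setting {k!r}")
            setattr(cfg, k, tuple(v) if isinstance(v, list) else v)
        return cfg


def load_manifest(path: str | Path) -> CohortManifest:
    path = Path(path)
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        raise ManifestError(f"cannot read manifest {path}: {exc}") from exc
    if not isinstance(doc, dict) or "subjects" not in doc:
        raise ManifestError(f"manifest {path} has no 'subjects' list")
    base = path.parent

    def resolve(p):
        return None if p is None else (base / p if not Path(p).is_absolute() else Path(p))

    subjects = []
    for i, s in enumerate(doc["subjects"]):
        if "image" not in s:
            raise ManifestError(f"subject #{i}: no image path")
        subjects.append(
            SubjectEntry(
                subject_id=str(s.get("id", f"S{i + 1:02d}")),
                image=resolve(s["image"]),
                landmarks=resolve(s.get("landmarks")),
                brain_mask=resolve(s.get("brain_mask")),
                csf_mask=resolve(s.get("csf_mask")),
            )
        )
    man = CohortManifest(
        subjects=subjects,
        voxel_mm=float(doc.get("voxel_mm", 0.5)),
        reference=doc.get("reference"),
        passes=int(doc.get("passes", 2)),
        seed=int(doc.get("seed", 0)),
        csf_bright=bool(doc.get("csf_bright", False)),
        registration=doc.get("registration", {}) or {},
        base_dir=base,
    )
    man.validate()
    return man


def _preprocess_subject(entry: SubjectEntry, man: CohortManifest) -> SubjectRecord:
    """reorient -> reslice -> bias-correct -> segment (or load masks)."""
    from .core_image import ImageVolume
    import numpy as np

    vol = read_volume(entry.image)
    lm = None
    if entry.landmarks is not None:
        lm = read_landmarks(entry.landmarks)
        vol = reorient_acpc(vol, lm)
        log.info("%s: reoriented to AC-PC frame", entry.subject_id)
    vol = reslice_isotropic(vol, man.voxel_mm)
    if entry.brain_mask is not None:

        def load_mask(path):
            mk = read_volume(path)
            if lm is not None:
                mk = reorient_acpc(mk, lm)
            return reslice_isotropic(mk, man.voxel_mm)

        brain = load_mask(entry.brain_mask)
        csf = load_mask(entry.csf_mask)
        b = (brain.data > 0.5).astype(np.float32)
        c = ((csf.data > 0.5) & ~(brain.data > 0.5)).astype(np.float32)
        masks = TissueMasks(
            brain=brain.with_data(b), csf=csf.with_data(c),
            ic=brain.with_data(np.maximum(b, c)),
        )
        ic_for_bias = masks.ic
        vol = bias_correct(vol, ic_for_bias)
    else:
        first = segment_tissues(vol, csf_bright=man.csf_bright)
        vol = bias_correct(vol, first.ic)
        masks = segment_tissues(vol, csf_bright=man.csf_bright)
    log.info("%s: preprocessing done", entry.subject_id)
    return SubjectRecord(image=vol, masks=masks, flipped=False, subject_id=entry.subject_id)


def run_pipeline(man: CohortManifest, mode: str = "symmetric"):
    """Execute the full atlas pipeline for a manifest.

    Returns ``(atlas, report, asymmetry)`` where ``report`` is the
    hemispheric volume table (per-subject rows from the input masks plus
    atlas rows from the probability maps) and ``asymmetry`` the template's
    asymmetry-index map.  Deterministic: identical manifests give
    bit-identical results.
    """
    import pandas as pd

    if mode not in ("symmetric", "asymmetric"):
        raise ValueError("mode must be 'symmetric' or 'asymmetric'")
    man.validate()
    subjects = [_preprocess_subject(e, man) for e in man.subjects]
    cfg = man.atlas_config()
    build = build_symmetric_atlas if mode == "symmetric" else build_asymmetric_atlas
    atlas = build(subjects, reference_id=man.reference, cfg=cfg)
    rows = [
        hemisphere_volume_report(
            {"brain": s.masks.brain, "csf": s.masks.csf}, label=s.subject_id
        )
        for s in subjects
    ]
    rows.append(
        hemisphere_volume_report(
            {"brain": atlas.brain_prob, "csf": atlas.csf_prob},
            label=f"{mode} atlas",
        )
    )
    report = pd.concat(rows, ignore_index=True)
    ai = asymmetry_index(atlas.template)
    return atlas, report, ai
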