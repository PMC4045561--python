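# symatlas

Symmetric newborn brain atlas construction from T1-weighted MRI.

Brain atlases made by plain averaging of spatially normalized scans
inherit the left-right asymmetries of the cohort and of the registration
reference.  For studies *of* hemispheric asymmetry — for instance the
lateralization of language-related structures already present around term
age — such an atlas biases the quantity under study.  `symatlas` builds a
template plus probabilistic brain and CSF models that are symmetric **by
construction**: every input head `I_i` enters together with its sagittal
mirror image; all 2N inputs are normalized to a reference with a
mask-weighted 12-parameter affine transform `A_i` followed by a smooth
cosine-basis (DCT) deformation `D_i`; the averaged reference-to-subject
map `T̄ = (1/2N) Σ D_i⁻¹` removes the geometric bias of the reference
choice; averaging gives the pass-1 atlas; a second pass uses that
template as reference; and the final atlas is `½(atlas + mirror(atlas))`.

Because every grid in the package keeps its x voxel centers symmetric
about the midsagittal plane x = 0, mirroring is a pure index reversal —
no interpolation — and the final template equals its own mirror **bit for
bit**: the voxelwise asymmetry index

    AI(x) = 2 · (V(x) − V(−x)) / (V(x) + V(−x))

is identically zero for the symmetric atlas, while the control pipeline
(same steps, no mirroring) leaves clearly nonzero differences.

Intended users: researchers building age-specific (here: term-newborn)
templates for asymmetry studies, and anyone needing a small, fully
deterministic, pure-Python reference implementation of unbiased
symmetric template construction with known-ground-truth synthetic
cohorts for testing.

## Worked example

Build a symmetric and a control atlas from a synthetic four-subject
cohort with a 5% enlarged left hemisphere:

```python
import numpy as np
from symatlas import (PhantomSpec, generate_cohort, AtlasConfig,
                      build_symmetric_atlas, build_asymmetric_atlas,
                      flip_sagittal, asymmetry_index,
                      hemisphere_volume_report)

spec = PhantomSpec(grid_mm=1.0, left_scale=1.05, seed=7)
cohort = generate_cohort(4, spec, seed=7)

sym = build_symmetric_atlas(cohort, reference_id="S01", cfg=AtlasConfig())
print("max |template - mirror|:",
      np.abs(sym.template.data - flip_sagittal(sym.template).data).max())
print("max |AI|:", np.abs(asymmetry_index(sym.template).ai.data).max())

asym = build_asymmetric_atlas(cohort, reference_id="S01", cfg=AtlasConfig())
print("control max |template - mirror|:",
      np.abs(asym.template.data - flip_sagittal(asym.template).data).max())

rep = hemisphere_volume_report({"brain": asym.brain_prob, "csf": asym.csf_prob})
print(rep[["structure", "left_pct", "right_pct", "diff_pct"]])
```

Output (a few minutes on one CPU):

```
max |template - mirror|: 0.0
max |AI|: 0.0
control max |template - mirror|: 69.85411
  structure   left_pct  right_pct  diff_pct
0     brain  53.093862  46.906138  6.187725
1       csf  52.473454  47.526546  4.946909
```

The symmetric atlas is exactly mirror-invariant (both maxima are the
floating-point zero, not a small number), whereas the control atlas
built from the same left-enlarged cohort shows intensity differences up
to 70 (on tissue means of 30–100) and puts ~53% of its brain probability
mass in the left hemisphere.  For the symmetric atlas the same report
reads exactly 50.0 / 50.0 with difference 0.0.

The same run from a shell:

```bash
symatlas phantom --n 4 --seed 7 --left-scale 1.05 --grid-mm 1.0 --out cohort/
symatlas build --manifest cohort/cohort.yaml --reference S01 --symmetric --out atlas/
symatlas evaluate atlas/ --out report/
```

`atlas/` then contains `template.nii.gz`, `brain_prob.nii.gz`,
`csf_prob.nii.gz`, the per-stage build log data in `provenance.json`, and
`report/` the asymmetry-index maps, difference images and the volume
table as CSV.

## Layout

| module | contents |
| --- | --- |
| `symatlas.core_image` | `ImageVolume`, NIfTI I/O, reslicing, AC-PC reorientation, grid-exact sagittal flip |
| `symatlas.phantom` | synthetic newborn-head cohorts with ground-truth masks, transforms, asymmetry |
| `symatlas.preprocess` | bias-field correction, three-class tissue segmentation, intracranial masks |
| `symatlas.registration` | mask-weighted affine (Levenberg–Marquardt) and DCT nonlinear registration, inversion, averaging |
| `symatlas.atlas` | flip augmentation, reference selection, two-pass pipeline, symmetrization |
| `symatlas.evaluation` | asymmetry index, difference images, hemispheric volume reports |
| `symatlas.cli` / `symatlas.manifest` | `symatlas` command-line tool and YAML cohort manifests |

See `docs/methods.md` for the model, parameter defaults, numerical
choices and known limitations.
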