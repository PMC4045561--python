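# Methods

## Problem and model

Brain atlases built by straightforward averaging of normalized scans
inherit the anatomical left-right asymmetries of the cohort (and of the
subject chosen as registration reference).  For studies *of* asymmetry —
e.g. of language-related lateralization emerging in newborns — such an
atlas biases the very quantity under study.  `symatlas` builds an atlas
that is symmetric by construction:

1. **Mirror augmentation.**  Each of the N preprocessed head images
   `I_i` (with brain mask `B_i`, CSF mask `C_i` and intracranial mask
   `IC_i = B_i ∪ C_i`) is duplicated as its sagittal mirror across the
   midplane x = 0, giving 2N inputs.
2. **Affine normalization.**  Every input is registered to a reference
   `I_R` with a 12-parameter transform `A_i` (translation, rotation,
   scale, shear) minimizing the IC-weighted sum of squared differences
   `Σ w(x) (I_R(x) − g·I_i(A_i x))²`; the global gain `g` is solved in
   closed form so scans from scanners with different intensity scaling
   can be mixed.  The transform is applied to the image and all masks.
3. **Nonlinear normalization.**  The residual shape difference is
   modeled by a smooth displacement field `D_i` expanded in the lowest
   k³ terms per component of a separable 3D cosine (DCT) basis, fitted
   by minimizing the same weighted SSD plus a bending-energy penalty
   `λ Σ c² ω⁴` (the analytic curvature integral of the basis terms).
4. **Unbiased averaging.**  The reference-to-subject maps
   `T_i = D_i⁻¹` are averaged coefficient-wise,
   `T̄ = (1/2N) Σ T_i`, and `T̄` is applied to every normalized image
   and mask.  This removes the mean geometric pull of the particular
   reference: for every deformation contributed by an original image,
   its mirror image contributes (approximately) the mirror-conjugate
   deformation, so `T̄`'s x-component vanishes on the midplane.
5. **Template and probabilistic models.**  The 2N resampled images are
   arithmetically averaged into the intensity template; the warped
   (continuous-valued) brain and CSF masks are averaged into
   probability maps.
6. **Second pass.**  The whole procedure is repeated with the pass-1
   template as reference (and the thresholded, smoothed pass-1
   brain+CSF support as weighting mask), removing the residual
   anatomy of the initial reference subject.
7. **Flip-symmetrization.**  The final atlas is
   `½ (pass-2 atlas + mirror(pass-2 atlas))`, applied identically to
   the template and both probability maps.

The control ("asymmetric") atlas runs steps 2–6 on the N originals only,
with no mirror augmentation and no final symmetrization.

## Why the symmetry is exact

Every grid produced by the package places its x voxel centers
symmetrically about x = 0 (an odd count with one column exactly on the
midplane).  Mirroring is then a pure index reversal — no interpolation —
and because IEEE addition is commutative,
`flip(½(A + flip(A))) = ½(flip(A) + A)` holds bit for bit.  The final
template therefore equals its own mirror *exactly*, and the voxelwise
asymmetry index `AI = 2(V − mirror V)/(V + mirror V)` (defined as 0 where
the denominator vanishes, i.e. in air) is identically zero.  This does not
depend on registration accuracy; registration quality determines only the
sharpness of the template, not its symmetry.

## Registration details

* **Objective.**  Weighted SSD normalized by the total weight, with the
  intracranial mask (Gaussian-smoothed, sigma 1 mm by default) as weight so
  scalp and skull do not drive alignment.  Out-of-field samples are 0
  (air).
* **Affine optimizer.**  Multi-resolution Levenberg–Marquardt on the 12
  parameters (scales optimized in log space), with analytic Jacobians
  from the sampled moving-image gradient; translation initialized from
  the intensity centroids, which keeps nearly rotation-symmetric heads
  out of rotation/translation local minima.  Only improving steps are
  accepted, so the per-level objective trace is non-increasing — an
  invariant the tests audit.  Default levels 4, 2, 1 mm for standalone
  use; the atlas pipeline uses 4 and 2 mm (the 1 mm polish changes
  recovered parameters by ≲0.01 mm on phantoms and is not worth its
  cost when two passes follow).
* **Nonlinear optimizer.**  L-BFGS on the basis coefficients with an
  analytic gradient computed by separable basis projections (cost
  ~k × number of voxels per evaluation).  Basis order k = 8 per axis by
  default (3·8³ coefficients); regularization λ = 0.01 in
  frequency-normalized units, enough to keep phantom-scale warps free of
  folding.  Levels 4 and 2 mm: the basis itself contains no structure
  finer than ~1/8 of the field of view, so fitting below 2 mm adds
  nothing.
* **Inversion.**  `T_i` is obtained by fixed-point iteration of
  `v(x) = −u(x + v(x))` on a stride-2 grid followed by a least-squares
  re-projection onto the same basis, rather than by a second
  reverse-direction registration: it is cheaper, deterministic, and its
  round-trip residual is < 0.1 voxel for smooth fields (asserted against
  a dense oracle).  Fields whose Jacobian determinant drops below 0.05
  raise an inversion error.
* **Basis sampling.**  Sampled cosine-basis matrices are symmetrized
  exactly on symmetric grids (`B[n−1−i,l] = (−1)^l B[i,l]`, with odd
  terms exactly zero on the midplane), so mirror conjugation of a
  deformation is an exact sign pattern on its coefficients and the
  mirror-pair average property holds to the last bit.

## Preprocessing

* **AC-PC reorientation** is rigid, from three expert landmarks (AC, PC,
  and one interhemispheric point; we require the third landmark
  explicitly rather than estimating the midsagittal plane).  AC becomes
  the origin, PC lies on −y, the interhemispheric point in the x = 0
  plane.
* **Reslicing** is trilinear to 0.5 mm cubic voxels (configurable) on a
  flip-exact grid.
* **Bias correction** models the nonuniformity as a smooth multiplicative
  field: a low-order separable cosine expansion of log-intensity
  (order per axis matched to a 40 mm FWHM scale) fitted by regularized
  least squares to the modal-intensity, low-local-variance voxels of the
  mask — restricting the fit this way keeps tissue contrast and
  partial-volume edges out of the field estimate.  Three fit/divide
  iterations; mask mean preserved.  The correction is idempotent to
  <1% RMS and leaves bias-free images essentially untouched.
* **Segmentation** is deliberately simple (the atlas framework, not the
  segmenter, is the contribution): Otsu background split, largest
  filled component as head, three-class 1D clustering (multi-Otsu
  initialized Lloyd iterations — deterministic and gain-invariant),
  classes ordered by intensity with a `csf_bright` switch for T2-like
  contrast, morphological cleanup (largest brain component, hole
  filling, CSF restricted to components adjacent to brain).  Externally
  supplied masks are accepted everywhere and take precedence.

## Synthetic cohorts

The phantom generator emulates a term-newborn head as nested ellipsoids —
scalp (semi-axes 44 × 56 × 46 mm), a 3 mm CSF shell, and a brain core
(0.78 of the head radii, ≈250 cm³) — voxelized with 2× supersampling at
0.5 mm (default) on a flip-exact grid.  Class mean intensities are
background 0, CSF 30, scalp 60, brain 100, a T1-like ordering in which
CSF is the darkest tissue class.  Controls:

* `left_scale` stretches the left (x < 0) half of brain and CSF along x,
  continuously at the midplane; the left brain-volume fraction is
  s/(1+s), so designed splits are analytic (52/48 ⇔ s = 52/48).
* `torque_deg` rotates the left half about z with a smooth midline blend,
  a surrogate for the normal interhemispheric torque.
* a multiplicative bias field (product of three low-frequency cosines)
  and additive Gaussian noise;
* per-subject cohort jitter: rigid offset (±3 mm, ±4°), anisotropic
  scale (±4%), shear (±0.02) and a smooth low-frequency warp (±1 mm) —
  magnitudes chosen to resemble the residual pose/size variation of
  reoriented newborn heads.  Ground-truth transforms and landmarks are
  recorded for recovery tests.

One integer seed drives everything; per-subject streams are derived by
subject counter, so subject k is identical in any cohort size.

What the phantoms do **not** model: cortical folding, gestational-age
contrast changes, real PSF/motion artifacts, or genuinely anatomical
asymmetries beyond the global scale/torque surrogates.  Passing tests
therefore demonstrate the correctness of the *framework* (geometry,
registration recovery, unbiased averaging, exact symmetrization), not
segmentation or registration performance on clinical data.

## Problem sizes and numerics

Unit tests run phantoms at 2 mm; segmentation accuracy is asserted at the
native 0.5 mm; the end-to-end atlas acceptance builds use a four-subject
cohort at 1 mm (≈1.4 M voxels per volume), where the symmetric build
takes a few minutes on one CPU.  Probability maps are stored float32 and
clipped to [0, 1] after resampling (trilinear interpolation preserves
`brain + csf ≤ 1`, and averaging preserves it further).  Subjects are
processed in canonical (id, flipped) order so atlas construction is
invariant to input order bit for bit.  Midplane voxel columns count half
to each hemisphere in volume reports, keeping mirrored structures at
exactly 50/50.  Hemispheric volumes from probability maps are reported
both thresholded at 0.5 and as continuous probability mass.

## Known limitations

* On the noise-free, piecewise-constant phantoms, sharp compartment
  boundaries alias the SSD objective: correcting a small rotation can
  cost more (in interpolation blur at edges) than the misalignment it
  removes, so the objective's own minimum sits a fraction of a voxel
  from the injected truth.  Injected translations and scales are
  recovered to 0.25 mm / 0.01 (the quantities that matter for the
  volume-preserving averaging); full rotation+shear mixtures are
  recovered to sub-voxel accuracy but not to 1/8 voxel.  Real MR images,
  with texture and smoother edges, do not share this degeneracy in the
  same form.  None of this affects the atlas's exact symmetry, which is
  structural.
* Registration is intensity-SSD only (with global gain); no
  mutual-information metric, so inter-modality alignment is out of scope.
* The cosine-basis warp is low-frequency by design; it cannot capture
  sulcal-scale shape differences.
* The simple segmenter assumes three distinguishable intensity classes
  and is intended for phantoms and as a fallback; real studies should
  supply masks from a dedicated newborn segmentation tool.
* `select_reference`'s automatic rule (minimal mean |log scale| + |shear|
  to all others) is a coarse proxy for "least deformed head"; an explicit
  operator choice is preferred.
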