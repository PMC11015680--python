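# Methods

This note records the scientific and numerical choices behind `imioreg`:
what is modelled, which parameters matter, what the synthetic phantoms do
and do not emulate, and where the design was genuinely open.

## Registration model

The transform is a dense 2D displacement field `v` on the fixed-image
grid, stored in millimetres with (row, col) components; `v` maps a fixed
point `p` to the moving-space point `p + v(p)`. This is the least
restricted transform model — nothing enforces diffeomorphism; folds are
*measured* (Jacobian determinant < 0), not prevented.

The objective is a weighted multi-channel SSD plus a tissue-weighted
first-difference penalty over the 4-neighbourhood:

    E(v) = Σ_c w_c Σ_i (F_c(i) − M_c(i + v(i)/h))²
         + s Σ_{(i,j)∈N4} λ(i,j) ‖v(i) − v(j)‖² .

Channels are the CT image mapped affinely from [−1024, 1024] HU to [0, 1]
plus binary guidance masks; the normalization puts all channels on one
scale so the per-channel weights compare like with like. Per station the
defaults are: liver — CT 0.5, liver 0.1, spleen 0.1, body 0.15, vertebra
0.15; abdomen — CT 0.4, body 0.1, vertebra 0.2, muscle 0.2, inside-SAT
0.1; thigh — CT 0.5, body 0.1, bone 0.2, lean 0.2. The CT channel always
carries the largest weight: masks contribute high-level correspondence
cues, the CT image the detailed gradient information.

`λ(i, j)` is the mean of the elasticity-class weights of the two voxels
(air 0.05, adipose 0.05, soft tissue 0.05, bone 0.1): deformations are
cheap in elastic tissue and twice as expensive across bone. The class map
is derived by HU thresholding inside the body mask; the class boundaries
reuse the printed mask windows (−190 HU body threshold for air/adipose,
−30 and 150 HU from the lean-tissue window for adipose/soft and
soft/bone), with the 150–200 HU gap assigned to bone so the four classes
are exhaustive and disjoint.

`s` (`reg_scale`, default 0.01, units intensity²/mm²) balances the two
terms. It is a free scale: the similarity term lives in normalized
intensity units while the penalty is quadratic in millimetres, so their
ratio is meaningful only jointly. The default was fixed by the same
procedure used for the other settings — preliminary runs scored with the
evaluation metrics (truth-field endpoint error, inverse consistency) on
warped phantoms; values within roughly a factor of four of 0.01 behave
equivalently, an order of magnitude larger visibly over-smooths.

### Optimizer

Optimization is discrete and coarse-to-fine. A Gaussian pyramid
(smoothing σ = 1 voxel, decimation by two; 8 levels configured, capped so
the coarsest grid keeps ≥ 4 voxels per side) is descended from the
coarsest level to level one, so the returned field — and anything
registered with it — lives on the original grid downscaled by a factor of
two per dimension (512² input → 256² output, spacing doubled). The field
is upsampled between levels with linear interpolation (mm values carry
over unchanged) and lightly smoothed (σ = 1 voxel).

Within a level, square blocks of `block_size` voxels (default 16) receive
one candidate update each: ± `step_size` voxels (default 0.5, expressed in
voxels of the current level) along each axis, additive update rule. A
move is accepted only if it strictly lowers the total energy; equal-energy
moves keep the current field, for determinism. Blocks are visited in a
checkerboard order, so simultaneously updated blocks share no regularizer
edge and the per-pass energy change is exactly the sum of the accepted
per-block changes — the total energy is therefore non-increasing across
outer iterations at every level, by construction, and the optimizer
asserts this invariant at run time. When a sweep accepts no move the step
is halved (`step_refinements` times, default 2) for sub-voxel refinement
before the level is declared converged; `max_iterations_per_level`
(default 30) bounds the work, returning the best field with a warning
flag when hit.

This block-move scheme was chosen over a max-flow/min-cut move-making
implementation: the acceptance surface for the optimizer is monotone
energy descent plus truth-field recovery, both of which the simpler
scheme satisfies, and it keeps the label graph trivially small (one label
per block). The interface (`register_pair`) hides the backend, so a
graph-cut implementation can be swapped in without touching callers.

### Accuracy floor

Endpoint accuracy is quantized by the half-resolution output grid: one
output voxel is ≈ 1.95 mm at the standard geometry (≈ 3.9 mm when 256²
inputs are used in scaled-down runs). Recovered fields for ground-truth
warps land within about one output voxel of the truth regardless of warp
size; relative-error statements (e.g. "registration halves the mean truth
displacement") are therefore meaningful for deformations clearly above
that floor.

## Preprocessing

Slices are resampled (linear interpolation, physical centres aligned) to
a 500 mm field of view on a 512² grid; intensities above 1024 HU are
truncated to 1024. The metal-implant flag (≥ 50 voxels above 2000 HU) is
decided *before* truncation, since truncation destroys the evidence;
flagged slices are marked, never dropped. The operation is idempotent.

Masks follow the classical recipes: body = threshold > −190 HU, largest
connected component (two for the thigh station), closing (disk radius 3),
hole filling; vertebra = > 200 HU opened with a radius-1 disk; thigh
cortical bone = > 200 HU with the enclosed marrow filled solid (fewer
local minima); lean = [−29, 150] HU minus the filled bone; inside-SAT =
the interior enclosed by the morphologically closed muscle wall (disk
radius 8 ≈ 8 mm — large enough to bridge anatomically plausible anterior
muscle gaps) minus the wall itself. The morphology radii are not dictated
by any protocol; they are configuration values validated by the phantom
Dice ≥ 0.95 tests. Organ masks that in production come from learned
segmentation models (liver, spleen, abdominal muscle) are accepted as
external inputs; phantom runs use the analytic ground truth. Liver slices
whose spleen mask is empty are excluded with a log message.

## Evaluation

Inverse consistency: for a pair (x, y), forward and reverse registrations
give `T_xy` and `T_yx`; the per-voxel composite displacement of
`T_yx ∘ T_xy` is computed on x's grid. VME is its mean magnitude (mm)
over Ω, IME the mean absolute difference (HU) between the image and
itself resampled through the composite (linear interpolation). Both
composite orders are evaluated and averaged into one value per pair. Ω is
the body mask on the output grid eroded by one voxel — the erosion avoids
border interpolation artifacts and is a configuration choice.

Jacobian determinants use central differences in the interior and
one-sided differences at borders, in consistent mm/mm units. Folds are
voxels with strictly negative determinant; exact zeros are reported
separately as degenerate. The log-determinant is NaN wherever the
determinant is not positive. Cohort maps (mean/STD of registered HU and
log-Jacobian, mean VME) use the population STD (divide by n), fixed for
reproducibility.

## Voxel-wise statistics

Template selection standardizes each station's measurement columns to
z-scores within the (cohort, sex) group using the sample SD (n−1) and
picks the subject minimizing Σ|z| — the subject closest to the group mean
in measurement space. Zero-variance columns are skipped with a warning;
ties break to the lexicographically smaller subject id. Station column
sets: liver — spleen, liver, VAT, SAT; abdomen — VAT, SAT, abdominal
muscle; thigh — thigh SAT, thigh muscle.

The voxel-wise analysis is mass-univariate simple OLS per voxel across
subjects (closed form: β₁ = cov(x, y)/var(x)), with the deformed HU stack
and the log-Jacobian stack as responses. The log (not raw) determinant is
the volume response because it is symmetric around zero for
expansion/contraction. No spatial smoothing and no multiple-testing
correction are applied — the deliverables are the β and R² maps
themselves. Voxels with zero response variance get β₁ = 0 and R² defined
as 0. Covariate adjustment (age, BMI) is not performed by default;
residualization is left to the caller.

## Phantoms

Each station is a composition of rotated ellipses painted with canonical
HU levels (air −1000, fat −100, lean 40–60, cortical bone ≥ 200, lung
−800, marrow −80, intestinal gas −1000), plus additive Gaussian noise
(default SD 12 HU) and a mild Gaussian smoothing (σ 0.6 voxels) standing
in for a medium-smooth reconstruction kernel. Liver slices contain body,
subcutaneous fat ring, liver, spleen, two lungs and a vertebra; abdominal
slices body, SAT ring, muscle ring, visceral fat with organ blobs and gas
pockets, and a vertebra; thigh slices two circular thighs with SAT ring,
lean interior, solid cortical bone with marrow, and small intermuscular
fat inclusions. An optional table object outside the body exercises the
body-mask cleanup, and bright voxels can be planted to exercise the metal
flag.

Cohorts draw per-subject geometry jitter (body scale SD 0.04, structure
scale SD 0.05, centre jitter 3 mm — free choices, held in configuration,
representing moderate anatomical variability) and BMI/age-like
covariates. A planted effect makes one structure's area a linear function
of a covariate; with zero geometry noise the construction is exactly
monotone. Ground-truth warps (translations, radial Gaussian bulges with
closed-form Jacobians) provide displacement fields that are consistent
with the warped images by construction; amplitudes that would fold are
rejected analytically.

Truth areas are defined as mask voxel count × voxel area. Pixel-centre
rasterization of an ellipse matches the analytic area only to the
boundary band (about half the perimeter times the pixel pitch), so
analytic-area checks use that tolerance rather than a single voxel.

What the phantoms do **not** emulate: projection/reconstruction physics
(beam hardening, photon noise correlations, kernel-specific texture),
fine anatomical texture and topology differences between subjects, organ
boundaries that are not smooth ellipses, and longitudinal or
contrast-enhancement effects. Passing phantom tests therefore shows the
machinery is correct and well-conditioned on smooth, well-contrasted
anatomy; it does not certify accuracy on clinical images with pathology,
implants or atypical anatomy.

## Study conditions for the reproduction script

`scripts/acceptance.py` uses 10 subjects per slice type on 256² grids
with the default population parameters and per-sex template selection —
a deliberately scaled-down cohort chosen so that a complete run
(60 forward/reverse registrations plus evaluation) is a desk-scale
computation. Group-mean VME and IME are averaged over the six
(station, sex) groups. All randomness derives from the `--seed` argument.

## Known limitations

- The optimizer's block moves make the field piecewise constant per block
  within a level; smoothness comes from the multi-scale accumulation and
  the inter-level smoothing, not from the parameterization.
- Registration output at half resolution bounds achievable endpoint
  accuracy to about one output voxel.
- The SSD is computed over the full grid with background fill by default;
  a region mask is available but unset, matching the simplest reading of
  the objective.
- 2D only; no attempt at 3D or multi-slice consistency.
- The voxel-wise fits are univariate; confounders are not adjusted.
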