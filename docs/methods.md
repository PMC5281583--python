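# Methods

`strokeseg` segments ischemic stroke lesions in quantitative T2 maps of the
mouse brain after transient middle cerebral artery occlusion (tMCAo).  The
lesion shows elevated T2 (vasogenic edema), but a plain threshold fails
because ventricles (CSF), periventricular structures and tissue surrounding
the brain share similarly elevated values, and because lesions and
ventricles vary strongly in shape, size and contrast across animals and
time points.  The method rests on two assumptions: (i) the T2 distribution
of infarcted tissue differs from that of healthy tissue, and (ii) only one
(the ipsilateral) hemisphere is affected, so the contralateral hemisphere
of the *same* scan can supply the healthy-tissue and ventricle intensity
models.  No population model is fitted; everything is estimated per scan.

## Level-set engine

Each stage partitions its domain into object `Ω_O = {φ ≥ 0}` and background
`Ω_B = {φ < 0}` by evolving a level-set field φ to minimize

    E(φ) = α · g(x) · Length(∂Ω_O) + μ · Area(Ω_O)
           − Σ_{Ω_O} log P(I(x); Ω_O) − Σ_{Ω_B} log P(I(x); Ω_B)

a region-competition energy in the Chan–Vese family.  The data terms are
region sums of negative log-likelihood under per-region intensity models —
either Gaussian (maximum-likelihood mean/sd, sd floored at 1e-3 of the unit
intensity range) or a 64-bin equal-width histogram over [0, 1] with a 1e-8
probability-mass floor (re-normalized).  Models marked *fixed* are
estimated once from a designated region and never updated; adaptive models
are re-fitted from the current partition every iteration.  `g(x) ∈ [0, 1]`
is an optional edge-stopping weight on the perimeter term.

Numerics.  φ is initialized as the signed Euclidean distance to the
initialization mask and re-initialized every 20 iterations; both times it
is capped at ±3 voxels, so every voxel stays within a few update steps of a
sign change rather than being stranded at a large distance (pure
front-propagation would otherwise be slowed, and the re-initialization
would discard accumulated data-force drift far from the front).  The
explicit update is

    φ ← φ + dt · [ α g δ_ε(φ) κ(φ) + log P_obj(I) − log P_bg(I) − μ ]

with κ the mean curvature of φ (central differences), δ_ε a smoothed Dirac
delta (ε = 1.5 voxels) gating only the curvature force, and
dt = 0.45 / max|force| (a CFL-like bound).  The data and area forces act
un-gated on every domain voxel; as a consequence a voxel's sign flips
exactly when the flip lowers the partition energy, so with fixed models and
α = μ = 0 the energy is non-increasing and the evolution converges to the
per-voxel maximum-likelihood classification.  Evolution is restricted to an
arbitrary domain mask (φ frozen outside), stops early when fewer than 0.01%
of domain voxels change label between consecutive iterations (armed only
after the first re-initialization interval, since no voxel can flip during
the first few CFL-bounded steps from a fresh signed distance), and is
fully deterministic.  Ties (φ = 0) count as object.  Length and Area are
measured in voxel units — the stage weights below were tuned unitless —
and Length counts object/background face pairs, each weighted by the mean
of g over the two incident voxels.

## Pipeline

Inputs: a quantitative T2 map (ms), its multi-echo train, and six template
labels — whole brain M_WB, ipsi-/contralateral hemisphere M_IBH/M_CBH,
ipsi-/contralateral ventricle M_IV/M_CV, periventricular zone M_PVZ —
brought into subject space by label propagation.  The built-in registration
(SimpleITK: normalized-correlation metric, Gaussian pyramid, four rigid +
two affine levels, the subject's echo sum as the fixed image) covers
rigid/affine alignment; a dense displacement field from an external
non-rigid tool can be supplied instead, and the phantom path provides
labels directly.  Labels are warped nearest-neighbor and the containment
invariants re-enforced by masking.

Preprocessing: all volumes are cropped to the tight bounding box of the
propagated M_WB (no margin; the stage domains prevent boundary effects) and
min–max rescaled to [0, 1].  Echo images additionally get a per-slice
normalization — each slice's cumulative intensity distribution is mapped
onto that of the maximum-entropy slice (64-bin histogram entropy, computed
after unit rescaling, ties to the lowest index) by exact histogram
matching.  The T2 map is never slice-normalized: its values are physical.

Stages (defaults in parentheses; all on the cropped grid):

1. **Whole brain** on the 4th echo (Gaussian/Gaussian, α=5, μ=2, n_iter=80,
   full grid, φ₀ = M_WB), then per-slice hole filling, per-slice opening
   with a radius-2 disk, and the largest 26-connected component → R_WB.
   Disk-based morphology is 2D per slice because slices are ~4× thicker
   than the in-plane voxel size; components are 3D.
2. **Contralateral ventricle** on the T2 map inside R_CBH = R_WB \ M_IBH
   (Gaussian/Gaussian, α=0.1, μ=0, n_iter=120, φ₀ = M_CV) → R_CV.
3. **Ventricles** on the T2 map inside R_WB (histogram object fixed from
   R_CV, histogram background adaptive, α=2, μ=1.5, n_iter=120,
   φ₀ = M_IV ∪ M_CV) with the gradient map enabled:
   g = 1 − e_v², where e_v is the negative Gaussian log-likelihood under
   the R_CV model, min–max scaled over the volume.  Voxels that do not look
   like ventricle get g ≈ 0, which suppresses the perimeter smoothing there
   and keeps the contour from being carried into lesion tissue that touches
   the ventricles → R_V (template labels as a logged fallback if empty).
4. **Stroke**: histogram models are fitted on R_WB \ (R_V ∪ M_PVZ) and
   R_CBH \ (R_V ∪ M_PVZ); the initialization R_s_init is the set of voxels
   in R_IBH \ (R_V ∪ M_PVZ) where the whole-brain model assigns *strictly*
   higher probability than the contralateral model (the lesion inflates the
   whole-brain histogram at elevated T2; equal-probability voxels are
   excluded).  Components of R_s_init that contain no *dense* voxel are
   discarded; a voxel is dense when ≥ 75% of its within-slice
   radius-4-disk neighbors (48 neighbors, the voxel itself excluded;
   at borders the fraction is over in-bounds neighbors) are also in
   R_s_init.  The level set then evolves inside R_IBH \ (R_V ∪ M_PVZ)
   (histogram object adaptive, histogram background fixed from R_CBH,
   α=0.3, μ=0, n_iter=80) → R_stroke.  An empty initialization is reported
   as "no lesion detected".

Lesion volume is the voxel count times the voxel volume, in mm³ (the only
place physical spacing enters).  No step consults ground-truth labels.

## Synthetic phantoms

The phantom generator produces the study conditions for all tests: a
96×96×16 grid at 0.12×0.12×0.50 mm (a typical 7 T MSME mouse protocol),
an ellipsoidal brain split at the midline, a curved ventricle tube pair, a
periventricular rim (per-slice dilation of the ventricles), and a lesion in
the ipsilateral hemisphere drawn per archetype — striatal, corticostriatal
(default), fragmented (two blobs), large-edema (engulfing the ventricle),
or none — with the blob scale bisected so the voxelized volume hits the
requested target (default 40 mm³) within 1%.  Tissue T2 values are
healthy 40±3 ms, ventricle/CSF 90±8 ms, lesion 65±6 ms (mean ± per-voxel
Gaussian texture), plus 2 ms global additive Gaussian noise.  These values
deliberately place the lesion *between* healthy tissue and CSF with partial
overlap — the confound the method is designed around — and are
configuration, not claims about mouse physiology.  Noise is additive
Gaussian (not Rician) because a fitted T2 map is a derived quantitative
image, not raw magnitude data.  Echo images are synthesized as
PD·exp(−n·TE/T2) (TE = 9 ms, 20 echoes) plus Gaussian noise.  The template
atlas is the truth atlas warped by a smooth random displacement of at most
2 voxels in-plane (1 through-plane), emulating residual registration error;
everything is deterministic given the seed.

What the phantoms do **not** emulate: partial-volume averaging at tissue
boundaries, coil sensitivity profiles, motion, susceptibility artifacts,
anatomically realistic ventricle/lesion shapes, and the large brain
deformations of severe edema.  Passing phantom tests therefore demonstrates
correctness of the machinery and the intended behavior of each stage under
the stated statistical structure, not clinical-grade accuracy on real
scans; phantom Dice scores (~0.97) are accordingly higher than what is
achievable on real data.

A known behavior worth stating: on a *lesion-free* phantom with
statistically exchangeable hemispheres, the strict probability comparison
behind R_s_init reduces, per histogram bin, to comparing two independent
sampling-noise estimates of the same distribution — a coin flip — so the
candidate mask covers about half the ipsilateral domain and percolates into
one connected component.  Whenever at least one dense voxel arises (roughly
half of seeds), the component is kept and the adaptive object model
stabilizes on the noise-selected intensity bins, yielding a spurious
"lesion" of roughly half the hemisphere.  The method is intended for scans
where an infarct is present (assumption (i)); its output on lesion-free
data should not be trusted as a lesion detector.

## Evaluation

Dice = 2|R₁∩R₂|/(|R₁|+|R₂|) (two empty masks → 1.0, logged); volumes in
mm³; ICC for absolute agreement between two measurement methods, two-way
model, single measures (McGraw–Wong ICC(A,1), computed via pingouin and
cross-checked in the tests against a hand-written ANOVA mean-squares
oracle).  The semi-automated baseline mirrors the observer workflow: the
group threshold is mean + 2·sd (sample sd) of per-animal contralateral-ROI
mean T2 values; the mask is strictly-above-threshold; the observer's manual
removal of confounding regions is represented by an optional exclusion-mask
argument, since that step cannot be automated.

## Problem sizes and design choices

Tests and the acceptance script use 10-phantom suites at the default
96×96×16 geometry (seeds 1–10; the script offsets them by its `--seed`),
an additional 10-phantom suite with lesion targets 15–70 mm³ for the
volume ICC, and a 64×64×8 two-population volume for the
maximum-likelihood-limit check.  The ±50% sensitivity harness re-runs only
the stroke stage on cached pre-stroke state, since the perturbed parameters
(α, μ, n_iter of that stage) affect nothing upstream.  Registration
recovery is checked on translated copies of the phantom echo sum.

Open choices resolved here: the energy's data terms are read as region
sums; adaptive models are re-fitted every iteration; slice entropy is
computed after unit rescaling; the whole-brain model region for R_s_init is
R_WB as the method description states (its formula subscript differs);
"4th echo" is 1-based; histogram matching is exact per slice; the
registration direction is subject-as-fixed with template labels pulled onto
the subject grid (configurable).
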