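# Methods

This note records the models, conventions, and numerical choices behind
`fodfbias`, and what the synthetic experiments do and do not establish.

## Conventions

World axes are RAS: +x right (medial–lateral, M–L), +y anterior
(anterior–posterior, A–P), +z superior. Voxel centers sit at integer voxel
coordinates; the NIfTI affine maps voxel indices to world mm. All fODFs in a
cohort are sampled on one shared, antipodally symmetric direction set, so a
direction index means the same orientation in every subject — a prerequisite
for per-direction cross-subject statistics.

## Direction set

The default set has 362 directions (181 antipodal pairs). Pairs are placed by
a deterministic electrostatic-repulsion optimization: points start uniformly
at random on the sphere (fixed seed), and each iteration applies inverse-square
repulsion from every other point *and its antipode*, projected onto the
tangent plane, with a linearly decaying step. The seed-0 result is shipped as
a versioned fixture (`data/sphere362_v1.tsv`, full double precision) so every
run and subject uses bit-identical directions. For 6 pairs the optimizer
reaches a minimum pairwise separation of ≈61°, close to the icosahedral
optimum of 63.43°, which is the quality check used in the tests.

## Orientation angle φ

φ(v) is computed as `degrees(atan2(|x|, |y|))` with the sign negative on the
right half-plane (x > 0), positive on the left, and exactly 0 when x = 0.
The `atan2` form is numerically well conditioned near both axes (a
`acos`-based complement loses ~7 digits near ±90°). When the axial projection
satisfies ‖(x, y)‖ ≤ 1e-8·‖v‖ the angle is undefined: it is stored as NaN
with an explicit flag, excluded from histograms, and the exclusion count is
reported. φ is invariant to positive scaling, antisymmetric under v → −v, and
symmetric under y → −y.

## Reweighting

Cross-subject σ uses the sample convention (ddof = 1): subjects are a sample
from a population. Two correspondence modes exist: `voxelwise` (default;
assumes grids are aligned across subjects, which the phantom guarantees) and
`roi_pooled` (one σ per direction over all subjects × ROI voxels, for data
without reliable voxel correspondence). The division guard defaults to
ε = 1e-8 × median ROI σ — scale-free, and only relevant where subjects agree
exactly; ε = 0 with an exact-zero σ raises an error naming the voxel. The
reweighted field is stored unnormalized (the method divides and stops);
normalization to sampling probabilities happens only inside the tracker's
`fodf_to_pmf`.

The change histogram compares per-voxel *probability* profiles (each voxel's
density vector normalized to unit sum) between the original and reweighted
fields. This is deliberate: the reweighted field carries an arbitrary global
scale of order 1/σ, so raw differences would be positive nearly everywhere
and the increase/decrease split would be vacuous. Per subject, positive and
negative differences are pooled over ROI voxels × directions, each pool's
median is the threshold (strictly above / strictly below, so the median
element itself never counts), the φ of qualifying directions are binned into
20 equal bins on [−90°, 90°], and bin counts are averaged across subjects.
An empty pool yields an all-zero histogram with a flag, not an error.

## Tracker

Rejection-based anatomically constrained propagation, bidirectional from each
seed (6 uniform random seeds per voxel by default). Per step (default length
0.5 × smallest voxel edge): tissue fractions are interpolated trilinearly at
the new point (nearest-edge extension beyond the grid); CSF fraction > 0.5
discards the streamline, GM fraction > 0.5 terminates it validly; otherwise
the next direction comes from the nearest voxel's clipped, normalized fODF
restricted to directions within 30° of the incoming direction (antipodal
polarity resolved by the sign of the dot product). Deterministic mode takes
the admissible argmax; probabilistic mode samples. An empty admissible set
discards with an angle violation; an all-zero fODF voxel discards as
degenerate; exhausting the step budget (1000) or leaving the volume discards
as a length failure. The "curving angle" rule is enforced as *discard when
the turn exceeds 30°*. Probabilistic runs are bit-stable given the RNG seed,
and reduce exactly to deterministic tracking when a voxel's mass lies on a
single antipodal pair (the initial pair member is canonicalized so both modes
emit the two halves in the same order). No probability floor is applied to
the sampling distribution: the sampler uses the cone-restricted profile as
is.

## Density statistics

A streamline contributes at most once per voxel (set semantics). Voxel
traversal is exact per segment via a 3-D digital differential analyzer
(Amanatides–Woo) on the half-integer voxel boundaries, verified in the tests
against an independent slab-clipping oracle, so thin diagonal crossings count
even when no vertex lands in the voxel. Density = traversals / number of
valid streamlines, hence values in [0, 1] and invariance to duplicating the
streamline set. ROI summaries: per-target mean density normalized over all
targets (shares sum to 1), and ROI mean over whole-WM mean (any log transform
is the caller's choice). Group statistics (ANOVA, t tests, corrections) are
deliberately not reimplemented; the TSV outputs feed any statistics package.

## Phantom

Grid 24 × 24 × 12 voxels of 1 mm. Gray-matter walls close the two M–L ends
(medial seed side, lateral target side); a CSF shell covers the remaining
boundary; the interior is WM. A 6 × 6-voxel WM corridor connects the two
walls; the seed ROI is the corridor slab x ∈ [1, 4], the lateral target is
the whole lateral GM wall, and a mid-corridor path ROI is provided for
density summaries. Per WM voxel and direction,

    density(d) = a_AP·e^{η_s} · K(d; ŷ, κ)      dominant A–P bundle
               + a_ML · w(v) · K(d; x̂, κ)       consistent M–L bundle (corridor)
               + Σ_j amp_{j,s} · K(d; axis_{j,s}, κ)   spurious kernels
               + max(N(0, τ²), 0)                directional noise

with K the antipodally symmetric Watson-type kernel
`exp(κ((d·μ)² − 1))` (peak 1), defaults a_AP = 1, a_ML = 0.15, κ = 20,
τ = 0.15, three spurious kernels per subject with amplitudes U[0, 0.3] and
uniformly random axes, 20 subjects, and η_s ~ N(0, 0.3²) a lognormal
across-subject spread of the dominant bundle's amplitude. All draws derive
from (master_seed, subject_index), so cohorts are pure functions of their
parameters.

The amplitude spread of the dominant bundle is essential, not decorative.
With purely additive iid noise, σ is the same at the consistent M–L
directions as at empty directions and flat across the two bundles, so
dividing by σ changes nothing except at the spurious-kernel directions —
no M–L recovery and no directional signature can emerge. Real bundle
strength varies between individuals; that variability is what makes the
dominant peak's cross-subject σ large in absolute terms and lets the
reweighting demote it relative to the consistent weak signal. A 30%
coefficient of variation is a realistic magnitude for between-subject tract
strength.

Known tension in the design: the corridor M–L mass fraction
(mass at |φ| > 81° over total) increases after reweighting for two reasons —
the consistent M–L signal is boosted, and the dominant A–P peak is
suppressed. The second mechanism operates even when a_ML = 0, so the
"fraction increases" readout is not by itself specific to the M–L signal;
specificity comes from the change-histogram signature (increases
concentrated at ±90° only when the M–L kernel is present) and the tracking
experiment. A fraction statistic that is simultaneously sensitive to A–P
suppression (which the directional signature requires) and inert when the
M–L signal is absent does not exist; the corresponding control check in the
acceptance suite documents this and is expected to fail.

What the phantom does not emulate: spherical-harmonic band-limiting of real
fODFs (noise here is independent per direction, i.e. angularly white, which
is harsher on the tracker than SH-smooth noise), spatially correlated noise,
imperfect inter-subject registration, partial-volume tissue fractions, and
curving pathway geometry. Passing on the phantom therefore demonstrates the
statistical mechanism of the correction, not performance on acquired data.

## Experiment sizes and runtimes

The replicate experiment (100 cohorts × 20 subjects) measures the corridor
fraction before/after reweighting; since the reweighting is voxelwise,
non-corridor voxels cannot affect the statistic and only corridor voxels are
generated (per-voxel values bit-identical to the full generator). The
tracking experiment uses one default cohort, 864 seeds per subject (6 per
seed-ROI voxel), identical seeds and RNG for the before/after fields, and an
exact paired sign test with ties dropped. These sizes keep the full suite
within a few minutes on one CPU while leaving the per-cohort statistics
comfortably powered.

## Limitations

* Voxelwise correspondence is assumed, not computed; registration error in
  real cohorts would inflate σ at sharp features and blunt the correction.
* The tracker is a minimal reference implementation (no particle-filter
  backtracking, nearest-voxel fODF lookup); it is meant for validating the
  reweighting, not for production human tractography.
* The ε guard and the unnormalized reweighted output mean downstream
  consumers must not interpret reweighted values as probabilities without
  renormalizing per voxel.
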