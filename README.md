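# fodfbias

Diagnosis and correction of anterior–posterior orientation bias in diffusion-MRI
fiber orientation distribution functions (fODFs), for tractography of crossing
pathways that a dominant bundle would otherwise suppress.

## The problem

In deep prefrontal white matter, fODFs can carry most of their probability mass
along the anterior–posterior (A–P) axis, because the large longitudinal bundles
dominate the diffusion signal. Probabilistic tractography then samples A–P
directions almost exclusively, and thin medial–lateral (M–L) pathways — such as
fibers crossing toward ventrolateral prefrontal cortex through the extreme
capsule — come out as false negatives even though the axons exist.

## The method

Two quantities are central:

**Orientation angle φ.** For a direction *d* with axial-plane projection
*d′ = (x, y)* (RAS axes: +x right/M–L, +y anterior/A–P), φ is the signed angle
between *d′* and the M–L axis, complemented so that φ = 0° on the A–P axis,
φ = −90° on the right half of the M–L axis, and φ = +90° on the left half.
φ ∈ [−90°, 90°]; directions with no axial projection are flagged undefined.

**Cross-subject variance reweighting.** For a cohort with a shared direction
set, compute per voxel and direction the cross-subject standard deviation
σ(v, d) and divide each subject's density by it:

    f̃ₛ(v, d) = fₛ(v, d) / (σ(v, d) + ε)

A real fiber bundle that is consistently present across subjects produces
consistent density in its direction (low σ → boosted); density produced by
noise or by between-subject variability is inconsistent (high σ → suppressed).
The effect is summarized by 20-bin histograms of φ for the directions whose
per-voxel probability rose/fell the most after reweighting.

The package also provides a minimal anatomically constrained tracker
(6 random seeds per voxel, 30° turning-angle cap, GM termination, CSF
discard; deterministic and probabilistic modes), streamline-density volumes
with ROI/WM normalizations, and a synthetic multi-subject crossing-fiber
phantom — a dominant A–P bundle with across-subject amplitude variability, a
weak but consistent M–L bundle in a corridor, subject-specific spurious
kernels, and truncated directional noise — on which the whole recovery
experiment runs in minutes.

## Worked example

```python
import numpy as np
from fodfbias import (PhantomParams, generate_cohort, reweight_cohort,
                      angles_for_set, ml_mass_fraction, change_histogram,
                      tracking_experiment, paired_sign_test, TrackingParams)

cohort = generate_cohort(PhantomParams(master_seed=0))   # 20 subjects
rew, sigma = reweight_cohort(cohort.cohort)
ang = angles_for_set(cohort.cohort.directions)
corridor = cohort.masks["corridor"]

f_before = np.mean([ml_mass_fraction(cohort.cohort.stack[s], ang, corridor)
                    for s in range(20)])
f_after = np.mean([ml_mass_fraction(rew.stack[s], ang, corridor)
                   for s in range(20)])
print(f"M-L mass fraction (corridor): {f_before:.4f} -> {f_after:.4f}")

h = change_histogram(cohort.cohort, rew, ang, corridor)
centers = (h.bin_edges[:-1] + h.bin_edges[1:]) / 2
print(f"modal increase bin: {centers[np.argmax(h.increase_counts)]:+.1f} deg")
print(f"modal decrease bin: {centers[np.argmax(h.decrease_counts)]:+.1f} deg")

df = tracking_experiment(cohort, TrackingParams(rng_seed=0))
res = paired_sign_test(df.reach_before, df.reach_after)
print(f"seed-to-target reach: {df.reach_before.mean():.4f} -> "
      f"{df.reach_after.mean():.4f} (sign test p = {res['p_value']:.2e}, "
      f"{res['n_increased']}/{res['n']} subjects increased)")
```

Output:

```
M-L mass fraction (corridor): 0.1057 -> 0.1170
modal increase bin: -85.5 deg
modal decrease bin: -4.5 deg
seed-to-target reach: 0.0147 -> 0.0187 (sign test p = 2.21e-03, 16/19 subjects increased)
```

Reading it: reweighting moves corridor fODF mass toward the M–L axis
(|φ| > 81°) in every subject; the directions whose probability rose the most
sit at φ ≈ ±90° (M–L) while those that fell sit at φ ≈ 0° (A–P) — the
orientation-bias correction acts exactly where it should; and the fraction of
streamlines that validly connect the medial seed wall to the lateral
gray-matter target rises in 16 of 19 informative subjects.

The same chain is available from the shell:

```sh
fodfbias phantom --n-subjects 20 --master-seed 0 --out ph
fodfbias reweight --phantom-dir ph --out ph_rw
fodfbias --seed 0 track --fodf ph_rw/sub-00_fodf_reweighted.nii.gz \
    --tissue-dir ph/tissue --seed-mask ph/masks/seed_roi.nii.gz \
    --target-mask ph/masks/target_lateral.nii.gz --out trk
fodfbias density --trk trk/streamlines.trk --status trk/status.tsv \
    --ref ph/tissue/wm.nii.gz --out dens
fodfbias hist --before-dir ph --after-dir ph_rw --out hist
```

Every output directory contains `config.yaml` with the effective
configuration, tool version, and input checksums.

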