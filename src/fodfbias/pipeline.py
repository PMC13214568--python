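"""End-to-end phantom experiments: reweight -> track -> measure recovery.

Two headline measurements, mirroring the deep-WM recovery scenario:

* ``ml_fraction_replicates`` — across many independently seeded cohorts,
  the across-subject mean fraction of fODF mass in near-M-L directions
  (|phi| > 81 degrees) in the corridor, before vs after reweighting.  With a
  consistent M-L bundle the fraction should increase in nearly every cohort;
  with the M-L amplitude at zero it should not move systematically.
* ``tracking_experiment`` — per subject, the fraction of streamlines seeded
  at the medial corridor wall that terminate validly in the lateral
  gray-matter target, before vs after reweighting.

Because the reweighting is voxelwise, voxels outside the corridor cannot
influence the corridor mass fraction, so the replicate runner generates and
reweights the corridor voxels only; this is a computational restriction, not
a change of model (the per-voxel generative law is the one in
:mod:`fodfbias.phantom`).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .errors import ParameterError
from .odf_core import (
    DirectionSet,
    OrientationAngles,
    angles_for_set,
    default_sphere,
)
from .phantom import PhantomCohort, PhantomParams, _geometry, subject_wm_profiles
from .reweight import reweight_cohort
from .tracking import StreamlineSet, TrackingParams, propagate, seed_points, VALID

__all__ = [
    "ml_fraction_replicates",
    "paired_sign_test",
    "tracking_experiment",
    "target_reach_fraction",
    "corridor_ml_fractions",
]

ML_PHI_MIN_DEG = 81.0  # outermost two bins of the 20-bin phi histogram


def _ml_dir_mask(angles: OrientationAngles) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        m = np.abs(angles.phi) > ML_PHI_MIN_DEG
    return m & angles.defined


def corridor_ml_fractions(stack_flat: np.ndarray, angles: OrientationAngles) -> np.ndarray:
    """Per-subject M-L mass fraction of a flat (subject, voxel, dir) stack."""
    ml = _ml_dir_mask(angles)
    total = stack_flat.sum(axis=(1, 2), dtype=np.float64)
    ml_mass = stack_flat[:, :, ml].sum(axis=(1, 2), dtype=np.float64)
    if np.any(total <= 0):
        raise ParameterError("a subject has no fODF mass in the region")
    return ml_mass / total


def ml_fraction_replicates(
    params: "PhantomParams | None" = None,
    n_replicates: int = 100,
    base_seed: int = 0,
    directions: "DirectionSet | None" = None,
) -> pd.DataFrame:
    """Before/after corridor M-L mass fractions over seeded cohort replicates.

    Replicate ``r`` uses ``master_seed = base_seed + r``.  Returns one row per
    replicate with columns ``replicate``, ``seed``, ``f_before``, ``f_after``
    (each the across-subject mean fraction), and ``increased``.

    Only corridor voxels are generated: the reweighting is per voxel, so no
    other voxel can affect the corridor statistic.  The division guard is the
    scale-free default computed from the corridor sigma.
    """
    if params is None:
        params = PhantomParams()
    if directions is None:
        directions = default_sphere()
    dirs = directions.vectors
    angles = angles_for_set(directions)
    _, masks = _geometry(params)
    wm = masks["wm"]
    corridor_in_wm = masks["corridor"][wm]
    n_corr = int(corridor_in_wm.sum())
    sub_corr = np.ones(n_corr, dtype=bool)  # corridor voxels are all corridor

    rows = []
    for r in range(n_replicates):
        p_r = replace(params, master_seed=base_seed + r)
        stack = np.empty((p_r.n_subjects, n_corr, dirs.shape[0]), dtype=np.float32)
        for s in range(p_r.n_subjects):
            stack[s] = _corridor_profiles(p_r, s, dirs, corridor_in_wm, sub_corr)
        sigma = stack.std(axis=0, ddof=1, dtype=np.float64)
        eps = 1e-8 * float(np.median(sigma))
        rew = stack / (sigma + eps)[None]
        f_before = float(corridor_ml_fractions(stack, angles).mean())
        f_after = float(corridor_ml_fractions(rew, angles).mean())
        rows.append(
            dict(replicate=r, seed=base_seed + r, f_before=f_before,
                 f_after=f_after, increased=f_after > f_before)
        )
    return pd.DataFrame(rows)


def _corridor_profiles(params, subject_index, dirs, corridor_in_wm, sub_corr):
    """Corridor rows of the subject's WM profile.

    Draws the full WM noise block so the per-voxel values are bit-identical
    to :func:`fodfbias.phantom.subject_wm_profiles`, then keeps the corridor.
    """
    full = subject_wm_profiles(params, subject_index, dirs, corridor_in_wm)
    return full[corridor_in_wm][sub_corr]


def paired_sign_test(before, after, alternative: str = "greater") -> dict:
    """Exact sign test on paired before/after values, ties dropped.

    Returns the number of informative (non-tied) pairs, the number of
    increases, and the binomial p-value against p=1/2.  With no informative
    pairs the p-value is 1 (no evidence of change either way).
    """
    b = np.asarray(before, dtype=np.float64)
    a = np.asarray(after, dtype=np.float64)
    if a.shape != b.shape:
        raise ParameterError("before/after must have matching shapes")
    informative = a != b
    n = int(informative.sum())
    k = int((a > b)[informative].sum())
    if n == 0:
        return {"n": 0, "n_increased": 0, "p_value": 1.0}
    res = binomtest(k, n, 0.5, alternative=alternative)
    return {"n": n, "n_increased": k, "p_value": float(res.pvalue)}


def target_reach_fraction(
    s: StreamlineSet,
    target_mask: np.ndarray,
    affine: np.ndarray,
) -> float:
    """Fraction of all generated streamlines that terminate validly in the target.

    A streamline counts when its status is valid and either endpoint's
    nearest voxel lies in the target mask.  The denominator is the full
    number of generated streamlines (discards included), so the measure
    reflects both validity and specificity of the tracking.
    """
    target_mask = np.asarray(target_mask, dtype=bool)
    if len(s) == 0:
        raise ParameterError("empty streamline set")
    inv = np.linalg.inv(np.asarray(affine, dtype=np.float64))
    shape = np.array(target_mask.shape)
    hits = 0
    for poly, status in zip(s.polylines, s.statuses):
        if status != VALID:
            continue
        pts = np.atleast_2d(poly)[[0, -1]]
        vox = pts @ inv[:3, :3].T + inv[:3, 3]
        idx = np.rint(vox).astype(int)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        if any(target_mask[tuple(i)] for i in idx[ok]):
            hits += 1
    return hits / len(s)


def tracking_experiment(
    phantom_cohort: PhantomCohort,
    tracking_params: "TrackingParams | None" = None,
    reweight_mode: str = "voxelwise",
) -> pd.DataFrame:
    """Seed-to-lateral-target tracking before vs after reweighting.

    Seeds every subject's streamlines from the medial corridor wall
    (``seed_roi``), tracks through the original and the reweighted field
    with identical parameters and RNG seed, and reports per subject the
    fraction of streamlines that validly reach the lateral target.
    """
    if tracking_params is None:
        tracking_params = TrackingParams()
    pc = phantom_cohort
    rew, _sigma = reweight_cohort(pc.cohort, mode=reweight_mode)
    seeds = seed_points(pc.masks["seed_roi"], pc.cohort.affine, tracking_params)
    rows = []
    for s in range(pc.cohort.n_subjects):
        f_before = pc.cohort.subject_field(s)
        f_after = rew.subject_field(s)
        sl_before = propagate(f_before, pc.tissue, seeds, tracking_params)
        sl_after = propagate(f_after, pc.tissue, seeds, tracking_params)
        frac_b = target_reach_fraction(sl_before, pc.masks["target_lateral"], pc.cohort.affine)
        frac_a = target_reach_fraction(sl_after, pc.masks["target_lateral"], pc.cohort.affine)
        rows.append(
            dict(subject=pc.cohort.subject_ids[s], reach_before=frac_b,
                 reach_after=frac_a, increased=frac_a > frac_b)
        )
    return pd.DataFrame(rows)
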