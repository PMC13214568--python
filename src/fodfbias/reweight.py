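"""Cross-subject variance reweighting of fODFs and phi change histograms.

The correction assumes that a real fiber bundle produces consistent fODF
density in its direction across subjects, while density produced by noise
varies from subject to subject.  Dividing each direction's density by its
cross-subject standard deviation therefore boosts consistent (presumed signal)
directions relative to inconsistent (presumed noise) ones.

The effect of the correction is summarized by histograms of the orientation
angle phi of the directions whose probability changed the most: for each
subject the per-(voxel, direction) differences reweighted - original are
split into increases and decreases, thresholded at the median of each pool,
and the phi angles of above-median increases / below-median decreases are
binned over 20 equal bins on [-90, 90] degrees, then averaged across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CardinalityError,
    DivisionGuardError,
    GridMismatchError,
    ParameterError,
)
from .odf_core import DirectionSet, FODFField, OrientationAngles

__all__ = [
    "CohortFODF",
    "StdField",
    "ChangeHistogram",
    "assemble_cohort",
    "cross_subject_std",
    "reweight_fodf",
    "reweight_cohort",
    "change_histogram",
]


@dataclass
class CohortFODF:
    """Subject-aligned stack of fODF fields on one grid and DirectionSet.

    ``stack`` is indexed (subject, i, j, k, direction).  ``roi_mask`` marks
    the voxels that cross-subject statistics are computed for.  Voxelwise use
    assumes the grids are already in correspondence across subjects.
    """

    stack: np.ndarray
    subject_ids: list
    roi_mask: np.ndarray
    affine: np.ndarray
    directions: DirectionSet

    def __post_init__(self):
        s = np.asarray(self.stack)
        if s.ndim != 5:
            raise ParameterError("cohort stack must be 5-D (subject, i, j, k, dir)")
        if s.shape[4] != self.directions.count:
            raise ParameterError("direction axis does not match DirectionSet")
        if len(self.subject_ids) != s.shape[0]:
            raise ParameterError("subject_ids length does not match stack")
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        if self.roi_mask.shape != s.shape[1:4]:
            raise GridMismatchError("roi_mask shape does not match cohort grid")
        self.stack = s
        self.affine = np.asarray(self.affine, dtype=np.float64).reshape(4, 4)

    @property
    def n_subjects(self) -> int:
        return int(self.stack.shape[0])

    def subject_field(self, index: int) -> FODFField:
        return FODFField(
            densities=self.stack[index],
            affine=self.affine,
            directions=self.directions,
            name=str(self.subject_ids[index]),
        )


@dataclass
class StdField:
    """Cross-subject standard deviation sigma(voxel, direction).

    NaN outside the ROI mask (those voxels were not processed).  The sample
    convention (ddof=1) treats subjects as a sample from a population.
    """

    sigma: np.ndarray
    roi_mask: np.ndarray
    ddof_convention: str = "sample (ddof=1)"
    mode: str = "voxelwise"


@dataclass
class ChangeHistogram:
    """Averaged phi histograms of above-median increases / decreases.

    ``increase_counts`` / ``decrease_counts`` are mean per-bin counts across
    subjects over ``n_bins`` equal bins spanning [-90, 90] degrees.  A pool
    that was empty in every subject leaves its histogram all-zero and sets the
    corresponding flag.  Directions with undefined phi are excluded from both
    pooling and binning; the number of excluded entries is recorded.
    """

    bin_edges: np.ndarray
    increase_counts: np.ndarray
    decrease_counts: np.ndarray
    per_subject_medians: list  # (median_increase, median_decrease) per subject
    n_excluded_undefined: int
    increase_flagged: bool = False
    decrease_flagged: bool = False


def assemble_cohort(fields, roi_mask, subject_ids=None) -> CohortFODF:
    """Stack per-subject FODFFields after checking grid/affine/direction equality."""
    fields = list(fields)
    if len(fields) < 2:
        raise CardinalityError("a cohort requires at least 2 subjects")
    ref = fields[0]
    for f in fields[1:]:
        if f.grid_shape != ref.grid_shape:
            raise GridMismatchError("cohort subjects have differing grid shapes")
        if not np.allclose(f.affine, ref.affine):
            raise GridMismatchError("cohort subjects have differing affines")
        if not np.array_equal(f.directions.vectors, ref.directions.vectors):
            raise GridMismatchError("cohort subjects have differing DirectionSets")
    if subject_ids is None:
        subject_ids = [f.name or f"sub-{i:02d}" for i, f in enumerate(fields)]
    stack = np.stack([f.densities for f in fields], axis=0)
    return CohortFODF(
        stack=stack,
        subject_ids=list(subject_ids),
        roi_mask=roi_mask,
        affine=ref.affine,
        directions=ref.directions,
    )


def cross_subject_std(cohort: CohortFODF, mode: str = "voxelwise") -> StdField:
    """Per-direction cross-subject standard deviation inside the ROI.

    ``voxelwise`` (default) computes sigma per (voxel, direction) across
    subjects and requires pre-aligned grids.  ``roi_pooled`` computes one
    sigma per direction over all subjects x all ROI voxels (defensible when
    nearby voxels carry similar directional information) and broadcasts it to
    every ROI voxel.  Voxels outside the ROI are marked NaN (absent).
    """
    if cohort.n_subjects < 2:
        raise CardinalityError("cross-subject std requires at least 2 subjects")
    mask = cohort.roi_mask
    sigma = np.full(cohort.stack.shape[1:], np.nan, dtype=np.float64)
    sub = cohort.stack[:, mask, :]  # (S, V, N), float64 accumulation below
    if mode == "voxelwise":
        sigma[mask] = sub.std(axis=0, ddof=1, dtype=np.float64)
    elif mode == "roi_pooled":
        pooled = sub.reshape(-1, sub.shape[-1]).std(axis=0, ddof=1, dtype=np.float64)
        sigma[mask] = pooled[None, :]
    else:
        raise ParameterError(f"unknown std mode {mode!r}")
    return StdField(sigma=sigma, roi_mask=mask.copy(), mode=mode)


def default_epsilon(sigma_field: StdField) -> float:
    """Scale-free division guard: 1e-8 x median sigma over the ROI."""
    vals = sigma_field.sigma[sigma_field.roi_mask]
    med = float(np.nanmedian(vals)) if vals.size else 0.0
    return 1e-8 * med


def reweight_fodf(
    subject_fodf: FODFField,
    sigma: StdField,
    epsilon: "float | None" = None,
) -> FODFField:
    """Divide each direction's density by its cross-subject std inside the ROI.

    ``out(v, d) = in(v, d) / (sigma(v, d) + epsilon)`` for ROI voxels; voxels
    outside the ROI pass through unchanged.  The output is deliberately not
    renormalized — normalization happens only when the tracker converts a
    voxel to sampling probabilities.  ``epsilon=None`` selects the scale-free
    default guard (1e-8 x median ROI sigma); ``epsilon=0`` with any exact-zero
    sigma inside the ROI raises DivisionGuardError naming the first offender.
    """
    if subject_fodf.grid_shape != sigma.sigma.shape[:3]:
        raise GridMismatchError("fODF and sigma grids differ")
    if subject_fodf.densities.shape[3] != sigma.sigma.shape[3]:
        raise GridMismatchError("fODF and sigma direction axes differ")
    if epsilon is None:
        epsilon = default_epsilon(sigma)
    if epsilon < 0:
        raise ParameterError("epsilon must be nonnegative")
    mask = sigma.roi_mask
    sig = sigma.sigma[mask]
    if epsilon == 0.0 and np.any(sig == 0.0):
        vox = np.argwhere(mask)[np.where((sig == 0.0).any(axis=1))[0][0]]
        raise DivisionGuardError(
            f"sigma is exactly zero inside the ROI (first at voxel {tuple(int(c) for c in vox)}) "
            "and epsilon is 0; pass a positive epsilon"
        )
    out = np.array(subject_fodf.densities, dtype=np.float64, copy=True)
    out[mask] = out[mask] / (sig + epsilon)
    if not np.all(np.isfinite(out[mask])):
        raise DivisionGuardError("reweighted field is not finite inside the ROI")
    return FODFField(
        densities=out,
        affine=subject_fodf.affine,
        directions=subject_fodf.directions,
        name=(subject_fodf.name + "_reweighted") if subject_fodf.name else "reweighted",
    )


def reweight_cohort(
    cohort: CohortFODF,
    mode: str = "voxelwise",
    epsilon: "float | None" = None,
):
    """Reweight every subject of a cohort by the cohort's own sigma.

    Returns ``(reweighted_cohort, sigma_field)``.
    """
    sigma = cross_subject_std(cohort, mode=mode)
    if epsilon is None:
        epsilon = default_epsilon(sigma)
    mask = cohort.roi_mask
    sig = sigma.sigma[mask]
    out = np.array(cohort.stack, copy=True)  # preserves the stack dtype
    inv = 1.0 / (sig + epsilon)
    for s in range(out.shape[0]):  # per subject keeps the temporary small
        out[s][mask] = out[s][mask] * inv
    rew = CohortFODF(
        stack=out,
        subject_ids=list(cohort.subject_ids),
        roi_mask=mask.copy(),
        affine=cohort.affine,
        directions=cohort.directions,
    )
    return rew, sigma


def _as_stack(obj) -> np.ndarray:
    if isinstance(obj, CohortFODF):
        return obj.stack
    if isinstance(obj, FODFField):
        return obj.densities[None]
    a = np.asarray(obj)
    if a.ndim == 4:
        return a[None]
    if a.ndim == 5:
        return a
    raise ParameterError("expected an FODFField, CohortFODF, or 4/5-D array")


def change_histogram(
    before,
    after,
    angles: OrientationAngles,
    roi_mask: np.ndarray,
    n_bins: int = 20,
    as_probability: bool = True,
) -> ChangeHistogram:
    """Histogram the phi angles of the largest density changes per subject.

    Per subject: (1) difference after - before per (voxel, direction) over the
    ROI; (2) split into increases (> 0) and decreases (< 0); (3) pool each
    sign over all ROI voxels and directions and take the pool median as
    threshold; (4) histogram the phi of directions with strictly above-median
    increases, and separately strictly below-median (most negative) decreases,
    over ``n_bins`` equal bins on [-90, 90]; (5) average counts across
    subjects.  Thresholding is strict on both sides so the median element
    itself is never counted.

    ``as_probability`` (default) normalizes each voxel's density vector to
    unit sum in both fields before differencing, so the comparison is between
    probability profiles rather than raw amplitudes — the reweighted field
    carries an arbitrary global scale (1/sigma), which would otherwise make
    every difference positive.  Voxels with no positive mass are skipped.

    An empty pool yields an all-zero histogram with the corresponding flag
    set, not an exception.
    """
    b = _as_stack(before).astype(np.float64)
    a = _as_stack(after).astype(np.float64)
    if a.shape != b.shape:
        raise GridMismatchError("before/after stacks have different shapes")
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != b.shape[1:4]:
        raise GridMismatchError("roi_mask does not match the field grid")
    if b.shape[4] != angles.phi.shape[0]:
        raise ParameterError("angles do not match the direction axis")
    if n_bins < 2:
        raise ParameterError("n_bins must be at least 2")

    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    defined = angles.defined
    phi = angles.phi

    n_sub = b.shape[0]
    inc_hists = np.zeros((n_sub, n_bins))
    dec_hists = np.zeros((n_sub, n_bins))
    medians = []
    n_excluded = 0
    inc_empty = np.zeros(n_sub, dtype=bool)
    dec_empty = np.zeros(n_sub, dtype=bool)

    bsel = b[:, roi_mask, :]  # (S, V, N)
    asel = a[:, roi_mask, :]
    for s in range(n_sub):
        bs, as_ = bsel[s], asel[s]
        if as_probability:
            bs = np.clip(bs, 0.0, None)
            as_ = np.clip(as_, 0.0, None)
            bsum = bs.sum(axis=1, keepdims=True)
            asum = as_.sum(axis=1, keepdims=True)
            ok = (bsum[:, 0] > 0) & (asum[:, 0] > 0)
            bs = bs[ok] / bsum[ok]
            as_ = as_[ok] / asum[ok]
        diff = as_ - bs  # (V, N)
        n_excluded += int(diff.shape[0] * (~defined).sum())
        diff = diff[:, defined]
        phid = phi[defined]
        pos = diff[diff > 0]
        neg = diff[diff < 0]
        med_pos = float(np.median(pos)) if pos.size else np.nan
        med_neg = float(np.median(neg)) if neg.size else np.nan
        medians.append((med_pos, med_neg))
        if pos.size:
            sel = diff > med_pos
            vals = np.broadcast_to(phid, diff.shape)[sel]
            inc_hists[s] = np.histogram(vals, bins=edges)[0]
        else:
            inc_empty[s] = True
        if neg.size:
            sel = diff < med_neg
            vals = np.broadcast_to(phid, diff.shape)[sel]
            dec_hists[s] = np.histogram(vals, bins=edges)[0]
        else:
            dec_empty[s] = True

    return ChangeHistogram(
        bin_edges=edges,
        increase_counts=inc_hists.mean(axis=0),
        decrease_counts=dec_hists.mean(axis=0),
        per_subject_medians=medians,
        n_excluded_undefined=n_excluded,
        increase_flagged=bool(inc_empty.all()),
        decrease_flagged=bool(dec_empty.all()),
    )
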