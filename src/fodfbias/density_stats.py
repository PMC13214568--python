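"""Streamline-density volumes, ROI summaries, and direction/bundle fractions.

Streamline density in a voxel is the number of *valid* streamlines passing
that voxel divided by the total number of valid streamlines, so values lie in
[0, 1].  "Passing" uses set semantics — a streamline contributes at most once
per voxel however often it re-enters — and voxel traversal is exact: each
polyline segment is walked with a 3-D digital differential analyzer
(Amanatides-Woo) over the voxel grid, so thin diagonal crossings are counted
even when no polyline vertex falls inside the voxel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CardinalityError, MaskError, ParameterError
from .tracking import StreamlineSet, VALID

__all__ = [
    "DensityVolume",
    "streamline_density",
    "roi_share",
    "wm_normalized_density",
    "direction_fractions",
    "bundle_overlap_fractions",
    "traverse_voxels",
]

logger = logging.getLogger(__name__)


@dataclass
class DensityVolume:
    """Per-voxel fraction of valid streamlines traversing the voxel."""

    density: np.ndarray
    n_valid_streamlines: int
    affine: np.ndarray

    def __post_init__(self):
        self.density = np.asarray(self.density, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64).reshape(4, 4)


def traverse_voxels(p0: np.ndarray, p1: np.ndarray, shape) -> list:
    """Voxels crossed by the segment p0 -> p1, in voxel coordinates.

    Voxel centers sit at integer coordinates, so voxel ``i`` spans
    ``[i - 0.5, i + 0.5)``.  Amanatides-Woo traversal; voxels outside the
    grid are skipped.  Endpoint voxels are included.
    """
    shape = tuple(int(s) for s in shape)
    # shift so that voxel boundaries sit at integers
    a = np.asarray(p0, dtype=np.float64) + 0.5
    b = np.asarray(p1, dtype=np.float64) + 0.5
    d = b - a
    cur = np.floor(a).astype(int)
    end = np.floor(b).astype(int)
    step = np.where(d > 0, 1, np.where(d < 0, -1, 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_delta = np.where(d != 0, np.abs(1.0 / d), np.inf)
        next_bound = np.where(step > 0, np.floor(a) + 1.0, np.floor(a))
        t_max = np.where(d != 0, (next_bound - a) / d, np.inf)
    out = []

    def _maybe(v):
        if all(0 <= v[i] < shape[i] for i in range(3)):
            out.append((int(v[0]), int(v[1]), int(v[2])))

    _maybe(cur)
    # bounded walk: at most the Manhattan distance between end voxels
    for _ in range(int(np.abs(end - cur).sum())):
        axis = int(np.argmin(t_max))
        cur[axis] += step[axis]
        t_max[axis] += t_delta[axis]
        _maybe(cur)
        if np.array_equal(cur, end):
            break
    return out


def streamline_density(
    s: StreamlineSet,
    grid_shape,
    affine: np.ndarray,
) -> DensityVolume:
    """Density volume from the valid streamlines of a StreamlineSet.

    Discarded streamlines are ignored entirely; duplicating every streamline
    leaves the result unchanged (both counts and the normalizer double).
    """
    affine = np.asarray(affine, dtype=np.float64)
    inv = np.linalg.inv(affine)
    valid = s.valid_polylines()
    n_valid = len(valid)
    if n_valid == 0:
        raise CardinalityError("no valid streamlines to accumulate")
    counts = np.zeros(tuple(grid_shape), dtype=np.int64)
    for poly in valid:
        pts = np.atleast_2d(np.asarray(poly, dtype=np.float64))
        vox_pts = pts @ inv[:3, :3].T + inv[:3, 3]
        visited = set()
        if len(vox_pts) == 1:
            visited.update(traverse_voxels(vox_pts[0], vox_pts[0], grid_shape))
        for i in range(len(vox_pts) - 1):
            visited.update(traverse_voxels(vox_pts[i], vox_pts[i + 1], grid_shape))
        for v in visited:
            counts[v] += 1
    return DensityVolume(
        density=counts / float(n_valid),
        n_valid_streamlines=n_valid,
        affine=affine,
    )


def roi_share(
    d: DensityVolume,
    targets: dict,
    seed_label: str = "seed",
) -> pd.DataFrame:
    """Mean density per target ROI, normalized over all targets.

    ``targets`` maps label -> binary mask.  Masks must be pairwise disjoint.
    Shares are each target's mean density divided by the sum of means, so
    they add to 1 for the seed; if every mean is zero the shares are NaN and
    the ``flagged`` column is set.  Invariant to global rescaling of the
    density volume.
    """
    if not targets:
        raise MaskError("no target masks given")
    masks = {}
    total_cover = np.zeros(d.density.shape, dtype=np.int64)
    for label, m in targets.items():
        m = np.asarray(m, dtype=bool)
        if m.shape != d.density.shape:
            raise MaskError(f"target {label!r} shape does not match the grid")
        if not m.any():
            raise MaskError(f"target {label!r} is empty")
        masks[label] = m
        total_cover += m
    if total_cover.max() > 1:
        raise MaskError("target masks overlap")
    means = {label: float(d.density[m].mean()) for label, m in masks.items()}
    total = sum(means.values())
    flagged = total == 0.0
    rows = []
    for label, mean in means.items():
        share = np.nan if flagged else mean / total
        rows.append(
            dict(seed_label=seed_label, target_label=label,
                 raw_mean_density=mean, normalized_share=share, flagged=flagged)
        )
    table = pd.DataFrame(rows)
    table.attrs["normalization_mode"] = "over_targets"
    return table


def wm_normalized_density(d: DensityVolume, roi: np.ndarray, wm: np.ndarray) -> float:
    """Cross-voxel mean density in the ROI relative to the whole-WM mean.

    Any log transform for downstream statistics is left to the caller.
    """
    roi = np.asarray(roi, dtype=bool)
    wm = np.asarray(wm, dtype=bool)
    if not roi.any():
        raise MaskError("roi mask is empty")
    if not wm.any():
        raise MaskError("wm mask is empty")
    wm_mean = float(d.density[wm].mean())
    if wm_mean == 0.0:
        raise ParameterError("WM mean density is zero; normalization undefined")
    return float(d.density[roi].mean()) / wm_mean


def direction_fractions(v1_rgb: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """ROI-average fractions of the three direction channels (M-L, A-P, S-I).

    Each voxel's nonnegative channel weights are normalized to sum 1, then
    averaged over the ROI; voxels whose channels are all zero are excluded
    (the count is logged).  The output sums to 1.
    """
    v1 = np.asarray(v1_rgb, dtype=np.float64)
    if v1.ndim != 4 or v1.shape[3] != 3:
        raise ParameterError("v1_rgb must be 4-D with 3 channels")
    if v1.min() < 0:
        raise ParameterError("channel weights must be nonnegative")
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise MaskError("roi mask is empty")
    vals = v1[roi]                      # (V, 3)
    sums = vals.sum(axis=1)
    ok = sums > 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("direction_fractions: excluded %d all-zero voxels", n_excluded)
    if not ok.any():
        raise MaskError("all ROI voxels have zero direction weights")
    frac = (vals[ok] / sums[ok, None]).mean(axis=0)
    return frac / frac.sum()


def bundle_overlap_fractions(bundle_masks: dict, roi: np.ndarray) -> dict:
    """Per-bundle share of the total bundle volume overlapping the ROI.

    ``|bundle & roi|`` divided by the sum over bundles; bundles may overlap
    each other, so the fractions sum to 1 by construction over the given set.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise MaskError("roi mask is empty")
    overlaps = {}
    for label, m in bundle_masks.items():
        m = np.asarray(m, dtype=bool)
        if m.shape != roi.shape:
            raise MaskError(f"bundle {label!r} shape does not match the ROI grid")
        overlaps[label] = int((m & roi).sum())
    total = sum(overlaps.values())
    if total == 0:
        raise MaskError("no bundle overlaps the ROI")
    return {label: n / total for label, n in overlaps.items()}
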