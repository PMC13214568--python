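"""Minimal deterministic and probabilistic streamline propagation.

Anatomically constrained, rejection-based tracking: tissue fraction maps
(GM/WM/CSF) decide where a streamline terminates validly (gray matter), where
it is discarded (CSF entry), and the turning angle between consecutive steps
is capped (default 30 degrees) — a streamline that cannot continue within the
angular cone is discarded rather than back-tracked.

Propagation is bidirectional from each seed: an initial direction is chosen
from the seed voxel's fODF and both polarities are tracked, then concatenated.
Tissue fractions are interpolated trilinearly at step points; fODFs are looked
up at the nearest voxel (interpolating hundreds of directions per step buys
nothing at phantom scale).  Deterministic mode follows the largest admissible
density; probabilistic mode samples the next direction from the voxel's
sampling probabilities restricted to the admissible cone.  Both modes are
bit-stable: deterministic always, probabilistic given the RNG seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import GridMismatchError, MaskError, ParameterError
from .odf_core import FODFField

__all__ = [
    "TissueMaps",
    "TrackingParams",
    "StreamlineSet",
    "seed_points",
    "propagate",
    "classify_termination",
    "VALID",
    "DISCARD_CSF",
    "DISCARD_ANGLE",
    "DISCARD_LENGTH",
    "DISCARD_DEGENERATE",
]

VALID = "valid_gm_termination"
DISCARD_CSF = "discarded_csf"
DISCARD_ANGLE = "discarded_angle"
DISCARD_LENGTH = "discarded_length"
DISCARD_DEGENERATE = "discarded_degenerate"

ALL_STATUSES = (VALID, DISCARD_CSF, DISCARD_ANGLE, DISCARD_LENGTH, DISCARD_DEGENERATE)


@dataclass
class TissueMaps:
    """GM/WM/CSF fraction volumes on the fODF grid (each in [0, 1])."""

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.gm = np.asarray(self.gm, dtype=np.float64)
        self.wm = np.asarray(self.wm, dtype=np.float64)
        self.csf = np.asarray(self.csf, dtype=np.float64)
        if not (self.gm.shape == self.wm.shape == self.csf.shape):
            raise GridMismatchError("tissue maps must share one grid")
        total = self.gm + self.wm + self.csf
        if total.max() > 1.0 + 1e-6:
            raise ParameterError("tissue fractions exceed 1 in some voxel")
        if min(self.gm.min(), self.wm.min(), self.csf.min()) < 0:
            raise ParameterError("tissue fractions must be nonnegative")
        self.affine = np.asarray(self.affine, dtype=np.float64).reshape(4, 4)

    @property
    def shape(self):
        return self.gm.shape


@dataclass
class TrackingParams:
    """Propagation parameters.

    ``step_size_mm=None`` resolves to half the smallest voxel edge.  The
    turning-angle cap (default 30 degrees) discards streamlines that would
    curve more sharply between consecutive steps.  Six seeds per voxel at
    uniformly random in-voxel locations is the default seeding density.
    """

    step_size_mm: "float | None" = None
    max_angle_deg: float = 30.0
    seeds_per_voxel: int = 6
    max_steps: int = 1000
    mode: str = "probabilistic"
    rng_seed: int = 0
    gm_stop: float = 0.5
    csf_stop: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.max_angle_deg < 90.0):
            raise ParameterError("max_angle_deg must be in (0, 90)")
        if self.seeds_per_voxel < 1:
            raise ParameterError("seeds_per_voxel must be >= 1")
        if self.max_steps < 1:
            raise ParameterError("max_steps must be >= 1")
        if self.mode not in ("deterministic", "probabilistic"):
            raise ParameterError("mode must be deterministic or probabilistic")
        if self.step_size_mm is not None and self.step_size_mm <= 0:
            raise ParameterError("step_size_mm must be positive")

    def resolve_step(self, affine: np.ndarray) -> float:
        if self.step_size_mm is not None:
            return float(self.step_size_mm)
        edges = np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)
        return 0.5 * float(edges.min())


@dataclass
class StreamlineSet:
    """Polylines in world coordinates with per-streamline status and seed."""

    polylines: list                # list of (n_points, 3) float64 arrays
    statuses: list                 # one of ALL_STATUSES per streamline
    seeds: np.ndarray              # (n, 3) world seed points
    step_size_mm: float = 0.0

    def __len__(self):
        return len(self.polylines)

    @property
    def n_valid(self) -> int:
        return sum(1 for s in self.statuses if s == VALID)

    def valid_polylines(self):
        return [p for p, s in zip(self.polylines, self.statuses) if s == VALID]


def seed_points(mask: np.ndarray, affine: np.ndarray, params: TrackingParams) -> np.ndarray:
    """Uniform random points inside each mask voxel, ``seeds_per_voxel`` each.

    Voxels are visited in index order and points are drawn from one seeded
    generator, so the full list is reproducible from ``params.rng_seed``.
    Returns world coordinates, shape (n_voxels * seeds_per_voxel, 3).
    """
    mask = np.asarray(mask, dtype=bool)
    vox = np.argwhere(mask)
    if vox.size == 0:
        raise MaskError("seed mask is empty")
    rng = np.random.default_rng(params.rng_seed)
    k = params.seeds_per_voxel
    offsets = rng.uniform(-0.5, 0.5, size=(vox.shape[0], k, 3))
    pts_vox = vox[:, None, :] + offsets                    # voxel coords
    pts_vox = pts_vox.reshape(-1, 3)
    affine = np.asarray(affine, dtype=np.float64)
    return pts_vox @ affine[:3, :3].T + affine[:3, 3]


def _interp(volume: np.ndarray, vox_pts: np.ndarray) -> np.ndarray:
    """Trilinear interpolation at voxel coordinates (centers at integers).

    Points beyond the grid take the nearest edge value, so the boundary
    tissue governs the first out-of-volume step.
    """
    pts = np.atleast_2d(vox_pts)
    return map_coordinates(volume, pts.T, order=1, mode="nearest")


class _Propagator:
    """Shared precomputation for tracking through one field."""

    def __init__(self, f: FODFField, tissue: TissueMaps, params: TrackingParams):
        if f.grid_shape != tissue.shape:
            raise GridMismatchError("fODF and tissue grids differ")
        if not np.allclose(f.affine, tissue.affine):
            raise GridMismatchError("fODF and tissue affines differ")
        self.f = f
        self.tissue = tissue
        self.params = params
        self.dirs = f.directions.vectors                       # (N, 3)
        dot = self.dirs @ self.dirs.T
        cos_max = np.cos(np.radians(params.max_angle_deg))
        self.cone = np.abs(dot) >= cos_max - 1e-12             # admissible pairs
        self.sign = np.where(dot >= 0, 1.0, -1.0)
        self.antipode = np.argmin(dot, axis=1)                 # index of -d
        self.inv_affine = np.linalg.inv(f.affine)
        self.step = params.resolve_step(f.affine)
        self.dens = np.clip(np.asarray(f.densities, dtype=np.float64), 0.0, None)
        self.shape = np.array(f.grid_shape)

    def world_to_voxel(self, p: np.ndarray) -> np.ndarray:
        return self.inv_affine[:3, :3] @ p + self.inv_affine[:3, 3]

    def in_bounds(self, v: np.ndarray) -> bool:
        return bool(np.all(v >= -0.5) and np.all(v <= self.shape - 0.5))

    def tissue_at(self, v: np.ndarray):
        gm = float(_interp(self.tissue.gm, v)[0])
        csf = float(_interp(self.tissue.csf, v)[0])
        return gm, csf

    def densities_at(self, v: np.ndarray) -> np.ndarray:
        idx = np.clip(np.rint(v).astype(int), 0, self.shape - 1)
        return self.dens[idx[0], idx[1], idx[2]]

    def _half(self, seed_w, dir_idx, polarity, rng):
        """Track one polarity from the seed; returns (points, reason)."""
        p = self.params
        pos = np.asarray(seed_w, dtype=np.float64)
        u_idx, u_sign = dir_idx, polarity
        points = []
        for _ in range(p.max_steps):
            u = u_sign * self.dirs[u_idx]
            new = pos + self.step * u
            v = self.world_to_voxel(new)
            gm, csf = self.tissue_at(v)
            if csf > p.csf_stop:
                return points, DISCARD_CSF
            if not self.in_bounds(v):
                return points, DISCARD_LENGTH
            points.append(new)
            if gm > p.gm_stop:
                return points, VALID
            dens = self.densities_at(v)
            if dens.sum() <= 0.0:
                return points, DISCARD_DEGENERATE
            w = dens * self.cone[u_idx]
            total = w.sum()
            if total <= 0.0:
                return points, DISCARD_ANGLE
            if p.mode == "deterministic":
                nxt = int(np.argmax(w))
            else:
                c = np.cumsum(w)
                nxt = int(np.searchsorted(c, rng.random() * c[-1], side="right"))
                nxt = min(nxt, len(w) - 1)
            u_sign = u_sign * self.sign[u_idx, nxt]
            u_idx = nxt
            pos = new
        return points, DISCARD_LENGTH

    def track_seed(self, seed_w, rng):
        p = self.params
        v = self.world_to_voxel(np.asarray(seed_w, dtype=np.float64))
        if not self.in_bounds(v):
            raise ParameterError(f"seed point {seed_w} outside the volume")
        dens = self.densities_at(v)
        if dens.sum() <= 0.0:
            return np.asarray([seed_w]), DISCARD_DEGENERATE
        if p.mode == "deterministic":
            first = int(np.argmax(dens))
        else:
            c = np.cumsum(dens)
            first = int(np.searchsorted(c, rng.random() * c[-1], side="right"))
            first = min(first, len(dens) - 1)
        # a direction and its antipode define the same line: canonicalize so
        # both modes emit the two halves in the same order
        first = min(first, int(self.antipode[first]))
        pts_a, reason_a = self._half(seed_w, first, +1.0, rng)
        pts_b, reason_b = self._half(seed_w, first, -1.0, rng)
        poly = np.asarray(list(reversed(pts_b)) + [np.asarray(seed_w, float)] + pts_a)
        status = _combine(reason_a, reason_b)
        return poly, status


def _combine(reason_a: str, reason_b: str) -> str:
    """Merge the two half-streamline outcomes into one status.

    Any discard condition on either half discards the whole streamline; the
    more informative discard reason wins (CSF entry over angle violation over
    degenerate voxel over length/bounds).  Valid requires both ends in GM.
    """
    reasons = {reason_a, reason_b}
    for r in (DISCARD_CSF, DISCARD_ANGLE, DISCARD_DEGENERATE, DISCARD_LENGTH):
        if r in reasons:
            return r
    return VALID


def propagate(
    f: FODFField,
    tissue: TissueMaps,
    seeds: np.ndarray,
    params: TrackingParams,
) -> StreamlineSet:
    """Bidirectional propagation from every seed point.

    Returns one streamline per seed; statuses partition the set.  See the
    module docstring for the stepping, stopping, and discard rules.
    """
    prop = _Propagator(f, tissue, params)
    rng = np.random.default_rng(params.rng_seed)
    seeds = np.atleast_2d(np.asarray(seeds, dtype=np.float64))
    polylines, statuses = [], []
    for s in seeds:
        poly, status = prop.track_seed(s, rng)
        polylines.append(poly)
        statuses.append(status)
    return StreamlineSet(
        polylines=polylines, statuses=statuses, seeds=seeds.copy(),
        step_size_mm=prop.step,
    )


def classify_termination(
    streamline: np.ndarray,
    tissue: TissueMaps,
    gm_stop: float = 0.5,
    csf_stop: float = 0.5,
    discard_trace: "str | None" = None,
) -> str:
    """Status of a finished streamline from its endpoint and discard trace.

    Pure and idempotent: a recorded discard reason wins outright; otherwise
    the final point's interpolated tissue fractions decide — CSF above
    threshold discards, GM above threshold is a valid termination, anything
    else means the step budget ran out inside WM.
    """
    if discard_trace is not None:
        if discard_trace not in ALL_STATUSES:
            raise ParameterError(f"unknown discard trace {discard_trace!r}")
        if discard_trace != VALID:
            return discard_trace
    pts = np.atleast_2d(np.asarray(streamline, dtype=np.float64))
    inv = np.linalg.inv(tissue.affine)
    v = inv[:3, :3] @ pts[-1] + inv[:3, 3]
    gm = float(_interp(tissue.gm, v)[0])
    csf = float(_interp(tissue.csf, v)[0])
    if csf > csf_stop:
        return DISCARD_CSF
    if gm > gm_stop:
        return VALID
    return DISCARD_LENGTH
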