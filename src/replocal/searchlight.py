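"""Spherical searchlight neighborhoods and a generic mapping engine.

A searchlight sweeps a small sphere of voxels over the analysis mask so that
every in-mask gray-matter voxel serves as a center exactly once; a
multivariate statistic computed on the sphere's patterns is assigned to the
center voxel.  The default radius of 3.0 voxels yields the canonical
123-voxel spherical neighborhood on the integer lattice (the count is
constant for any radius in [3, sqrt(10))).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid import MaskVolume, StatMap, SubjectBetaSet

log = logging.getLogger(__name__)

DEFAULT_RADIUS_VOX = 3.0


def sphere_offsets(radius_vox: float) -> np.ndarray:
    """Integer lattice offsets (dx,dy,dz) with Euclidean norm <= radius.

    Returned in deterministic lexicographic order; always includes (0,0,0).
    """
    if radius_vox < 0:
        raise ValueError(f"radius must be nonnegative, got {radius_vox}")
    r = int(np.floor(radius_vox))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius_vox**2
    offsets = np.column_stack([dx[keep], dy[keep], dz[keep]])
    order = np.lexsort((offsets[:, 2], offsets[:, 1], offsets[:, 0]))
    return offsets[order]


@dataclass
class SearchlightSpec:
    """Sphere radius (voxel units) with precomputed lattice offsets."""

    radius_vox: float = DEFAULT_RADIUS_VOX
    min_members: int = 10
    offsets: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.offsets is None:
            self.offsets = sphere_offsets(self.radius_vox)

    @property
    def n_offsets(self) -> int:
        return len(self.offsets)


@dataclass
class Neighborhoods:
    """One neighborhood per in-mask center, members as in-mask vector indices."""

    members: list          # per center: int array of in-mask indices
    flagged: np.ndarray    # True where |members| < spec.min_members
    spec: SearchlightSpec

    def __len__(self):
        return len(self.members)


def neighborhoods(mask: MaskVolume, spec: SearchlightSpec = None,
                  valid: np.ndarray = None) -> Neighborhoods:
    """Spherical neighborhoods clipped to the grid and to the mask.

    ``valid`` optionally excludes flagged voxels (e.g. zero-variance) from
    membership while still emitting a neighborhood for every in-mask center.
    """
    if spec is None:
        spec = SearchlightSpec()
    dims = np.asarray(mask.grid.dims)
    # in-mask vector index at each grid position, -1 elsewhere / invalid
    idx_vol = np.full(mask.grid.dims, -1, dtype=np.int64)
    keep = np.ones(mask.n_voxels, dtype=bool) if valid is None else np.asarray(valid, bool)
    flat = idx_vol.ravel()
    flat[mask.indices[keep]] = np.flatnonzero(keep)
    centers = mask.ijk
    n = centers.shape[0]
    member_table = np.full((n, spec.n_offsets), -1, dtype=np.int64)
    for k, off in enumerate(spec.offsets):
        pos = centers + off
        inside = np.all((pos >= 0) & (pos < dims), axis=1)
        lin = np.ravel_multi_index(pos[inside].T, mask.grid.dims)
        member_table[inside, k] = flat[lin]
    members = [row[row >= 0] for row in member_table]
    flagged = np.array([m.size < spec.min_members for m in members])
    if flagged.any():
        log.info("%d neighborhood(s) smaller than %d members flagged",
                 int(flagged.sum()), spec.min_members)
    return Neighborhoods(members, flagged, spec)


def run_searchlight(betasets, fn, spec: SearchlightSpec = None,
                    centers: np.ndarray = None, kind: str = "stat"):
    """Map ``fn`` over every searchlight neighborhood.

    ``fn(submatrices, members)`` receives the per-subject pattern
    submatrices (stimuli x neighborhood voxels) and must return either a
    scalar (one group map) or a length-n_subjects vector (per-subject maps).
    Failures at a center yield NaN there and are logged with the center's
    voxel coordinate.  ``centers`` optionally restricts evaluation to a
    subset of in-mask vector indices (e.g. an ROI), leaving NaN elsewhere.
    """
    if isinstance(betasets, SubjectBetaSet):
        betasets = [betasets]
    mask = betasets[0].mask
    for b in betasets[1:]:
        if not b.mask.grid.matches(mask.grid) or not np.array_equal(
            b.mask.indices, mask.indices
        ):
            raise ValueError(f"subject {b.subject_id} is not on the shared mask")
    valid = np.logical_and.reduce([b.valid_voxels for b in betasets])
    nbh = neighborhoods(mask, spec, valid=valid)
    n_centers = len(nbh)
    todo = range(n_centers) if centers is None else np.asarray(centers, int)
    out = None
    ijk = mask.ijk
    for c in todo:
        m = nbh.members[c]
        if m.size < 2:
            continue
        try:
            res = fn([b.beta[:, m] for b in betasets], m)
        except Exception as exc:
            log.warning("searchlight center %s failed: %s", tuple(ijk[c]), exc)
            continue
        res = np.atleast_1d(np.asarray(res, dtype=float))
        if out is None:
            out = np.full((res.size, n_centers), np.nan)
        out[:, c] = res
    if out is None:
        out = np.full((1, n_centers), np.nan)
    maps = [StatMap(mask, row, kind) for row in out]
    return maps[0] if len(maps) == 1 else maps
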