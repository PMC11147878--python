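"""Volume geometry, NIfTI/TSV I/O, smoothing, cluster labeling, peaks, hemispheres.

Conventions
-----------
World coordinates come from the NIfTI affine (RAS-like: world x increases to
the anatomical right), so voxels with world x < 0 belong to the left
hemisphere and x > 0 to the right.  Volumes are written as 32-bit float,
masks as 8-bit integers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

log = logging.getLogger(__name__)

#: required columns of a stimulus table
STIM_TABLE_COLUMNS = ("stimulus_id", "word", "transcription", "word_id")

#: 3D structuring elements by neighbor count
CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


class GridMismatchError(ValueError):
    """Two volumes that must share a grid do not."""


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a 3D voxel grid: shape plus a voxel-to-world affine."""

    dims: tuple[int, int, int]
    affine: np.ndarray  # 4x4 voxel -> world (mm)

    def __post_init__(self):
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if any(d < 1 for d in self.dims):
            raise ValueError(f"all grid dims must be >= 1, got {self.dims}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "affine", affine)
        vs = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
        if np.any(vs <= 0):
            raise ValueError(f"voxel sizes must be positive, got {vs}")

    @property
    def voxel_size(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def matches(self, other: "VolumeGrid", atol: float = 1e-4) -> bool:
        return self.dims == other.dims and np.allclose(
            self.affine, other.affine, atol=atol
        )


def centered_grid(dims, voxel_size=3.0) -> VolumeGrid:
    """Grid whose world origin sits at the volume center (RAS axes)."""
    dims = tuple(int(d) for d in dims)
    vs = np.broadcast_to(np.asarray(voxel_size, float), (3,))
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vs)
    affine[:3, 3] = -vs * (np.asarray(dims) - 1) / 2.0
    return VolumeGrid(dims, affine)


@dataclass
class MaskVolume:
    """Boolean voxel mask with a bijective linear index over in-mask voxels."""

    grid: VolumeGrid
    data: np.ndarray  # bool, shape == grid.dims

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != self.grid.dims:
            raise GridMismatchError(
                f"mask shape {self.data.shape} != grid dims {self.grid.dims}"
            )
        if not self.data.any():
            raise ValueError("mask has no in-mask voxels")
        # linear (C-order) indices of in-mask voxels; position in this array
        # is the canonical in-mask index used by beta matrices and stat maps
        self.indices = np.flatnonzero(self.data.ravel())

    @property
    def n_voxels(self) -> int:
        return int(self.indices.size)

    @property
    def ijk(self) -> np.ndarray:
        """(n_voxels, 3) integer voxel coordinates of in-mask voxels."""
        return np.column_stack(np.unravel_index(self.indices, self.grid.dims))

    def world_coords(self) -> np.ndarray:
        return self.grid.voxel_to_world(self.ijk)

    def embed(self, values: np.ndarray, fill=0.0) -> np.ndarray:
        """Scatter a per-in-mask-voxel vector back into a full 3D volume."""
        values = np.asarray(values)
        if values.shape != (self.n_voxels,):
            raise ValueError(
                f"expected {self.n_voxels} values, got shape {values.shape}"
            )
        vol = np.full(self.grid.dims, fill, dtype=float).ravel()
        vol[self.indices] = values
        return vol.reshape(self.grid.dims)

    def extract(self, volume: np.ndarray) -> np.ndarray:
        if volume.shape != self.grid.dims:
            raise GridMismatchError(
                f"volume shape {volume.shape} != grid dims {self.grid.dims}"
            )
        return volume.ravel()[self.indices]


@dataclass
class SubjectBetaSet:
    """Per-subject stimulus-by-voxel activation estimates on a masked grid.

    ``valid_voxels`` flags voxels usable downstream; all-constant columns are
    flagged invalid at construction (and by z-scoring for zero variance).
    """

    subject_id: str
    mask: MaskVolume
    beta: np.ndarray  # (n_stimuli, n_voxels)
    stimulus_ids: np.ndarray
    valid_voxels: np.ndarray = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.stimulus_ids = np.asarray(self.stimulus_ids)
        if self.beta.ndim != 2:
            raise ValueError("beta must be 2D (stimuli x voxels)")
        if self.beta.shape[1] != self.mask.n_voxels:
            raise GridMismatchError(
                f"beta has {self.beta.shape[1]} voxel columns but the mask "
                f"has {self.mask.n_voxels} in-mask voxels"
            )
        if self.beta.shape[0] != self.stimulus_ids.size:
            raise ValueError(
                f"beta has {self.beta.shape[0]} rows but "
                f"{self.stimulus_ids.size} stimulus ids were given"
            )
        if self.valid_voxels is None:
            constant = np.ptp(self.beta, axis=0) == 0
            if constant.any():
                log.warning(
                    "subject %s: %d all-constant voxel(s) flagged invalid",
                    self.subject_id, int(constant.sum()),
                )
            self.valid_voxels = ~constant
        self.valid_voxels = np.asarray(self.valid_voxels, dtype=bool)

    @property
    def n_stimuli(self) -> int:
        return self.beta.shape[0]


@dataclass
class StatMap:
    """Scalar per-in-mask-voxel map (fidelity, RSA coefficient, t, z or p).

    Missing values (failed searchlight centers, excluded voxels) are NaN.
    """

    mask: MaskVolume
    values: np.ndarray
    kind: str = "stat"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.mask.n_voxels,):
            raise ValueError(
                f"values shape {self.values.shape} does not match mask size "
                f"{self.mask.n_voxels}"
            )

    def to_volume(self, fill=0.0) -> np.ndarray:
        vals = np.where(np.isfinite(self.values), self.values, fill)
        return self.mask.embed(vals, fill=fill)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _grid_of(img) -> VolumeGrid:
    return VolumeGrid(tuple(img.shape[:3]), img.affine)


def read_mask(path) -> MaskVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"mask must be 3D, got shape {data.shape}")
    return MaskVolume(_grid_of(img), data > 0)


def write_mask(mask: MaskVolume, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def read_stimulus_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"stimulus_id": str, "word_id": str})
    missing = [c for c in STIM_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"stimulus table missing required columns: {missing}")
    if table["stimulus_id"].duplicated().any():
        dupes = table.loc[table["stimulus_id"].duplicated(), "stimulus_id"]
        raise ValueError(f"duplicate stimulus_id values: {sorted(set(dupes))}")
    return table


def write_stimulus_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_beta_set(volume_path, mask_path, table_path, subject_id=None) -> SubjectBetaSet:
    """Load a 4D beta volume restricted to a mask, aligned to a stimulus table.

    The 4th dimension of the volume must equal the number of table rows; the
    volume and mask must share grid geometry.
    """
    img = nib.load(str(volume_path))
    if img.ndim != 4:
        raise ValueError(f"beta volume must be 4D, got shape {img.shape}")
    mask = read_mask(mask_path)
    if not mask.grid.matches(_grid_of(img)):
        raise GridMismatchError(
            f"beta volume grid {img.shape[:3]} / affine does not match mask "
            f"grid {mask.grid.dims}"
        )
    table = read_stimulus_table(table_path)
    n_frames = img.shape[3]
    if n_frames != len(table):
        raise ValueError(
            f"beta volume has {n_frames} frames but the stimulus table has "
            f"{len(table)} rows"
        )
    data = np.asanyarray(img.dataobj)
    beta = data.reshape(-1, n_frames)[mask.indices].T.astype(float)
    sid = subject_id if subject_id is not None else Path(str(volume_path)).stem
    return SubjectBetaSet(sid, mask, beta, table["stimulus_id"].to_numpy())


def write_beta_set(betas: SubjectBetaSet, volume_path) -> None:
    """Write a beta set as a 4D float32 NIfTI (zeros outside the mask)."""
    dims = betas.mask.grid.dims
    vol = np.zeros(dims + (betas.n_stimuli,), dtype=np.float32)
    flat = vol.reshape(-1, betas.n_stimuli)
    flat[betas.mask.indices] = betas.beta.T.astype(np.float32)
    nib.save(nib.Nifti1Image(vol, betas.mask.grid.affine), str(volume_path))


def write_statmap(stat: StatMap, path, fill=0.0) -> None:
    img = nib.Nifti1Image(
        stat.to_volume(fill=fill).astype(np.float32), stat.mask.grid.affine
    )
    nib.save(img, str(path))


def read_statmap(path, mask: MaskVolume, kind: str = "stat") -> StatMap:
    img = nib.load(str(path))
    if not mask.grid.matches(_grid_of(img)):
        raise GridMismatchError("stat map grid does not match mask grid")
    return StatMap(mask, mask.extract(np.asanyarray(img.dataobj).astype(float)), kind)


# ---------------------------------------------------------------------------
# Processing
# ---------------------------------------------------------------------------

def average_presentations(betas: SubjectBetaSet, repetition_map) -> SubjectBetaSet:
    """Average the repeated presentations of each word into one row per word.

    ``repetition_map`` maps stimulus_id -> word_id; output rows follow the
    first appearance of each word among the input stimuli.
    """
    word_ids = []
    for sid in betas.stimulus_ids:
        if sid not in repetition_map:
            raise KeyError(f"stimulus {sid!r} missing from repetition map")
        word_ids.append(repetition_map[sid])
    order = list(dict.fromkeys(word_ids))  # first-appearance order
    rows = np.empty((len(order), betas.beta.shape[1]))
    wid_arr = np.asarray(word_ids)
    for i, wid in enumerate(order):
        sel = wid_arr == wid
        if not sel.any():
            raise ValueError(f"word {wid!r} has no presentations")
        rows[i] = betas.beta[sel].mean(axis=0)
    return SubjectBetaSet(
        betas.subject_id, betas.mask, rows, np.asarray(order),
        valid_voxels=betas.valid_voxels.copy(),
    )


def fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian_smooth(stat: StatMap, fwhm_mm: float, mask_normalize: bool = True) -> StatMap:
    """Gaussian-smooth a stat map with an isotropic FWHM given in mm.

    With ``mask_normalize`` the kernel weights are renormalized over in-mask
    finite voxels, so zeros outside the mask (and NaN holes) do not attenuate
    edge values; a constant map is then preserved exactly.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm must be nonnegative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return StatMap(stat.mask, stat.values.copy(), stat.kind)
    sigma_vox = fwhm_to_sigma(fwhm_mm) / stat.mask.grid.voxel_size
    finite = np.isfinite(stat.values)
    vol = stat.mask.embed(np.where(finite, stat.values, 0.0))
    sm = ndimage.gaussian_filter(vol, sigma=sigma_vox)
    if mask_normalize:
        support = stat.mask.embed(finite.astype(float))
        weight = ndimage.gaussian_filter(support, sigma=sigma_vox)
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = np.where(weight > 1e-12, sm / weight, 0.0)
    out = stat.mask.extract(sm)
    out[~finite] = np.nan
    return StatMap(stat.mask, out, stat.kind)


@dataclass
class ClusterLabels:
    """Connected-component labeling of a suprathreshold voxel set."""

    labels: np.ndarray          # 3D int, 0 = background
    sizes_vox: np.ndarray       # size (voxels) of cluster k at index k-1
    voxel_volume_mm3: float

    @property
    def n_clusters(self) -> int:
        return int(self.sizes_vox.size)

    @property
    def sizes_mm3(self) -> np.ndarray:
        return self.sizes_vox * self.voxel_volume_mm3


def label_clusters(binary, grid: VolumeGrid = None, connectivity: int = 26) -> ClusterLabels:
    """Label connected components of a 3D boolean volume.

    ``connectivity`` is the 3D neighbor count: 6 (faces), 18 (+edges) or
    26 (+corners, the default).
    """
    if connectivity not in CONNECTIVITY_STRUCTS:
        raise ValueError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    binary = np.asarray(binary, dtype=bool)
    labels, n = ndimage.label(binary, structure=CONNECTIVITY_STRUCTS[connectivity])
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:].astype(int)
    vol = grid.voxel_volume_mm3 if grid is not None else 1.0
    return ClusterLabels(labels, sizes, vol)


def local_extrema(stat: StatMap, clusters: ClusterLabels, min_sep_mm: float) -> pd.DataFrame:
    """Cluster-wise peak table by greedy descending-|value| suppression.

    Within each cluster, candidate voxels are visited in descending absolute
    value (ties broken by ascending linear index); a candidate closer than
    ``min_sep_mm`` (world distance) to any already-accepted peak of the same
    cluster is suppressed.  Columns: x, y, z, value, cluster_id, cluster_mm3.
    """
    if min_sep_mm <= 0:
        raise ValueError(f"min_sep_mm must be positive, got {min_sep_mm}")
    grid = stat.mask.grid
    labels_flat = clusters.labels.ravel()[stat.mask.indices]
    world = stat.mask.world_coords()
    rows = []
    for cid in range(1, clusters.n_clusters + 1):
        in_cluster = np.flatnonzero(
            (labels_flat == cid) & np.isfinite(stat.values)
        )
        if in_cluster.size == 0:
            continue
        vals = stat.values[in_cluster]
        order = np.lexsort((stat.mask.indices[in_cluster], -np.abs(vals)))
        accepted = []
        for j in order:
            xyz = world[in_cluster[j]]
            if all(np.linalg.norm(xyz - a) >= min_sep_mm for a in accepted):
                accepted.append(xyz)
                rows.append(
                    dict(
                        x=xyz[0], y=xyz[1], z=xyz[2],
                        value=vals[j], cluster_id=cid,
                        cluster_mm3=clusters.sizes_mm3[cid - 1],
                    )
                )
    return pd.DataFrame(rows, columns=["x", "y", "z", "value", "cluster_id", "cluster_mm3"])


def hemisphere_counts(mask: MaskVolume, atol: float = 1e-6):
    """Count in-mask voxels left (world x<0), right (x>0) and midline (x=0)."""
    x = mask.world_coords()[:, 0]
    mid = np.abs(x) <= atol
    left = int(np.sum((x < 0) & ~mid))
    right = int(np.sum((x > 0) & ~mid))
    return left, right, int(mid.sum())
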