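"""Representational fidelity: leave-one-out RDM reliability and the mROI.

Representational fidelity (RF) measures how reproducible a region's
representational geometry is across subjects: each subject's RDM is
correlated with the elementwise mean of all other subjects' RDMs.  Run in a
searchlight over word-level activity patterns, the group RF map highlights
cortex carrying multivariate structure shared across people, and
thresholding it (voxel p plus a cluster-extent filter) yields the
multivariate region of interest (mROI) used as an inclusive localizer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .grid import MaskVolume, StatMap, label_clusters
from .rdm import RDM, _corr_rows, vectorize_lower
from .searchlight import SearchlightSpec, run_searchlight

log = logging.getLogger(__name__)


class EmptyROIError(RuntimeError):
    """No voxel survived ROI definition thresholds."""


@dataclass
class ROIMask:
    """Boolean voxel set within an analysis mask, with provenance."""

    analysis_mask: MaskVolume
    member: np.ndarray  # bool over in-mask vector of analysis_mask
    name: str = "roi"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.member = np.asarray(self.member, dtype=bool)
        if self.member.shape != (self.analysis_mask.n_voxels,):
            raise ValueError("member vector does not match analysis mask size")

    @property
    def n_voxels(self) -> int:
        return int(self.member.sum())

    @property
    def indices(self) -> np.ndarray:
        """In-mask vector indices (into the analysis mask) of ROI voxels."""
        return np.flatnonzero(self.member)

    def to_mask_volume(self) -> MaskVolume:
        return MaskVolume(
            self.analysis_mask.grid, self.analysis_mask.embed(self.member.astype(float)) > 0
        )

    @classmethod
    def from_mask_volume(cls, roi: MaskVolume, analysis_mask: MaskVolume = None,
                         name: str = "roi", provenance: dict = None) -> "ROIMask":
        if analysis_mask is None:
            analysis_mask = roi
        if not roi.grid.matches(analysis_mask.grid):
            raise ValueError("ROI and analysis mask are on different grids")
        member = analysis_mask.extract(roi.data.astype(float)) > 0
        return cls(analysis_mask, member, name, provenance or {})


def _pearson_vec(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _loo_corr(vecs: np.ndarray, correlation: str = "pearson") -> np.ndarray:
    """Leave-one-out correlations of each row with the mean of the others."""
    S = vecs.shape[0]
    if correlation == "spearman":
        ranked = np.apply_along_axis(stats.rankdata, 1, vecs)
    total = vecs.sum(axis=0)
    out = np.empty(S)
    for s in range(S):
        others = (total - vecs[s]) / (S - 1)
        if correlation == "spearman":
            out[s] = _pearson_vec(ranked[s], stats.rankdata(others))
        else:
            out[s] = _pearson_vec(vecs[s], others)
    return out


def loo_fidelity(rdms, correlation: str = "pearson") -> np.ndarray:
    """Per-subject leave-one-RDM-out fidelity for a list of subject RDMs.

    For each subject s the statistic is the correlation between that
    subject's vectorized RDM and the elementwise mean of everyone else's.
    """
    rdms = list(rdms)
    if len(rdms) < 3:
        raise ValueError("leave-one-out fidelity needs at least 3 subjects")
    ref = rdms[0].labels
    for i, r in enumerate(rdms[1:], 1):
        if not np.array_equal(r.labels, ref):
            raise ValueError(f"RDM labels of subject {i} do not match subject 0")
    vecs = np.vstack([vectorize_lower(r).v for r in rdms])
    return _loo_corr(vecs, correlation)


def fidelity_searchlight(betasets, spec: SearchlightSpec = None,
                         correlation: str = "pearson", centers=None):
    """Whole-mask searchlight RF map for each subject plus the group mean.

    Expects per-word (presentation-averaged) beta sets on a shared mask.
    Returns (subject_maps, group_map); the group map is the across-subject
    mean fidelity at each center.
    """
    betasets = list(betasets)
    if len(betasets) < 3:
        raise ValueError("fidelity searchlight needs at least 3 subjects")
    n_stim = betasets[0].n_stimuli
    tri = np.tril_indices(n_stim, k=-1)

    def fn(submats, members):
        vecs = np.vstack([(1.0 - _corr_rows(X))[tri] for X in submats])
        return _loo_corr(vecs, correlation)

    subject_maps = run_searchlight(betasets, fn, spec=spec, centers=centers,
                                   kind="fidelity")
    stacked = np.vstack([m.values for m in subject_maps])
    group = StatMap(betasets[0].mask, stacked.mean(axis=0), "fidelity")
    return subject_maps, group


def fisher_z(r: np.ndarray, rmax: float = 1.0 - 1e-7) -> np.ndarray:
    """Variance-stabilizing arctanh of correlation values, clipped near +/-1."""
    return np.arctanh(np.clip(r, -rmax, rmax))


def define_mroi(subject_maps, voxel_p: float = 0.05, extent_vox: int = 120,
                connectivity: int = 26, method: str = "t",
                n_perm: int = 2000, seed: int = 0, name: str = "mroi") -> ROIMask:
    """Threshold group fidelity into a multivariate ROI.

    Subject fidelity values are Fisher z-transformed and tested per voxel
    with a one-sided one-sample t against 0 (only positive reproducibility
    defines a localizer); voxels with p < ``voxel_p`` are kept and connected
    components smaller than ``extent_vox`` voxels are dropped.
    ``method='signflip'`` replaces the t-test p with a sign-flip permutation
    p-value (caveat: leave-one-out values are not independent across
    subjects, so the t-test is a pragmatic convention, not exact).
    """
    subject_maps = list(subject_maps)
    if len(subject_maps) < 3:
        raise ValueError("mROI definition needs at least 3 subject maps")
    mask = subject_maps[0].mask
    Z = fisher_z(np.vstack([m.values for m in subject_maps]))
    ok = np.all(np.isfinite(Z), axis=0)
    S = Z.shape[0]
    mean = Z.mean(axis=0)
    sd = Z.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(S))
    if method == "t":
        p = stats.t.sf(t, df=S - 1)
    elif method == "signflip":
        rng = np.random.default_rng(seed)
        exceed = np.ones(Z.shape[1])
        for _ in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=S)
            perm_mean = (Z * signs[:, None]).mean(axis=0)
            exceed += perm_mean >= mean
        p = exceed / (n_perm + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    supra = ok & np.isfinite(p) & (p < voxel_p)
    vol = mask.embed(supra.astype(float)) > 0
    clusters = label_clusters(vol, mask.grid, connectivity)
    keep = np.zeros_like(vol)
    for cid in range(1, clusters.n_clusters + 1):
        if clusters.sizes_vox[cid - 1] >= extent_vox:
            keep |= clusters.labels == cid
    member = mask.extract(keep.astype(float)) > 0
    if not member.any():
        raise EmptyROIError(
            f"no voxel survived voxel_p={voxel_p} with extent>={extent_vox}"
        )
    prov = dict(voxel_p=voxel_p, extent_vox=extent_vox, connectivity=connectivity,
                method=method, n_subjects=S)
    return ROIMask(mask, member, name=name, provenance=prov)
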