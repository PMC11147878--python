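"""Partial-correlation RSA searchlight and group-level inference.

The semantic question — does a region's activity geometry track word
meaning? — is confounded by the fact that words also differ in spelling and
sound.  The partial-correlation RSA therefore rank-transforms all RDM
vectors (Spearman), residualizes both the neural RDM and the semantic
predictor on the orthographic and phonological control RDMs, and correlates
the residuals.  Group maps are Fisher z-transformed, smoothed, t-tested
against zero and cluster-extent corrected with a sign-flip permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grid import MaskVolume, StatMap, gaussian_smooth, label_clusters, local_extrema
from .rdm import RDMVector, _corr_rows, zscore_across_stimuli
from .fidelity import fisher_z
from .searchlight import SearchlightSpec, run_searchlight

log = logging.getLogger(__name__)

COLLINEARITY_WARN_R = 0.7


class CollinearControlsError(ValueError):
    """The control RDM set is rank deficient."""


def _as_vec(x) -> np.ndarray:
    return x.v if isinstance(x, RDMVector) else np.asarray(x, dtype=float)


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v)  # average ranks for ties


def _control_basis(controls_ranked: np.ndarray) -> np.ndarray:
    """Orthonormal basis (incl. intercept) spanning the rank-transformed controls."""
    X = np.column_stack([np.ones(controls_ranked.shape[1])] + list(controls_ranked))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise CollinearControlsError(
            "control RDMs are collinear (design rank "
            f"{rank} < {X.shape[1]} columns)"
        )
    Q, _ = np.linalg.qr(X)
    return Q


def partial_spearman(target, predictor, controls=()) -> float:
    """Spearman correlation of target and predictor, partialling out controls.

    All vectors are rank-transformed (average ranks); target and predictor
    are residualized on the controls by least squares with an intercept, and
    the Pearson correlation of the residuals is returned.  With no controls
    this is exactly the plain Spearman rho.
    """
    t = _as_vec(target)
    p = _as_vec(predictor)
    ctr = [_as_vec(c) for c in controls]
    n = t.size
    if p.size != n or any(c.size != n for c in ctr):
        raise ValueError("all RDM vectors must have equal length")
    if n < len(ctr) + 3:
        raise ValueError(
            f"need at least {len(ctr) + 3} entries for {len(ctr)} control(s)"
        )
    rt, rp = _rank(t), _rank(p)
    if np.std(rt) == 0 or np.std(rp) == 0:
        return float("nan")
    Q = _control_basis(np.vstack([_rank(c) for c in ctr]) if ctr else np.empty((0, n)))
    res_t = rt - Q @ (Q.T @ rt)
    res_p = rp - Q @ (Q.T @ rp)
    nt, np_ = np.linalg.norm(res_t), np.linalg.norm(res_p)
    # a vector fully explained by the controls has nothing left to correlate
    tol = 1e-8
    if nt <= tol * np.linalg.norm(rt - rt.mean()) or \
            np_ <= tol * np.linalg.norm(rp - rp.mean()):
        return 0.0
    return float(np.clip(res_t @ res_p / (nt * np_), -1.0, 1.0))


@dataclass
class PartialRSAModel:
    """A target predicted RDM plus control RDMs to partial out."""

    target: RDMVector
    controls: list = field(default_factory=list)
    target_name: str = "target"
    control_names: list = None

    def __post_init__(self):
        n = self.target.v.size
        if self.control_names is None:
            self.control_names = [f"control{i}" for i in range(len(self.controls))]
        vecs = [self.target.v] + [_as_vec(c) for c in self.controls]
        names = [self.target_name] + list(self.control_names)
        for name, v in zip(names, vecs):
            if v.size != n:
                raise ValueError(f"predictor {name!r} has length {v.size} != {n}")
        for i in range(len(vecs)):
            for j in range(i + 1, len(vecs)):
                r = np.corrcoef(vecs[i], vecs[j])[0, 1]
                if abs(r) >= COLLINEARITY_WARN_R:
                    log.warning(
                        "predictors %r and %r are collinear (|r|=%.2f >= %.1f)",
                        names[i], names[j], abs(r), COLLINEARITY_WARN_R,
                    )


def rsa_searchlight(betasets, model: PartialRSAModel,
                    spec: SearchlightSpec = None, centers=None,
                    zscore: bool = True):
    """Per-subject searchlight maps of the partial Spearman coefficient.

    Betas are z-scored across stimuli within each voxel (the RSA convention)
    before neural RDMs are built.  At each center the neural RDM vector is
    rank-transformed, residualized on the (precomputed) control basis, and
    correlated with the residualized target ranks.
    """
    betasets = [zscore_across_stimuli(b) for b in betasets] if zscore else list(betasets)
    n_stim = betasets[0].n_stimuli
    n_pairs = n_stim * (n_stim - 1) // 2
    if model.target.v.size != n_pairs:
        raise ValueError(
            f"model vectors have {model.target.v.size} pairs but the data "
            f"have {n_stim} stimuli ({n_pairs} pairs)"
        )
    tri = np.tril_indices(n_stim, k=-1)
    ctr_ranks = (np.vstack([_rank(_as_vec(c)) for c in model.controls])
                 if model.controls else np.empty((0, n_pairs)))
    Q = _control_basis(ctr_ranks)
    rt = _rank(model.target.v)
    res_t = rt - Q @ (Q.T @ rt)
    nt = np.linalg.norm(res_t)
    if nt == 0:
        raise ValueError("target RDM has zero variance after partialling")
    res_t = res_t / nt

    def fn(submats, members):
        out = np.empty(len(submats))
        for s, X in enumerate(submats):
            v = (1.0 - _corr_rows(X))[tri]
            rp = _rank(v)
            res_p = rp - Q @ (Q.T @ rp)
            npn = np.linalg.norm(res_p)
            if npn <= 1e-8 * np.linalg.norm(rp - rp.mean()):
                out[s] = 0.0
            else:
                out[s] = np.clip(res_p @ res_t / npn, -1, 1)
        return out

    maps = run_searchlight(betasets, fn, spec=spec, centers=centers, kind="rsa_coef")
    return maps if isinstance(maps, list) else [maps]


@dataclass
class GroupResult:
    """Group-level RSA statistics and the cluster-corrected mask."""

    t_map: StatMap
    z_map: StatMap
    p_map: StatMap
    thresholded: np.ndarray      # 3D bool of surviving voxels
    cluster_table: pd.DataFrame
    thresholds: dict
    null_max_sizes: np.ndarray


def group_rsa(subject_maps, fwhm: float = 5.0, voxel_p: float = 0.005,
              cluster_alpha: float = 0.05, n_perm: int = 1000, seed: int = 0,
              connectivity: int = 26, min_peak_sep_mm: float = 11.0,
              fisher_before_smooth: bool = True) -> GroupResult:
    """One-sample group inference on subject coefficient maps.

    Subject maps are Fisher z-transformed, Gaussian-smoothed (``fwhm`` mm,
    mask-normalized), and entered into a two-tailed one-sample t-test against
    zero.  Voxels with p < ``voxel_p`` are clustered (|t| suprathreshold) and
    cluster extents are corrected by a sign-flip permutation null of the
    maximum cluster size; clusters with corrected p <= ``cluster_alpha``
    survive.  ``fisher_before_smooth=False`` smooths the raw coefficients
    and z-transforms afterwards.
    """
    subject_maps = list(subject_maps)
    if len(subject_maps) < 3:
        raise ValueError("group inference needs at least 3 subject maps")
    if n_perm < 100:
        log.warning("n_perm=%d is very low; cluster p-values will be coarse", n_perm)
    mask = subject_maps[0].mask
    S = len(subject_maps)

    def prep(m: StatMap) -> np.ndarray:
        if fisher_before_smooth:
            z = StatMap(mask, fisher_z(m.values), "z")
            return gaussian_smooth(z, fwhm).values
        sm = gaussian_smooth(m, fwhm).values
        return fisher_z(sm)

    Z = np.vstack([prep(m) for m in subject_maps])
    ok = np.all(np.isfinite(Z), axis=0)
    df = S - 1
    tcrit = stats.t.isf(voxel_p / 2.0, df)

    def tmap(M: np.ndarray) -> np.ndarray:
        mean = M.mean(axis=0)
        sd = M.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(sd > 0, mean / (sd / np.sqrt(S)), 0.0)
        return np.where(ok, t, np.nan)

    def max_cluster_size(t: np.ndarray) -> tuple:
        supra = np.isfinite(t) & (np.abs(t) > tcrit)
        vol = mask.embed(supra.astype(float)) > 0
        clusters = label_clusters(vol, mask.grid, connectivity)
        mx = int(clusters.sizes_vox.max()) if clusters.n_clusters else 0
        return mx, clusters

    t_obs = tmap(Z)
    obs_max, clusters = max_cluster_size(t_obs)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=S)
        null[i], _ = max_cluster_size(tmap(Z * signs[:, None]))

    p_vox = np.where(ok, 2.0 * stats.t.sf(np.abs(t_obs), df), np.nan)
    rows, keep = [], np.zeros(mask.grid.dims, dtype=bool)
    for cid in range(1, clusters.n_clusters + 1):
        size = int(clusters.sizes_vox[cid - 1])
        p_clu = (1.0 + np.sum(null >= size)) / (n_perm + 1.0)
        if p_clu <= cluster_alpha:
            keep |= clusters.labels == cid
        in_c = mask.extract((clusters.labels == cid).astype(float)) > 0
        peak = np.nanargmax(np.where(in_c, np.abs(t_obs), -np.inf))
        xyz = mask.world_coords()[peak]
        rows.append(dict(cluster_id=cid, n_voxels=size,
                         mm3=size * mask.grid.voxel_volume_mm3,
                         p_cluster=p_clu, survives=p_clu <= cluster_alpha,
                         peak_x=xyz[0], peak_y=xyz[1], peak_z=xyz[2],
                         peak_t=t_obs[peak]))
    table = pd.DataFrame(rows, columns=["cluster_id", "n_voxels", "mm3", "p_cluster",
                                        "survives", "peak_x", "peak_y", "peak_z", "peak_t"])
    with np.errstate(divide="ignore"):
        z_vals = np.sign(t_obs) * stats.norm.isf(np.clip(p_vox, 1e-300, 1.0) / 2.0)
    thresholds = dict(fwhm=fwhm, voxel_p=voxel_p, cluster_alpha=cluster_alpha,
                      n_perm=n_perm, seed=seed, connectivity=connectivity,
                      fisher_before_smooth=fisher_before_smooth,
                      observed_max_cluster=obs_max)
    return GroupResult(
        t_map=StatMap(mask, t_obs, "t"),
        z_map=StatMap(mask, z_vals, "z"),
        p_map=StatMap(mask, p_vox, "p"),
        thresholded=keep,
        cluster_table=table,
        thresholds=thresholds,
        null_max_sizes=null,
    )


def peak_table(result: GroupResult, min_sep_mm: float = 11.0) -> pd.DataFrame:
    """Local-extrema table of the surviving clusters (peaks >= min_sep apart)."""
    clusters = label_clusters(result.thresholded,
                              result.t_map.mask.grid,
                              result.thresholds["connectivity"])
    return local_extrema(result.t_map, clusters, min_sep_mm)
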