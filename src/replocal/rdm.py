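"""Representational dissimilarity matrices: construction, vectorization, comparison.

The RDM is the atom of both the fidelity analysis and RSA: a symmetric
condition-by-condition matrix of pairwise dissimilarities with a zero
diagonal, built either from neural activity patterns (observed) or from
stimulus properties (predicted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import SubjectBetaSet

log = logging.getLogger(__name__)


@dataclass
class RDM:
    """Condition-by-condition dissimilarity matrix with ordered labels."""

    labels: np.ndarray
    D: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.D = np.asarray(self.D, dtype=float)
        self.validate()

    def validate(self, atol: float = 1e-10) -> None:
        n = self.D.shape[0]
        if self.D.ndim != 2 or self.D.shape != (n, n):
            raise ValueError(f"D must be square, got shape {self.D.shape}")
        if n < 2:
            raise ValueError("an RDM needs at least 2 conditions")
        if self.labels.size != n:
            raise ValueError(
                f"{self.labels.size} labels for a {n}x{n} matrix"
            )
        if not np.all(np.isfinite(self.D)):
            raise ValueError("RDM entries must be finite")
        if not np.allclose(self.D, self.D.T, atol=atol):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(self.D), 0.0, atol=atol):
            raise ValueError("RDM diagonal must be zero")

    @property
    def n(self) -> int:
        return self.D.shape[0]

    def vectorize(self) -> "RDMVector":
        return vectorize_lower(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)


@dataclass
class RDMVector:
    """Strictly-lower-triangle entries of an RDM, row-major.

    Entry order is (1,0), (2,0), (2,1), (3,0), ... — i.e. rows of the lower
    triangle in sequence, matching ``numpy.tril_indices(n, -1)``.
    """

    labels: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.v = np.asarray(self.v, dtype=float)
        n = self.labels.size
        if self.v.size != n * (n - 1) // 2:
            raise ValueError(
                f"vector length {self.v.size} does not match n(n-1)/2 for "
                f"n={n} labels"
            )


def vectorize_lower(rdm: RDM) -> RDMVector:
    i, j = np.tril_indices(rdm.n, k=-1)
    return RDMVector(rdm.labels, rdm.D[i, j])


def devectorize(vec: RDMVector) -> RDM:
    n = vec.labels.size
    D = np.zeros((n, n))
    i, j = np.tril_indices(n, k=-1)
    D[i, j] = vec.v
    D[j, i] = vec.v
    return RDM(vec.labels, D)


# ---------------------------------------------------------------------------
# Constructors
# ---------------------------------------------------------------------------

def zscore_across_stimuli(betas: SubjectBetaSet) -> SubjectBetaSet:
    """Standardize each voxel's betas across stimuli (mean 0, sample SD 1).

    Zero-variance voxels cannot be standardized; they are zeroed and flagged
    invalid so the searchlight engine excludes them.
    """
    if betas.n_stimuli < 2:
        raise ValueError("z-scoring needs at least 2 stimuli")
    mu = betas.beta.mean(axis=0)
    sd = betas.beta.std(axis=0, ddof=1)
    # exactly-constant columns have zero range; sd alone can be O(eps) there
    dead = (sd == 0) | (np.ptp(betas.beta, axis=0) == 0)
    if dead.any():
        log.warning(
            "subject %s: %d zero-variance voxel(s) excluded from z-scoring",
            betas.subject_id, int(dead.sum()),
        )
    safe_sd = np.where(dead, 1.0, sd)
    z = (betas.beta - mu) / safe_sd
    z[:, dead] = 0.0
    return SubjectBetaSet(
        betas.subject_id, betas.mask, z, betas.stimulus_ids,
        valid_voxels=betas.valid_voxels & ~dead,
    )


def _corr_rows(X: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation between rows of a 2D array."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc ** 2).sum(axis=1))
    if np.any(norms == 0):
        bad = np.flatnonzero(norms == 0)
        raise ValueError(f"zero-variance pattern row(s) at index {bad.tolist()}")
    Xn = Xc / norms[:, None]
    R = Xn @ Xn.T
    return np.clip(R, -1.0, 1.0)


def neural_rdm(patterns: np.ndarray, labels=None, metric: str = "correlation") -> RDM:
    """Observed RDM from a stimulus-by-voxel pattern matrix.

    The default dissimilarity is correlation distance, 1 - Pearson r between
    activity patterns; ``metric='euclidean'`` is available.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2 or patterns.shape[0] < 2 or patterns.shape[1] < 2:
        raise ValueError("patterns must be (>=2 stimuli) x (>=2 voxels)")
    if labels is None:
        labels = np.arange(patterns.shape[0])
    if metric == "correlation":
        try:
            D = 1.0 - _corr_rows(patterns)
        except ValueError as exc:
            raise ValueError(f"cannot build neural RDM: {exc}") from exc
    elif metric == "euclidean":
        diff = patterns[:, None, :] - patterns[None, :, :]
        D = np.sqrt((diff ** 2).sum(axis=-1))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0
    return RDM(np.asarray(labels), D)


def property_rdm(values, labels=None) -> RDM:
    """Predicted RDM from a per-stimulus scalar: absolute pairwise difference."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 property values")
    if labels is None:
        labels = np.arange(values.size)
    labels = np.asarray(labels)
    bad = ~np.isfinite(values)
    if bad.any():
        raise ValueError(
            f"missing property value for stimulus {labels[bad].tolist()}"
        )
    D = np.abs(values[:, None] - values[None, :])
    return RDM(labels, D)


def familiarity_rdm(responses: pd.DataFrame) -> RDM:
    """Per-subject RDM from binary familiarity judgments.

    ``responses`` is words x presentations with entries 0/1 (NaN = missing
    response).  Each word's judgments are averaged over its available
    presentations and words are compared by absolute difference of means;
    words with no valid response are dropped with a warning.
    """
    means = responses.mean(axis=1, skipna=True)
    dropped = means.index[means.isna()]
    if len(dropped) > 0:
        log.warning(
            "familiarity RDM: %d word(s) with no valid responses excluded: %s",
            len(dropped), list(dropped),
        )
        means = means.dropna()
    if means.size < 2:
        raise ValueError("fewer than 2 words with valid familiarity responses")
    return property_rdm(means.to_numpy(), labels=means.index.to_numpy())


def average_rdms(rdms) -> RDM:
    """Elementwise mean of RDMs sharing identical labels and order."""
    rdms = list(rdms)
    if not rdms:
        raise ValueError("no RDMs to average")
    ref = rdms[0].labels
    bad = [i for i, r in enumerate(rdms) if not np.array_equal(r.labels, ref)]
    if bad:
        raise ValueError(f"label mismatch in RDM(s) at position(s) {bad}")
    D = np.mean([r.D for r in rdms], axis=0)
    return RDM(ref, D)


def rdm_correlation(a, b, method: str = "spearman") -> float:
    """Correlation between two RDM vectors (Spearman by default).

    Returns NaN (flagged missing) when either vector has zero variance.
    """
    va = a.v if isinstance(a, RDMVector) else np.asarray(a, dtype=float)
    vb = b.v if isinstance(b, RDMVector) else np.asarray(b, dtype=float)
    if va.size != vb.size:
        raise ValueError(f"length mismatch: {va.size} vs {vb.size}")
    if va.size < 3:
        raise ValueError("need at least 3 entries to correlate")
    if np.std(va) == 0 or np.std(vb) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(va, vb).statistic)
    if method == "spearman":
        return float(stats.spearmanr(va, vb).statistic)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_rdm(rdm: RDM, path) -> None:
    rdm.to_frame().to_csv(path, sep="\t")


def read_rdm(path) -> RDM:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return RDM(frame.columns.to_numpy(), frame.to_numpy())
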