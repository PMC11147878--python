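"""ROI querying, overlap accounting, laterality index and stimulus matching.

ROIs are compared for *sensitivity* by extracting mean parameter estimates
over each ROI's top-20% most active voxels, and for *validity* by the
laterality index LI = (V_left - V_right) / (V_left + V_right), where V is
the count of significant voxels in each hemisphere (positive LI =
left-lateralized, the expected direction for language).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import MaskVolume, StatMap, hemisphere_counts
from .fidelity import ROIMask

log = logging.getLogger(__name__)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def top_fraction(stat: StatMap, roi: ROIMask, fraction: float = 0.2) -> np.ndarray:
    """Indices (into the analysis-mask vector) of the top-valued ROI voxels.

    Selects k = max(1, round(fraction * |roi|)) voxels (round half away from
    zero); ties are broken by ascending linear voxel index, so the selection
    is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    idx = roi.indices
    if idx.size == 0:
        raise ValueError(f"ROI {roi.name!r} is empty")
    k = max(1, _round_half_away(fraction * idx.size))
    vals = stat.values[idx]
    vals = np.where(np.isfinite(vals), vals, -np.inf)
    order = np.lexsort((idx, -vals))
    return np.sort(idx[order[:k]])


def _paired_t(diffs: np.ndarray):
    """Two-tailed paired t from per-subject differences."""
    diffs = np.asarray(diffs, float)
    n = diffs.size
    sd = diffs.std(ddof=1)
    if sd == 0:
        t = 0.0 if np.allclose(diffs.mean(), 0) else math.inf * np.sign(diffs.mean())
    else:
        t = diffs.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1) if math.isfinite(t) else 0.0
    return float(t), int(n - 1), float(p)


def compare_roi_means(subject_maps, roi_voxel_sets: dict) -> pd.DataFrame:
    """Pairwise paired two-tailed t-tests on per-subject ROI mean estimates.

    ``roi_voxel_sets`` maps ROI name -> selected voxel indices (typically the
    output of :func:`top_fraction`).  Subjects with no valid voxel in an ROI
    are dropped pairwise.
    """
    subject_maps = list(subject_maps)
    if len(subject_maps) < 3:
        raise ValueError("ROI comparison needs at least 3 subjects")
    means = {}
    for name, vox in roi_voxel_sets.items():
        per_subj = []
        for m in subject_maps:
            vals = m.values[np.asarray(vox, int)]
            vals = vals[np.isfinite(vals)]
            per_subj.append(vals.mean() if vals.size else np.nan)
        means[name] = np.asarray(per_subj)
    rows = []
    names = list(roi_voxel_sets)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = means[names[i]], means[names[j]]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < len(a):
                log.warning("dropped %d subject(s) pairwise for %s vs %s",
                            int((~ok).sum()), names[i], names[j])
            t, df, p = _paired_t(a[ok] - b[ok])
            rows.append(dict(roi_a=names[i], roi_b=names[j],
                             mean_a=np.nanmean(a), mean_b=np.nanmean(b),
                             t=t, df=df, p=p))
    table = pd.DataFrame(rows)
    table.attrs["per_subject_means"] = means
    return table


def overlap_stats(a: ROIMask, b: ROIMask) -> dict:
    """Intersection counts and percentages (to one decimal) of two ROIs."""
    if not a.analysis_mask.grid.matches(b.analysis_mask.grid):
        raise ValueError("ROIs are on different grids")
    if not np.array_equal(a.analysis_mask.indices, b.analysis_mask.indices):
        raise ValueError("ROIs use different analysis masks")
    inter = a.member & b.member
    n_a, n_b, n_i = int(a.member.sum()), int(b.member.sum()), int(inter.sum())
    if n_i:
        inter_mv = MaskVolume(a.analysis_mask.grid,
                              a.analysis_mask.embed(inter.astype(float)) > 0)
        left, right, mid = hemisphere_counts(inter_mv)
    else:
        left = right = mid = 0
    return dict(
        n_a=n_a, n_b=n_b, n_intersection=n_i,
        intersection_left=left, intersection_right=right,
        intersection_midline=mid,
        pct_of_a=round(100.0 * n_i / n_a, 1) if n_a else float("nan"),
        pct_of_b=round(100.0 * n_i / n_b, 1) if n_b else float("nan"),
    )


@dataclass
class LateralityResult:
    v_left: int
    v_right: int
    v_midline: int

    @property
    def li(self) -> float:
        """(V_left - V_right) / (V_left + V_right); NaN when undefined."""
        total = self.v_left + self.v_right
        if total == 0:
            return float("nan")
        return (self.v_left - self.v_right) / total


def laterality_index(roi) -> LateralityResult:
    """Laterality index of an ROI (or MaskVolume); midline voxels excluded."""
    mv = roi.to_mask_volume() if isinstance(roi, ROIMask) else roi
    left, right, mid = hemisphere_counts(mv)
    if left + right == 0:
        log.warning("laterality index undefined: no lateralized voxels")
    return LateralityResult(left, right, mid)


def li_from_counts(v_left: int, v_right: int) -> float:
    return LateralityResult(int(v_left), int(v_right), 0).li


def per_subject_li(subject_maps, analysis_roi: ROIMask, fraction: float = 0.2) -> np.ndarray:
    """Per-subject LIs from each subject's own top-``fraction`` voxels."""
    out = []
    for m in subject_maps:
        vox = top_fraction(m, analysis_roi, fraction)
        member = np.zeros(m.mask.n_voxels, bool)
        member[vox] = True
        roi = ROIMask(m.mask, member, name="subject-top")
        out.append(laterality_index(roi).li)
    return np.asarray(out)


def compare_li(li_a, li_b):
    """Paired two-tailed t-test on per-subject LI differences (NaNs dropped)."""
    li_a = np.asarray(li_a, float)
    li_b = np.asarray(li_b, float)
    if li_a.size != li_b.size:
        raise ValueError("LI vectors must be the same length")
    ok = np.isfinite(li_a) & np.isfinite(li_b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 subjects with defined LIs in both ROIs")
    if ok.sum() < li_a.size:
        log.warning("dropped %d subject(s) with undefined LI", int((~ok).sum()))
    return _paired_t(li_a[ok] - li_b[ok])


def pooled_two_sample_t(m1: float, sd1: float, n1: int,
                        m2: float, sd2: float, n2: int):
    """Two-sample t (pooled variance) from group summaries; returns (t, df).

    The magnitude of the mean difference is used, matching the convention of
    reporting |t| in stimulus-matching tables.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if s2 == 0:
        return (0.0 if m1 == m2 else float("inf")), df
    t = abs(m1 - m2) / math.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    return float(t), int(df)


def matching_report(table: pd.DataFrame, group_column: str,
                    property_columns) -> pd.DataFrame:
    """Group means, SDs and pooled two-sample t per stimulus property.

    ``table`` must contain exactly two groups in ``group_column``; rows with
    a missing value for a property are excluded from that property's test.
    """
    groups = sorted(table[group_column].dropna().unique().tolist())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    g1, g2 = groups
    rows = []
    for col in property_columns:
        vals = table[[group_column, col]].dropna()
        dropped = len(table) - len(vals)
        if dropped:
            log.info("property %r: %d row(s) with missing values excluded", col, dropped)
        a = vals.loc[vals[group_column] == g1, col].astype(float)
        b = vals.loc[vals[group_column] == g2, col].astype(float)
        t, df = pooled_two_sample_t(a.mean(), a.std(ddof=1), len(a),
                                    b.mean(), b.std(ddof=1), len(b))
        rows.append({
            "property": col,
            f"mean_{g1}": a.mean(), f"sd_{g1}": a.std(ddof=1),
            f"mean_{g2}": b.mean(), f"sd_{g2}": b.std(ddof=1),
            "t": t, "df": df,
        })
    return pd.DataFrame(rows)
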