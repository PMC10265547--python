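"""Tractogram reproducibility metrics.

Binary-mask measures (Dice, overlap/overreach, bundle adjacency), density
measures (weighted Dice, density correlation), reliability (two-way random
absolute-agreement single-measure ICC with F-based confidence bounds), and
the descriptive statistics used to summarize per-bundle similarity scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .io import ReferenceGrid, voxel_to_world
from .maps import DensityMap
from .voi import VOIMask

__all__ = [
    "UndefinedScoreError",
    "RatingsMatrix",
    "ICCResult",
    "dsc",
    "wdsc",
    "density_correlation",
    "overlap_overreach",
    "bundle_adjacency",
    "icc_single_agreement",
    "summary_stats",
    "max_abs_intersession_diff",
]


class UndefinedScoreError(ValueError):
    """The metric is undefined for these inputs (e.g. zero variance)."""


def _check_grids(a, b):
    if a.grid != b.grid:
        raise ValueError("inputs must share a reference grid")


def dsc(mask_a: VOIMask, mask_b: VOIMask) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|); two empty masks score 1."""
    _check_grids(mask_a, mask_b)
    a, b = mask_a.data, mask_b.data
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0  # vacuous agreement, flagged by convention
    return 2.0 * int((a & b).sum()) / denom


def wdsc(density_a: DensityMap, density_b: DensityMap) -> float:
    """Weighted Dice on streamline-density proportions.

    Each map is normalized to per-voxel proportions; the score is the summed
    proportion mass (from both maps) lying on the intersection of their
    supports, divided by the total mass 2. Equals plain Dice when both maps
    are uniform over equal-sized supports.
    """
    _check_grids(density_a, density_b)
    ta, tb = density_a.counts.sum(), density_b.counts.sum()
    if ta == 0 or tb == 0:
        raise UndefinedScoreError("weighted Dice undefined for a zero-total density map")
    pa = density_a.counts / ta
    pb = density_b.counts / tb
    inter = (density_a.counts > 0) & (density_b.counts > 0)
    return float((pa[inter].sum() + pb[inter].sum()) / 2.0)


def density_correlation(density_a: DensityMap, density_b: DensityMap) -> float:
    """Pearson correlation of raw counts over the union of supports."""
    _check_grids(density_a, density_b)
    union = (density_a.counts > 0) | (density_b.counts > 0)
    if union.sum() < 3:
        raise UndefinedScoreError("need >= 3 voxels in the union of supports")
    x = density_a.counts[union].astype(float)
    y = density_b.counts[union].astype(float)
    if x.std() == 0 or y.std() == 0:
        raise UndefinedScoreError("density correlation undefined: zero variance over the union")
    r, _ = stats.pearsonr(x, y)
    return float(r)


def overlap_overreach(candidate_mask: VOIMask, reference_mask: VOIMask) -> tuple[float, float]:
    """(OL, OR): fraction of reference recovered, extra volume over reference."""
    _check_grids(candidate_mask, reference_mask)
    c, r = candidate_mask.data, reference_mask.data
    nr = int(r.sum())
    if nr == 0:
        raise UndefinedScoreError("overlap/overreach undefined for an empty reference")
    ol = int((c & r).sum()) / nr
    over = int((c & ~r).sum()) / nr
    return float(ol), float(over)


def bundle_adjacency(mask_a: VOIMask, mask_b: VOIMask, grid: ReferenceGrid | None = None) -> float:
    """Symmetric mean nearest-voxel distance (mm) between non-shared parts.

    0.5 * [mean over A\\B of distance to nearest B voxel center +
           mean over B\\A of distance to nearest A voxel center];
    an empty difference contributes 0 to its term.
    """
    _check_grids(mask_a, mask_b)
    if grid is None:
        grid = mask_a.grid
    a, b = mask_a.data, mask_b.data
    if not a.any() or not b.any():
        raise UndefinedScoreError("bundle adjacency undefined for an empty mask")
    pa = voxel_to_world(np.argwhere(a), grid)
    pb = voxel_to_world(np.argwhere(b), grid)
    only_a = voxel_to_world(np.argwhere(a & ~b), grid) if (a & ~b).any() else None
    only_b = voxel_to_world(np.argwhere(b & ~a), grid) if (b & ~a).any() else None
    term_a = cKDTree(pb).query(only_a)[0].mean() if only_a is not None else 0.0
    term_b = cKDTree(pa).query(only_b)[0].mean() if only_b is not None else 0.0
    return float(0.5 * (term_a + term_b))


@dataclass
class RatingsMatrix:
    """Items x sessions score matrix for reliability analysis.

    Rows containing non-finite cells are dropped (and reported via
    ``n_dropped``) before any ICC computation.
    """

    values: np.ndarray
    item_labels: list[str] | None = None
    session_labels: list[str] | None = None
    n_dropped: int = 0

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("ratings must be a 2-D items x sessions array")
        complete = np.all(np.isfinite(vals), axis=1)
        self.n_dropped = int((~complete).sum())
        if self.n_dropped:
            vals = vals[complete]
            if self.item_labels is not None:
                self.item_labels = [l for l, ok in zip(self.item_labels, complete) if ok]
        if vals.shape[0] < 2 or vals.shape[1] < 2:
            raise ValueError("need >= 2 complete items and >= 2 sessions")
        self.values = vals


@dataclass
class ICCResult:
    icc: float
    lower: float
    upper: float
    p_value: float
    df1: int
    df2: float


def icc_single_agreement(ratings: RatingsMatrix, confidence: float = 0.95) -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-measure ICC.

    Uses the two-way ANOVA decomposition (rows = items, columns = sessions):
    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)), with the
    F-based confidence interval of McGraw & Wong and the p-value from
    F = MSR/MSE on (n-1, (n-1)(k-1)) degrees of freedom.
    """
    x = ratings.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if sst == 0 or denom == 0:
        raise UndefinedScoreError("ICC undefined: zero total variance")
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse == 0:
        # perfect within-item agreement: degenerate interval at the estimate
        return ICCResult(icc=float(icc), lower=float(icc), upper=float(icc), p_value=0.0, df1=df1, df2=df2)

    f_obs = msr / mse
    p = float(stats.f.sf(f_obs, df1, df2))

    a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isfinite(a) and np.isfinite(b):
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1.0 - alpha / 2.0, df1, v)
        f_u = stats.f.ppf(1.0 - alpha / 2.0, v, df1)
        lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    else:  # icc == 1 exactly
        lower = upper = 1.0
    return ICCResult(icc=float(icc), lower=float(lower), upper=float(upper), p_value=p, df1=df1, df2=df2)


def summary_stats(values) -> dict:
    """Median, sample stdev, IQR (linear-interpolation quantiles) and min."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("summary_stats needs at least one finite value")
    q1, q3 = np.percentile(v, [25, 75])
    return {
        "median": float(np.median(v)),
        "stdev": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "iqr": float(q3 - q1),
        "min": float(v.min()),
    }


def max_abs_intersession_diff(score_pairs) -> float:
    """Max over subjects of |session-1 score - session-2 score|."""
    pairs = np.asarray(score_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] == 0:
        raise ValueError("score_pairs must be a non-empty (n, 2) array")
    return float(np.abs(pairs[:, 0] - pairs[:, 1]).max())
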