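"""Binned signal profiles, pairwise regression, and correlation structure.

For locus-wide comparison between samples the repeat is divided into
100-bp bins and the median signal per bin taken; pairs of samples are
compared by ordinary least-squares regression with the F-test p-value,
reporting the adjusted R-squared (which, unlike the raw statistic, can
go negative for anti-predictive fits and is the form printed in
locus-wide comparisons); sample sets are summarized as a symmetric score
matrix ordered by hierarchical clustering for heatmap display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as _stats
from scipy.cluster import hierarchy as _hierarchy

from .signal import SignalTrack

__all__ = [
    "BinnedProfile",
    "RegressionResult",
    "CorrelationMatrix",
    "RegressionUndefinedError",
    "bin_median",
    "pairwise_regression",
    "correlation_matrix",
]


class RegressionUndefinedError(ValueError):
    """Raised when the predictor has zero variance and the regression
    statistics are undefined."""


@dataclass
class BinnedProfile:
    name: str
    bin_size: int
    medians: np.ndarray

    def __len__(self) -> int:
        return len(self.medians)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    r_squared_adjusted: float
    f_statistic: float
    f_test_p: float
    n: int


@dataclass
class CorrelationMatrix:
    names: List[str]
    scores: np.ndarray  # symmetric, diagonal 1 for correlation-based scores
    order: List[int]  # dendrogram leaf order (permutation of samples)
    linkage: np.ndarray

    def ordered_names(self) -> List[str]:
        return [self.names[i] for i in self.order]


def bin_median(track: SignalTrack, bin_size: int = 100, name: str = "") -> BinnedProfile:
    """Median of the per-base signal in consecutive ``bin_size`` windows.

    Bin j covers [j*bin_size, min((j+1)*bin_size, L)); the final bin may
    be short.  Even-count medians are the mean of the two central order
    statistics (numpy convention).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    L = len(track)
    if L == 0:
        raise ValueError("empty signal track")
    n_bins = math.ceil(L / bin_size)
    medians = np.array(
        [
            np.median(track.values[j * bin_size : min((j + 1) * bin_size, L)])
            for j in range(n_bins)
        ]
    )
    return BinnedProfile(name=name or track.chrom, bin_size=bin_size, medians=medians)


def pairwise_regression(a: BinnedProfile, b: BinnedProfile) -> RegressionResult:
    """Ordinary least squares of profile ``b`` on profile ``a``.

    Reports slope/intercept, R², adjusted R² = 1 − (1−R²)(n−1)/(n−2),
    and the overall F-test (1, n−2 df) p-value.  R², adjusted R² and the
    p-value are symmetric in (a, b); the slope is not.
    """
    x = np.asarray(a.medians, dtype=float)
    y = np.asarray(b.medians, dtype=float)
    if len(x) != len(y):
        raise ValueError("profiles have different bin counts")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 bins for regression")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise RegressionUndefinedError("predictor profile has zero variance")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    syy = float(np.sum((y - y.mean()) ** 2))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    ss_res = syy - slope * sxy
    r2 = 1.0 - ss_res / syy if syy > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    if ss_res <= 0.0:
        f_stat = math.inf
        p = 0.0
    else:
        f_stat = (r2 / (1.0 - r2)) * (n - 2) if r2 < 1.0 else math.inf
        p = float(_stats.f.sf(f_stat, 1, n - 2))
    return RegressionResult(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        r_squared_adjusted=r2_adj,
        f_statistic=f_stat,
        f_test_p=p,
        n=n,
    )


def correlation_matrix(
    profiles: Sequence[BinnedProfile],
    score: str = "pearson",
    method: str = "complete",
    metric: str = "euclidean",
) -> CorrelationMatrix:
    """All pairwise scores between profiles, with a clustered ordering.

    ``score`` is Pearson correlation or the adjusted R² of the pairwise
    OLS fit.  Hierarchical clustering (Euclidean distance on the raw
    profile vectors, complete linkage by default) supplies the leaf
    order used to arrange heatmaps; the result is deterministic given
    the input order.  Profiles with zero variance get NaN scores against
    other profiles (flagged undefined) but keep a diagonal of 1.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    n_bins = {len(p) for p in profiles}
    if len(n_bins) != 1:
        raise ValueError("profiles have differing bin counts")
    if score not in ("pearson", "adjusted_r2"):
        raise ValueError(f"unknown score {score!r}")
    m = len(profiles)
    data = np.vstack([p.medians for p in profiles]).astype(float)
    scores = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            xi, xj = data[i], data[j]
            if xi.std() == 0.0 or xj.std() == 0.0:
                val = math.nan
            elif score == "pearson":
                val = float(np.corrcoef(xi, xj)[0, 1])
            else:
                val = pairwise_regression(profiles[i], profiles[j]).r_squared_adjusted
            scores[i, j] = scores[j, i] = val
    Z = _hierarchy.linkage(data, method=method, metric=metric)
    order = [int(i) for i in _hierarchy.leaves_list(Z)]
    return CorrelationMatrix(
        names=[p.name for p in profiles], scores=scores, order=order, linkage=Z
    )
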