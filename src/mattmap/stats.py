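"""Slice-wise transit-time profiles, distance regression and ROI analyses.

Arrival time in the cerebral arterial tree increases with distance from the
major input arteries, so the mean breakpoint per axial slice rises roughly
linearly in the caudal-to-cranial direction.  This module computes the
slice profile, its linear regression against distance (slope in ms/mm,
adjusted R^2), global-maximum summaries across groups, pre/post slope
differences, and region-level cross-modal correlations (e.g. macrovascular
vs tissue arrival time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .fitting import MattMap


@dataclass
class SliceProfile:
    """Mean/sd breakpoint per (group of) slice(s) vs distance from slice 0."""

    distance: np.ndarray   # mm, centre of each slice group
    mean_matt: np.ndarray  # ms
    sd_matt: np.ndarray    # ms (NaN for single-voxel entries)
    n_voxels: np.ndarray   # defined voxels per entry

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"distance_mm": self.distance, "mean_matt_ms": self.mean_matt,
             "sd_matt_ms": self.sd_matt, "n_voxels": self.n_voxels}
        )


@dataclass
class DistanceRegression:
    """OLS of slice-mean breakpoint on distance."""

    slope: float       # ms/mm
    intercept: float   # ms
    adj_r2: float
    n: int
    r2: float = np.nan
    p: float = np.nan

    def predict(self, d) -> float:
        return self.intercept + self.slope * np.asarray(d, float)


def slice_profile(matt_map, slice_thickness: float,
                  group_size: int = 1) -> SliceProfile:
    """Per-slice(-group) mean and sd of the defined breakpoint map.

    Distance is measured from the centre of the most caudal slice (slice 0)
    in mm; a group of ``group_size`` slices is placed at the centre of the
    group.  Slices with no defined voxels are dropped.
    """
    if slice_thickness <= 0:
        raise ValueError("slice_thickness must be > 0")
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    matt = matt_map.matt if isinstance(matt_map, MattMap) else np.asarray(
        matt_map, float)
    nz = matt.shape[2]
    dist, mean, sd, n = [], [], [], []
    for start in range(0, nz, group_size):
        sl = matt[:, :, start:start + group_size]
        vals = sl[np.isfinite(sl)]
        if vals.size == 0:
            continue
        centre = start + (min(group_size, nz - start) - 1) / 2.0
        dist.append(centre * slice_thickness)
        mean.append(float(vals.mean()))
        sd.append(float(vals.std(ddof=1)) if vals.size > 1 else 0.0)
        n.append(int(vals.size))
    if not dist:
        raise ValueError("map has no defined voxels")
    return SliceProfile(np.array(dist), np.array(mean), np.array(sd),
                        np.array(n))


def fit_distance_regression(profile: SliceProfile,
                            weight_by_voxels: bool = False,
                            exclude_distance_range: tuple[float, float] | None
                            = None) -> DistanceRegression:
    """OLS of mean breakpoint on distance; adjusted R^2 goodness of fit.

    ``exclude_distance_range`` censors a distance window (e.g. oscillatory
    arrival values near the carotid siphon) before fitting.
    """
    d = profile.distance
    y = profile.mean_matt
    w = profile.n_voxels.astype(float)
    if exclude_distance_range is not None:
        lo, hi = exclude_distance_range
        keep = (d < lo) | (d > hi)
        d, y, w = d[keep], y[keep], w[keep]
    n = d.size
    if n < 3:
        raise ValueError("need at least 3 profile entries")
    if weight_by_voxels:
        W = np.diag(w)
        X = np.column_stack([np.ones(n), d])
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        intercept, slope = beta
        yhat = X @ beta
        ybar = np.average(y, weights=w)
        r2 = 1.0 - np.sum(w * (y - yhat) ** 2) / np.sum(w * (y - ybar) ** 2)
        p = np.nan
    else:
        res = sps.linregress(d, y)
        slope, intercept = res.slope, res.intercept
        r2 = res.rvalue**2
        p = res.pvalue
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return DistanceRegression(slope=float(slope), intercept=float(intercept),
                              adj_r2=float(adj_r2), n=int(n), r2=float(r2),
                              p=float(p))


def predict_at_distance(reg: DistanceRegression, d: float) -> float:
    """Regression-predicted mean breakpoint (ms) at distance ``d`` mm."""
    return float(reg.intercept + reg.slope * d)


def group_summary(matt_tot_values) -> tuple[float, float, float]:
    """Mean, sample sd and range of a set of global-maximum values.

    sd uses the n-1 denominator and is NaN for a single value; range is
    max minus min.
    """
    vals = np.asarray(matt_tot_values, float)
    if vals.size == 0:
        raise ValueError("empty value list")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else np.nan
    return float(vals.mean()), sd, float(vals.max() - vals.min())


def slope_difference(pre: DistanceRegression | float,
                     post: DistanceRegression | float) -> float:
    """Pre-minus-post distance-regression slope (ms/mm).

    Positive values mean faster arrival (flatter gradient) after the
    vasodilatory challenge.
    """
    s_pre = pre.slope if isinstance(pre, DistanceRegression) else float(pre)
    s_post = post.slope if isinstance(post, DistanceRegression) else float(post)
    return s_pre - s_post


def roi_correlation(table_a: pd.DataFrame, table_b: pd.DataFrame,
                    field_a: str = "mean_matt_ms",
                    field_b: str = "mean_matt_ms") -> dict:
    """Region-level association between two modalities.

    Pairwise-complete regions only; OLS of ``field_b`` on ``field_a`` with
    Pearson r and a two-sided p-value from the t distribution with n-2
    degrees of freedom.
    """
    a = table_a[field_a]
    b = table_b.loc[table_a.index.intersection(table_b.index), field_b]
    joined = pd.DataFrame({"a": a, "b": b}).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError("need at least 3 pairwise-complete regions")
    res = sps.linregress(joined["a"], joined["b"])
    r = res.rvalue
    adj_r2 = 1.0 - (1.0 - r**2) * (n - 1) / (n - 2)
    return {
        "pearson_r": float(r),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "adj_r2": float(adj_r2),
        "p": float(res.pvalue),
        "n": n,
    }


class SliceTrendRegression(BaseEstimator):
    """sklearn-style estimator for the slice-distance arrival-time trend.

    ``fit(matt_map)`` computes the slice profile and its distance
    regression; ``predict(d)`` evaluates the fitted line at distances in
    mm.
    """

    def __init__(self, slice_thickness: float = 1.0, group_size: int = 1,
                 weight_by_voxels: bool = False,
                 exclude_distance_range=None):
        self.slice_thickness = slice_thickness
        self.group_size = group_size
        self.weight_by_voxels = weight_by_voxels
        self.exclude_distance_range = exclude_distance_range

    def fit(self, matt_map, y=None):
        self.profile_ = slice_profile(matt_map, self.slice_thickness,
                                      self.group_size)
        reg = fit_distance_regression(
            self.profile_, weight_by_voxels=self.weight_by_voxels,
            exclude_distance_range=self.exclude_distance_range)
        self.regression_ = reg
        self.slope_ = reg.slope
        self.intercept_ = reg.intercept
        self.adj_r2_ = reg.adj_r2
        return self

    def predict(self, d):
        return self.regression_.predict(d)
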