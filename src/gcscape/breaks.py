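"""Exact Fisher-Jenks natural-breaks clustering of 1-D GC% values.

The Fisher-Jenks method partitions sorted one-dimensional values into k
contiguous classes minimizing the sum of squared deviations from class
means (SDCM). The goodness of variance fit,

    GVF = (SDAM - SDCM) / SDAM,

where SDAM is the sum of squared deviations from the array mean, ranges
from 0 (single class, no fit) to 1 (perfect fit); the smallest k whose
optimal partition reaches a GVF threshold (0.9 by default) is selected as
the natural class count.

Window GC% tracks can contain millions of values, and the exact dynamic
program is quadratic in the number of *distinct* values, so raw values are
binned to 0.01 GC% resolution into a weighted multiset first; the weighted
DP is then exact on the binned data. GC% of a w-bp window is a multiple of
100/w, so for the window sizes in routine use the binning is lossless or
nearly so.

Exposed both as scikit-learn style estimators (:class:`FisherJenksBreaks`,
:class:`NaturalBreaksKSelector`) and as plain functions (:func:`fisher_jenks`,
:func:`gvf`, :func:`select_k`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "WeightedValues",
    "BreaksResult",
    "fisher_jenks",
    "gvf",
    "select_k",
    "FisherJenksBreaks",
    "NaturalBreaksKSelector",
]

DEFAULT_BIN_RESOLUTION = 0.01
DEFAULT_GVF_THRESHOLD = 0.9
DEFAULT_K_MAX = 10


@dataclass(frozen=True)
class WeightedValues:
    """Strictly ascending distinct values with positive integer multiplicities."""

    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        w = np.asarray(self.weights, dtype=np.int64)
        if v.ndim != 1 or w.ndim != 1 or v.size != w.size:
            raise ValueError("values and weights must be 1-D and of equal length")
        if v.size == 0:
            raise ValueError("empty value set")
        if not np.all(np.diff(v) > 0):
            raise ValueError("values must be strictly ascending")
        if np.any(w < 1):
            raise ValueError("weights must be >= 1")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_raw(
        cls, raw: Sequence[float], bin_resolution: float = DEFAULT_BIN_RESOLUTION
    ) -> "WeightedValues":
        """Bin raw values to ``bin_resolution`` and collapse to a weighted multiset."""
        x = np.asarray(raw, dtype=float).ravel()
        x = x[np.isfinite(x)]
        if x.size == 0:
            raise ValueError("empty value set")
        if bin_resolution > 0:
            x = np.round(x / bin_resolution) * bin_resolution
        values, weights = np.unique(x, return_counts=True)
        return cls(values, weights)

    @property
    def n_distinct(self) -> int:
        return int(self.values.size)

    @property
    def total_weight(self) -> int:
        return int(self.weights.sum())

    def expand(self) -> np.ndarray:
        """The explicit multiset (for small-n cross-checks)."""
        return np.repeat(self.values, self.weights)


@dataclass
class BreaksResult:
    """One optimal k-class partition of a weighted value set.

    ``break_values`` are the k-1 class boundaries, each the midpoint between
    the maximum of one class and the minimum of the next, so every value
    falls in exactly one class. ``class_assignment`` maps each distinct
    value to its class index 0..k-1.
    """

    k: int
    break_values: np.ndarray
    class_assignment: np.ndarray
    sdam: float
    sdcm: float
    gvf: float
    values: WeightedValues = field(repr=False)
    threshold_reached: bool = True

    def class_summary(self) -> pd.DataFrame:
        """Per-class min, max, count (with multiplicity) and weighted mean."""
        rows = []
        v, w = self.values.values, self.values.weights
        for c in range(self.k):
            sel = self.class_assignment == c
            vw = w[sel]
            rows.append(
                {
                    "class": c,
                    "min": float(v[sel].min()),
                    "max": float(v[sel].max()),
                    "count": int(vw.sum()),
                    "mean": float(np.average(v[sel], weights=vw)),
                }
            )
        return pd.DataFrame(rows)

    def assign(self, x: Sequence[float]) -> np.ndarray:
        """Class index for arbitrary values; a value equal to a break goes low."""
        return np.searchsorted(self.break_values, np.asarray(x, dtype=float), side="left")

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "break_values": [float(b) for b in self.break_values],
            "sdam": self.sdam,
            "sdcm": self.sdcm,
            "gvf": self.gvf,
            "threshold_reached": self.threshold_reached,
            "classes": self.class_summary().to_dict(orient="records"),
        }


def _coerce_weighted(
    values: Union[WeightedValues, Sequence[float]],
    bin_resolution: float = DEFAULT_BIN_RESOLUTION,
) -> WeightedValues:
    if isinstance(values, WeightedValues):
        return values
    return WeightedValues.from_raw(values, bin_resolution=bin_resolution)


def _prefix_moments(wv: WeightedValues):
    v, w = wv.values, wv.weights.astype(float)
    W = np.concatenate(([0.0], np.cumsum(w)))
    S = np.concatenate(([0.0], np.cumsum(w * v)))
    Q = np.concatenate(([0.0], np.cumsum(w * v * v)))
    return W, S, Q


def _jenks_dp(wv: WeightedValues, k_max: int):
    """Weighted Fisher dynamic program up to k_max classes.

    Returns (dp, back): dp[c, j] is the minimal SDCM of the first j distinct
    values split into c+1 contiguous classes; back[c, j] the split index
    (smallest at ties, for determinism).
    """
    m = wv.n_distinct
    W, S, Q = _prefix_moments(wv)

    dp = np.full((k_max, m + 1), np.inf)
    back = np.zeros((k_max, m + 1), dtype=np.int64)
    j_all = np.arange(1, m + 1)
    # one class: cost of the full prefix
    dp[0, 1:] = np.maximum(Q[j_all] - S[j_all] ** 2 / W[j_all], 0.0)
    for c in range(1, k_max):
        for j in range(c + 1, m + 1):
            i = np.arange(c, j)
            w_seg = W[j] - W[i]
            s_seg = S[j] - S[i]
            q_seg = Q[j] - Q[i]
            seg = np.maximum(q_seg - s_seg * s_seg / w_seg, 0.0)
            total = dp[c - 1, i] + seg
            a = int(np.argmin(total))  # first minimum: deterministic tie-break
            dp[c, j] = total[a]
            back[c, j] = i[a]
    return dp, back


def _backtrack(back: np.ndarray, k: int, m: int) -> np.ndarray:
    """Class start indices (length k, first always 0) from the DP back-pointers."""
    bounds = np.empty(k, dtype=np.int64)
    j = m
    for c in range(k - 1, -1, -1):
        i = back[c, j] if c > 0 else 0
        bounds[c] = i
        j = i
    return bounds


def _result_from_bounds(wv: WeightedValues, bounds: np.ndarray, sdcm: float) -> BreaksResult:
    v = wv.values
    k = bounds.size
    assignment = np.zeros(wv.n_distinct, dtype=np.int64)
    for c in range(1, k):
        assignment[bounds[c] :] = c
    break_values = np.array(
        [(v[bounds[c] - 1] + v[bounds[c]]) / 2.0 for c in range(1, k)], dtype=float
    )
    sdam = _sdam(wv)
    g = (sdam - sdcm) / sdam if sdam > 0 else 0.0
    return BreaksResult(
        k=k,
        break_values=break_values,
        class_assignment=assignment,
        sdam=float(sdam),
        sdcm=float(sdcm),
        gvf=float(min(max(g, 0.0), 1.0)),
        values=wv,
    )


def _sdam(wv: WeightedValues) -> float:
    v, w = wv.values, wv.weights.astype(float)
    mean = np.average(v, weights=w)
    return float(np.sum(w * (v - mean) ** 2))


def fisher_jenks(
    values: Union[WeightedValues, Sequence[float]],
    k: int,
    bin_resolution: float = DEFAULT_BIN_RESOLUTION,
) -> BreaksResult:
    """Exact optimal partition of 1-D values into k contiguous classes.

    ``values`` may be a :class:`WeightedValues` multiset or a raw sequence
    (binned to ``bin_resolution`` first). Requires 1 <= k <= number of
    distinct values; the optimum minimizes SDCM and is deterministic.
    """
    wv = _coerce_weighted(values, bin_resolution)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > wv.n_distinct:
        raise ValueError(
            f"k={k} exceeds the number of distinct values ({wv.n_distinct})"
        )
    dp, back = _jenks_dp(wv, k)
    bounds = _backtrack(back, k, wv.n_distinct)
    return _result_from_bounds(wv, bounds, float(dp[k - 1, wv.n_distinct]))


def gvf(
    values: Union[WeightedValues, Sequence[float]],
    assignment: Sequence[int],
    bin_resolution: float = DEFAULT_BIN_RESOLUTION,
) -> float:
    """Goodness of variance fit of a contiguous class assignment.

    Returns (SDAM - SDCM)/SDAM; by convention 0 when SDAM is 0 (all values
    identical). ``assignment`` gives a class index per distinct value (or per
    raw value when ``values`` is an unbinned raw sequence) and must be
    non-decreasing (classes are intervals of the sorted values).
    """
    wv = _coerce_weighted(values, bin_resolution)
    a = np.asarray(assignment, dtype=np.int64)
    if a.size != wv.n_distinct:
        raw = None if isinstance(values, WeightedValues) else np.asarray(
            values, dtype=float
        ).ravel()
        if raw is None or a.size != raw.size:
            raise ValueError("assignment length must match the number of values")
        # per-raw-value assignment: collapse onto the distinct values, requiring
        # duplicates to share a class
        binned = np.round(raw / bin_resolution) * bin_resolution if bin_resolution > 0 else raw
        idx = np.searchsorted(wv.values, binned)
        collapsed = np.empty(wv.n_distinct, dtype=np.int64)
        for d in range(wv.n_distinct):
            classes = np.unique(a[idx == d])
            if classes.size != 1:
                raise ValueError("duplicate values assigned to different classes")
            collapsed[d] = classes[0]
        a = collapsed
    if np.any(np.diff(a) < 0):
        raise ValueError("assignment must be non-decreasing over sorted values")
    sdam = _sdam(wv)
    if sdam == 0:
        return 0.0
    v, w = wv.values, wv.weights.astype(float)
    sdcm = 0.0
    for c in np.unique(a):
        sel = a == c
        mean = np.average(v[sel], weights=w[sel])
        sdcm += float(np.sum(w[sel] * (v[sel] - mean) ** 2))
    return float((sdam - sdcm) / sdam)


def select_k(
    values: Union[WeightedValues, Sequence[float]],
    gvf_threshold: float = DEFAULT_GVF_THRESHOLD,
    k_max: int = DEFAULT_K_MAX,
    bin_resolution: float = DEFAULT_BIN_RESOLUTION,
) -> BreaksResult:
    """Smallest class count whose optimal partition reaches the GVF threshold.

    Runs the DP once up to ``k_max`` (capped at the number of distinct
    values) and returns the result for the smallest k with GVF >=
    ``gvf_threshold``. If no k reaches it — including the degenerate
    constant-array case, where GVF is 0 for every k — the k_max result is
    returned with ``threshold_reached=False``.
    """
    if not 0.0 < gvf_threshold < 1.0:
        raise ValueError("gvf_threshold must be in (0, 1)")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    wv = _coerce_weighted(values, bin_resolution)
    k_cap = min(k_max, wv.n_distinct)
    sdam = _sdam(wv)
    dp, back = _jenks_dp(wv, k_cap)
    m = wv.n_distinct
    chosen = None
    for k in range(1, k_cap + 1):
        sdcm = float(dp[k - 1, m])
        g = (sdam - sdcm) / sdam if sdam > 0 else 0.0
        if g >= gvf_threshold:
            chosen = k
            break
    if chosen is None:
        if sdam == 0:
            # constant array: every partition fits equally badly; report k=1
            result = _result_from_bounds(wv, np.zeros(1, dtype=np.int64), 0.0)
            result.threshold_reached = False
            return result
        chosen = k_cap
        flagged = False
    else:
        flagged = True
    bounds = _backtrack(back, chosen, m)
    result = _result_from_bounds(wv, bounds, float(dp[chosen - 1, m]))
    result.threshold_reached = flagged
    return result


def gvf_path(
    values: Union[WeightedValues, Sequence[float]],
    k_max: int = DEFAULT_K_MAX,
    bin_resolution: float = DEFAULT_BIN_RESOLUTION,
) -> np.ndarray:
    """Optimal GVF for each k in 1..min(k_max, distinct); non-decreasing in k."""
    wv = _coerce_weighted(values, bin_resolution)
    k_cap = min(k_max, wv.n_distinct)
    sdam = _sdam(wv)
    dp, _ = _jenks_dp(wv, k_cap)
    sdcm = dp[:, wv.n_distinct]
    if sdam == 0:
        return np.zeros(k_cap)
    return np.clip((sdam - sdcm) / sdam, 0.0, 1.0)


def _as_1d(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D value array or (n, 1) column, got shape {x.shape}")
    if x.size == 0:
        raise ValueError("empty value set")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    return x


class FisherJenksBreaks(ClusterMixin, BaseEstimator):
    """Fixed-k Fisher-Jenks natural-breaks clustering estimator.

    Parameters
    ----------
    n_classes : int, default 5
        Number of contiguous classes k.
    bin_resolution : float, default 0.01
        GC% binning resolution applied before the exact weighted DP; 0
        disables binning.

    Attributes
    ----------
    breaks_ : ndarray of shape (n_classes - 1,)
        Class boundaries (midpoints between adjacent classes).
    labels_ : ndarray of shape (n_samples,)
        Class index of each training value.
    gvf_, sdam_, sdcm_ : float
        Goodness of variance fit and its two components.
    result_ : BreaksResult
        Full partition record.
    """

    def __init__(self, n_classes: int = 5, bin_resolution: float = DEFAULT_BIN_RESOLUTION):
        self.n_classes = n_classes
        self.bin_resolution = bin_resolution

    def fit(self, X, y=None):
        x = _as_1d(X)
        res = fisher_jenks(
            WeightedValues.from_raw(x, self.bin_resolution), self.n_classes
        )
        self.result_ = res
        self.breaks_ = res.break_values
        self.gvf_ = res.gvf
        self.sdam_ = res.sdam
        self.sdcm_ = res.sdcm
        self.labels_ = res.assign(x)
        return self

    def predict(self, X):
        if not hasattr(self, "result_"):
            raise AttributeError("estimator is not fitted")
        return self.result_.assign(_as_1d(X))

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class NaturalBreaksKSelector(ClusterMixin, BaseEstimator):
    """GVF-threshold selection of the natural class count.

    Fits Fisher-Jenks partitions for k = 1..k_max and keeps the smallest k
    whose GVF reaches ``gvf_threshold`` (paper-style natural cluster count).

    Attributes
    ----------
    k_ : int
        Selected class count.
    gvf_ : float
        GVF of the selected partition.
    gvf_path_ : ndarray
        Optimal GVF for each candidate k (non-decreasing).
    threshold_reached_ : bool
        False when even k_max fails the threshold (k_ is then k_max).
    breaks_, labels_, result_ : as in :class:`FisherJenksBreaks`.
    """

    def __init__(
        self,
        gvf_threshold: float = DEFAULT_GVF_THRESHOLD,
        k_max: int = DEFAULT_K_MAX,
        bin_resolution: float = DEFAULT_BIN_RESOLUTION,
    ):
        self.gvf_threshold = gvf_threshold
        self.k_max = k_max
        self.bin_resolution = bin_resolution

    def fit(self, X, y=None):
        x = _as_1d(X)
        wv = WeightedValues.from_raw(x, self.bin_resolution)
        res = select_k(wv, self.gvf_threshold, self.k_max)
        self.result_ = res
        self.k_ = res.k
        self.gvf_ = res.gvf
        self.breaks_ = res.break_values
        self.threshold_reached_ = res.threshold_reached
        self.gvf_path_ = gvf_path(wv, self.k_max)
        self.labels_ = res.assign(x)
        return self

    def predict(self, X):
        if not hasattr(self, "result_"):
            raise AttributeError("estimator is not fitted")
        return self.result_.assign(_as_1d(X))

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
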