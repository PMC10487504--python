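"""Isochore-family classification of GC% windows and segment merging.

Windows are labeled with the classical isochore families — AT-rich "light"
L1, L2 and GC-rich "heavy" H1, H2, H3 — by fixed GC% intervals, and maximal
runs of identically-labeled contiguous windows are merged into isochore-style
segments. Family intervals are lower-open, upper-closed; a GC% exactly on a
boundary belongs to the lower family. The default boundaries (37, 41, 46,
53 GC%) are the conventional isochore-family limits of the segmentation
literature and are fully configurable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .windows import NPolicy, WindowedGC

__all__ = [
    "IsochoreFamilySpec",
    "SegmentMap",
    "IsochoreFamilyClassifier",
    "classify_windows",
    "merge_segments",
    "isofamily_histogram",
    "range_compression_report",
]

DEFAULT_FAMILIES = (
    ("L1", 0.0, 37.0),
    ("L2", 37.0, 41.0),
    ("H1", 41.0, 46.0),
    ("H2", 46.0, 53.0),
    ("H3", 53.0, 100.0),
)


@dataclass(frozen=True)
class IsochoreFamilySpec:
    """Ordered, contiguous GC% intervals covering (0, 100], one per family."""

    families: tuple = DEFAULT_FAMILIES

    def __post_init__(self) -> None:
        fams = tuple((str(n), float(lo), float(hi)) for n, lo, hi in self.families)
        if not fams:
            raise ValueError("at least one family required")
        names = [f[0] for f in fams]
        if len(set(names)) != len(names):
            raise ValueError("family names must be unique")
        if fams[0][1] != 0.0 or fams[-1][2] != 100.0:
            raise ValueError("family intervals must cover (0, 100]")
        for (_, _, hi_a), (_, lo_b, _) in zip(fams, fams[1:]):
            if hi_a != lo_b:
                raise ValueError("family intervals must be contiguous and ascending")
        for _, lo, hi in fams:
            if not lo < hi:
                raise ValueError("family intervals must be ascending")
        object.__setattr__(self, "families", fams)

    @property
    def names(self) -> list:
        return [f[0] for f in self.families]

    @property
    def uppers(self) -> np.ndarray:
        return np.array([f[2] for f in self.families])

    def classify(self, gc: Sequence[float]) -> np.ndarray:
        """Family name for each GC% value; boundary values go to the lower family."""
        x = np.asarray(gc, dtype=float)
        if np.any(~np.isfinite(x)) or np.any(x <= 0.0) or np.any(x > 100.0):
            bad = x[~(np.isfinite(x) & (x > 0.0) & (x <= 100.0))]
            raise ValueError(f"GC% outside (0, 100]: {bad[:5]}")
        idx = np.searchsorted(self.uppers, x, side="left")
        return np.asarray(self.names, dtype=object)[idx]

    @classmethod
    def from_mapping(cls, bounds: Mapping[str, float]) -> "IsochoreFamilySpec":
        """Build from an ordered name -> upper-bound mapping (last must be 100)."""
        fams = []
        lo = 0.0
        for name, hi in bounds.items():
            fams.append((name, lo, float(hi)))
            lo = float(hi)
        return cls(tuple(fams))

    @classmethod
    def from_file(cls, path: Union[str, os.PathLike]) -> "IsochoreFamilySpec":
        """Read 'name<TAB or =>upper_gc' lines, ascending; '#' comments allowed."""
        bounds: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" in line:
                    name, val = line.split("=", 1)
                else:
                    name, val = line.split(None, 1)
                bounds[name.strip()] = float(val)
        return cls.from_mapping(bounds)


@dataclass
class SegmentMap:
    """Merged same-family genomic segments (the isochore-style output).

    ``frame`` columns: seq_id, start, end, family, mean_gc — non-overlapping,
    sorted, with mean_gc the length-weighted mean GC% of the member windows.
    """

    assembly_id: str
    frame: pd.DataFrame

    def to_bed(self, path: Union[str, os.PathLike]) -> None:
        self.frame[["seq_id", "start", "end", "family"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    def segment_lengths(self) -> np.ndarray:
        return (self.frame["end"] - self.frame["start"]).to_numpy()


class IsochoreFamilyClassifier(BaseEstimator):
    """Interval classifier mapping GC% values to isochore-family labels.

    A stateless transformer in estimator clothing so it can sit in sklearn
    pipelines next to :class:`~gcscape.breaks.FisherJenksBreaks`; ``fit``
    only validates the family specification.
    """

    def __init__(self, family_spec: IsochoreFamilySpec | None = None):
        self.family_spec = family_spec

    def fit(self, X=None, y=None):
        self.families_ = self.family_spec or IsochoreFamilySpec()
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "families_"):
            self.fit()
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        return self.families_.classify(x)

    def transform(self, X) -> np.ndarray:
        return self.predict(X)


def classify_windows(
    windows: WindowedGC,
    spec: IsochoreFamilySpec | None = None,
    n_policy: NPolicy | None = None,
) -> pd.Series:
    """Family label per window, aligned to ``windows.frame``; excluded windows get NA."""
    spec = spec or IsochoreFamilySpec()
    mask = windows.included_mask(n_policy)
    labels = pd.Series(pd.NA, index=windows.frame.index, dtype="object", name="family")
    gc = windows.frame["gc_percent"].to_numpy()[mask]
    labels.iloc[np.flatnonzero(mask)] = spec.classify(gc)
    return labels


def merge_segments(windows: WindowedGC, labels: pd.Series) -> SegmentMap:
    """Merge maximal runs of identically-labeled contiguous windows.

    A run breaks at sequence boundaries, at excluded (NA-labeled) windows —
    assembly gaps must not be bridged into fake long isochores — and at any
    coordinate discontinuity. ``mean_gc`` is the window-length-weighted mean.
    """
    f = windows.frame
    segs = []
    cur = None  # [seq_id, start, end, family, gc_weight_sum, length_sum]
    for i in range(len(f)):
        row = f.iloc[i]
        lab = labels.iloc[i]
        if pd.isna(lab):
            cur = _flush(segs, cur)
            continue
        contiguous = (
            cur is not None
            and cur[0] == row["seq_id"]
            and cur[2] == row["start"]
            and cur[3] == lab
        )
        span = int(row["end"] - row["start"])
        if contiguous:
            cur[2] = int(row["end"])
            cur[4] += row["gc_percent"] * span
            cur[5] += span
        else:
            cur = _flush(segs, cur)
            cur = [row["seq_id"], int(row["start"]), int(row["end"]), lab,
                   row["gc_percent"] * span, span]
    _flush(segs, cur)
    frame = pd.DataFrame(segs, columns=["seq_id", "start", "end", "family", "mean_gc"])
    return SegmentMap(assembly_id=windows.assembly_id, frame=frame)


def _flush(segs: list, cur):
    if cur is not None:
        segs.append((cur[0], cur[1], cur[2], cur[3], cur[4] / cur[5]))
    return None


def isofamily_histogram(
    windows: WindowedGC,
    labels: pd.Series,
    bin_width: float = 1.0,
    n_policy: NPolicy | None = None,
) -> pd.DataFrame:
    """Stacked per-family GC% histogram: rows (bin_low, family, count).

    Summing counts over families within each bin reproduces the plain GC%
    histogram exactly — the comparison surface between a family-colored
    isochore plot and the authentic GC% distribution.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    mask = windows.included_mask(n_policy) & labels.notna().to_numpy()
    gc = windows.frame["gc_percent"].to_numpy()[mask]
    fam = labels.to_numpy()[mask]
    bin_low = np.floor(gc / bin_width) * bin_width
    table = (
        pd.DataFrame({"bin_low": bin_low, "family": fam})
        .groupby(["bin_low", "family"], sort=True)
        .size()
        .reset_index(name="count")
    )
    return table


def range_compression_report(
    windowed_by_size: Mapping[int, WindowedGC],
    n_policy: NPolicy | None = None,
) -> pd.DataFrame:
    """Dispersion of window GC% per window size: min, p1, p99, max, sd, range.

    Quantifies how a coarse window (100 kb) compresses the apparent GC%
    range relative to a fine one (1 kb); sorted by window size.
    """
    if len(windowed_by_size) < 2:
        raise ValueError("need windowed GC at >= 2 window sizes")
    rows = []
    for size in sorted(windowed_by_size):
        vals = windowed_by_size[size].values(n_policy)
        p1, p99 = np.percentile(vals, [1, 99])
        rows.append(
            {
                "window_size": size,
                "n_windows": vals.size,
                "min": float(vals.min()),
                "p1": float(p1),
                "p99": float(p99),
                "max": float(vals.max()),
                "sd": float(vals.std(ddof=0)),
                "p99_minus_p1": float(p99 - p1),
            }
        )
    return pd.DataFrame(rows)
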