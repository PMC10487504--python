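"""Result tables: cluster-count matrices, multiscale histograms, size stats.

Each function consumes window GC% tracks or plain value lists already
produced by the other modules and emits a tidy pandas table; nothing here
recomputes anything from FASTA. Plot rendering, when wanted, happens on top
of these tables and is deliberately out of the tested surface.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import List, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .breaks import DEFAULT_GVF_THRESHOLD, DEFAULT_K_MAX, select_k
from .windows import WindowedGC

__all__ = [
    "DEFAULT_WINDOW_SIZES",
    "ClusterCountTable",
    "SizeStats",
    "build_cluster_count_table",
    "multiscale_histogram_table",
    "size_stats",
    "run_manifest",
]

DEFAULT_WINDOW_SIZES = (1_000, 3_000, 10_000, 20_000, 100_000)


@dataclass
class ClusterCountTable:
    """Selected natural class count per (assembly, window size), with GVF."""

    k: pd.DataFrame  # assemblies x window sizes -> selected k
    gvf: pd.DataFrame  # same shape -> GVF of the selected partition
    threshold_reached: pd.DataFrame  # same shape -> bool


def _values_of(entry) -> np.ndarray:
    if isinstance(entry, WindowedGC):
        return entry.values()
    return np.asarray(entry, dtype=float)


def build_cluster_count_table(
    assemblies: Mapping[str, Mapping[int, Union[WindowedGC, Sequence[float]]]],
    gvf_threshold: float = DEFAULT_GVF_THRESHOLD,
    k_max: int = DEFAULT_K_MAX,
    window_sizes: Sequence[int] = DEFAULT_WINDOW_SIZES,
) -> ClusterCountTable:
    """Natural class count per assembly and window size.

    ``assemblies`` maps assembly id -> {window size -> WindowedGC or GC%
    values}. Every configured window size must be present for every
    assembly; a gap is an error naming the missing cells.
    """
    sizes = list(window_sizes)
    missing = [
        (a, s) for a, per_size in assemblies.items() for s in sizes if s not in per_size
    ]
    if missing:
        raise ValueError(f"missing window sizes: {missing}")
    k_rows, gvf_rows, flag_rows = {}, {}, {}
    for assembly, per_size in assemblies.items():
        res = {s: select_k(_values_of(per_size[s]), gvf_threshold, k_max) for s in sizes}
        k_rows[assembly] = {s: r.k for s, r in res.items()}
        gvf_rows[assembly] = {s: r.gvf for s, r in res.items()}
        flag_rows[assembly] = {s: r.threshold_reached for s, r in res.items()}
    return ClusterCountTable(
        k=pd.DataFrame.from_dict(k_rows, orient="index")[sizes],
        gvf=pd.DataFrame.from_dict(gvf_rows, orient="index")[sizes],
        threshold_reached=pd.DataFrame.from_dict(flag_rows, orient="index")[sizes],
    )


def multiscale_histogram_table(
    windowed_by_size: Mapping[int, Union[WindowedGC, Sequence[float]]],
    bin_width: float = 1.0,
) -> pd.DataFrame:
    """Long-format GC% histogram per window size: (window_size, bin_low, count, density).

    Densities are normalized within each window size; empty bins are omitted.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if not windowed_by_size:
        raise ValueError("need at least one window size")
    frames = []
    for size in sorted(windowed_by_size):
        vals = _values_of(windowed_by_size[size])
        bin_low = np.floor(vals / bin_width) * bin_width
        counts = pd.Series(bin_low).value_counts().sort_index()
        frames.append(
            pd.DataFrame(
                {
                    "window_size": size,
                    "bin_low": counts.index.to_numpy(),
                    "count": counts.to_numpy(),
                    "density": counts.to_numpy() / vals.size,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass
class SizeStats:
    """Five-number-style summary of one group of lengths, with Tukey outliers."""

    group: str
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    outliers: List[float]

    def to_row(self) -> dict:
        return {
            "group": self.group,
            "n": self.n,
            "mean": self.mean,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "outliers": ",".join(f"{o:g}" for o in self.outliers),
        }


def size_stats(lengths_by_group: Mapping[str, Sequence[float]]) -> List[SizeStats]:
    """Mean, median, quartiles and Tukey (1.5 IQR) outliers per group of lengths."""
    out = []
    for group, lengths in lengths_by_group.items():
        x = np.asarray(lengths, dtype=float)
        if x.size == 0:
            raise ValueError(f"group {group!r} is empty")
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        outliers = sorted(float(v) for v in x[(x < lo) | (x > hi)])
        out.append(
            SizeStats(
                group=group,
                n=int(x.size),
                mean=float(x.mean()),
                median=float(med),
                q1=float(q1),
                q3=float(q3),
                outliers=outliers,
            )
        )
    return out


def run_manifest(config: Mapping, seeds: Mapping | None = None) -> dict:
    """Reproducibility manifest: the config itself, a stable hash of it, seeds."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return {
        "config": json.loads(canonical),
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seeds": dict(seeds or {}),
    }
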