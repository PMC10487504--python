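"""Non-overlapping fixed-size window GC% scanning of FASTA assemblies.

Every downstream stage (natural-breaks clustering, isochore-family
segmentation, multiscale histograms) consumes the per-window GC% track
produced here. Windows are half-open 0-based intervals; GC% is computed
over unambiguous bases only (case-insensitive), and ambiguous IUPAC codes
are all treated as N. Soft-masked lower-case bases count as their base
identity: masking records repeat annotation, not composition.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Tuple, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "NPolicy",
    "WindowedGC",
    "scan_fasta",
    "windows_from_sequences",
    "whole_sequence_gc",
]

_GC_BYTES = frozenset(b"GCgc")
_AT_BYTES = frozenset(b"ATat")

# lookup tables over the 256 byte values: 1 where the byte is an unambiguous
# G/C (resp. A/T), else 0; everything else (N and the other IUPAC codes,
# which carry no defined composition) counts as ambiguous
_IS_GC = np.zeros(256, dtype=np.int64)
_IS_AT = np.zeros(256, dtype=np.int64)
for _b in _GC_BYTES:
    _IS_GC[_b] = 1
for _b in _AT_BYTES:
    _IS_AT[_b] = 1

WINDOW_COLUMNS = ["assembly_id", "seq_id", "start", "end", "gc_percent", "n_fraction"]


@dataclass(frozen=True)
class NPolicy:
    """Window-exclusion policy for ambiguous (N) content.

    A window is excluded from downstream value sets when its fraction of
    ambiguous bases exceeds ``max_n_fraction``; GC% itself is always
    computed over the unambiguous bases only. Trailing partial windows
    (sequence length not divisible by the window size) stay in the
    coordinate track but are dropped from value sets unless
    ``include_partial`` is set, so that short-window variance does not
    inflate histogram tails.
    """

    max_n_fraction: float = 0.5
    include_partial: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_n_fraction <= 1.0:
            raise ValueError("max_n_fraction must be in [0, 1]")


@dataclass
class WindowedGC:
    """Per-window GC% values with genomic coordinates for one assembly.

    ``frame`` has columns seq_id, start, end, gc_percent, n_fraction with
    0-based half-open coordinates, contiguous and sorted within each
    sequence. Windows with no unambiguous base have NaN gc_percent and are
    never part of value sets.
    """

    assembly_id: str
    window_size: int
    frame: pd.DataFrame
    n_policy: NPolicy = field(default_factory=NPolicy)

    def included_mask(self, n_policy: NPolicy | None = None) -> np.ndarray:
        """Boolean mask of windows admitted to downstream value sets."""
        pol = n_policy or self.n_policy
        f = self.frame
        mask = (f["n_fraction"].to_numpy() <= pol.max_n_fraction) & np.isfinite(
            f["gc_percent"].to_numpy()
        )
        if not pol.include_partial:
            full = (f["end"] - f["start"]).to_numpy() == self.window_size
            mask &= full
        return mask

    def values(self, n_policy: NPolicy | None = None) -> np.ndarray:
        """GC% values of the admitted windows, in genomic order."""
        return self.frame["gc_percent"].to_numpy()[self.included_mask(n_policy)]

    def to_tsv(self, path: Union[str, os.PathLike]) -> None:
        out = self.frame.copy()
        out.insert(0, "assembly_id", self.assembly_id)
        out.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: Union[str, os.PathLike], window_size: int | None = None) -> "WindowedGC":
        frame = pd.read_csv(path, sep="\t")
        missing = [c for c in WINDOW_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"window TSV {path} lacks columns: {missing}")
        assembly = str(frame["assembly_id"].iloc[0]) if len(frame) else ""
        if window_size is None:
            window_size = int((frame["end"] - frame["start"]).max()) if len(frame) else 0
        return cls(
            assembly_id=assembly,
            window_size=int(window_size),
            frame=frame.drop(columns=["assembly_id"]).reset_index(drop=True),
        )

    def to_bed(self, path: Union[str, os.PathLike]) -> None:
        """BED4 track; the name column carries GC% to two decimals."""
        with open(path, "w") as fh:
            for row in self.frame.itertuples(index=False):
                gc = "NA" if not np.isfinite(row.gc_percent) else f"{row.gc_percent:.2f}"
                fh.write(f"{row.seq_id}\t{row.start}\t{row.end}\t{gc}\n")


def _open_maybe_gzip(path: Union[str, os.PathLike]):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_fasta(path: Union[str, os.PathLike]) -> Iterator[Tuple[str, np.ndarray]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    n_records = 0
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            seq = bytes(record.seq)
            if len(seq) == 0:
                raise ValueError(f"malformed FASTA record with empty sequence: {record.id!r}")
            n_records += 1
            yield record.id, np.frombuffer(seq, dtype=np.uint8)
    if n_records == 0:
        raise ValueError(f"no FASTA records found in {path}")


def _coerce_sequence(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq.astype(np.uint8, copy=False)
    if isinstance(seq, (bytes, bytearray)):
        return np.frombuffer(bytes(seq), dtype=np.uint8)
    return np.frombuffer(str(seq).encode("ascii"), dtype=np.uint8)


def _window_frame(seq_id: str, arr: np.ndarray, window_size: int) -> pd.DataFrame:
    length = arr.size
    starts = np.arange(0, length, window_size, dtype=np.int64)
    ends = np.minimum(starts + window_size, length)
    gc_cum = np.concatenate(([0], np.cumsum(_IS_GC[arr])))
    at_cum = np.concatenate(([0], np.cumsum(_IS_AT[arr])))
    gc = gc_cum[ends] - gc_cum[starts]
    at = at_cum[ends] - at_cum[starts]
    span = ends - starts
    unamb = gc + at
    with np.errstate(invalid="ignore", divide="ignore"):
        gc_percent = np.where(unamb > 0, 100.0 * gc / np.maximum(unamb, 1), np.nan)
    n_fraction = (span - unamb) / span
    return pd.DataFrame(
        {
            "seq_id": seq_id,
            "start": starts,
            "end": ends,
            "gc_percent": gc_percent,
            "n_fraction": n_fraction,
        }
    )


def windows_from_sequences(
    sequences: Iterable[Tuple[str, Union[str, bytes, np.ndarray]]],
    window_size: int,
    assembly_id: str = "",
    n_policy: NPolicy | None = None,
) -> WindowedGC:
    """Window an in-memory assembly given as (seq_id, sequence) pairs."""
    if window_size < 1:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    frames = [_window_frame(seq_id, _coerce_sequence(seq), window_size) for seq_id, seq in sequences]
    if not frames:
        raise ValueError("no sequences supplied")
    frame = pd.concat(frames, ignore_index=True)
    return WindowedGC(
        assembly_id=assembly_id,
        window_size=window_size,
        frame=frame,
        n_policy=n_policy or NPolicy(),
    )


def scan_fasta(
    fasta_path: Union[str, os.PathLike],
    window_size: int,
    n_policy: NPolicy | None = None,
    assembly_id: str | None = None,
) -> WindowedGC:
    """Scan a (possibly gzipped) FASTA into a non-overlapping window GC% track.

    Parameters
    ----------
    fasta_path
        Plain or gzip FASTA; multi-sequence.
    window_size
        Window length in bp (>= 1). The last window of each sequence may be
        shorter; see :class:`NPolicy` for how partial and gap-rich windows
        enter downstream value sets.
    """
    if window_size < 1:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    if assembly_id is None:
        name = Path(fasta_path).name
        for suffix in (".gz", ".fa", ".fasta", ".fna"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
        assembly_id = name
    return windows_from_sequences(
        _iter_fasta(fasta_path), window_size, assembly_id=assembly_id, n_policy=n_policy
    )


def whole_sequence_gc(fasta_path: Union[str, os.PathLike]) -> float:
    """GC% over all unambiguous bases of a whole assembly."""
    gc_total = 0
    at_total = 0
    for _, arr in _iter_fasta(fasta_path):
        gc_total += int(_IS_GC[arr].sum())
        at_total += int(_IS_AT[arr].sum())
    if gc_total + at_total == 0:
        raise ValueError("assembly contains no unambiguous bases")
    return 100.0 * gc_total / (gc_total + at_total)


def sequence_gc(seq: Union[str, bytes, np.ndarray]) -> float:
    """GC% of one in-memory sequence over its unambiguous bases."""
    arr = _coerce_sequence(seq)
    gc = int(_IS_GC[arr].sum())
    at = int(_IS_AT[arr].sum())
    if gc + at == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return 100.0 * gc / (gc + at)
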