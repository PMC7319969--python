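"""On-disk formats: per-base depth TSV, FASTA window composition, BED, window tables.

Conventions used throughout the package:

* depth TSV (``samtools depth`` dialect): three tab-separated columns
  ``chrom  pos  depth`` with 1-based positions; positions absent from the
  file carry depth 0;
* all in-memory and BED coordinates are 0-based half-open;
* gzip-compressed inputs are accepted transparently (by ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "BaseDepthRecord",
    "WindowComposition",
    "TruthInterval",
    "CnvCall",
    "read_depth_table",
    "window_composition_from_fasta",
    "write_calls_bed",
    "read_bed_intervals",
    "write_truth_bed",
    "write_window_table",
    "read_window_table",
]

WINDOW_TABLE_COLUMNS = [
    "chrom", "start", "end", "r_raw", "r_corrsize", "r_corrgc",
    "rds", "excluded", "called_state", "max_bf",
]


@dataclass(frozen=True)
class BaseDepthRecord:
    """One line of a per-base depth table (``pos`` is 1-based)."""
    chrom: str
    pos: int
    depth: int


@dataclass(frozen=True)
class WindowComposition:
    """Reference composition of one window: N-base count and GC fraction.

    ``gc_fraction`` is computed over defined (non-N) bases and set to 0.0
    when the window is all Ns.
    """
    chrom: str
    start: int
    end: int
    n_count: int
    gc_fraction: float


@dataclass(frozen=True)
class TruthInterval:
    """A ground-truth CNV interval with its integer copy-number label."""
    chrom: str
    start: int
    end: int
    cn_state: int


@dataclass(frozen=True)
class CnvCall:
    """A called CNV region (maximal same-state run of retained windows)."""
    chrom: str
    start: int
    end: int
    state: str
    max_bf: float
    n_windows: int = 0


def _open_text(path, mode: str = "rt") -> TextIO:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


class DepthParseError(ValueError):
    """Malformed per-base depth line."""


def read_depth_table(path, chrom_filter: Optional[str] = None) -> list[BaseDepthRecord]:
    """Read a samtools-depth-style TSV into a list of records in file order.

    Parameters
    ----------
    path
        TSV with at least three columns (chrom, 1-based pos, depth).
    chrom_filter
        If given, only records on this chromosome are returned.

    Raises
    ------
    DepthParseError
        On a line whose position or depth does not parse as an integer,
        naming the offending 1-based line number.
    """
    out: list[BaseDepthRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DepthParseError(f"line {lineno}: expected >=3 tab-separated columns")
            chrom = parts[0]
            if chrom_filter is not None and chrom != chrom_filter:
                continue
            try:
                pos = int(parts[1])
                depth = int(parts[2])
            except ValueError as exc:
                raise DepthParseError(f"line {lineno}: non-integer pos/depth in {parts[1:3]!r}") from exc
            if pos < 1 or depth < 0:
                raise DepthParseError(f"line {lineno}: pos must be >=1 and depth >=0")
            out.append(BaseDepthRecord(chrom, pos, depth))
    return out


def read_depth_arrays(path, chrom_filter: Optional[str] = None) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read a depth TSV into per-chromosome (pos, depth) integer arrays.

    Array-based sibling of :func:`read_depth_table` for large inputs.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
        names=["chrom", "pos", "depth"], dtype={"chrom": str},
    )
    if not (np.issubdtype(df["pos"].dtype, np.integer) and np.issubdtype(df["depth"].dtype, np.integer)):
        raise DepthParseError("non-integer pos/depth column")
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom_filter is not None and chrom != chrom_filter:
            continue
        out[str(chrom)] = (sub["pos"].to_numpy(np.int64), sub["depth"].to_numpy(np.int64))
    return out


def _iter_fasta(path) -> Iterator[tuple[str, str]]:
    name = None
    chunks: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise IOError("FASTA does not start with a '>' header")
                chunks.append(line)
    if name is not None:
        yield name, "".join(chunks)


def window_composition_from_fasta(path, window_size: int) -> list[WindowComposition]:
    """Tile each FASTA sequence with non-overlapping windows, left to right.

    The final window of a sequence may be shorter.  ``n_count`` counts
    ``N``/``n`` characters; ``gc_fraction`` is (#G + #C) / (#defined bases),
    case-insensitive, 0.0 when every base is N.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    out: list[WindowComposition] = []
    for name, seq in _iter_fasta(path):
        seq = seq.upper()
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_n = arr == ord("N")
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        for start in range(0, len(seq), window_size):
            end = min(start + window_size, len(seq))
            n = int(is_n[start:end].sum())
            defined = (end - start) - n
            gc = float(is_gc[start:end].sum()) / defined if defined > 0 else 0.0
            out.append(WindowComposition(name, start, end, n, gc))
    return out


def write_calls_bed(calls: Sequence[CnvCall], path, include_normal: bool = False) -> None:
    """Write calls as a BED-like TSV: chrom, start, end, state, max BF.

    Calls must be sorted by (chrom, start), non-overlapping within a
    chromosome, and adjacent calls must differ in state (the caller is
    expected to have merged same-state neighbours).  Abnormal-state calls
    only unless ``include_normal``.
    """
    by_chrom: dict[str, CnvCall] = {}
    seen_order: list[tuple[str, int]] = []
    for c in calls:
        if c.end <= c.start:
            raise ValueError(f"call {c.chrom}:{c.start}-{c.end} has end <= start")
        prev = by_chrom.get(c.chrom)
        if prev is not None:
            if c.start < prev.end:
                raise ValueError(
                    f"calls overlap or are unsorted on {c.chrom}: "
                    f"{prev.start}-{prev.end} then {c.start}-{c.end}")
            if c.start == prev.end and c.state == prev.state:
                raise ValueError(
                    f"adjacent same-state calls on {c.chrom} at {c.start} must be merged")
        by_chrom[c.chrom] = c
        seen_order.append((c.chrom, c.start))
    if seen_order != sorted(seen_order, key=lambda t: (t[0], t[1])):
        raise ValueError("calls must be sorted by (chrom, start)")

    with _open_text(path, "wt") as fh:
        fh.write("#chrom\tstart\tend\tstate\tmax_bf\n")
        for c in calls:
            if not include_normal and _is_normal_label(c.state):
                continue
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.state}\t{_fmt_bf(c.max_bf)}\n")


def _is_normal_label(state: str) -> bool:
    return state in ("CN2", "normal")


def _fmt_bf(x: float) -> str:
    if np.isinf(x):
        return "inf"
    return f"{x:.6g}"


def read_bed_intervals(path) -> list[TruthInterval]:
    """Read a truth/calls BED (chrom, start, end, label[, ...]) file.

    The 4th column is parsed as an integer CN when possible, otherwise
    mapped from {loss, normal, gain} labels to {1, 2, 3}; "CN<k>" labels
    parse to k.  Missing 4th column defaults to state 3 (gain-like marker).
    """
    out: list[TruthInterval] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"BED interval with end <= start: {line!r}")
            state = 3
            if len(parts) > 3:
                state = _parse_state_label(parts[3])
            out.append(TruthInterval(chrom, start, end, state))
    return out


def _parse_state_label(label: str) -> int:
    mapping = {"loss": 1, "normal": 2, "gain": 3}
    if label in mapping:
        return mapping[label]
    if label.upper().startswith("CN"):
        return int(label[2:])
    return int(label)


def write_truth_bed(truth: Sequence[TruthInterval], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("#chrom\tstart\tend\tcn\n")
        for t in truth:
            fh.write(f"{t.chrom}\t{t.start}\t{t.end}\t{t.cn_state}\n")


def write_window_table(df: pd.DataFrame, path) -> None:
    """Write the per-window TSV (chrom, start, end, R_Raw, R_CorrSize,
    R_CorrGC, RDS, excluded flag, called state, max BF)."""
    out = df.copy()
    for col in WINDOW_TABLE_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[WINDOW_TABLE_COLUMNS]
    out["excluded"] = out["excluded"].astype(int)
    with _open_text(path, "wt") as fh:
        fh.write("#" + "\t".join(WINDOW_TABLE_COLUMNS) + "\n")
        for row in out.itertuples(index=False):
            vals = []
            for col, v in zip(WINDOW_TABLE_COLUMNS, row):
                if isinstance(v, float):
                    vals.append("nan" if np.isnan(v) else _fmt_bf(v))
                else:
                    vals.append(str(v))
            fh.write("\t".join(vals) + "\n")


def read_window_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment=None, skiprows=1,
                     names=WINDOW_TABLE_COLUMNS)
    df["excluded"] = df["excluded"].astype(bool)
    return df
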