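"""From per-base depths to adjusted window read-depth signals (RDSs).

Pipeline per sample::

    base depths --bin--> R_Raw --N-adjust--> R_CorrSize --GC LOESS--> R_CorrGC
                                                        --mask-->     excluded
    R_CorrGC --log (single) / log-ratio (paired)--> D_i on retained windows

The GC step fits a locally weighted quadratic regression (tricube weights,
span 0.75) of depth on GC fraction over windows with GC in [0.20, 0.80] and
rescales each in-range window by (mean fitted-set depth) / (fitted depth at
its GC); windows with extreme GC are left unadjusted.  Windows with more
than half indefinable bases or zero raw depth are excluded from every
downstream step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import WindowComposition

__all__ = [
    "WindowDepthTable",
    "RdsTrack",
    "bin_base_depths",
    "adjust_indefinable_bases",
    "gc_correct",
    "mask_windows",
    "compute_rds",
    "preprocess_sample",
    "build_window_frame",
]

log = logging.getLogger(__name__)

GC_FIT_LO = 0.20
GC_FIT_HI = 0.80
LOESS_SPAN = 0.75
MIN_GC_FIT_WINDOWS = 10


def build_window_frame(windows: list[WindowComposition]) -> pd.DataFrame:
    """Window composition list -> DataFrame backbone of a WindowDepthTable."""
    return pd.DataFrame({
        "chrom": [w.chrom for w in windows],
        "start": np.array([w.start for w in windows], dtype=np.int64),
        "end": np.array([w.end for w in windows], dtype=np.int64),
        "n_count": np.array([w.n_count for w in windows], dtype=np.int64),
        "gc_fraction": np.array([w.gc_fraction for w in windows], dtype=float),
    })


@dataclass
class WindowDepthTable:
    """Per-window raw and corrected depths on a fixed window grid.

    ``frame`` columns: chrom, start, end, n_count, gc_fraction, r_raw,
    r_corrsize, r_corrgc, excluded (bool), gc_unadjusted (bool).
    """
    frame: pd.DataFrame

    @property
    def window_sizes(self) -> np.ndarray:
        return (self.frame["end"] - self.frame["start"]).to_numpy()

    @property
    def excluded(self) -> np.ndarray:
        return self.frame["excluded"].to_numpy()


@dataclass
class RdsTrack:
    """Read-depth signals D_i over retained windows, in genomic order.

    ``d`` aligns with ``frame`` (retained windows only); ``index`` holds each
    retained window's position in the original grid.
    """
    frame: pd.DataFrame
    d: np.ndarray
    index: np.ndarray
    mode: str  # "single" | "paired"

    def __post_init__(self):
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite RDS on a retained window")


def bin_base_depths(pos: np.ndarray, depth: np.ndarray,
                    windows: pd.DataFrame) -> np.ndarray:
    """Sum base depths into windows (summation method).

    Parameters
    ----------
    pos, depth
        1-based base positions (sorted) and their depths for one chromosome.
    windows
        Window frame for the same chromosome (contiguous tiling from 0).

    Returns the raw window depth R_Raw per window.  A base on a window
    border (e.g. pos 101 with 100 bp windows) belongs to the right window
    under the half-open convention.
    """
    starts = windows["start"].to_numpy()
    ends = windows["end"].to_numpy()
    if len(pos) == 0:
        return np.zeros(len(windows), dtype=float)
    pos0 = np.asarray(pos, dtype=np.int64) - 1  # 0-based
    if pos0.max() >= ends[-1]:
        raise ValueError(
            f"base position {pos0.max() + 1} lies beyond the last window end {ends[-1]}")
    if pos0.min() < starts[0]:
        raise ValueError("base position before the first window")
    idx = np.searchsorted(starts, pos0, side="right") - 1
    return np.bincount(idx, weights=np.asarray(depth, dtype=float),
                       minlength=len(windows))


def adjust_indefinable_bases(r_raw: np.ndarray, window_size: np.ndarray,
                             n_count: np.ndarray) -> np.ndarray:
    """R_CorrSize = R_Raw * window_size / (window_size - n_count).

    Windows that are all Ns (n_count == window_size) are left uncorrected
    here; they are flagged for exclusion by :func:`mask_windows`.
    """
    r_raw = np.asarray(r_raw, dtype=float)
    window_size = np.asarray(window_size, dtype=float)
    n_count = np.asarray(n_count, dtype=float)
    denom = window_size - n_count
    out = r_raw.copy()
    ok = denom > 0
    out[ok] = r_raw[ok] * window_size[ok] / denom[ok]
    return out


def mask_windows(r_raw: np.ndarray, window_size: np.ndarray,
                 n_count: np.ndarray) -> np.ndarray:
    """Exclusion mask: more than half indefinable bases, or zero depth."""
    r_raw = np.asarray(r_raw)
    return (np.asarray(n_count) > np.asarray(window_size) / 2.0) | (r_raw == 0)


def _loess_quadratic(x_fit: np.ndarray, y_fit: np.ndarray,
                     x_eval: np.ndarray, span: float = LOESS_SPAN) -> np.ndarray:
    """Locally weighted quadratic regression with tricube weights.

    Fits on (x_fit, y_fit) and predicts at x_eval.  For large fitting sets
    the curve is evaluated on a grid of x values and interpolated, which is
    the standard way production LOESS implementations keep the cost linear.
    """
    x_fit = np.asarray(x_fit, dtype=float)
    y_fit = np.asarray(y_fit, dtype=float)
    n = len(x_fit)
    k = max(3, int(np.ceil(span * n)))
    k = min(k, n)

    uniq = np.unique(x_fit)
    if len(uniq) <= 200:
        grid = uniq
    else:
        grid = np.linspace(uniq[0], uniq[-1], 201)

    fitted = np.empty(len(grid))
    for j, g in enumerate(grid):
        dist = np.abs(x_fit - g)
        h = np.partition(dist, k - 1)[k - 1]
        if h <= 0:
            fitted[j] = y_fit[dist == 0].mean()
            continue
        w = (1.0 - np.clip(dist / h, 0.0, 1.0) ** 3) ** 3
        sel = w > 0
        xs = x_fit[sel] - g
        ws = w[sel]
        X = np.column_stack([np.ones(xs.size), xs, xs * xs])
        sw = np.sqrt(ws)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], y_fit[sel] * sw, rcond=None)
        fitted[j] = coef[0]
    if len(grid) == 1:
        return np.full(len(x_eval), fitted[0])
    return np.interp(x_eval, grid, fitted)


def gc_correct(r_corrsize: np.ndarray, gc_fraction: np.ndarray,
               excluded: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """GC-bias correction: R_CorrGC = R_CorrSize * mean(R_GC-set) / R_GC,i.

    The local regression is fitted on retained windows with GC in the closed
    interval [0.20, 0.80]; windows outside that range (or with non-positive
    fitted depth) are returned unadjusted.  Returns (r_corrgc, unadjusted
    flag).  If fewer than 10 windows are fittable the correction is skipped
    genome-wide with a warning.
    """
    r = np.asarray(r_corrsize, dtype=float)
    gc = np.asarray(gc_fraction, dtype=float)
    excluded = np.asarray(excluded, dtype=bool)
    in_range = (gc >= GC_FIT_LO) & (gc <= GC_FIT_HI)
    fit_set = in_range & ~excluded
    unadjusted = ~in_range

    if fit_set.sum() < MIN_GC_FIT_WINDOWS:
        warnings.warn(
            "fewer than 10 windows with GC in [0.20, 0.80]; GC correction skipped",
            RuntimeWarning, stacklevel=2)
        return r.copy(), np.ones_like(unadjusted)

    fitted = _loess_quadratic(gc[fit_set], r[fit_set], gc)
    r_bar = r[fit_set].mean()
    out = r.copy()
    apply = in_range & (fitted > 0)
    out[apply] = r[apply] * r_bar / fitted[apply]
    unadjusted = unadjusted | (in_range & (fitted <= 0))
    return out, unadjusted


def compute_rds(case: WindowDepthTable, control: WindowDepthTable | None = None,
                mode: str = "single") -> RdsTrack:
    """Log (single) or log-ratio (paired) transform over retained windows.

    Paired mode requires both samples on the same window grid; the exclusion
    mask is the union of the two samples' masks (a log-ratio needs both
    depths positive).
    """
    if mode == "single":
        if control is not None:
            raise ValueError("single mode takes no control sample")
        f = case.frame
        keep = ~f["excluded"].to_numpy()
        d = np.log(f["r_corrgc"].to_numpy()[keep])
        frame = f.loc[keep, ["chrom", "start", "end"]].reset_index(drop=True)
        return RdsTrack(frame, d, np.flatnonzero(keep), "single")
    if mode == "paired":
        if control is None:
            raise ValueError("paired mode requires a control sample")
        fc, fn = case.frame, control.frame
        same = (len(fc) == len(fn)
                and (fc["chrom"].to_numpy() == fn["chrom"].to_numpy()).all()
                and (fc["start"].to_numpy() == fn["start"].to_numpy()).all()
                and (fc["end"].to_numpy() == fn["end"].to_numpy()).all())
        if not same:
            raise ValueError("case and control window grids differ")
        keep = ~(fc["excluded"].to_numpy() | fn["excluded"].to_numpy())
        d = np.log(fc["r_corrgc"].to_numpy()[keep] / fn["r_corrgc"].to_numpy()[keep])
        frame = fc.loc[keep, ["chrom", "start", "end"]].reset_index(drop=True)
        return RdsTrack(frame, d, np.flatnonzero(keep), "paired")
    raise ValueError(f"unknown mode {mode!r}")


def preprocess_sample(windows: pd.DataFrame, r_raw: np.ndarray) -> WindowDepthTable:
    """Full single-sample correction chain on a window frame.

    ``windows`` must carry chrom/start/end/n_count/gc_fraction; ``r_raw``
    aligns with it.  Adds r_raw, r_corrsize, r_corrgc, excluded,
    gc_unadjusted columns.
    """
    f = windows.copy()
    size = (f["end"] - f["start"]).to_numpy()
    n_count = f["n_count"].to_numpy()
    r_raw = np.asarray(r_raw, dtype=float)
    excluded = mask_windows(r_raw, size, n_count)
    r_corrsize = adjust_indefinable_bases(r_raw, size, n_count)
    r_corrgc, unadj = gc_correct(r_corrsize, f["gc_fraction"].to_numpy(), excluded)
    f["r_raw"] = r_raw
    f["r_corrsize"] = r_corrsize
    f["r_corrgc"] = r_corrgc
    f["excluded"] = excluded
    f["gc_unadjusted"] = unadj
    return WindowDepthTable(f)
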