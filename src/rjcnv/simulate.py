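"""Synthetic CNV layouts and window-level depth data.

The default design mirrors a chr20-scale benchmark: a 63 Mb diploid genome
carrying 20 deletion pieces (CN 1) and 20 duplication pieces (CN 3, 4 or 5,
uniform), two pieces of each of the ten sizes 1, 2.5, 5, 10, 25, 50, 100,
250, 500 and 1000 kb per type — 7,774,000 bp, ~12.3% of the genome.
Pieces are placed uniformly at random on the window grid, non-overlapping
and separated by at least one normal window.

Depths are emitted at the window level.  A window at copy number ``cn``
has expected raw depth ``coverage x window_size x cn/2``.  Two noise
models are available:

* ``"read"`` (default) — single-end reads of ``read_length`` bp start as
  a Poisson process whose local rate is proportional to the copy number;
  each read adds its overlap length to every window it touches.  This
  reproduces the variance structure of piled aligned reads (window-sum
  variance of order read_length x mean, a small e^-rate mass at exactly
  zero depth, and correlation across window borders), which is what makes
  low-coverage data genuinely harder than high-coverage data.
* ``"poisson"`` — independent per-base Poisson counts summed per window
  (variance equals the mean); the idealized emission the hierarchical
  model assumes.

An optional multiplicative GC bias gives the preprocessing stage
something to correct, and synthetic GC fractions are attached so the full
correction path can run.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import TruthInterval
from .preprocess import WindowDepthTable

__all__ = ["SimulationDesign", "generate_cnv_truth", "simulate_window_depths",
           "paper_design", "scaled_design", "write_depth_tsv"]

PIECE_SIZES_KB = (1, 2.5, 5, 10, 25, 50, 100, 250, 500, 1000)
LOW_COVERAGE = 2.2
HIGH_COVERAGE = 22.0


@dataclass
class SimulationDesign:
    genome_length: int = 63_000_000
    window_size: int = 100
    chrom: str = "sim1"
    size_menu: tuple[float, ...] = tuple(s * 1000 for s in PIECE_SIZES_KB)
    pieces_per_size: int = 2
    gain_cn_menu: tuple[int, ...] = (3, 4, 5)
    coverage: float = LOW_COVERAGE
    read_length: int = 70
    noise: str = "read"           # "read" | "poisson"
    gc_bias: float = 0.0          # relative amplitude of a smooth GC bias
    gc_mean: float = 0.41
    gc_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        total = 2 * self.pieces_per_size * sum(self.size_menu)
        if total >= self.genome_length:
            raise ValueError("CNV content would exceed the genome length")
        if any(s < self.window_size or s % self.window_size for s in self.size_menu):
            raise ValueError("piece sizes must be positive multiples of the window size")

    @property
    def total_cnv_bp(self) -> int:
        return int(2 * self.pieces_per_size * sum(self.size_menu))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["size_menu"] = list(self.size_menu)
        d["gain_cn_menu"] = list(self.gain_cn_menu)
        return d


def paper_design(coverage: float = LOW_COVERAGE, seed: int = 0) -> SimulationDesign:
    """The full chr20-scale layout (63 Mb, sizes 1 kb - 1 Mb)."""
    return SimulationDesign(coverage=coverage, seed=seed)


def scaled_design(coverage: float = LOW_COVERAGE, seed: int = 0,
                  genome_length: int = 6_300_000,
                  window_size: int = 100) -> SimulationDesign:
    """Desk-scale layout: 6.3 Mb genome, piece sizes 2.5-100 kb (the full
    menu divided by ten with sub-2.5 kb pieces dropped), 770,000 bp =
    12.2% CNV content.  Other genome lengths scale the menu
    proportionally (rounded to whole windows)."""
    base_menu = (2500, 5000, 10_000, 25_000, 50_000, 100_000)
    f = genome_length / 6_300_000
    menu = tuple(max(window_size,
                     round(s * f / window_size) * window_size)
                 for s in base_menu)
    return SimulationDesign(
        genome_length=genome_length, window_size=window_size,
        size_menu=menu, coverage=coverage, seed=seed)


def generate_cnv_truth(design: SimulationDesign,
                       rng: np.random.Generator | None = None) -> list[TruthInterval]:
    """Place loss and gain pieces uniformly at random on the window grid,
    non-overlapping with >= 1 normal window between pieces."""
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    w = design.window_size
    n_win = design.genome_length // w
    pieces: list[tuple[int, int]] = []   # (len_windows, cn)
    for size in design.size_menu:
        lw = int(size) // w
        for _ in range(design.pieces_per_size):
            pieces.append((lw, 1))
        for _ in range(design.pieces_per_size):
            cn = int(design.gain_cn_menu[rng.integers(len(design.gain_cn_menu))])
            pieces.append((lw, cn))
    if not pieces:
        return []
    # place large pieces first; each placement forbids adjacency by padding
    order = sorted(range(len(pieces)), key=lambda i: -pieces[i][0])
    placed: list[tuple[int, int, int]] = []   # (start_w, end_w, cn)
    for idx in order:
        lw, cn = pieces[idx]
        ok = False
        for _ in range(10_000):
            s = int(rng.integers(0, n_win - lw + 1))
            e = s + lw
            if all(e + 1 <= ps or s >= pe + 1 for ps, pe, _ in placed):
                placed.append((s, e, cn))
                ok = True
                break
        if not ok:
            raise RuntimeError("could not place all CNV pieces; genome too small")
    placed.sort()
    return [TruthInterval(design.chrom, s * w, e * w, cn) for s, e, cn in placed]


def _window_cn(design: SimulationDesign, truth: list[TruthInterval]) -> np.ndarray:
    w = design.window_size
    n_win = math.ceil(design.genome_length / w)
    cn = np.full(n_win, 2, dtype=np.int64)
    for t in truth:
        if t.end > design.genome_length:
            raise ValueError("truth interval beyond the genome")
        w0, w1 = t.start // w, math.ceil(t.end / w)
        cn[w0:w1] = t.cn_state
    return cn


def _synthetic_gc(design: SimulationDesign, rng: np.random.Generator,
                  n_win: int) -> np.ndarray:
    """Smooth, autocorrelated GC landscape clipped to (0.25, 0.65)."""
    rough = rng.normal(0.0, 1.0, n_win)
    kernel = np.ones(25) / 25.0
    smooth = np.convolve(rough, kernel, mode="same")
    smooth /= max(smooth.std(), 1e-12)
    gc = design.gc_mean + design.gc_sd * smooth
    return np.clip(gc, 0.25, 0.65)


def simulate_window_depths(truth: list[TruthInterval], design: SimulationDesign,
                           mode: str = "single",
                           rng: np.random.Generator | None = None,
                           ) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Simulate the raw window-depth table for the case (and, in paired
    mode, an all-CN2 control from an independent stream).

    Returns a window frame with columns chrom/start/end/n_count/gc_fraction/
    r_raw/cn_truth, plus the control r_raw array (paired) or None.
    """
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    w = design.window_size
    n_win = math.ceil(design.genome_length / w)
    starts = np.arange(n_win, dtype=np.int64) * w
    ends = np.minimum(starts + w, design.genome_length)
    sizes = (ends - starts).astype(float)
    cn = _window_cn(design, truth)
    gc = _synthetic_gc(design, rng, n_win)

    bias = np.ones(n_win)
    if design.gc_bias > 0:
        # smooth unimodal bias centred at the typical GC
        bias = 1.0 + design.gc_bias * np.sin(2.0 * np.pi * (gc - design.gc_mean)
                                             / (8.0 * design.gc_sd))

    if design.noise == "poisson":
        mean_case = design.coverage * sizes * (cn / 2.0) * bias
        case_raw = rng.poisson(mean_case).astype(float)
        control_raw = None
        if mode == "paired":
            mean_ctrl = design.coverage * sizes * 1.0 * bias
            control_raw = rng.poisson(mean_ctrl).astype(float)
    elif design.noise == "read":
        case_raw = _read_process_depths(design, starts, ends, cn / 2.0 * bias, rng)
        control_raw = None
        if mode == "paired":
            control_raw = _read_process_depths(design, starts, ends, bias, rng)
    else:
        raise ValueError(f"unknown noise model {design.noise!r}")

    frame = pd.DataFrame({
        "chrom": design.chrom,
        "start": starts, "end": ends,
        "n_count": np.zeros(n_win, dtype=np.int64),
        "gc_fraction": gc,
        "r_raw": case_raw,
        "cn_truth": cn,
    })
    return frame, control_raw


def _read_process_depths(design: SimulationDesign, starts: np.ndarray,
                         ends: np.ndarray, rel_rate: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Window depths from a Poisson read process.

    Read starts in window i arrive at rate coverage/read_length x rel_rate_i
    per base; each read contributes its overlap length to every window it
    spans (reads are truncated at the genome end).
    """
    length = int(design.read_length)
    genome_len = int(ends[-1])
    w = design.window_size
    sizes = (ends - starts).astype(float)
    lam = design.coverage / length * rel_rate * sizes
    counts = rng.poisson(lam)
    n_reads = int(counts.sum())
    depth = np.zeros(len(starts))
    if n_reads == 0:
        return depth
    read_start = np.repeat(starts, counts) + rng.integers(
        0, np.repeat(sizes.astype(np.int64), counts))
    read_end = np.minimum(read_start + length, genome_len)
    win = read_start // w
    pos = read_start.copy()
    while True:
        seg_end = np.minimum((win + 1) * w, read_end)
        contrib = seg_end - pos
        live = contrib > 0
        if not live.any():
            break
        depth += np.bincount(win[live], weights=contrib[live],
                             minlength=len(starts))
        pos = seg_end
        win = win + 1
        alive = (pos < read_end) & (win < len(starts))
        win, pos, read_end = win[alive], pos[alive], read_end[alive]
    return depth


def write_depth_tsv(frame: pd.DataFrame, raw_col: str, path) -> None:
    """Emit a per-base depth TSV (depth spread uniformly within each
    window) so the base-level preprocessing path can be exercised.  Only
    sensible for small genomes."""
    from .io_formats import _open_text
    with _open_text(path, "wt") as fh:
        for row in frame.itertuples(index=False):
            total = int(getattr(row, raw_col))
            size = row.end - row.start
            if total <= 0:
                continue
            base = total // size
            extra = total - base * size
            for offset in range(size):
                depth = base + (1 if offset < extra else 0)
                if depth > 0:
                    fh.write(f"{row.chrom}\t{row.start + offset + 1}\t{depth}\n")
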