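"""From sampler tallies to Bayes factors, window calls and CNV regions.

For window i and abnormal state k the Bayes factor against the normal
state is the posterior odds over the prior odds,

    BF_i(k) = (#iterations with state k / #iterations with state 2) * w02 / w0k,

and a window is called abnormal when its maximum BF strictly exceeds the
threshold (default 20, "decisive" on the usual evidence scale).  Adjacent
retained windows with the same called state merge into one region; runs
break at excluded-window gaps.  Region coordinates are window-grid
resolution only — the method does not refine breakpoints below the window
size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import CnvCall

__all__ = ["bayes_factors", "call_window_states", "merge_into_regions",
           "state_label"]

DEFAULT_BF_THRESHOLD = 20.0


def bayes_factors(tally: np.ndarray, w0) -> np.ndarray:
    """Per-window BF for every abnormal state.

    Parameters
    ----------
    tally
        (I, K) post-burn-in iteration counts per window and state.
    w0
        Prior state weights (length K); the normal state is label 2
        (index 1).

    Returns an (I, K) array; the normal-state column is NaN.  Windows whose
    normal count is 0 while the abnormal count is positive get ``inf``;
    abnormal count 0 gives 0.
    """
    tally = np.asarray(tally, dtype=float)
    w0 = np.asarray(w0, dtype=float)
    i_n, k = tally.shape
    if tally.sum(axis=1).min() <= 0:
        raise ValueError("tally has a window with no recorded iterations")
    normal = tally[:, 1]
    out = np.full((i_n, k), np.nan)
    for j in range(k):
        if j == 1:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = tally[:, j] / normal
        ratio = np.where(tally[:, j] == 0, 0.0, ratio)
        out[:, j] = ratio * (w0[1] / w0[j])
    return out


def call_window_states(bf: np.ndarray, threshold: float = DEFAULT_BF_THRESHOLD,
                       normal_state: int = 2) -> np.ndarray:
    """Assign each window the argmax abnormal state if its maximum BF
    strictly exceeds the threshold, else the normal state.

    Ties at the argmax break toward the state closest to normal, then the
    lowest label.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    bf = np.asarray(bf, dtype=float)
    i_n, k = bf.shape
    labels = np.arange(1, k + 1)
    abn = [j for j in range(k) if j != normal_state - 1]
    sub = bf[:, abn]
    best = np.nanmax(sub, axis=1)
    out = np.full(i_n, normal_state, dtype=np.int64)
    hit = best > threshold
    if hit.any():
        # tie-break: distance to normal, then label
        order = sorted(abn, key=lambda j: (abs(j + 1 - normal_state), j))
        chosen = np.zeros(i_n, dtype=np.int64)
        assigned = np.zeros(i_n, dtype=bool)
        for j in order:
            take = hit & ~assigned & (bf[:, j] == best)
            chosen[take] = labels[j]
            assigned |= take
        out[hit] = chosen[hit]
    return out


def state_label(state: int, mode: str) -> str:
    if mode == "paired":
        return {1: "loss", 2: "normal", 3: "gain"}[int(state)]
    return f"CN{int(state)}"


def merge_into_regions(window_states: np.ndarray, window_starts: np.ndarray,
                       window_ends: np.ndarray, chroms,
                       max_bf: np.ndarray | None = None,
                       mode: str = "single") -> list[CnvCall]:
    """Combine maximal runs of equal-state retained windows into calls.

    Inputs align with *retained* windows in genomic order.  Runs break at
    excluded-window gaps (any coordinate discontinuity) and at chromosome
    changes.  ``max_bf`` supplies the per-window maximum abnormal BF used
    to annotate regions.
    """
    window_states = np.asarray(window_states)
    window_starts = np.asarray(window_starts)
    window_ends = np.asarray(window_ends)
    chroms = np.asarray(chroms)
    n = len(window_states)
    if not (len(window_starts) == len(window_ends) == len(chroms) == n):
        raise ValueError("inputs must align")
    if max_bf is None:
        max_bf = np.full(n, np.nan)
    calls: list[CnvCall] = []
    i = 0
    while i < n:
        j = i
        while (j + 1 < n
               and chroms[j + 1] == chroms[i]
               and window_starts[j + 1] == window_ends[j]
               and window_states[j + 1] == window_states[i]):
            j += 1
        seg_bf = max_bf[i:j + 1]
        with np.errstate(invalid="ignore"):
            bf_val = np.nanmax(seg_bf) if np.any(~np.isnan(seg_bf)) else np.nan
        calls.append(CnvCall(
            chrom=str(chroms[i]), start=int(window_starts[i]),
            end=int(window_ends[j]), state=state_label(window_states[i], mode),
            max_bf=float(bf_val), n_windows=j - i + 1))
        i = j + 1
    return calls
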