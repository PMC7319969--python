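"""Scoring calls against a truth set.

Base-level metrics are per-basepair over retained-window territory, on the
collapsed three-class scale {loss, normal, gain}:

* overall accuracy — fraction of evaluated bp whose called class matches
  the truth class;
* recall (per type) — CNV bp of that type also called abnormal (any
  abnormal class by default; ``strict_state`` demands the same class);
* FPR (per type) — truth-normal bp called that abnormal type;
* precision — called-CNV bp that are truth-CNV bp.

Region-level detection follows the any-position rule: a truth region
counts as detected as soon as one of its basepairs is covered by an
abnormal call of any state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CnvCall, TruthInterval

__all__ = ["base_metrics", "region_detection_rate", "collapse_state"]


def collapse_state(cn: int) -> int:
    """Absolute CN (or 3-state label) -> {1: loss, 2: normal, 3: gain}."""
    if cn < 2:
        return 1
    if cn == 2:
        return 2
    return 3


def _call_state_code(state: str) -> int:
    if state == "loss":
        return 1
    if state == "normal":
        return 2
    if state == "gain":
        return 3
    if state.upper().startswith("CN"):
        return collapse_state(int(state[2:]))
    return collapse_state(int(state))


def _segment_classes(chrom: str, lo: int, hi: int,
                     intervals: list[tuple[int, int, int]],
                     cuts: np.ndarray) -> np.ndarray:
    """Class per atomic segment between consecutive cuts, default normal."""
    out = np.full(len(cuts) - 1, 2, dtype=np.int64)
    for s, e, c in intervals:
        i0 = np.searchsorted(cuts, s, side="left")
        i1 = np.searchsorted(cuts, e, side="left")
        out[i0:i1] = c
    return out


def base_metrics(calls: list[CnvCall], truth: list[TruthInterval],
                 windows: pd.DataFrame, strict_state: bool = False) -> dict:
    """Per-bp confusion over retained windows; rates as percentages.

    ``windows`` needs chrom/start/end/excluded columns covering the
    evaluated territory (the caller's window table).
    """
    total = {"n": 0, "correct": 0,
             "truth_loss": 0, "truth_gain": 0, "truth_normal": 0,
             "hit_loss": 0, "hit_gain": 0,
             "fp_loss": 0, "fp_gain": 0,
             "called_cnv": 0, "called_cnv_true": 0}
    for chrom, wsub in windows.groupby("chrom", sort=False):
        retained = wsub.loc[~wsub["excluded"].astype(bool)]
        if retained.empty:
            continue
        t_iv = [(t.start, t.end, collapse_state(t.cn_state))
                for t in truth if t.chrom == chrom]
        c_iv = [(c.start, c.end, _call_state_code(c.state))
                for c in calls if c.chrom == chrom]
        cuts = np.unique(np.concatenate(
            [retained["start"].to_numpy(), retained["end"].to_numpy()]
            + [np.array([s for s, e, _ in t_iv + c_iv], dtype=np.int64)]
            + [np.array([e for s, e, _ in t_iv + c_iv], dtype=np.int64)]))
        if len(cuts) < 2:
            continue
        seg_len = np.diff(cuts)
        # retained mask per atomic segment
        ret = np.zeros(len(seg_len), dtype=bool)
        i0 = np.searchsorted(cuts, retained["start"].to_numpy(), side="left")
        i1 = np.searchsorted(cuts, retained["end"].to_numpy(), side="left")
        for a, b in zip(i0, i1):
            ret[a:b] = True
        t_cls = _segment_classes(chrom, cuts[0], cuts[-1], t_iv, cuts)
        c_cls = _segment_classes(chrom, cuts[0], cuts[-1], c_iv, cuts)
        ln = seg_len[ret]
        t_cls, c_cls = t_cls[ret], c_cls[ret]

        total["n"] += int(ln.sum())
        total["correct"] += int(ln[t_cls == c_cls].sum())
        for code, name in ((1, "loss"), (3, "gain")):
            t_is = t_cls == code
            total[f"truth_{name}"] += int(ln[t_is].sum())
            if strict_state:
                hit = t_is & (c_cls == code)
            else:
                hit = t_is & (c_cls != 2)
            total[f"hit_{name}"] += int(ln[hit].sum())
            total[f"fp_{name}"] += int(ln[(t_cls == 2) & (c_cls == code)].sum())
        total["truth_normal"] += int(ln[t_cls == 2].sum())
        called = c_cls != 2
        total["called_cnv"] += int(ln[called].sum())
        total["called_cnv_true"] += int(ln[called & (t_cls != 2)].sum())

    def pct(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    return {
        "overall_accuracy": pct(total["correct"], total["n"]),
        "recall_loss": pct(total["hit_loss"], total["truth_loss"]),
        "recall_gain": pct(total["hit_gain"], total["truth_gain"]),
        "fpr_loss": pct(total["fp_loss"], total["truth_normal"]),
        "fpr_gain": pct(total["fp_gain"], total["truth_normal"]),
        "fpr": pct(total["fp_loss"] + total["fp_gain"], total["truth_normal"]),
        "recall": pct(total["hit_loss"] + total["hit_gain"],
                      total["truth_loss"] + total["truth_gain"]),
        "precision": pct(total["called_cnv_true"], total["called_cnv"]),
        "evaluated_bp": total["n"],
    }


def region_detection_rate(calls: list[CnvCall], truth: list[TruthInterval],
                          size_bins: tuple[float, ...] | None = None) -> pd.DataFrame:
    """Detection per (type, size): a truth region is detected iff >= 1 bp
    of it overlaps an abnormal call of any state.

    Returns a tidy frame with columns type/size/n/detected/rate (percent);
    ``size_bins`` restricts and orders the size column (exact sizes).
    """
    abn = [(c.chrom, c.start, c.end) for c in calls if _call_state_code(c.state) != 2]
    rows = []
    for t in truth:
        if collapse_state(t.cn_state) == 2:
            continue
        hit = any(ch == t.chrom and s < t.end and e > t.start for ch, s, e in abn)
        rows.append({"type": "loss" if collapse_state(t.cn_state) == 1 else "gain",
                     "size": t.end - t.start, "detected": int(hit)})
    df = pd.DataFrame(rows, columns=["type", "size", "detected"])
    if size_bins is not None:
        df = df[df["size"].isin(size_bins)]
    if df.empty:
        return pd.DataFrame(columns=["type", "size", "n", "detected", "rate"])
    g = df.groupby(["type", "size"], as_index=False).agg(
        n=("detected", "size"), detected=("detected", "sum"))
    g["rate"] = 100.0 * g["detected"] / g["n"]
    return g.sort_values(["type", "size"]).reset_index(drop=True)
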