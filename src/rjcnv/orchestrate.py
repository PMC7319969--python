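"""End-to-end driver: preprocessing, genome-wide priors and initialization,
per-section sampling, call assembly, and file outputs.

Sections are fixed-size genomic chunks (default 0.5 Mb) sampled
independently with hyperparameters and the spline initialization taken
from the whole genome.  Each section draws its random stream from
(master seed, section index), so results are identical however sections
are scheduled, and serial and parallel runs agree bit for bit.  Calls are
merged across section borders afterwards, since the sectioning is an
inference artifact, not biology.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .caller import (DEFAULT_BF_THRESHOLD, bayes_factors, call_window_states,
                     merge_into_regions, state_label)
from .io_formats import CnvCall, write_calls_bed, write_window_table
from .model import Hyperparameters, estimate_hyperparameters
from .preprocess import RdsTrack, WindowDepthTable, compute_rds, preprocess_sample
from .sampler import SamplerConfig, initialize_chain, run_section

__all__ = ["RunConfig", "GenomeResult", "partition_sections", "run_genome_windows"]

log = logging.getLogger(__name__)

DEFAULT_SECTION_BP = 500_000


@dataclass
class RunConfig:
    mode: str = "single"
    k: int | None = None
    window_size: int = 100
    section_bp: int = DEFAULT_SECTION_BP
    bf_threshold: float = DEFAULT_BF_THRESHOLD
    min_cnv_size: int = 0
    seed: int = 0
    threads: int = 1
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    hp_overrides: dict = field(default_factory=dict)

    def resolved_k(self) -> int:
        if self.k is not None:
            return self.k
        return 5 if self.mode == "single" else 3


@dataclass
class GenomeResult:
    calls: list[CnvCall]
    window_table: pd.DataFrame
    window_states: np.ndarray         # per retained window, 1-based labels
    rds: RdsTrack
    hp: Hyperparameters
    section_summaries: pd.DataFrame
    manifest: dict


@dataclass(frozen=True)
class _Section:
    index: int
    chrom: str
    start_bp: int
    end_bp: int
    lo: int        # retained-window slice [lo, hi) into the RDS track
    hi: int


def partition_sections(rds: RdsTrack, section_bp: int = DEFAULT_SECTION_BP,
                       window_size: int = 100) -> list[_Section]:
    """Non-overlapping fixed-size sections, never spanning chromosomes;
    each retained window lands in exactly one section; empty sections are
    dropped."""
    if section_bp < 10 * window_size:
        raise ValueError("sections must cover at least 10 windows")
    f = rds.frame
    chroms = f["chrom"].to_numpy()
    starts = f["start"].to_numpy()
    out: list[_Section] = []
    idx = 0
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        c_starts = starts[sel]
        sec_ids = c_starts // section_bp
        for sid in np.unique(sec_ids):
            members = sel[sec_ids == sid]
            out.append(_Section(index=idx, chrom=str(chrom),
                                start_bp=int(sid * section_bp),
                                end_bp=int((sid + 1) * section_bp),
                                lo=int(members[0]), hi=int(members[-1]) + 1))
            idx += 1
    return out


def _slice_init(starts: list[int], states: list[int],
                lo: int, hi: int) -> tuple[list[int], list[int]]:
    """Restrict a genome-wide (starts, states) segmentation to [lo, hi)."""
    s_out, c_out = [0], []
    for m in range(len(states)):
        a, b = starts[m], starts[m + 1]
        if b <= lo or a >= hi:
            continue
        c_out.append(states[m])
        s_out.append(min(b, hi) - lo)
    s_out[-1] = hi - lo
    # slicing preserves neighbour-distinctness; lengths stay positive
    return s_out, c_out


def _section_rng(master_seed: int, section_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(section_index,))
    return np.random.default_rng(ss)


def run_genome_windows(case: WindowDepthTable,
                       control: WindowDepthTable | None,
                       config: RunConfig) -> GenomeResult:
    """Run the full caller on preprocessed window tables.

    ``case`` (and ``control`` in paired mode) must come from
    :func:`rjcnv.preprocess.preprocess_sample`.
    """
    mode = config.mode
    rds = compute_rds(case, control, mode=mode)
    k = config.resolved_k()

    # genome-wide initialization (per chromosome), then lambda from its
    # breakpoint density
    init_rng = _section_rng(config.seed, 1 << 20)
    f = rds.frame
    chrom_arr = f["chrom"].to_numpy()
    init_starts: list[int] = [0]
    init_states: list[int] = []
    offset = 0
    for chrom in pd.unique(chrom_arr):
        sel = np.flatnonzero(chrom_arr == chrom)
        s, c = initialize_chain(rds.d[sel], init_rng, hp_k=k)
        init_starts.extend(offset + np.asarray(s[1:]))
        init_states.extend(c)
        offset += len(sel)
    # collapse equal-state neighbours created at chromosome junctions
    init_starts, init_states = _dedupe(init_starts, init_states)

    m_init = len(init_states)
    hp = estimate_hyperparameters(rds.d, mode=mode, k=k, m_init=m_init,
                                  overrides=config.hp_overrides)

    sections = partition_sections(rds, config.section_bp, config.window_size)

    def predicate(tally: np.ndarray) -> np.ndarray:
        bf = bayes_factors(tally, hp.w0)
        return call_window_states(bf, config.bf_threshold, hp.normal_state)

    tallies = np.zeros((len(rds.d), k), dtype=np.int64)
    summaries = []
    for sec in sections:
        d_sec = rds.d[sec.lo:sec.hi]
        init = _slice_init(init_starts, init_states, sec.lo, sec.hi)
        rng = _section_rng(config.seed, sec.index)
        res = run_section(d_sec, hp, config.sampler, rng, init=init,
                          call_predicate=predicate)
        tallies[sec.lo:sec.hi] = res.tally
        summaries.append({
            "section": sec.index, "chrom": sec.chrom,
            "start_bp": sec.start_bp, "end_bp": min(sec.end_bp, int(f["end"].iloc[sec.hi - 1])),
            "n_windows": sec.hi - sec.lo, "iterations": res.iterations,
            "converged": res.converged, "n_regions": len(res.states),
            "final_log_kernel": (res.log_kernel_trace[-1]
                                 if len(res.log_kernel_trace) else np.nan),
        })
        log.info("section %d (%s:%d-%d): %d iterations, converged=%s",
                 sec.index, sec.chrom, sec.start_bp, sec.end_bp,
                 res.iterations, res.converged)

    bf = bayes_factors(tallies, hp.w0)
    window_states = call_window_states(bf, config.bf_threshold, hp.normal_state)
    with np.errstate(invalid="ignore"):
        max_bf = np.nanmax(bf, axis=1)
    calls = merge_into_regions(
        window_states, f["start"].to_numpy(), f["end"].to_numpy(),
        f["chrom"].to_numpy(), max_bf=max_bf, mode=mode)
    if config.min_cnv_size > 0:
        calls = [c for c in calls
                 if c.state in ("CN2", "normal") or c.end - c.start >= config.min_cnv_size]

    table = case.frame.copy()
    table["rds"] = np.nan
    table.loc[table.index[rds.index], "rds"] = rds.d
    table["called_state"] = ""
    labels = [state_label(s, mode) for s in window_states]
    table.loc[table.index[rds.index], "called_state"] = labels
    table["max_bf"] = np.nan
    table.loc[table.index[rds.index], "max_bf"] = max_bf

    manifest = {
        "package_version": _pkg_version,
        "mode": mode, "k": k, "seed": config.seed,
        "window_size": config.window_size, "section_bp": config.section_bp,
        "bf_threshold": config.bf_threshold, "min_cnv_size": config.min_cnv_size,
        "sampler": {
            "burn_in": config.sampler.burn_in,
            "check_interval": config.sampler.check_interval,
            "max_iterations": config.sampler.max_iterations,
            "move_probs": list(config.sampler.move_probs),
            "state_update_mode": config.sampler.state_update_mode,
            "enumeration_limit": config.sampler.enumeration_limit,
        },
        "hyperparameters": hp.to_dict(),
        "n_sections": len(sections),
        "n_retained_windows": int(len(rds.d)),
        "non_converged_sections": [s["section"] for s in summaries
                                   if not s["converged"]],
    }
    summary_df = (pd.DataFrame(summaries).sort_values("section")
                  .reset_index(drop=True))
    return GenomeResult(calls=calls, window_table=table,
                        window_states=window_states, rds=rds, hp=hp,
                        section_summaries=summary_df,
                        manifest=manifest)


def _dedupe(starts: list[int], states: list[int]) -> tuple[list[int], list[int]]:
    s_out, c_out = [starts[0]], []
    for m, lab in enumerate(states):
        if c_out and lab == c_out[-1]:
            s_out[-1] = starts[m + 1]
        else:
            c_out.append(lab)
            s_out.append(starts[m + 1])
    return s_out, c_out


def write_outputs(result: GenomeResult, prefix: str) -> dict[str, str]:
    """Write calls BED, window TSV, section diagnostics and run manifest."""
    paths = {
        "calls": f"{prefix}.calls.bed",
        "windows": f"{prefix}.windows.tsv",
        "sections": f"{prefix}.sections.tsv",
        "manifest": f"{prefix}.manifest.json",
    }
    write_calls_bed(result.calls, paths["calls"])
    write_window_table(result.window_table, paths["windows"])
    result.section_summaries.to_csv(paths["sections"], sep="\t", index=False)
    with open(paths["manifest"], "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
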