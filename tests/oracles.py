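"""Independent brute-force oracles used to cross-check pipeline scorers.

These deliberately re-derive each quantity with plain loops from the
definitions, sharing no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def hrd_loh_oracle(segments: pd.DataFrame, chrom_lengths: dict[str, int],
                   min_size: int = 15_000_000,
                   subchrom_frac: float = 0.9) -> int:
    """Enumerate merged subchromosomal LOH runs > min_size, chromosome by
    chromosome, segment by segment."""
    total = 0
    for chrom, length in chrom_lengths.items():
        segs = sorted(
            (r for r in segments.to_dict("records") if r["chrom"] == chrom),
            key=lambda r: r["start"])
        runs = []
        current = None
        for r in segs:
            loh = r["minor_cn"] == 0 and r["total_cn"] >= 1
            if loh:
                if current is not None and r["start"] <= current[1]:
                    current = (current[0], max(current[1], r["end"]))
                else:
                    if current is not None:
                        runs.append(current)
                    current = (r["start"], r["end"])
            else:
                if current is not None:
                    runs.append(current)
                    current = None
        if current is not None:
            runs.append(current)
        for s, e in runs:
            size = e - s
            if size > min_size and size < subchrom_frac * length:
                total += 1
    return total


def lst_oracle(segments: pd.DataFrame, smooth_below: int = 3_000_000,
               min_flank: int = 10_000_000) -> int:
    """Count large-scale transitions: drop segments < smooth_below, merge
    equal total-CN neighbours, then count boundaries with two long flanks."""
    total = 0
    for chrom in segments["chrom"].unique():
        segs = sorted(
            (r for r in segments.to_dict("records") if r["chrom"] == chrom),
            key=lambda r: r["start"])
        kept = [r for r in segs if r["end"] - r["start"] >= smooth_below]
        merged = []
        for r in kept:
            if merged and merged[-1]["total_cn"] == r["total_cn"]:
                merged[-1] = dict(merged[-1], end=r["end"])
            else:
                merged.append(dict(r))
        for left, right in zip(merged, merged[1:]):
            if (left["end"] - left["start"] >= min_flank
                    and right["end"] - right["start"] >= min_flank):
                total += 1
    return total


def bh_oracle(pvals: np.ndarray) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * n / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def filter_predicates_oracle(call: dict) -> list[str]:
    """Evaluate each exclusion filter on one call, straight from the
    definitions; returns the list of violated filter names."""
    violated = []
    if call["segdup"]:
        violated.append("segdup")
    if call["mapability"] < 0.5:
        violated.append("mapability")
    if call["normal_alt"] > 0:
        violated.append("normal_evidence")
    if call["normal_depth"] < 10:
        violated.append("normal_depth")
    if call["tumor_depth"] < 8:
        violated.append("tumor_depth")
    if call["tumor_alt"] < 3:
        violated.append("tumor_alt_reads")
    if call["tumor_alt"] / call["tumor_depth"] < 0.05:
        violated.append("vaf")
    if call["popaf"] > 0.02:
        violated.append("popaf")
    if not call["qual"] > 20:
        violated.append("quality")
    return violated


def window_cover_probability_oracle(event_len: int, chrom_len: int,
                                    window_size: int) -> np.ndarray:
    """Exact per-window cover probability for one event placed uniformly,
    by enumerating every possible start."""
    n_windows = -(-chrom_len // window_size)
    counts = np.zeros(n_windows)
    n_starts = chrom_len - event_len + 1
    for start in range(n_starts):
        first = start // window_size
        last = (start + event_len - 1) // window_size
        counts[first:last + 1] += 1
    return counts / n_starts
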