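"""Allele-specific copy-number processing and per-tumor genomic-scar scores.

Two scar scores quantify the "BRCA-like" phenotype of a profile:

* **HRD-LOH** — the number of subchromosomal LOH runs (minor-allele copy
  number 0 with at least one retained copy) longer than 15 Mb, after
  merging adjacent LOH segments; whole-chromosome LOH does not count.
* **LST** (large-scale state transitions) — the number of breakpoints
  between adjacent copy-number segments each at least 10 Mb long, after
  smoothing out segments shorter than 3 Mb; counted per chromosome arm
  when an arm model is supplied, per chromosome otherwise.

Tumors at or above a score threshold (default 15 for both) are flagged
BRCA-like. Segment tables use 0-based half-open coordinates with columns
``sample, chrom, start, end, num_probes, total_cn, minor_cn``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel


@dataclass
class HRDProfile:
    """Per-tumor HRD scar scores and BRCA-like flags."""

    sample_id: str
    hrd_loh: int
    lst: int
    pct_altered: float
    brca_like_hrd: bool = False
    brca_like_lst: bool = False


def _check_segments(seg: pd.DataFrame) -> None:
    if (seg["end"] <= seg["start"]).any():
        raise ValueError("segment end must exceed start")
    if (seg["minor_cn"] > seg["total_cn"] - seg["minor_cn"]).any():
        raise ValueError("minor-allele copy number exceeds total - minor")


def filter_segments(segments: pd.DataFrame, min_length: int = 50_000,
                    min_probes: int = 21) -> pd.DataFrame:
    """Drop small / poorly supported SCNA segments.

    Non-diploid segments must be longer than ``min_length`` (strict, per
    "larger than 50 kb") with at least ``min_probes`` probes; diploid
    heterozygous segments are always retained as background.
    """
    _check_segments(segments)
    length = segments["end"] - segments["start"]
    diploid = (segments["total_cn"] == 2) & (segments["minor_cn"] == 1)
    keep = diploid | ((length > min_length) & (segments["num_probes"] >= min_probes))
    return segments.loc[keep].copy()


def _loh_runs(seg: pd.DataFrame) -> list[tuple[int, int]]:
    """Merged runs of adjacent LOH segments (minor 0, total >= 1) on one
    sorted sample-chromosome table."""
    runs: list[list[int]] = []
    for rec in seg.sort_values("start").itertuples():
        if rec.minor_cn != 0 or rec.total_cn < 1:
            continue
        if runs and rec.start <= runs[-1][1]:
            runs[-1][1] = max(runs[-1][1], rec.end)
        else:
            runs.append([rec.start, rec.end])
    return [(s, e) for s, e in runs]


def hrd_loh_score(segments: pd.DataFrame, genome: GenomeModel,
                  min_size: int = 15_000_000,
                  subchrom_frac: float = 0.9) -> int:
    """HRD-LOH score of one sample's segments.

    Counts merged LOH runs longer than ``min_size`` that remain
    subchromosomal (run shorter than ``subchrom_frac`` of its chromosome,
    tolerating unsegmented telomeric gaps). Homozygous deletions (total
    copy number 0) do not extend LOH runs.
    """
    score = 0
    for chrom, grp in segments.groupby("chrom"):
        chrom_len = genome.length_of(str(chrom))
        for s, e in _loh_runs(grp):
            if e - s > min_size and (e - s) < subchrom_frac * chrom_len:
                score += 1
    return score


def _smooth_and_merge(seg: pd.DataFrame, smooth_below: int) -> list[list]:
    """Drop segments shorter than the smoothing size, then merge adjacent
    segments with identical total copy number (LST is a total-copy-number
    scar; copy-neutral LOH is no state change here); merged spans absorb
    the removed territory between their members."""
    merged: list[list] = []
    for rec in seg.sort_values("start").itertuples():
        if rec.end - rec.start < smooth_below:
            continue
        if merged and merged[-1][2] == rec.total_cn:
            merged[-1][1] = rec.end
        else:
            merged.append([rec.start, rec.end, rec.total_cn])
    return merged


def lst_score(segments: pd.DataFrame, smooth_below: int = 3_000_000,
              min_flank: int = 10_000_000,
              arms: pd.DataFrame | None = None) -> int:
    """Large-scale state transition count of one sample's segments.

    Per chromosome arm (``arms``: chrom, start, end; whole chromosomes with
    a warning-free fallback when absent): after 3-Mb smoothing, count
    breakpoints whose two flanking merged segments are both >= 10 Mb.
    """
    if arms is not None and len(arms) == 0:
        warnings.warn("empty arm model; falling back to whole chromosomes",
                      stacklevel=2)
        arms = None
    score = 0
    for chrom, grp in segments.groupby("chrom"):
        if arms is not None:
            chrom_arms = arms[arms["chrom"] == chrom]
            pieces = [
                grp[(grp["end"] > a.start) & (grp["start"] < a.end)]
                .assign(start=lambda d, a=a: d["start"].clip(lower=a.start),
                        end=lambda d, a=a: d["end"].clip(upper=a.end))
                for a in chrom_arms.itertuples()
            ] or [grp]
        else:
            pieces = [grp]
        for piece in pieces:
            merged = _smooth_and_merge(piece, smooth_below)
            score += sum(
                1 for a, b in zip(merged, merged[1:])
                if a[1] - a[0] >= min_flank and b[1] - b[0] >= min_flank
            )
    return score


def percent_genome_altered(segments: pd.DataFrame,
                           genome: GenomeModel) -> float:
    """Percent of the genome affected by copy-number change or LOH
    (total copy number != 2, or minor-allele copy number 0)."""
    altered = (segments["total_cn"] != 2) | (segments["minor_cn"] == 0)
    length = (segments["end"] - segments["start"])[altered].sum()
    return 100.0 * float(length) / genome.total_length


def classify_brca_like(profile: HRDProfile, hrd_threshold: int = 15,
                       lst_threshold: int = 15) -> HRDProfile:
    """Set the BRCA-like flags: inclusive at both thresholds ("set to 15")."""
    profile.brca_like_hrd = profile.hrd_loh >= hrd_threshold
    profile.brca_like_lst = profile.lst >= lst_threshold
    return profile


def hrd_profile(segments: pd.DataFrame, sample_id: str, genome: GenomeModel,
                hrd_threshold: int = 15, lst_threshold: int = 15,
                arms: pd.DataFrame | None = None) -> HRDProfile:
    """Compute and classify the full scar profile of one sample."""
    prof = HRDProfile(
        sample_id=sample_id,
        hrd_loh=hrd_loh_score(segments, genome),
        lst=lst_score(segments, arms=arms),
        pct_altered=percent_genome_altered(segments, genome),
    )
    return classify_brca_like(prof, hrd_threshold, lst_threshold)


# ---------------------------------------------------------------------------
# SCNA events

EVENT_COLUMNS = ["sample", "chrom", "start", "end", "event_class", "focal"]

#: events entering gain-like vs loss-like significance testing
GAIN_LIKE = ("gain", "amplification")
LOSS_LIKE = ("deletion",)


def extract_events(segments: pd.DataFrame,
                   focal_below: int = 1_000_000) -> pd.DataFrame:
    """Map non-diploid segments to SCNA events.

    Classes follow the reporting convention amplification (total CN > 4),
    gain (total CN = 3) and deletion (total CN < 2); segments at total copy
    number 4 or copy-neutral LOH fall in none of the three classes and
    yield no event. Events shorter than ``focal_below`` are flagged focal.
    """
    rows = []
    for rec in segments.itertuples():
        if rec.total_cn > 4:
            cls = "amplification"
        elif rec.total_cn == 3:
            cls = "gain"
        elif rec.total_cn < 2:
            cls = "deletion"
        else:
            continue
        rows.append(dict(sample=rec.sample, chrom=rec.chrom, start=rec.start,
                         end=rec.end, event_class=cls,
                         focal=(rec.end - rec.start) < focal_below))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def recurrent_focal_regions(events: pd.DataFrame, cohort_size: int,
                            min_frequency: float = 0.15) -> pd.DataFrame:
    """Union overlapping focal events across samples into regions and keep
    those hitting more than ``min_frequency`` of the cohort.

    Regions are formed separately for gain-like and loss-like events; the
    frequency of a region is the fraction of samples with at least one
    overlapping focal event.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    focal = events[events["focal"]]
    rows = []
    for side, classes in (("gain", GAIN_LIKE), ("loss", LOSS_LIKE)):
        sub = focal[focal["event_class"].isin(classes)]
        for chrom, grp in sub.groupby("chrom"):
            grp = grp.sort_values("start")
            cur = None
            clusters = []
            for rec in grp.itertuples():
                if cur is None or rec.start >= cur[1]:
                    cur = [rec.start, rec.end, {rec.sample}]
                    clusters.append(cur)
                else:
                    cur[1] = max(cur[1], rec.end)
                    cur[2].add(rec.sample)
            for s, e, samples in clusters:
                freq = len(samples) / cohort_size
                if freq > min_frequency:
                    rows.append(dict(chrom=chrom, start=s, end=e, side=side,
                                     n_samples=len(samples), frequency=freq))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "side", "n_samples",
                       "frequency"])
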