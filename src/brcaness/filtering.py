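"""Somatic variant exclusion filters and per-tumor mutation summaries.

The filter chain reproduces a conservative tumor/normal exome cleaning
scheme: calls are discarded when they fall in segmental duplications or
poorly mapable regions, show any variant evidence in the matched normal,
lack read support in either sample, sit below a minimum variant allele
frequency, are common in population databases, or have low call quality.
Every threshold is a :class:`FilterConfig` field; pass conditions are
evaluated inclusively at the stated boundary (a VAF of exactly 0.05
passes), reflecting a literal reading of exclusions phrased as strict
inequalities ("fewer than 10 reads").

All filters are pure per-call predicates, so the chain is idempotent and
order-independent, and a call may be tallied under several filters at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contexts import is_transition

#: filter names, in reporting order
FILTER_NAMES = ("segdup", "mapability", "normal_evidence", "normal_depth",
                "tumor_depth", "tumor_alt_reads", "vaf", "popaf", "quality",
                "unannotatable")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the somatic exclusion filters (pass-side semantics)."""

    min_mapability: float = 0.5
    max_normal_alt: int = 0
    min_normal_depth: int = 10
    min_tumor_depth: int = 8
    min_tumor_alt: int = 3
    min_vaf: float = 0.05
    max_popaf: float = 0.02
    min_qual: float = 20.0  # phred floor; pass requires qual > floor

    def __post_init__(self) -> None:
        for name in ("min_mapability", "max_normal_alt", "min_normal_depth",
                     "min_tumor_depth", "min_tumor_alt", "min_vaf",
                     "max_popaf", "min_qual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ValueError("min_vaf must lie in [0, 1]")


@dataclass
class TumorSummary:
    """Per-tumor mutation burden summary.

    ``dn_ds`` (non-synonymous : synonymous exonic mutations) and ``ts_tv``
    (exonic transitions : transversions) are NaN when their denominator is
    zero.
    """

    tumor_id: str
    n_snv: int = 0
    n_indel: int = 0
    dn_ds: float = float("nan")
    ts_tv: float = float("nan")
    exclusions: dict[str, int] = field(default_factory=dict)


def compute_vaf(tumor_alt: int, tumor_depth: int) -> float:
    """Variant allele frequency = variant reads / total depth in the tumor."""
    if tumor_depth <= 0:
        raise ValueError("uncallable site: tumor depth is zero")
    return tumor_alt / tumor_depth


def _violations(calls: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Boolean frame, one column per filter, True where the call fails it."""
    required = ["segdup", "mapability", "normal_alt", "normal_depth",
                "tumor_depth", "tumor_alt", "popaf", "qual"]
    unannotatable = calls[required].isna().any(axis=1)
    depth = calls["tumor_depth"].to_numpy(float)
    vaf = np.divide(calls["tumor_alt"].to_numpy(float), depth,
                    out=np.zeros(len(calls)), where=depth > 0)
    out = pd.DataFrame(index=calls.index)
    out["segdup"] = calls["segdup"].fillna(False).astype(bool)
    out["mapability"] = calls["mapability"] < cfg.min_mapability
    out["normal_evidence"] = calls["normal_alt"] > cfg.max_normal_alt
    out["normal_depth"] = calls["normal_depth"] < cfg.min_normal_depth
    out["tumor_depth"] = calls["tumor_depth"] < cfg.min_tumor_depth
    out["tumor_alt_reads"] = calls["tumor_alt"] < cfg.min_tumor_alt
    out["vaf"] = (vaf < cfg.min_vaf) | (depth <= 0)
    out["popaf"] = calls["popaf"] > cfg.max_popaf
    out["quality"] = ~(calls["qual"] > cfg.min_qual)
    out = out.fillna(True)  # a missing annotation cannot demonstrate a pass
    out["unannotatable"] = unannotatable
    return out


def apply_somatic_filters(
    calls: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the exclusion-filter chain to a call table.

    Returns the passing calls (original row order preserved) and a tally of
    how many calls each filter excluded; a call failing several filters is
    counted under each of them.
    """
    cfg = config or FilterConfig()
    if calls.empty:
        return calls.copy(), {name: 0 for name in FILTER_NAMES}
    bad = _violations(calls, cfg)
    tally = {name: int(bad[name].sum()) for name in FILTER_NAMES}
    passing = calls.loc[~bad.any(axis=1)].copy()
    return passing, tally


def summarize_tumor(calls: pd.DataFrame, tumor_id: str,
                    exclusions: dict[str, int] | None = None) -> TumorSummary:
    """Summarize one tumor's passing calls (burden, Dn:Ds, Ts:Tv).

    Exonic mutations are those with effect in {synonymous, missense,
    truncating}; non-synonymous = missense + truncating. Transitions are
    C<->T and A<->G substitutions among exonic SNVs.
    """
    snv = calls[calls["vclass"] == "SNV"]
    exonic = snv[snv["effect"].isin(["synonymous", "missense", "truncating"])]
    n_syn = int((exonic["effect"] == "synonymous").sum())
    n_nonsyn = len(exonic) - n_syn
    ts = sum(is_transition(r, a) for r, a in zip(exonic["ref"], exonic["alt"]))
    tv = len(exonic) - ts
    return TumorSummary(
        tumor_id=tumor_id,
        n_snv=len(snv),
        n_indel=int((calls["vclass"] == "indel").sum()),
        dn_ds=n_nonsyn / n_syn if n_syn else float("nan"),
        ts_tv=ts / tv if tv else float("nan"),
        exclusions=dict(exclusions or {}),
    )
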