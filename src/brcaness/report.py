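"""Driver prioritization, recurrence screening and cohort reporting.

Candidate drivers are kept when they are protein-truncating or splice-site
mutations, or missense changes predicted damaging by all three of SIFT
(<= 0.05), PolyPhen2 (> 0.8) and MutationTaster (> 0.8); a minimum VAF of
0.05 is enforced throughout. Genes mutated in two or more distinct tumors
are reported as recurrent. The same predicate screens germline calls
against a susceptibility panel (with LOH-overlap annotation), and the
cohort report aggregates per-tumor burden summaries, HRD scar profiles and
gene-by-tumor mutation tables into Table-1-style output.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .filtering import TumorSummary
from .scna import HRDProfile


@dataclass(frozen=True)
class DriverCallConfig:
    """Retention thresholds for driver prioritization."""

    sift_max: float = 0.05
    pp2_min: float = 0.8
    mt_min: float = 0.8
    min_vaf: float = 0.05
    min_recurrent_tumors: int = 2
    retained_effects: tuple[str, ...] = ("truncating", "splice")

    def __post_init__(self) -> None:
        for name in ("sift_max", "pp2_min", "mt_min", "min_vaf"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def prioritize_variants(calls: pd.DataFrame,
                        config: DriverCallConfig | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the driver retention predicate to a call table.

    Returns (retained calls, excluded calls with a ``reason`` column).
    Truncating and splice mutations are always retained; missense calls
    need damaging predictions from all three scores, and missense calls
    with any score missing are excluded as ``unscored``. All retained
    calls must reach the minimum VAF.
    """
    cfg = config or DriverCallConfig()
    vaf = calls["tumor_alt"] / calls["tumor_depth"]
    always = calls["effect"].isin(cfg.retained_effects)
    missense = calls["effect"] == "missense"
    scores = calls[["sift", "pp2", "mt"]]
    unscored = missense & scores.isna().any(axis=1)
    damaging = (missense & ~unscored
                & (calls["sift"] <= cfg.sift_max)
                & (calls["pp2"] > cfg.pp2_min)
                & (calls["mt"] > cfg.mt_min))
    keep = (always | damaging) & (vaf >= cfg.min_vaf)
    excluded = calls.loc[~keep].copy()
    reason = np.where(unscored[~keep], "unscored",
                      np.where(vaf[~keep] < cfg.min_vaf, "low_vaf", "benign"))
    excluded["reason"] = reason
    return calls.loc[keep].copy(), excluded


def recurrent_genes(retained: pd.DataFrame,
                    min_tumors: int = 2) -> pd.DataFrame:
    """Genes with retained mutations in at least ``min_tumors`` distinct
    tumors, ranked by tumor count then alphabetically. Multiple mutations
    within one tumor count once."""
    counts = (retained.groupby("gene")["tumor"].nunique()
              .rename("n_tumors").reset_index())
    hits = counts[counts["n_tumors"] >= min_tumors]
    return (hits.sort_values(["n_tumors", "gene"], ascending=[False, True])
            .reset_index(drop=True))


def germline_candidate_screen(germline: pd.DataFrame, panel: list[str],
                              loh_segments: pd.DataFrame | None = None,
                              config: DriverCallConfig | None = None
                              ) -> pd.DataFrame:
    """Screen germline calls for damaging variants in susceptibility genes.

    Variants in ``panel`` genes surviving the driver predicate are flagged;
    when a tumor LOH segment table is supplied (sample/chrom/start/end with
    minor_cn = 0 rows, or any interval table), each flagged variant is
    annotated with whether its tumor shows LOH over the locus.
    """
    if germline.empty:
        return germline.assign(loh_overlap=pd.Series(dtype=bool))
    in_panel = germline[germline["gene"].isin(panel)]
    retained, _ = prioritize_variants(in_panel, config)
    overlaps = []
    for rec in retained.itertuples():
        hit = False
        if loh_segments is not None and len(loh_segments):
            seg = loh_segments
            if "minor_cn" in seg.columns:
                seg = seg[(seg["minor_cn"] == 0) & (seg["total_cn"] >= 1)]
            if "sample" in seg.columns:
                seg = seg[seg["sample"] == rec.tumor]
            hit = bool(((seg["chrom"] == rec.chrom) & (seg["start"] < rec.pos)
                        & (seg["end"] >= rec.pos)).any())
        overlaps.append(hit)
    out = retained.copy()
    out["loh_overlap"] = overlaps
    return out


# ---------------------------------------------------------------------------
# cohort report


def load_cohort_table() -> pd.DataFrame:
    """Packaged per-tumor summary table of the 32-sample reference cohort
    (SNV/indel burden, Dn:Ds, Ts:Tv, %SCNA, clone count)."""
    path = resources.files("brcaness.data") / "os_cohort_table.tsv"
    return pd.read_csv(path, sep="\t")


def load_gene_panel() -> pd.DataFrame:
    """Packaged 69-gene BRCA-network panel (BRCA1/2 plus 67 interactors).

    Gene symbols are real; the coordinates are synthetic placeholders laid
    out on the toy karyotype. Supply a real BED for GRCh37 runs.
    """
    path = resources.files("brcaness.data") / "brca_network_toy.synthetic.bed"
    return pd.read_csv(path, sep="\t", names=["chrom", "start", "end", "gene"])


def _column_stats(values: pd.Series) -> dict:
    """Median (mean of central order statistics for even n) and range over
    the non-missing values of one summary column."""
    vals = pd.to_numeric(values, errors="coerce").dropna()
    if vals.empty:
        return {"median": float("nan"), "min": float("nan"),
                "max": float("nan"), "n": 0}
    return {"median": float(vals.median()), "min": float(vals.min()),
            "max": float(vals.max()), "n": int(len(vals))}


def cohort_report(summaries: list[TumorSummary] | pd.DataFrame,
                  hrd_profiles: list[HRDProfile] | None = None,
                  gene_table: pd.DataFrame | None = None,
                  exposures: pd.DataFrame | None = None) -> dict:
    """Aggregate per-tumor summaries into the cohort report bundle.

    Returns a dict with the per-tumor table, cohort median/range statistics
    for each numeric column, and (when supplied) HRD profiles, a
    gene-by-tumor mutation matrix and signature exposures. Missing stages
    appear as explicit ``None`` gaps.
    """
    if isinstance(summaries, pd.DataFrame):
        per_tumor = summaries.copy()
    else:
        per_tumor = pd.DataFrame([
            dict(id=s.tumor_id, snv=s.n_snv, indels=s.n_indel,
                 dn_ds=s.dn_ds, ts_tv=s.ts_tv) for s in summaries])
    if hrd_profiles:
        hrd = pd.DataFrame([
            dict(id=p.sample_id, hrd_loh=p.hrd_loh, lst=p.lst,
                 pct_scna=p.pct_altered, brca_like_hrd=p.brca_like_hrd,
                 brca_like_lst=p.brca_like_lst) for p in hrd_profiles])
        per_tumor = per_tumor.merge(hrd, on="id", how="outer")
    stats = {
        col: _column_stats(per_tumor[col])
        for col in per_tumor.columns
        if col != "id" and pd.api.types.is_numeric_dtype(
            pd.to_numeric(per_tumor[col], errors="coerce"))
    }
    matrix = None
    if gene_table is not None and len(gene_table):
        matrix = pd.crosstab(gene_table["gene"], gene_table["tumor"])
    return {
        "per_tumor": per_tumor,
        "cohort_stats": stats,
        "gene_by_tumor": matrix,
        "exposures": exposures,
        "gaps": [name for name, val in (("hrd_profiles", hrd_profiles),
                                        ("gene_table", gene_table),
                                        ("exposures", exposures))
                 if val is None],
    }
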