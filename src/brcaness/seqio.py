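"""Reading and writing the pipeline's on-disk formats.

Variant catalogs travel as VCF v4.2 with the annotation INFO tags the
filtering stage consumes (GENE, EFF, SIFT, PP2, MT, POPAF, MAPQ50, SEGDUP,
TNC) and per-sample AD/DP for the TUMOR and NORMAL columns; segment tables
travel as SEG-style TSV. Files written here are read back with cyvcf2 /
pandas, so round-trips are validated by an independent parser.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

VCF_COLUMNS = ["tumor", "chrom", "pos", "ref", "alt", "vclass", "tumor_depth",
               "tumor_alt", "normal_depth", "normal_alt", "qual", "mapability",
               "segdup", "popaf", "gene", "effect", "sift", "pp2", "mt",
               "context"]

SEG_COLUMNS = ["sample", "chrom", "start", "end", "num_probes",
               "total_cn", "minor_cn"]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=brcaness
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=EFF,Number=1,Type=String,Description="Coding effect class">
##INFO=<ID=SIFT,Number=1,Type=Float,Description="SIFT score (low = damaging)">
##INFO=<ID=PP2,Number=1,Type=Float,Description="PolyPhen2 score">
##INFO=<ID=MT,Number=1,Type=Float,Description="MutationTaster score">
##INFO=<ID=POPAF,Number=1,Type=Float,Description="Population allele frequency">
##INFO=<ID=MAPQ50,Number=1,Type=Float,Description="Mapability score in [0,1]">
##INFO=<ID=SEGDUP,Number=0,Type=Flag,Description="Segmental duplication region">
##INFO=<ID=TNC,Number=1,Type=String,Description="Pyrimidine-normalized trinucleotide context">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
"""


def write_vcf(calls: pd.DataFrame, path: str | os.PathLike,
              contigs: dict[str, int] | None = None) -> None:
    """Write a catalog of one tumor's calls (or a cohort; tumor id is kept in
    the filename by convention, one file per tumor) as VCF v4.2 text."""
    tumors = calls["tumor"].unique() if len(calls) else []
    if len(tumors) > 1:
        raise ValueError("write one VCF per tumor; got multiple tumor ids")
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 "TUMOR\tNORMAL\n")
        for rec in calls.sort_values(["chrom", "pos"]).itertuples():
            info = [f"GENE={rec.gene}", f"EFF={rec.effect}"]
            for tag, val in (("SIFT", rec.sift), ("PP2", rec.pp2),
                             ("MT", rec.mt)):
                if pd.notna(val):
                    info.append(f"{tag}={val:g}")
            info += [f"POPAF={rec.popaf:g}", f"MAPQ50={rec.mapability:g}"]
            if rec.segdup:
                info.append("SEGDUP")
            if isinstance(rec.context, str) and rec.context:
                info.append(f"TNC={rec.context}")
            t_ref = rec.tumor_depth - rec.tumor_alt
            n_ref = rec.normal_depth - rec.normal_alt
            fh.write("\t".join([
                str(rec.chrom), str(rec.pos), ".", rec.ref, rec.alt,
                f"{rec.qual:g}", "PASS", ";".join(info), "AD:DP",
                f"{t_ref},{rec.tumor_alt}:{rec.tumor_depth}",
                f"{n_ref},{rec.normal_alt}:{rec.normal_depth}",
            ]) + "\n")


def read_vcf(path: str | os.PathLike, tumor_id: str | None = None) -> pd.DataFrame:
    """Read an annotated tumor/normal VCF into the canonical call table.

    Accepts any VCF carrying the documented INFO tags and TUMOR/NORMAL
    sample columns with AD/DP.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        t_idx, n_idx = samples.index("TUMOR"), samples.index("NORMAL")
    except ValueError as exc:
        raise ValueError("VCF must contain TUMOR and NORMAL samples") from exc
    if tumor_id is None:
        tumor_id = os.path.splitext(os.path.basename(str(path)))[0]
    rows = []
    for v in vcf:
        ad = v.format("AD")
        dp = v.format("DP")
        alt = v.ALT[0] if v.ALT else ""
        vclass = "SNV" if len(v.REF) == 1 and len(alt) == 1 else "indel"
        rows.append(dict(
            tumor=tumor_id, chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt,
            vclass=vclass,
            tumor_depth=int(dp[t_idx][0]), tumor_alt=int(ad[t_idx][1]),
            normal_depth=int(dp[n_idx][0]), normal_alt=int(ad[n_idx][1]),
            qual=float(v.QUAL) if v.QUAL is not None else np.nan,
            mapability=_info_float(v, "MAPQ50"),
            segdup=bool(v.INFO.get("SEGDUP", False)),
            popaf=_info_float(v, "POPAF"),
            gene=v.INFO.get("GENE", ""), effect=v.INFO.get("EFF", ""),
            sift=_info_float(v, "SIFT"), pp2=_info_float(v, "PP2"),
            mt=_info_float(v, "MT"), context=v.INFO.get("TNC", "") or "",
        ))
    return pd.DataFrame(rows, columns=VCF_COLUMNS)


def read_contigs(path: str | os.PathLike) -> dict[str, int]:
    """Contig names and lengths declared in a VCF header (may be empty)."""
    vcf = VCF(str(path))
    try:
        return dict(zip(vcf.seqnames, vcf.seqlens))
    except AttributeError:
        return {}


def _info_float(variant, tag: str) -> float:
    val = variant.INFO.get(tag)
    return float(val) if val is not None else np.nan


def write_seg(segments: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write segments as SEG-style TSV (0-based half-open coordinates)."""
    segments[SEG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_seg(path: str | os.PathLike) -> pd.DataFrame:
    seg = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SEG_COLUMNS) - set(seg.columns)
    if missing:
        raise ValueError(f"SEG file missing columns: {sorted(missing)}")
    return seg[SEG_COLUMNS]


def write_truth(truth: pd.DataFrame, path: str | os.PathLike) -> None:
    """Audit/ground-truth sidecar TSV (never consumed by pipeline stages)."""
    truth.to_csv(path, sep="\t", index=False)
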