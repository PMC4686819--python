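"""Cancer-cell-fraction estimation, clone counting and gene-level clonality.

The CCF of a point mutation is inverted from its VAF given tumor purity,
local total copy number and mutation multiplicity:

    CCF = VAF * (purity * CN_total + 2 * (1 - purity)) / (purity * m)

with multiplicity m chosen as the integer in [1, CN_total] whose expected
clonal VAF is closest to the observation (preferring assignments that keep
CCF plausible). Clones are counted by 1-D agglomerative merging of the
per-variant CCFs with a configurable merge tolerance — a deliberately
simple substitute for Dirichlet-process clustering. SCNA events are labeled
clonal when their cellular fraction reaches a threshold (default 0.9), and
gene-level clonal/subclonal SCNA frequencies across a cohort are combined
into the product coordinate used to rank genes and cluster them by
Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

CCF_CAP = 1.0  # a cancer-cell fraction cannot exceed 1; overshoot is noise


@dataclass(frozen=True)
class TumorContext:
    """Purity and local copy state needed to invert a VAF into a CCF."""

    tumor_id: str
    purity: float
    cn_total: int = 2
    cn_minor: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must lie in (0, 1]; 0 is uninformative")
        if self.cn_total < 1:
            raise ValueError("total copy number at a mutated locus must be >= 1")


@dataclass
class CCFEstimate:
    multiplicity: int
    ccf: float
    clonal: bool


def expected_vaf(purity: float, ccf: float, multiplicity: int,
                 cn_total: int) -> float:
    """Expected VAF of a mutation on ``multiplicity`` copies, present in a
    fraction ``ccf`` of tumor cells, in an impure diploid-normal mixture."""
    return purity * ccf * multiplicity / (purity * cn_total + 2 * (1 - purity))


def estimate_ccf(vaf: float, context: TumorContext,
                 clonal_threshold: float = 0.9,
                 multiplicity: int | None = None) -> CCFEstimate:
    """Invert a VAF into a CCF estimate, choosing the multiplicity.

    Among m in [1, CN_total], picks the m whose expected clonal VAF is
    nearest the observation; the resulting CCF is capped at 1, since read
    sampling noise can otherwise push clonal mutations to nominal CCFs
    slightly above 1 (re-assigning them a higher multiplicity instead would
    fabricate intermediate subclones). When the multiplicity is known
    (e.g. from phasing or simulation truth), pass it explicitly and the
    inversion is exact for any true CCF <= 1.
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError("vaf must lie in [0, 1]")
    denom = context.purity * context.cn_total + 2 * (1 - context.purity)
    if multiplicity is not None:
        if not 1 <= multiplicity <= context.cn_total:
            raise ValueError("multiplicity must lie in [1, CN_total]")
        m = multiplicity
    else:
        m = min(
            range(1, context.cn_total + 1),
            key=lambda k: abs(
                expected_vaf(context.purity, 1.0, k, context.cn_total) - vaf))
    ccf = min(vaf * denom / (context.purity * m), CCF_CAP)
    return CCFEstimate(multiplicity=m, ccf=ccf, clonal=ccf >= clonal_threshold)


def count_clones(ccfs, merge_tol: float = 0.1,
                 clonal_threshold: float = 0.9,
                 min_cluster_frac: float = 0.05) -> dict:
    """Count clones by 1-D single-linkage merging of CCF estimates.

    Sorted CCFs are split wherever the gap between neighbours exceeds
    ``merge_tol``; each resulting group is one clone. Groups smaller than
    ``max(2, min_cluster_frac * n)`` variants are absorbed into the cluster
    with the nearest center — a handful of read-noise outliers does not
    constitute a clone, which also means true subclones carrying fewer
    than ~5% of mutations are not resolved. Returns the clone count, per-variant cluster
    assignments (input order), cluster centers (means, descending), and
    the per-variant clonal flag — membership in the highest-center cluster
    when that center is >= ``clonal_threshold``.
    """
    ccfs = np.asarray(list(ccfs), dtype=float)
    if len(ccfs) == 0:
        raise ValueError("need at least one CCF estimate")
    order = np.argsort(ccfs)
    labels_sorted = np.zeros(len(ccfs), dtype=int)
    cluster = 0
    for i in range(1, len(ccfs)):
        if ccfs[order[i]] - ccfs[order[i - 1]] > merge_tol:
            cluster += 1
        labels_sorted[i] = cluster
    labels = np.empty(len(ccfs), dtype=int)
    labels[order] = labels_sorted
    min_size = max(2, int(np.ceil(min_cluster_frac * len(ccfs))))
    while True:  # absorb undersized outlier clusters
        ids, sizes = np.unique(labels, return_counts=True)
        small = ids[sizes < min_size]
        if len(small) == 0 or len(ids) == 1:
            break
        means = {k: ccfs[labels == k].mean() for k in ids}
        k = min(small, key=lambda k: sizes[list(ids).index(k)])
        others = [j for j in ids if j != k]
        target = min(others, key=lambda j: abs(means[j] - means[k]))
        labels[labels == k] = target
    ids = np.unique(labels)
    relabeled = np.searchsorted(ids, labels)
    labels = relabeled
    cluster = len(ids) - 1
    centers = np.array([ccfs[labels == k].mean() for k in range(cluster + 1)])
    rank = np.argsort(-centers)  # relabel so cluster 0 has highest center
    relabel = np.empty_like(rank)
    relabel[rank] = np.arange(len(rank))
    labels = relabel[labels]
    centers = centers[rank]
    clonal = (labels == 0) & (centers[0] >= clonal_threshold)
    return {"n_clones": len(centers), "labels": labels, "centers": centers,
            "clonal": clonal}


def scna_clonality(cellular_fraction: float | None,
                   clonal_threshold: float = 0.9) -> str:
    """Label an SCNA event clonal/subclonal from its cellular fraction."""
    if cellular_fraction is None or (isinstance(cellular_fraction, float)
                                     and np.isnan(cellular_fraction)):
        return "unknown"
    return "clonal" if cellular_fraction >= clonal_threshold else "subclonal"


def fit_scna_fraction(observed_logratio: float, purity: float,
                      event_cn: int, grid_step: float = 0.01) -> float:
    """Grid-search the cellular fraction of a single SCNA event.

    Models the observed log2 ratio of a segment as a mixture of tumor cells
    with the event (copy number ``event_cn``), tumor cells without it
    (diploid) and normal contamination, and returns the fraction f in
    [0, 1] minimizing the absolute deviation from the expectation.
    """
    fs = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    cn_mix = fs * event_cn + (1 - fs) * 2.0
    expected = np.log2((purity * cn_mix + 2 * (1 - purity)) / 2.0)
    return float(fs[np.argmin(np.abs(expected - observed_logratio))])


# ---------------------------------------------------------------------------
# gene-level clonality map


def gene_clonality_map(events: pd.DataFrame, genes: pd.DataFrame,
                       cohort_size: int) -> pd.DataFrame:
    """Gene-level clonal and subclonal SCNA frequencies across a cohort.

    ``events`` needs sample/chrom/start/end plus a ``clonality`` column
    ("clonal" | "subclonal" | "unknown"; unknowns are excluded); ``genes``
    is a BED-like frame with gene/chrom/start/end. A gene's clonal
    frequency is the fraction of the cohort with at least one clonal event
    overlapping it; the product coordinate is clonal x subclonal frequency.
    """
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    if genes[["chrom", "start", "end"]].isna().any().any():
        bad = genes.loc[genes[["chrom", "start", "end"]].isna().any(axis=1),
                        "gene"].iloc[0]
        raise ValueError(f"gene without interval: {bad}")
    rows = []
    for g in genes.itertuples():
        hit = events[(events["chrom"] == g.chrom) & (events["end"] > g.start)
                     & (events["start"] < g.end)]
        clonal = hit.loc[hit["clonality"] == "clonal", "sample"].nunique()
        subclonal = hit.loc[hit["clonality"] == "subclonal", "sample"].nunique()
        cf, sf = clonal / cohort_size, subclonal / cohort_size
        rows.append(dict(gene=g.gene, clonal_freq=cf, subclonal_freq=sf,
                         product=cf * sf))
    return pd.DataFrame(rows, columns=["gene", "clonal_freq", "subclonal_freq",
                                       "product"])


def cluster_genes(profiles: pd.DataFrame, distance_cutoff: float = 0.2,
                  n_clusters: int | None = None) -> pd.DataFrame:
    """Agglomerative (average-linkage Euclidean) clustering of gene
    profiles on (clonal_freq, subclonal_freq), plus an outlier ranking by
    distance from the cohort centroid (rank 1 = most outlying)."""
    if len(profiles) < 2:
        raise ValueError("need at least two gene profiles to cluster")
    X = profiles[["clonal_freq", "subclonal_freq"]].to_numpy(float)
    if np.allclose(pdist(X), 0.0):
        labels = np.zeros(len(X), dtype=int)
    else:
        Z = linkage(X, method="average", metric="euclidean")
        if n_clusters is not None:
            labels = fcluster(Z, t=n_clusters, criterion="maxclust") - 1
        else:
            labels = fcluster(Z, t=distance_cutoff, criterion="distance") - 1
    centroid = X.mean(axis=0)
    dist = np.linalg.norm(X - centroid, axis=1)
    out = profiles.copy()
    out["cluster"] = labels
    out["centroid_distance"] = dist
    out["outlier_rank"] = (-dist).argsort().argsort() + 1
    return out
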