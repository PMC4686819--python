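"""Synthetic tumor-normal variant catalogs and allele-specific segment profiles.

Every downstream stage of the pipeline (filtering, spectra, HRD scoring,
SCNA significance, clonality, driver reporting) is exercised on data from
this module, which emulates an exome-sequenced discovery cohort with paired
normals plus SNP-array copy-number profiles, with full ground truth:

* SNV trinucleotide contexts are drawn from a per-tumor mixture of generator
  signatures, so spectrum and NMF recovery can be checked against truth.
* Read support follows the standard allele-frequency model
  ``VAF = purity * CCF * multiplicity / (purity * CN_total + 2 * (1 - purity))``
  with Poisson depths and binomial alt counts.
* Segment profiles tile each chromosome exactly, with requested numbers of
  large LOH segments and large-scale-transition breakpoints realized by
  construction, plus recurrent focal loci embedded at a chosen penetrance.

Ground truth (signature of origin, true CCF, intended filter fate, per-tumor
HRD-LOH/LST counts, locus carrier status) is returned in sidecar tables and
never written into the VCF/SEG records the pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .contexts import CHANNELS_96, channel_parts
from .genome import GenomeModel

_EFFECTS = ("synonymous", "missense", "truncating", "splice", "noncoding")
_SNV_EFFECT_P = (0.25, 0.55, 0.12, 0.05, 0.03)

#: artifact modes cycled by ``n_filter_artifacts``, named after the filter
#: each one is constructed to violate (exactly one violation per call)
ARTIFACT_MODES = (
    "segdup", "mapability", "normal_evidence", "normal_depth",
    "tumor_depth", "tumor_alt_reads", "vaf", "popaf", "quality",
)


def default_generator_signatures() -> pd.DataFrame:
    """Three well-separated generator signatures on the 96 channels.

    Rows are signatures, columns the 96 channels; each row sums to 1.
    The three processes occupy disjoint substitution-class blocks (C>T with
    CpG enrichment, C>A, T>C) plus a tiny uniform floor so no channel has
    probability zero.
    """
    sigs = np.full((3, 96), 1e-4)
    blocks = {0: "C>T", 1: "C>A", 2: "T>C"}
    for row, sub in blocks.items():
        for i, ch in enumerate(CHANNELS_96):
            if ch[2:5] != sub:
                continue
            w = 1.0
            if sub == "C>T" and ch[6] == "G":  # CpG-focused, ageing-like
                w = 4.0
            elif ch[0] in "CT":
                w = 1.5
            sigs[row, i] += w
    sigs /= sigs.sum(axis=1, keepdims=True)
    return pd.DataFrame(sigs, index=["SigA", "SigB", "SigC"], columns=CHANNELS_96)


@dataclass(frozen=True)
class RecurrentLocus:
    """A recurrent SCNA locus embedded across the cohort at a penetrance."""

    chrom: str
    start: int
    end: int
    kind: str  # "deletion" | "gain" | "amplification"
    penetrance: float

    _CN = {"deletion": (1, 0), "gain": (3, 1), "amplification": (5, 1)}

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("locus end must exceed start")
        if self.kind not in self._CN:
            raise ValueError(f"unknown locus kind {self.kind!r}")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must lie in [0, 1]")

    @property
    def copy_state(self) -> tuple[int, int]:
        return self._CN[self.kind]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Scalar per-tumor fields broadcast to all tumors; sequences must have
    length ``n_tumors``. ``seed`` drives every random draw and is recorded
    in all outputs.
    """

    n_tumors: int = 1
    snv_count: int | Sequence[int] = 100
    indel_count: int | Sequence[int] = 20
    signatures: pd.DataFrame | None = None
    signature_weights: Sequence[float] | np.ndarray | None = None
    purity: float | Sequence[float] = 1.0
    mean_depth: float = 150.0
    ccf_values: tuple[float, ...] = (1.0,)
    ccf_weights: tuple[float, ...] = (1.0,)
    loh_segments: int | Sequence[int] = 0
    loh_size: int = 20_000_000
    lst_breakpoints: int | Sequence[int] = 0
    recurrent_loci: tuple[RecurrentLocus, ...] = ()
    background_events: int | Sequence[int] = 0
    background_length_range: tuple[int, int] = (500_000, 2_900_000)
    planted_driver_genes: tuple[str, ...] = ()
    driver_tumors_per_gene: int = 3
    n_filter_artifacts: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumors < 1:
            raise ValueError("n_tumors must be >= 1")
        if self.signatures is None:
            self.signatures = default_generator_signatures()
        sig = np.asarray(self.signatures, dtype=float)
        if sig.ndim != 2 or sig.shape[1] != 96:
            raise ValueError("generator signatures must be defined on 96 channels")
        if (sig < 0).any():
            raise ValueError("generator signatures must be non-negative")
        n_sigs = sig.shape[0]
        if self.signature_weights is None:
            self.signature_weights = np.full((self.n_tumors, n_sigs), 1.0 / n_sigs)
        w = np.atleast_2d(np.asarray(self.signature_weights, dtype=float))
        if w.shape[0] == 1:
            w = np.repeat(w, self.n_tumors, axis=0)
        if w.shape != (self.n_tumors, n_sigs):
            raise ValueError(
                f"mixture dimension mismatch: weights {w.shape} vs "
                f"{self.n_tumors} tumors x {n_sigs} signatures"
            )
        if (w < 0).any():
            raise ValueError("mixture weights must be non-negative")
        sums = w.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("mixture weights must sum to 1 per tumor")
        self.signature_weights = w / sums[:, None]
        for p in self._per_tumor(self.purity, float):
            if not 0.0 < p <= 1.0:
                raise ValueError("purity must lie in (0, 1]")
        if abs(sum(self.ccf_weights) - 1.0) > 1e-6:
            raise ValueError("ccf_weights must sum to 1")

    def _per_tumor(self, value, cast) -> list:
        if np.isscalar(value):
            return [cast(value)] * self.n_tumors
        vals = [cast(v) for v in value]
        if len(vals) != self.n_tumors:
            raise ValueError("per-tumor sequence length must equal n_tumors")
        return vals

    def tumor_ids(self) -> list[str]:
        return [f"T{i + 1:03d}" for i in range(self.n_tumors)]


@dataclass
class VariantSimulation:
    """Catalog of simulated calls plus the audit sidecar."""

    calls: pd.DataFrame
    truth: pd.DataFrame
    seed: int


@dataclass
class SegmentSimulation:
    """Tiled allele-specific segments plus per-tumor truth tables."""

    segments: pd.DataFrame
    truth: pd.DataFrame
    locus_carriers: pd.DataFrame
    seed: int


# ---------------------------------------------------------------------------
# variant catalog


def _expected_vaf(purity: float, ccf: float, mult: int, cn_total: int) -> float:
    return purity * ccf * mult / (purity * cn_total + 2.0 * (1.0 - purity))


def _draw_position(rng, genome: GenomeModel) -> tuple[str, int]:
    lengths = np.asarray(genome.chrom_lengths, dtype=float)
    ci = rng.choice(len(lengths), p=lengths / lengths.sum())
    pos = int(rng.integers(2, genome.chrom_lengths[ci] - 1)) + 1  # 1-based
    return genome.chrom_names[ci], pos


def _effect_scores(rng, effect: str) -> tuple[float, float, float]:
    """SIFT / PolyPhen2 / MutationTaster scores consistent with the effect."""
    if effect == "missense":
        if rng.random() < 0.3:  # damaging-predicted missense
            return (round(rng.uniform(0.0, 0.05), 4),
                    round(rng.uniform(0.81, 1.0), 4),
                    round(rng.uniform(0.81, 1.0), 4))
        return (round(rng.uniform(0.1, 1.0), 4),
                round(rng.uniform(0.0, 0.79), 4),
                round(rng.uniform(0.0, 0.79), 4))
    if effect in ("truncating", "splice"):
        return (np.nan, np.nan, np.nan)
    return (round(rng.uniform(0.2, 1.0), 4),
            round(rng.uniform(0.0, 0.5), 4),
            round(rng.uniform(0.0, 0.5), 4))


def _base_call(rng, config, genome, tumor, purity) -> dict:
    depth = max(1, int(rng.poisson(config.mean_depth)))
    ndepth = max(1, int(rng.poisson(config.mean_depth)))
    chrom, pos = _draw_position(rng, genome)
    return dict(
        tumor=tumor, chrom=chrom, pos=pos,
        tumor_depth=depth, normal_depth=ndepth, normal_alt=0,
        qual=round(rng.uniform(40.0, 90.0), 1),
        mapability=round(rng.uniform(0.8, 1.0), 3),
        segdup=False, popaf=0.0,
        gene=f"GENE{int(rng.integers(0, 5000)):04d}",
    )


def _finish_snv(rng, rec, truth, config, purity, ccf, channel) -> None:
    ref, alt, five, three = channel_parts(channel)
    mult, cn = 1, 2
    vaf = _expected_vaf(purity, ccf, mult, cn)
    rec.update(ref=ref, alt=alt, vclass="SNV", context=channel,
               tumor_alt=int(rng.binomial(rec["tumor_depth"], vaf)))
    truth.update(true_ccf=ccf, multiplicity=mult, cn_total=cn, true_vaf=vaf)


def generate_variant_catalog(
    config: SimulationConfig, genome: GenomeModel
) -> VariantSimulation:
    """Simulate per-tumor somatic variant catalogs with audit ground truth.

    Returns a :class:`VariantSimulation` whose ``calls`` frame holds one
    annotated tumor/normal call per row (the pipeline input) and whose
    ``truth`` frame carries the audit fields (signature of origin, true CCF,
    intended filter fate) aligned row-for-row with ``calls``.
    """
    rng = np.random.default_rng([config.seed, 1])
    sigs = np.asarray(config.signatures, dtype=float)
    sigs = sigs / sigs.sum(axis=1, keepdims=True)
    sig_names = list(getattr(config.signatures, "index", range(len(sigs))))
    snvs = config._per_tumor(config.snv_count, int)
    indels = config._per_tumor(config.indel_count, int)
    purities = config._per_tumor(config.purity, float)
    ids = config.tumor_ids()

    # planted recurrent drivers: gene -> tumor indices carrying it
    driver_plan: list[tuple[int, str]] = []
    for gene in config.planted_driver_genes:
        k = min(config.driver_tumors_per_gene, config.n_tumors)
        for ti in rng.choice(config.n_tumors, size=k, replace=False):
            driver_plan.append((int(ti), gene))

    rows, truths = [], []
    for ti, tumor in enumerate(ids):
        purity = purities[ti]
        weights = np.asarray(config.signature_weights)[ti]
        for _ in range(snvs[ti]):
            si = int(rng.choice(len(sigs), p=weights))
            channel = CHANNELS_96[int(rng.choice(96, p=sigs[si]))]
            ccf = float(rng.choice(config.ccf_values, p=config.ccf_weights))
            rec = _base_call(rng, config, genome, tumor, purity)
            effect = str(rng.choice(_EFFECTS, p=_SNV_EFFECT_P))
            sift, pp2, mt = _effect_scores(rng, effect)
            rec.update(effect=effect, sift=sift, pp2=pp2, mt=mt)
            truth = dict(tumor=tumor, signature=sig_names[si], intended_fate="pass")
            _finish_snv(rng, rec, truth, config, purity, ccf, channel)
            rows.append(rec)
            truths.append(truth)
        for _ in range(indels[ti]):
            ccf = float(rng.choice(config.ccf_values, p=config.ccf_weights))
            rec = _base_call(rng, config, genome, tumor, purity)
            vaf = _expected_vaf(purity, ccf, 1, 2)
            base, ins = rng.choice(list("ACGT")), rng.choice(list("ACGT"))
            ref, alt = (base, base + ins) if rng.random() < 0.5 else (base + ins, base)
            effect = "truncating" if rng.random() < 0.6 else "noncoding"
            rec.update(ref=ref, alt=alt, vclass="indel", context="",
                       tumor_alt=int(rng.binomial(rec["tumor_depth"], vaf)),
                       effect=effect, sift=np.nan, pp2=np.nan, mt=np.nan)
            rows.append(rec)
            truths.append(dict(tumor=tumor, signature="", intended_fate="pass",
                               true_ccf=ccf, multiplicity=1, cn_total=2,
                               true_vaf=vaf))
        for pti, gene in driver_plan:
            if pti != ti:
                continue
            channel = CHANNELS_96[int(rng.choice(96, p=sigs[0]))]
            rec = _base_call(rng, config, genome, tumor, purity)
            rec.update(effect="truncating", gene=gene,
                       sift=np.nan, pp2=np.nan, mt=np.nan)
            truth = dict(tumor=tumor, signature="driver", intended_fate="pass")
            _finish_snv(rng, rec, truth, config, purity, 1.0, channel)
            rec["tumor_alt"] = max(rec["tumor_alt"], 3)  # drivers stay callable
            rows.append(rec)
            truths.append(truth)
        for ai in range(config.n_filter_artifacts):
            mode = ARTIFACT_MODES[ai % len(ARTIFACT_MODES)]
            channel = CHANNELS_96[int(rng.choice(96, p=sigs[0]))]
            rec = _base_call(rng, config, genome, tumor, purity)
            rec.update(effect="missense", sift=0.5, pp2=0.5, mt=0.5)
            truth = dict(tumor=tumor, signature="artifact", intended_fate=mode)
            _finish_snv(rng, rec, truth, config, purity, 1.0, channel)
            rec["tumor_alt"] = max(3, min(rec["tumor_alt"], rec["tumor_depth"]))
            if mode == "segdup":
                rec["segdup"] = True
            elif mode == "mapability":
                rec["mapability"] = 0.3
            elif mode == "normal_evidence":
                rec["normal_alt"] = 1
            elif mode == "normal_depth":
                rec["normal_depth"] = 9
            elif mode == "tumor_depth":
                rec["tumor_depth"], rec["tumor_alt"] = 7, 3
            elif mode == "tumor_alt_reads":
                rec["tumor_depth"], rec["tumor_alt"] = 100, 2
            elif mode == "vaf":
                rec["tumor_depth"], rec["tumor_alt"] = 100, 4
            elif mode == "popaf":
                rec["popaf"] = 0.05
            elif mode == "quality":
                rec["qual"] = 15.0
            rows.append(rec)
            truths.append(truth)

    cols = ["tumor", "chrom", "pos", "ref", "alt", "vclass", "tumor_depth",
            "tumor_alt", "normal_depth", "normal_alt", "qual", "mapability",
            "segdup", "popaf", "gene", "effect", "sift", "pp2", "mt", "context"]
    calls = pd.DataFrame(rows, columns=cols)
    truth = pd.DataFrame(truths)
    truth["seed"] = config.seed
    return VariantSimulation(calls=calls, truth=truth, seed=config.seed)


# ---------------------------------------------------------------------------
# segment profiles


def _carve(pieces: list[list], start: int, end: int, state: tuple[int, int]) -> None:
    """Overlay [start, end) with the given (total, minor) state in place."""
    out = []
    for s, e, t, m in pieces:
        if e <= start or s >= end:
            out.append([s, e, t, m])
            continue
        if s < start:
            out.append([s, start, t, m])
        if e > end:
            out.append([end, e, t, m])
    out.append([start, end, state[0], state[1]])
    out.sort()
    pieces[:] = out


def _is_diploid_across(pieces: list[list], start: int, end: int) -> bool:
    return all(t == 2 and m == 1 for s, e, t, m in pieces
               if not (e <= start or s >= end))


def _truth_hrd_loh(pieces: list[list], chrom_len: int,
                   min_size: float = 15e6, subchrom_frac: float = 0.9) -> int:
    """By-construction HRD-LOH bookkeeping on a final piece list."""
    count, run = 0, None
    runs = []
    for s, e, t, m in pieces + [[chrom_len + 1, chrom_len + 2, 2, 1]]:
        if m == 0 and t >= 1:
            run = [s, e] if run is None or s > run[1] else [run[0], e]
            continue
        if run is not None:
            runs.append(run)
            run = None
    for s, e in runs:
        if e - s > min_size and (e - s) < subchrom_frac * chrom_len:
            count += 1
    return count


def _truth_lst(pieces: list[list], smooth_below: float = 3e6,
               min_flank: float = 10e6) -> int:
    """By-construction LST bookkeeping: drop <3 Mb pieces, merge equal
    total-CN states, count breakpoints with both flanks >= 10 Mb."""
    kept = [p for p in pieces if p[1] - p[0] >= smooth_below]
    merged: list[list] = []
    for s, e, t, m in kept:
        if merged and merged[-1][2] == t:
            merged[-1][1] = e
        else:
            merged.append([s, e, t, m])
    return sum(
        1
        for a, b in zip(merged, merged[1:])
        if a[1] - a[0] >= min_flank and b[1] - b[0] >= min_flank
    )


def generate_segment_profile(
    config: SimulationConfig, genome: GenomeModel
) -> SegmentSimulation:
    """Simulate allele-specific copy-number profiles tiling each chromosome.

    Requested large LOH segments and LST breakpoints are realized exactly
    (on disjoint chromosomes), recurrent loci are embedded per tumor with
    the configured penetrance, and uniform background events are overlaid
    on diploid territory only. Per-tumor HRD-LOH/LST/percent-altered ground
    truth is computed from the final piece lists and returned alongside.
    """
    rng = np.random.default_rng([config.seed, 2])
    loh_counts = config._per_tumor(config.loh_segments, int)
    lst_counts = config._per_tumor(config.lst_breakpoints, int)
    bg_counts = config._per_tumor(config.background_events, int)
    ids = config.tumor_ids()
    n_chrom = len(genome.chrom_names)
    margin = 2_000_000

    for locus in config.recurrent_loci:
        if locus.end > genome.length_of(locus.chrom):
            raise ValueError(f"locus {locus} extends beyond its chromosome")

    seg_rows, truth_rows, carrier_rows = [], [], []
    for ti, tumor in enumerate(ids):
        pieces = {c: [[0, genome.chrom_lengths[i], 2, 1]]
                  for i, c in enumerate(genome.chrom_names)}

        # --- LOH plants, chromosomes from the front of the karyotype
        k_loh, size = loh_counts[ti], int(config.loh_size)
        loh_chroms_used = 0
        if k_loh:
            placed = 0
            for ci, chrom in enumerate(genome.chrom_names):
                L = genome.chrom_lengths[ci]
                if size > L:
                    raise ValueError(
                        f"requested LOH segment of {size} bp exceeds {chrom}")
                cap = int((L - margin) // (size + margin))
                take = min(cap, k_loh - placed)
                if take > 0:
                    loh_chroms_used = ci + 1
                for j in range(take):
                    start = margin + j * (size + margin) \
                        + int(rng.integers(0, margin // 2))
                    _carve(pieces[chrom], start, start + size, (2, 0))
                placed += take
                if placed == k_loh:
                    break
            if placed < k_loh:
                raise ValueError("genome too small for requested LOH segments")

        # --- LST plants, chromosomes from the back of the karyotype
        k_lst = lst_counts[ti]
        lst_chroms: set[str] = set()
        ci = n_chrom - 1
        while k_lst > 0:
            if ci < loh_chroms_used:
                raise ValueError("not enough chromosomes for LST plants")
            L = genome.chrom_lengths[ci]
            cap = max(0, L // 11_000_000 - 1)  # pieces of >=11 Mb
            take = min(cap, k_lst)
            if take > 0:
                n_pieces = take + 1
                bounds = np.linspace(0, L, n_pieces + 1).astype(int)
                chrom = genome.chrom_names[ci]
                lst_chroms.add(chrom)
                for j in range(n_pieces):
                    if j % 2 == 1:
                        _carve(pieces[chrom], int(bounds[j]), int(bounds[j + 1]),
                               (3, 1))
                k_lst -= take
            ci -= 1

        # --- recurrent loci at penetrance
        for locus in config.recurrent_loci:
            carrier = bool(rng.random() < locus.penetrance)
            carrier_rows.append(dict(sample=tumor, chrom=locus.chrom,
                                     start=locus.start, end=locus.end,
                                     kind=locus.kind, carrier=carrier))
            if carrier:
                _carve(pieces[locus.chrom], locus.start, locus.end,
                       locus.copy_state)

        # --- uniform background events on still-diploid territory
        for _ in range(bg_counts[ti]):
            for _try in range(50):
                ci2 = int(rng.choice(n_chrom,
                                     p=np.asarray(genome.chrom_lengths, float)
                                     / genome.total_length))
                L = genome.chrom_lengths[ci2]
                length = int(rng.integers(*config.background_length_range))
                if length >= L:
                    continue
                chrom = genome.chrom_names[ci2]
                if chrom in lst_chroms:  # keep planted LST flanks intact
                    continue
                start = int(rng.integers(0, L - length))
                if _is_diploid_across(pieces[chrom], start, start + length):
                    state = (3, 1) if rng.random() < 0.5 else (1, 0)
                    _carve(pieces[chrom], start, start + length, state)
                    break

        hrd = lst = 0
        altered = 0
        for i, chrom in enumerate(genome.chrom_names):
            plist = pieces[chrom]
            hrd += _truth_hrd_loh(plist, genome.chrom_lengths[i])
            lst += _truth_lst(plist)
            for s, e, t, m in plist:
                if (t, m) != (2, 1):
                    altered += e - s
                seg_rows.append(dict(
                    sample=tumor, chrom=chrom, start=s, end=e,
                    num_probes=max(1, int((e - s) * genome.probe_density)),
                    total_cn=t, minor_cn=m))
        truth_rows.append(dict(sample=tumor, hrd_loh=hrd, lst=lst,
                               pct_altered=100.0 * altered / genome.total_length,
                               seed=config.seed))

    return SegmentSimulation(
        segments=pd.DataFrame(seg_rows),
        truth=pd.DataFrame(truth_rows),
        locus_carriers=pd.DataFrame(
            carrier_rows,
            columns=["sample", "chrom", "start", "end", "kind", "carrier"]),
        seed=config.seed,
    )
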