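"""Reference genome models: karyotype, probe density and exome 3-mer background.

A :class:`GenomeModel` carries everything downstream stages need to know about
the reference: chromosome names and lengths, an (optional) SNP-array probe
density, and the 96-channel trinucleotide frequency table of the captured
exome used to normalize mutation spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contexts import CHANNELS_96


@dataclass(frozen=True)
class GenomeModel:
    """Karyotype plus exome trinucleotide background.

    Parameters
    ----------
    chrom_names : tuple of str
        Chromosome names, in karyotype order.
    chrom_lengths : tuple of int
        Chromosome lengths in bp; strictly positive.
    trinuc_freqs : ndarray of shape (96,)
        Relative frequency of the reference 3-mer context of each of the 96
        channels in the captured exome; strictly positive, summing to 1.
    probe_density : float
        Array probes per bp (CytoScanHD-like arrays are roughly one probe
        per kb genome-wide).
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    trinuc_freqs: np.ndarray = field(repr=False)
    probe_density: float = 1e-3

    def __post_init__(self) -> None:
        if len(self.chrom_names) == 0:
            raise ValueError("genome must have at least one chromosome")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chromosome names and lengths differ in number")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be > 0")
        freqs = np.asarray(self.trinuc_freqs, dtype=float)
        if freqs.shape != (96,):
            raise ValueError("trinuc_freqs must have shape (96,)")
        if not (freqs > 0).all():
            raise ValueError("trinucleotide frequencies must be strictly positive")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("trinucleotide frequencies must sum to 1 within 1e-9")
        object.__setattr__(self, "trinuc_freqs", freqs)
        if self.probe_density <= 0:
            raise ValueError("probe density must be > 0")

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome: {chrom!r}") from None


def _exome_trinuc_background() -> np.ndarray:
    """Deterministic, non-uniform stand-in for an exome 3-mer frequency table.

    Synthetic: shaped to resemble a capture design in which NpCpG contexts
    are depleted and GC-flanked contexts enriched, but not derived from any
    real bait set.
    """
    weights = np.empty(96)
    for i, ch in enumerate(CHANNELS_96):
        five, three, ref = ch[0], ch[6], ch[2]
        w = 1.0
        w *= 1.4 if five in "GC" else 0.8
        w *= 1.3 if three in "GC" else 0.9
        if ref == "C" and three == "G":  # CpG depletion
            w *= 0.45
        weights[i] = w
    return weights / weights.sum()


def toy_genome(probe_density: float = 1e-3) -> GenomeModel:
    """Reduced 5-chromosome karyotype (50-250 Mb) for desk-scale runs."""
    return GenomeModel(
        chrom_names=("chr1", "chr2", "chr3", "chr4", "chr5"),
        chrom_lengths=(250_000_000, 200_000_000, 150_000_000, 100_000_000, 50_000_000),
        trinuc_freqs=_exome_trinuc_background(),
        probe_density=probe_density,
    )


#: rounded GRCh37 chromosome lengths (Mb precision is ample for simulation)
_GRCH37_MB = {
    "chr1": 249, "chr2": 243, "chr3": 198, "chr4": 191, "chr5": 181,
    "chr6": 171, "chr7": 159, "chr8": 146, "chr9": 141, "chr10": 136,
    "chr11": 135, "chr12": 134, "chr13": 115, "chr14": 107, "chr15": 103,
    "chr16": 90, "chr17": 81, "chr18": 78, "chr19": 59, "chr20": 63,
    "chr21": 48, "chr22": 51, "chrX": 155, "chrY": 59,
}


def grch37_like_genome(probe_density: float = 1e-3) -> GenomeModel:
    """24-chromosome model with GRCh37-like lengths (rounded to 1 Mb)."""
    return GenomeModel(
        chrom_names=tuple(_GRCH37_MB),
        chrom_lengths=tuple(mb * 1_000_000 for mb in _GRCH37_MB.values()),
        trinuc_freqs=_exome_trinuc_background(),
        probe_density=probe_density,
    )
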