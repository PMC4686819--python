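"""Trinucleotide substitution-context conventions.

All single-base substitutions are pyrimidine-normalized: a mutation whose
reference base is a purine (A or G) is reported on the reverse-complement
strand, so every SNV falls into one of six classes (C>A, C>G, C>T, T>A,
T>C, T>G) and, with its 5' and 3' flanking bases, into one of 96 canonical
channels written ``5'[ref>alt]3'`` (e.g. ``A[C>T]G``).
"""

from __future__ import annotations

import itertools

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the six pyrimidine-normalized substitution classes, in conventional order
SUB_CLASSES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: the 96 canonical channels: class-major, then 5' flank, then 3' flank
CHANNELS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUB_CLASSES
    for five, three in itertools.product("ACGT", "ACGT")
)

CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}

#: substitution class of each of the 96 channels (for 6-class marginals)
CHANNEL_CLASS = tuple(c[2:5] for c in CHANNELS_96)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase ACGT only)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def normalize_snv(ref: str, alt: str, five: str, three: str) -> str:
    """Return the canonical channel for a substitution with flanking bases.

    Purine-reference calls are reverse-complemented onto the pyrimidine
    strand, which also swaps and complements the flanks.

    >>> normalize_snv("G", "A", "C", "T")   # reverse strand of A[C>T]G
    'A[C>T]G'
    """
    ref, alt, five, three = ref.upper(), alt.upper(), five.upper(), three.upper()
    if ref in "AG":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        five, three = COMPLEMENT[three], COMPLEMENT[five]
    channel = f"{five}[{ref}>{alt}]{three}"
    if channel not in CHANNEL_INDEX:
        raise ValueError(f"not a canonical substitution context: {channel!r}")
    return channel


def channel_parts(channel: str) -> tuple[str, str, str, str]:
    """Split ``'A[C>T]G'`` into (ref, alt, 5' flank, 3' flank)."""
    if channel not in CHANNEL_INDEX:
        raise ValueError(f"malformed context string: {channel!r}")
    return channel[2], channel[4], channel[0], channel[6]


def is_transition(ref: str, alt: str) -> bool:
    """True for purine<->purine or pyrimidine<->pyrimidine substitutions."""
    return {ref.upper(), alt.upper()} in ({"A", "G"}, {"C", "T"})
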