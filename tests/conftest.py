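import numpy as np
import pandas as pd
import pytest

from brcaness.genome import toy_genome


@pytest.fixture(scope="session")
def genome():
    return toy_genome()


#: copy states a SNP-array profile plausibly emits: (total, minor)
COPY_STATES = [(0, 0), (1, 0), (2, 0), (2, 1), (3, 0), (3, 1), (4, 1),
               (4, 2), (5, 1), (5, 2)]


def random_profile(rng: np.random.Generator, sample: str = "S1") -> tuple:
    """A random segment tiling of 1-3 chromosomes with random copy states.

    Returns (segments DataFrame, {chrom: length}) for brute-force oracle
    comparisons.
    """
    n_chrom = int(rng.integers(1, 4))
    rows, lengths = [], {}
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        length = int(rng.integers(60, 220)) * 1_000_000
        lengths[chrom] = length
        n_breaks = int(rng.integers(0, 13))
        bounds = np.sort(rng.integers(1, length, size=n_breaks))
        bounds = np.unique(np.concatenate([[0], bounds, [length]]))
        for s, e in zip(bounds[:-1], bounds[1:]):
            total, minor = COPY_STATES[rng.integers(len(COPY_STATES))]
            rows.append(dict(sample=sample, chrom=chrom, start=int(s),
                             end=int(e), num_probes=max(1, (e - s) // 1000),
                             total_cn=total, minor_cn=minor))
    return pd.DataFrame(rows), lengths
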