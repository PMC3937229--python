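import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cis_select.core import GenomeModel, coerce_cohort, toy_genome


@pytest.fixture
def toy_100mb() -> GenomeModel:
    return toy_genome(n_chroms=1, length=100_000_000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_cohort(rows) -> pd.DataFrame:
    """rows: (chrom, pos, strand, sample_id, reads) or full 6-tuples."""
    full = [r if len(r) == 6 else (r[0], r[1], r[2], r[3], "", r[4]) for r in rows]
    return coerce_cohort(
        pd.DataFrame(full, columns=["chrom", "pos", "strand", "sample_id", "genotype", "reads"])
    )


@pytest.fixture
def small_cohort() -> pd.DataFrame:
    return make_cohort(
        [
            ("chr1", 100, "+", "T1", 10),
            ("chr1", 250, "-", "T1", 5),
            ("chr1", 5_000, "+", "T2", 120),
            ("chr2", 700, "-", "T2", 1),
            ("chr2", 800, "+", "T3", 99),
        ]
    )
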