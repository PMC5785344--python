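import numpy as np
import pandas as pd
import pytest

from bsamap.genome import Chromosome, GenomeModel


@pytest.fixture
def small_genome() -> GenomeModel:
    """Two short chromosomes with a handful of founder sites."""
    chroms = [Chromosome("chrA", 10_000_000, 100.0),
              Chromosome("chrB", 5_000_000, 50.0)]
    sites = pd.DataFrame({
        "chrom": ["chrA"] * 5 + ["chrB"] * 3,
        "pos": [1_000_000, 3_000_000, 5_000_000, 7_000_000, 9_000_000,
                1_000_000, 2_500_000, 4_000_000],
        "donor": list("AATGC") + list("TAG"),
        "recurrent": list("GCCAA") + list("CGT"),
    })
    return GenomeModel(chroms, sites)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
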