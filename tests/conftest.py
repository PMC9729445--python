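import numpy as np
import pandas as pd
import pytest

from hybridzone import synthetic_data as synth
from hybridzone.genotype_io import GenotypeMatrix, SampleTable


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset shared by read-only tests."""
    cfg = synth.SimConfig(
        seed=11,
        n_loci=300,
        chrom_plan=[("1", 120), ("2", 100), ("Z", 80)],
        divergence=0.6,
        missing_rate=0.05,
    )
    return synth.simulate_hybrid_zone(cfg)


@pytest.fixture()
def tiny_gm():
    """Hand-written 4 individuals x 5 loci matrix (1 missing call)."""
    values = np.array(
        [
            [0, 1, 2, 0, 1],
            [0, 1, 2, 1, -1],
            [2, 1, 0, 0, 0],
            [2, 0, 0, 0, 0],
        ],
        dtype=np.int8,
    )
    meta = pd.DataFrame(
        {
            "chrom": ["1", "1", "1", "2", "2"],
            "pos": [100, 200, 300, 100, 250],
            "rad_locus": ["L0", "L0", "L1", "L2", "L3"],
        }
    )
    return GenotypeMatrix(values=values, individuals=["a", "b", "c", "d"], locus_meta=meta)


@pytest.fixture()
def tiny_samples():
    return SampleTable(
        pd.DataFrame(
            {
                "individual": ["a", "b", "c", "d"],
                "site": ["s1", "s1", "s2", "s2"],
                "lon": [-94.1, -94.1, -93.9, -93.9],
                "lat": [38.1, 38.1, 38.3, 38.3],
                "period": ["historical", "modern", "historical", "modern"],
                "panel": ["", "", "", ""],
            }
        )
    )
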