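import numpy as np
import pandas as pd
import pytest

from invabc.genotype_io import GenotypeMatrix, LocusDef
from invabc.synthetic_data import make_toy_fixtures


def build_matrix(pop_calls, loci=None):
    """Helper: {pop: [[(a1,a2) per locus] per individual]} -> GenotypeMatrix."""
    first = next(iter(pop_calls.values()))
    n_loci = len(first[0])
    if loci is None:
        loci = [LocusDef(f"L{j + 1}", 3 if j else 2, "FAM") for j in range(n_loci)]
    ids, pops, rows = [], [], []
    for pop, individuals in pop_calls.items():
        for i, genotypes in enumerate(individuals):
            ids.append(f"{pop}_{i:02d}")
            pops.append(pop)
            rows.append([list(c) for c in genotypes])
    meta = pd.DataFrame({"id": ids, "population": pops, "year": 2015})
    return GenotypeMatrix(meta, loci, np.array(rows, dtype=np.int32))


@pytest.fixture(scope="session")
def toy_fixtures():
    return make_toy_fixtures()


@pytest.fixture
def two_pop_toy():
    """The 2-pop, 1-locus worked example: A {100:18, 102:2}, B {100:6, 102:14}."""
    A = [[(100, 100)]] * 8 + [[(100, 102)]] * 2
    B = [[(100, 100)]] * 2 + [[(100, 102)]] * 2 + [[(102, 102)]] * 6
    return build_matrix({"A": A, "B": B}, loci=[LocusDef("L1", 2, "FAM")])
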