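import numpy as np
import pytest

from ssrpop.io import Accession, GenotypeTable, LocusDef
from ssrpop.simulate import SimConfig, simulate_collection


def make_table(calls, ids=None, loci=None, **acc_kwargs):
    """Hand-build a GenotypeTable from a list of per-accession call lists."""
    n_loci = len(calls[0])
    ids = ids or [f"A{i:03d}" for i in range(len(calls))]
    loci = loci or [f"L{l + 1:02d}" for l in range(n_loci)]
    return GenotypeTable(
        loci=[LocusDef(l) for l in loci],
        accessions=[Accession(i) for i in ids],
        calls=[[tuple(sorted(c)) for c in row] for row in calls],
    )


@pytest.fixture(scope="session")
def collection():
    """Mid-size simulated collection with clones, triploids and trios."""
    cfg = SimConfig(n_per_group=40, n_groups=3, drift_f=0.05,
                    n_clone_groups=5, triploid_fraction=0.08, n_trios=8,
                    missing_rate=0.01, seed=20)
    table, truth = simulate_collection(cfg)
    return cfg, table, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
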