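import numpy as np
import pytest

from ssrkit.genotype_io import AccessionRecord, AlleleCall, GenotypeTable
from ssrkit.simulate import SimulationConfig, simulate_collection


def make_table(profiles, loci=None, records=None):
    """Build a GenotypeTable from {acc_id: {locus: iterable of sizes}}."""
    if loci is None:
        loci = sorted({l for p in profiles.values() for l in p})
    if records is None:
        records = {
            acc: AccessionRecord(acc, name=acc) for acc in profiles
        }
    calls = {}
    for acc, prof in profiles.items():
        for locus in loci:
            sizes = prof.get(locus)
            calls[(acc, locus)] = AlleleCall(
                locus, frozenset(sizes) if sizes else frozenset()
            )
    return GenotypeTable(
        [records[a] for a in profiles], loci, calls
    )


@pytest.fixture(scope="session")
def hwe_population():
    """One panmictic diploid population, no error, for null checks."""
    cfg = SimulationConfig(
        seed=11, n_loci=12, n_subpops=1, fst_target=0.0,
        n_founders=200, triploid_fraction=0.0,
    )
    table, _, manifest = simulate_collection(cfg)
    return table, manifest


@pytest.fixture(scope="session")
def structured_collection():
    """Two well-separated subpopulations (F_ST 0.3)."""
    cfg = SimulationConfig(
        seed=7, n_loci=15, n_subpops=2, fst_target=0.3,
        n_founders=50, triploid_fraction=0.0,
    )
    table, _, manifest = simulate_collection(cfg)
    return table, manifest


@pytest.fixture(scope="session")
def mixed_collection():
    """Study-like collection: clones, triploids, offspring, 19 loci."""
    cfg = SimulationConfig(
        seed=13, n_loci=19, n_subpops=2, fst_target=0.1,
        n_founders=40, n_clone_groups=3, clone_copies=3,
        triploid_fraction=0.2, n_offspring=8,
    )
    table, _, manifest = simulate_collection(cfg)
    return table, manifest


def rng_of(seed):
    return np.random.default_rng(seed)
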