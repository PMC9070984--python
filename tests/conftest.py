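import pytest

from phagewo.core_io import RunConfig
from phagewo.synthetic_data import SimConfig, simulate
from phagewo.typing import cluster_types, distance_matrix, flag_pseudogenes


@pytest.fixture(scope="session")
def seed1_dataset():
    """Default synthetic dataset at seed 1 with its planted truth."""
    return simulate(SimConfig(rng_seed=1))


@pytest.fixture(scope="session")
def seed1_typed(seed1_dataset):
    """Seed-1 dataset carried through pseudogene filtering and typing."""
    aln, truth = seed1_dataset
    func = flag_pseudogenes(aln).functional()
    cfg = RunConfig(rng_seed=1)
    dm = distance_matrix(func)
    local = cluster_types(dm, func, cfg, scope="per_species")
    glob = cluster_types(dm, func, cfg, scope="global")
    return {
        "aln": aln,
        "truth": truth,
        "functional": func,
        "cfg": cfg,
        "dm": dm,
        "local_types": local,
        "global_types": glob,
    }


@pytest.fixture()
def fast_cfg():
    """Config with light permutation counts for statistic-only checks."""
    return RunConfig(n_perm=20, bootscan_reps=30, bootscan_n_perm=10, rng_seed=7)
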