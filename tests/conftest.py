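from __future__ import annotations

import numpy as np
import pytest

import repeatphylo as rp
from repeatphylo.experiments import regime_replicates

QUARTET = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def quartet_tree():
    return rp.read_newick(QUARTET)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_seq(rng, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def mutate(seq: str, n_subs: int, rng) -> str:
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_subs, replace=False):
        out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
    return "".join(out)


@pytest.fixture
def toy_libraries(rng):
    """Three tiny species libraries: one shared family, one A-specific."""
    fam1 = random_seq(rng, 200)
    fam2 = random_seq(rng, 180)
    libs = []
    for sp in ("A", "B", "C"):
        contigs = [
            rp.RepeatContig("shared", sp, mutate(fam1, 4, rng), abundance=0.02)
        ]
        if sp == "A":
            contigs.append(rp.RepeatContig("own", sp, fam2, abundance=0.01))
        libs.append(rp.RepeatLibrary(species=sp, contigs=contigs))
    return libs


# -- session-scoped replicate caches shared by the acceptance tests -------

N_REGIME_REPS = 100
N_HT_REPS = 50


@pytest.fixture(scope="session")
def young_runs():
    return regime_replicates("young_flock", N_REGIME_REPS, base_seed=0)


@pytest.fixture(scope="session")
def ancient_runs():
    return regime_replicates("ancient_flock", N_REGIME_REPS, base_seed=0)


@pytest.fixture(scope="session")
def ht_runs():
    return regime_replicates("young_flock", N_HT_REPS, base_seed=1000, ht_rate=0.08)
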