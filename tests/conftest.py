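import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def random_residues(rng: np.random.Generator, length: int, p=(0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(rng.choice(list("ACGT"), size=length, p=list(p)))


@pytest.fixture
def rng():
    return np.random.default_rng(20180702)


@pytest.fixture
def small_genome():
    from mtg4 import synthetic as syn

    cfg = syn.SimConfig(
        rng_seed=11, genome_length=3000, n_planted_g4=5, motif_spacing=450,
        at_fraction=0.62, gc_skew=-0.2,
    )
    genome, truth = syn.make_genome(cfg)
    return cfg, genome, truth
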