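import numpy as np
import pytest

from vatkit import simcluster as sc

LINKED = {("e2L", "e2R")}


@pytest.fixture(scope="session")
def clean_config():
    """Structural evolution only: duplication + crossover, no noise."""
    return sc.SimConfig(
        seed=7, n_accessions=6, sub_rate=0.0,
        te_insertion_rate=0.0, stop_gain_rate=0.0,
    )


@pytest.fixture(scope="session")
def clean_panel(clean_config):
    anc, regions, truth = sc.simulate_panel(clean_config)
    return anc, regions, truth


@pytest.fixture(scope="session")
def noisy_panel():
    cfg = sc.SimConfig(seed=13, n_accessions=8)
    anc, regions, truth = sc.simulate_panel(cfg)
    return cfg, anc, regions, truth


def mutate_seq(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[("ACGT".index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)
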