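from __future__ import annotations

import numpy as np
import pytest

from evescout import synthetic


@pytest.fixture(scope="session")
def small_planted():
    """A small host genome with one planted element per clade, noiseless hits."""
    genome = synthetic.generate_host(
        synthetic.HostGenomeSpec(8, (40_000, 60_000), 0.51, seed=11))
    plants = [
        synthetic.PlantSpec("PLVB", 23_000, -10.0, tir_len=300),
        synthetic.PlantSpec("PLVA", 25_000, -10.0, tir_len=300),
        synthetic.PlantSpec("PLV2", 15_000, -10.0, tir_len=200),
        synthetic.PlantSpec("NCLDV", 30_000, -10.0),
        synthetic.PlantSpec("CHeCME", 18_000, -8.0),
    ]
    genome, truth = synthetic.plant_elements(genome, plants, seed=12,
                                             min_flank=6000, base_gc=0.51)
    lengths = {name: len(s) for name, s in genome.items()}
    hits = synthetic.simulate_marker_hits(truth, lengths, seed=13)
    return genome, truth, hits


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])
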