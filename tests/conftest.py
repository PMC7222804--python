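from __future__ import annotations

import numpy as np
import pytest

from mtcpg.seqio import GenomeRecord
from mtcpg.synthetic import IslandSpec, SynthSpec, generate_genome


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20200411)


@pytest.fixture()
def fasta_file(tmp_path):
    def make(seq: str, name: str = "chrM", fname: str = "genome.fa"):
        p = tmp_path / fname
        p.write_text(f">{name}\n{seq}\n")
        return p
    return make


# one planted island well inside the detectable regime (see docs/methods.md)
PLANT = dict(length=600, gc=0.62, obs_exp=1.4)


@pytest.fixture(scope="session")
def planted_genome():
    spec = SynthSpec(length=16500, seed=7, islands=(
        IslandSpec(position=3001, **PLANT),
        IslandSpec(position=9001, **PLANT),
    ))
    genome, truth = generate_genome(spec)
    return spec, genome, truth


def make_planted(seed: int, positions=(3001, 9001)) -> tuple:
    spec = SynthSpec(length=16500, seed=seed, islands=tuple(
        IslandSpec(position=p, **PLANT) for p in positions))
    return generate_genome(spec)


@pytest.fixture()
def tiny_genome() -> GenomeRecord:
    return GenomeRecord("tiny", "A" * 20 + "CGCG" + "A" * 20)
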