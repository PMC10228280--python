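import numpy as np
import pytest

from isocoupler import simulate
from isocoupler.core import Config


@pytest.fixture(scope="session")
def cfg() -> Config:
    return Config()


@pytest.fixture(scope="session")
def small_world(cfg):
    """Six genes (alternating strands), clean reads, genome with planted
    signals. Session-scoped: tests must not mutate it."""
    spec = simulate.preset_spec("dominant", expression=120)
    models, tss, pas, truth, genome = simulate.simulate_gene_models(
        6, spec, cfg, seed=11
    )
    reads, polya, frame = simulate.simulate_reads(truth, cfg, seed=12)
    return dict(
        models=models, tss=tss, pas=pas, truth=truth, genome=genome,
        reads=reads, polya=polya, frame=frame,
    )


@pytest.fixture(scope="session")
def artifact_world(cfg):
    """Four genes with truncation, internal priming and tail loss."""
    spec = simulate.preset_spec("dominant", expression=150)
    models, tss, pas, truth, genome = simulate.simulate_gene_models(
        4, spec, cfg, seed=21
    )
    reads, polya, frame = simulate.simulate_reads(
        truth, cfg, seed=22,
        p_truncate_5p=0.15, p_internal_prime=0.2, p_tailless=0.1,
    )
    return dict(
        models=models, tss=tss, pas=pas, truth=truth, genome=genome,
        reads=reads, polya=polya, frame=frame,
    )
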