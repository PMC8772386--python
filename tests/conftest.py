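import numpy as np
import pytest

from gaplm import (
    FlankPair,
    ModelConfig,
    NucleotideSequence,
    SimulationConfig,
    build_model,
    make_gap_case,
)


@pytest.fixture(scope="session")
def easy_case():
    """Error-free, well-covered simulated gap reused across tests."""
    cfg = SimulationConfig(
        region_length=1800,
        gap_length=50,
        flank_length=250,
        read_length=100,
        fragment_mean=300,
        fragment_sd=30.0,
        coverage_depth=60.0,
        substitution_error_rate=0.0,
        seed=11,
    )
    return make_gap_case(cfg)


@pytest.fixture
def tiny_model():
    """Small untrained model for structural tests."""
    return build_model(ModelConfig(embedding_dim=8, recurrent_units=12), seed=0)


@pytest.fixture
def uniform_model(tiny_model):
    """Model whose output layer is zeroed: always predicts (¼, ¼, ¼, ¼)."""
    tiny_model.params["Wy"][:] = 0.0
    tiny_model.params["by"][:] = 0.0
    return tiny_model


@pytest.fixture
def small_flanks():
    rng = np.random.default_rng(3)
    bases = lambda n: "".join(rng.choice(list("ACGT"), size=n))
    return FlankPair(
        "g1",
        NucleotideSequence("g1_left", bases(100)),
        NucleotideSequence("g1_right", bases(100)),
    )


def random_sequence(rng, n, id="s"):
    return NucleotideSequence(id, "".join(rng.choice(list("ACGT"), size=n)))
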