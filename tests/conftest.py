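import numpy as np
import pytest

from nacscan.motifs import WeightScheme, build_all_default, build_nacbs
from nacscan.simulate import SimConfig


@pytest.fixture(scope="session")
def default_models():
    return build_all_default()


@pytest.fixture(scope="session")
def nacbs8(default_models):
    return next(m for m in default_models if m.name == "NACBS-8")


@pytest.fixture(scope="session")
def sharp_nacbs8():
    """Near-deterministic instance model used for planting."""
    return build_nacbs("NACBS-8", WeightScheme(core_prob=0.995, minor_prob=0.99))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_sim_config():
    """Scaled-down study for pipeline smoke tests."""
    return SimConfig(
        n_promoters=250,
        up_size=40,
        down_size=40,
        n_genes=120,
        coexpr_n_genes=150,
        coexpr_set_size=25,
        seed=7,
    )


def random_motif(rng, length, name="rand"):
    """A random letter-probability model (test helper)."""
    from nacscan.motifs import MotifModel

    probs = rng.dirichlet(np.ones(4) * 0.8, size=length)
    probs = np.maximum(probs, 1e-3)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return MotifModel(name=name, consensus="n" * length, probs=probs)
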