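import numpy as np
import pytest

from evosoc.dynamics import ScenarioConfig
from evosoc.network import InterSocietySpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_config(**kw) -> ScenarioConfig:
    """ScenarioConfig with a small default society; fields overridable."""
    spec_keys = {f for f in ("n_o", "p_c_oo", "n_d", "n_i", "p_c_od", "p_c_do", "p_c_dd", "p_c_ii")}
    spec_kwargs = {k: kw.pop(k) for k in list(kw) if k in spec_keys}
    spec_kwargs.setdefault("n_o", 6)
    spec_kwargs.setdefault("p_c_oo", 0.5)
    kw.setdefault("a_over_b", 100.0)
    return ScenarioConfig(society=InterSocietySpec(**spec_kwargs), **kw)


def random_irreducible(n: int, p: float, seed: int) -> np.ndarray:
    """Small random irreducible binary matrix (rejection sampling)."""
    from evosoc.network import generate_support_matrix

    return generate_support_matrix(n, p, np.random.default_rng(seed)).C
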