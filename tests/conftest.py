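import numpy as np
import pytest

from aggkin import (
    ArrheniusParam,
    Condition,
    ParameterSet,
    build_scheme,
    preset_truth,
)


@pytest.fixture(scope="session")
def scheme():
    return build_scheme(4)


@pytest.fixture(scope="session")
def scheme3():
    return build_scheme(3)


@pytest.fixture(scope="session")
def mab1():
    return preset_truth("mab1like")


@pytest.fixture(scope="session")
def cond50():
    return Condition(40.0, 50.0)


@pytest.fixture()
def perturb_params():
    """Deterministic x3 / /3 perturbation of a truth parameter set,
    alternating direction per reaction (the standard distant start)."""

    def _perturb(params: ParameterSet, fk: float = 3.0, fe: float = 1.25):
        out = ParameterSet()
        for j, (lbl, p) in enumerate(params.items()):
            out[lbl] = ArrheniusParam(
                p.k_ref * (fk if j % 2 == 0 else 1.0 / fk),
                p.E_a * (fe if j % 2 else 1.0 / fe),
            )
        return out

    return _perturb


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
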