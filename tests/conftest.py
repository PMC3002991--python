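import numpy as np
import pytest

from rhodeact.scheme import DynamicsPreset, build_scheme


@pytest.fixture(scope="session")
def wt_slow():
    return build_scheme(6, "slow")


@pytest.fixture(scope="session")
def wt_fast():
    return build_scheme(6, "fast")


@pytest.fixture(scope="session")
def p3_slow():
    return build_scheme(3, "slow")


@pytest.fixture(scope="session")
def arrko_slow():
    return build_scheme(6, "slow", arrestin_ko=True)


@pytest.fixture(scope="session")
def toy_two_state():
    """One phosphorylation site, lam1 = 1/s, mu2 = 1/s: P1(t) = exp(-t)."""
    preset = DynamicsPreset("toy", omega=1.0, mu_max=1.0, nu1=1.0, k_nu=0.5,
                            tau_R_target=float("nan"))
    return build_scheme(1, preset, mu_threshold=1, label="toy")


@pytest.fixture(scope="session")
def grid_3s():
    return np.arange(0.0, 3.0 + 1e-12, 1e-3)
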