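import numpy as np
import pytest

import genestab as gs


@pytest.fixture
def fly_params() -> gs.ModelParams:
    """Default fly-like unstable network: Lambda=0.1/day, M0~0.005/day."""
    return gs.ModelParams()


@pytest.fixture
def stable_params() -> gs.ModelParams:
    """Same network with the coupling reduced below the separatrix."""
    return gs.ModelParams(beta=0.001)


@pytest.fixture
def fly_gp() -> gs.GompertzParams:
    """Fly-like demographic pair (gamma = 0.05)."""
    return gs.GompertzParams(M0=0.005, Lambda=0.1)


def draw_params(rng: np.random.Generator, zero_prob: float = 0.05) -> gs.ModelParams:
    """Random valid parameter set spanning both stability regimes."""

    def rate() -> float:
        return float(10.0 ** rng.uniform(-2, 1))

    beta, p, K, c, delta = rate(), rate(), rate(), rate(), rate()
    if rng.uniform() < zero_prob:
        K = 0.0
    G = float(rng.integers(1, 2000))
    return gs.ModelParams(
        beta=beta, p=p, G=G, K=K, c=c, delta=delta,
        f_p=rate() * 0.01, f_g=rate() * 1e-5, omega=rate(),
    )


def params_with_rates(Lambda: float, c: float = 3.0, delta: float = 2.0,
                      G: float = 1000.0, **kw) -> gs.ModelParams:
    """Parameter set with a prescribed near-separatrix rate Lambda.

    Solves beta*p*K*G = c*delta + Lambda*(c+delta) with p = K = 1.
    """
    loop = c * delta + Lambda * (c + delta)
    if loop <= 0:
        raise ValueError("requested Lambda is too negative for these repair rates")
    return gs.ModelParams(beta=loop / G, p=1.0, G=G, K=1.0, c=c, delta=delta, **kw)
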