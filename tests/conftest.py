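import numpy as np
import pytest

import neurophonon as nv


@pytest.fixture(scope="session")
def activated():
    return nv.preset("activated")


@pytest.fixture(scope="session")
def suppressed():
    return nv.preset("suppressed")


@pytest.fixture(scope="session")
def exploratory():
    return nv.preset("exploratory")


@pytest.fixture(scope="session")
def activated_long_run():
    """60 s single-channel activated simulation at full rate (seed 11)."""
    model, rec = nv.make_fixture("activated", 1, 0.0, seed=11, duration=60.0)
    return model, rec


@pytest.fixture(scope="session")
def small_network_recording():
    """4-channel coupled activated network, 10 s, decimated to 256 Hz."""
    model, rec = nv.make_fixture(
        "activated", 4, 0.5, seed=42, duration=10.0, decimate_to=256.0
    )
    return model, rec


def hetero_model(n=3, seed=0, coupling=0.3):
    """Small heterogeneous stable network used across phonon/spectra tests."""
    rng = np.random.default_rng(seed)
    osc = tuple(
        nv.OscillatorParams(
            lambda_=float(rng.uniform(1.0, 3.0)),
            zeta=float(rng.uniform(0.5, 2.0)),
            chi=float(rng.uniform(0.0, 1.0)),
            omega=2 * np.pi * float(rng.uniform(8.0, 12.0)),
            D=float(rng.uniform(0.005, 0.02)),
        )
        for _ in range(n)
    )
    K = np.zeros((n, n), dtype=complex)
    for j in range(n):
        k = (j + 1) % n
        if k != j:
            K[j, k] = K[k, j] = coupling * (1 + 0.3j)
    return nv.NetworkModel(osc, K)
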