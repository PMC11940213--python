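import numpy as np
import pytest

from drg_t2map import EchoTrainParams, PhantomSpec, B1FieldSpec, generate_phantom


@pytest.fixture(scope="session")
def params() -> EchoTrainParams:
    return EchoTrainParams()


@pytest.fixture(scope="session")
def echo_times(params) -> np.ndarray:
    return params.echo_times_ms


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noiseless phantom with uniform B1 = 1 and known truth, shared per session."""
    spec = PhantomSpec(snr=float("inf"), b1_field=B1FieldSpec(constant=1.0), seed=11)
    vol, mask, truth = generate_phantom(spec)
    return spec, vol, mask, truth


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default phantom (smooth B1, Rician noise at SNR 50), shared per session."""
    spec = PhantomSpec(seed=7)
    vol, mask, truth = generate_phantom(spec)
    return spec, vol, mask, truth
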