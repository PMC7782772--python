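import numpy as np
import pytest

import chirplift as cl


@pytest.fixture(scope="session")
def linear_spec() -> cl.ChirpSpec:
    return cl.ChirpSpec(kind="linear")


@pytest.fixture(scope="session")
def linear_signal(linear_spec) -> cl.SoundSignal:
    return cl.make_chirp(linear_spec)


@pytest.fixture(scope="session")
def linear_tf(linear_signal) -> cl.TFImage:
    return cl.stft(linear_signal)


@pytest.fixture(scope="session")
def tone_signal() -> cl.SoundSignal:
    return cl.make_chirp(cl.ChirpSpec(kind="linear", f0=1000.0, slope=0.0, duration=1.0))


def kernel_quadrature(params: cl.KernelParams, n: int = 120) -> float:
    """Gauss-Legendre integral of the kernel over +-8 sigma (normalisation oracle)."""
    mean, cov = cl.kernel_mean_cov(params, (0.0, 0.0))
    so, sn = np.sqrt(np.diag(cov))
    x, w = np.polynomial.legendre.leggauss(n)
    om = mean[0] + 8.0 * so * x
    nu = mean[1] + 8.0 * sn * x
    vals = cl.kernel_value(om[:, None], nu[None, :], 0.0, 0.0, params)
    return float(8.0 * so * 8.0 * sn * w @ vals @ w)
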