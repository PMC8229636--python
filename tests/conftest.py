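import numpy as np
import pytest

import censgeom as cg


@pytest.fixture(scope="session")
def rayleigh():
    return cg.get_model("rayleigh")


@pytest.fixture(scope="session")
def exponential():
    return cg.get_model("exponential")


@pytest.fixture(scope="session")
def gamma_model():
    return cg.get_model("gamma")


@pytest.fixture(scope="session")
def table2():
    """Insulating-fluid breakdown sample (n=19, m=8)."""
    return cg.table2_fixture()


@pytest.fixture(scope="session")
def table2_scheme(table2):
    return table2.scheme


def make_sample_with_stat(m: int, n: int, S: float) -> "cg.ProgressiveSample":
    """Conventional Type-II scheme sample engineered so that the Rayleigh
    sufficient statistic sum (1+R_r) x_r^2 equals S exactly (hence lam_hat = m/S)."""
    scheme = cg.named_scheme(n, m, "R1")
    w = 1.0 + np.asarray(scheme.R)
    base = S / w.sum()
    x = np.sqrt(base * np.ones(m))
    x = np.sort(x + np.linspace(0.0, 1e-9, m))
    samp = cg.ProgressiveSample(scheme, x)
    # the 1e-9 jitter used to break ties perturbs S at ~1e-9 relative; rescale
    actual = float(np.sum(w * samp.x**2))
    return cg.ProgressiveSample(scheme, samp.x * np.sqrt(S / actual))
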