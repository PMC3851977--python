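import numpy as np
import pytest
from scipy.integrate import quad

import varfreq as vf


@pytest.fixture(scope="session")
def grid_values():
    return vf.FrequencyGrid().values


@pytest.fixture(scope="session")
def uniform_prior():
    return vf.GridDistribution.uniform()


def quadrature_posterior(n, m, q_avg, prior, floor_quality=20.0):
    """Independent oracle: adaptive quadrature of p(f) * B_{m,n}(f, f+E-2Ef).

    Integrates the defining integral at every grid point (stabilised by the
    integrand's maximum so deep sites do not underflow), then normalizes.
    Shares no code with the incomplete-beta implementation path.
    """
    e_bound = 10.0 ** (-(q_avg if q_avg is not None else floor_quality) / 10.0)

    def log_integrand(x):
        out = 0.0
        if n:
            out += n * np.log(x) if x > 0 else -np.inf
        if m - n:
            out += (m - n) * np.log1p(-x) if x < 1 else -np.inf
        return out

    peak = np.clip(n / m, 1e-12, 1 - 1e-12)
    shift = log_integrand(peak)
    kernel = np.empty(prior.values.size)
    for i, f in enumerate(prior.values):
        a = f
        b = f + e_bound - 2.0 * e_bound * f
        lo, hi = min(a, b), max(a, b)
        if hi - lo == 0.0:
            kernel[i] = np.exp(log_integrand(f) - shift)
        else:
            value, _ = quad(lambda x: np.exp(log_integrand(x) - shift), lo, hi, limit=200)
            kernel[i] = value / (hi - lo)
    weights = prior.weights * kernel
    return weights / weights.sum()
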