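import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_920)


@pytest.fixture(scope="session")
def normal_hist_fit():
    """Cubic P-spline fit to a 10,000-draw standard-normal histogram with an
    AIC-selected penalty; shared by moment/score/density checks."""
    from psica.pspline_density import build_histogram, fit_penalized_poisson, select_penalty

    sample = np.random.default_rng(7).standard_normal(10_000)
    hist = build_histogram(sample)
    delta = select_penalty(hist, np.logspace(-3, 3, 7))
    model = fit_penalized_poisson(hist, penalty=delta)
    return sample, hist, model


def hist_moments(hist):
    w = hist.counts / hist.counts.sum()
    mean = float(np.sum(hist.midpoints * w))
    var = float(np.sum((hist.midpoints - mean) ** 2 * w))
    return mean, var


def density_moments(model, n_grid=4001):
    g = np.linspace(model.domain[0], model.domain[1], n_grid)
    f = model.density(g)
    mean = float(np.trapezoid(g * f, g))
    var = float(np.trapezoid((g - mean) ** 2 * f, g))
    return mean, var
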