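import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_fixture():
    """10 markers x 3 traits x 50 samples, one planted effect."""
    from ratioscan import FixtureConfig, TraitSpec, make_fixture

    cfg = FixtureConfig(
        n_markers=10, n_samples=50, maf_range=(0.2, 0.5),
        traits=[TraitSpec("alpha", betas=0.8, noise_sd=1.0),
                TraitSpec("beta", noise_sd=1.0),
                TraitSpec("gamma", noise_sd=2.0)],
        seed=11)
    return make_fixture(cfg)


def naive_ols(x, y):
    """Independent reference OLS: explicit residual arithmetic via
    statsmodels, complete cases only.  Oracle for the scan engine."""
    import statsmodels.api as sm

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mask = ~np.isnan(x) & ~np.isnan(y)
    model = sm.OLS(y[mask], sm.add_constant(x[mask])).fit()
    return (model.params[1], model.bse[1], model.pvalues[1],
            int(mask.sum()))
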