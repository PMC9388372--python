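import numpy as np
import pytest

import tempmort as tm


@pytest.fixture(scope="session")
def small_city():
    """One 2-year simulated city under the default template."""
    scenario = tm.default_template(n_years=2)
    return scenario, tm.simulate_city(scenario)


@pytest.fixture(scope="session")
def fitted_city(small_city):
    """Cross-basis spec, cross-basis and conditional Poisson fit for the city."""
    _, series = small_city
    spec = tm.CrossBasisSpec(tm.SplineSpec.from_percentiles(series.temp_c))
    cb = tm.build_cross_basis(series.temp_c, spec)
    fit = tm.fit_conditional_poisson(series, cb)
    return spec, cb, fit


@pytest.fixture(scope="session")
def reduced_curve(small_city, fitted_city):
    _, series = small_city
    spec, _, fit = fitted_city
    return tm.reduce_to_overall(
        fit.coef, fit.vcov, spec, ref_temp=float(np.median(series.temp_c))
    )


def linear_curve(slope: float, ref: float, lo: float = 0.0, hi: float = 40.0,
                 var: float = 0.0) -> tm.ReducedCurve:
    """A purely linear exposure-response curve: logRR(x) = slope * (x - ref)."""
    spec = tm.SplineSpec((lo, hi), ())
    return tm.ReducedCurve(np.array([slope]), np.array([[var]]), spec, ref)
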