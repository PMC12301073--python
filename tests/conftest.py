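import numpy as np
import pytest

import bathrisk as br


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-unit cohort over three 4-year periods, with one modifier."""
    return br.make_cohort(
        n_units=4,
        period_defs=[(2000, 2003), (2004, 2007), (2008, 2011)],
        modifier_effects={"insulation": float(np.log(0.76))},
        seed=20,
    )


@pytest.fixture(scope="session")
def single_unit_fit():
    """A converged GAM fit on one simulated unit (strong seasonal signal)."""
    rng = np.random.default_rng(5)
    spec = br.UnitSpec("u1", 3e6, 16.0, seasonal_amplitude=11.0)
    temps = br.simulate_temperature(spec, "2000-01-01", "2007-12-31", rng)
    curve = br.make_true_curve(9.7, 1.8, 30.3)
    y = br.simulate_counts(temps["tmean"].to_numpy(), curve, spec, 1.3, rng)
    lam, fit = br.select_lambda_reml(y, temps["tmean"].to_numpy(), np.log(3e6), k=10)
    return fit


def simulate_unit_counts(seed, peak_rr=9.7, years=6, population=2e6, mean_temp=15.0,
                         amplitude=9.5, dispersion=1.3):
    """Helper: one unit's daily temperatures and counts plus the true curve."""
    rng = np.random.default_rng(seed)
    spec = br.UnitSpec("u", population, mean_temp, seasonal_amplitude=amplitude)
    temps = br.simulate_temperature(spec, "2000-01-01", f"{1999 + years}-12-31", rng)
    curve = br.make_true_curve(peak_rr, 1.8, 30.3)
    y = br.simulate_counts(temps["tmean"].to_numpy(), curve, spec, dispersion, rng)
    return temps, y, curve, spec
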