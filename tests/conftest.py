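import dataclasses

import numpy as np
import pytest

from moultfit import growth, synthetic


def zero_noise_template(**overrides):
    """HADU-female-like cohort template with all stochasticity removed."""
    base = synthetic.default_templates()[0]
    fields = dict(sd_shed_day=0.0, sd_A=0.0, sd_mu=0.0, sd_mass0=0.0,
                  noise_sd_p9=0.0, noise_sd_mass=0.0)
    fields.update(overrides)
    return dataclasses.replace(base, **fields)


@pytest.fixture(scope="session")
def noisy_recovery():
    """200 simulated birds at published-cohort-like parameters with 2 mm P9
    noise, fitted once and shared across recovery tests."""
    template = zero_noise_template(
        n_birds=200, sd_A=3.3, sd_mu=0.13, sd_shed_day=3.0, sd_mass0=24.2,
        noise_sd_p9=2.0, noise_sd_mass=10.0)
    birds, truths = synthetic.simulate_cohort(template, seed=42)
    fits = [growth.fit_growth(b) for b in birds]
    timings = [growth.moult_timing(f) for f in fits]
    true_timings = []
    for t in truths:
        tf = growth.GrowthFit("gompertz", t.true_A, t.true_mu, t.true_lambda,
                              0.0, 14, np.nan, True)
        true_timings.append(growth.moult_timing(tf))
    return birds, truths, fits, timings, true_timings
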