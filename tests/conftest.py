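import numpy as np
import pytest

import chargevar as cv


@pytest.fixture
def clean_cparams():
    """Chromatogram parameters with every noise source off."""
    return cv.ChromatogramParams(
        noise_sd=0.0, retention_jitter_sd=0.0, baseline_drift=0.0, baseline_offset=0.0
    )


@pytest.fixture
def standard_chromatogram(clean_cparams):
    """Noiseless trace of the reference-standard composition."""
    return cv.synthesize_chromatogram(cv.standard_record(), clean_cparams)


@pytest.fixture
def arrested_params():
    """Growth-arrested, feed-free configuration with constant glucose.

    mu = 0, q_gluc = 0 and no feeding keep the viable cell count,
    production rate and glucose concentration constant, so the acidic
    build-up has the closed form  acidic(t) = k * r * g * t  with
    r the constant daily IgG increment.
    """
    return cv.SimulationParams(
        mu_max_per_temp={37.0: 0.0, 34.0: 0.0, 31.0: 0.0},
        q_gluc=0.0,
        feed_start_day=20,
        feed_end_day=13,
        initial_glucose=5.0,
    )


@pytest.fixture
def noiseless_study():
    design = cv.study_design(master_seed=11, noisy=False)
    return cv.generate_study(design)


def kinetic_datasets(runs, **kwargs):
    out = []
    for run in runs:
        corr = cv.dilution_correct(run)
        rates = cv.compute_rates(run, corr)
        out.append(cv.compute_D(rates, corr, run_id=run.run_id, **kwargs))
    return out
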