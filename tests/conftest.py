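import numpy as np
import pytest

import timebisect as tb


@pytest.fixture(scope="session")
def exp1_ps():
    return tb.build_design("exp1", "PS")


@pytest.fixture(scope="session")
def exp1_ns():
    return tb.build_design("exp1", "NS")


@pytest.fixture(scope="session")
def exp1_schedules(exp1_ps, exp1_ns):
    return [tb.enumerate_trials(exp1_ps, 11), tb.enumerate_trials(exp1_ns, 12)]


@pytest.fixture(scope="session")
def clean_erp_params():
    """ERP generator with all components that overlap the CNV ramp zeroed,
    no noise and no participant heterogeneity — for exactness checks."""
    return tb.ErpParams(
        n1_amp_uv=0.0,
        p2_amp_uv=0.0,
        offset_p2_amp_intercept_uv=0.0,
        offset_p2_amp_gain_uv_per_s=0.0,
        lpct_amp_intercept_uv=0.0,
        lpct_amp_gain_uv_per_s=0.0,
        noise_sd_uv=0.0,
        pink_noise_sd_uv=0.0,
        cnv_slope_sd=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_exp1_epochs(exp1_ps, exp1_ns):
    """19-participant epochs on the exp1 duration sets, 2 trials per cell,
    zero noise and zero heterogeneity — cheap but structurally complete."""
    import dataclasses

    params = tb.ErpParams(noise_sd_uv=0.0, pink_noise_sd_uv=0.0, cnv_slope_sd=0.0)
    scheds = [
        tb.enumerate_trials(dataclasses.replace(d, repetitions=(2,) * 7), i)
        for i, d in enumerate([exp1_ps, exp1_ns])
    ]
    return tb.simulate_epochs(scheds, params, 19, 5)
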