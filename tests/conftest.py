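import dataclasses

import numpy as np
import pytest

import profilesim as ps


@pytest.fixture(scope="session")
def casemix():
    return ps.CaseMixConfig()


@pytest.fixture(scope="session")
def small_dataset(casemix):
    """One generated dataset at a desk-scale design (K=6, n_k=400)."""
    root = np.random.SeedSequence(20240817)
    s_model, s_truth, s_fill, s_out = root.spawn(4)
    spec = ps.ScenarioSpec(K=6, p_out=1 / 3, min_volume=400, max_volume=400)
    amodel = ps.draw_assignment_model(spec.K, s_model)
    truth = ps.allocate_provider_truth(spec, s_truth)
    cohort = ps.fill_quotas(amodel, casemix, truth.volumes, s_fill)
    gamma00 = ps.calibrate_intercept(cohort, truth, ps.OutcomeModel().beta, spec.p_bar)
    model = dataclasses.replace(ps.OutcomeModel(), gamma00=gamma00)
    y = ps.draw_outcomes(cohort, truth, model, s_out)
    return spec, truth, cohort, y
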