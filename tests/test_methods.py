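"""The six risk-adjustment methods and their classification rules."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

import profilesim as ps
from profilesim.methods import (
    GPSMatrix,
    MethodFailure,
    PositivityError,
    classify_gps_a,
    classify_lrf,
    classify_lrr,
    classify_weighted,
    estimate_gps,
    ipw_weights,
    mmws_weights,
    run_all_methods,
    trim_weights,
)
from profilesim.outcome import NORMAL, OUTLIER_HIGH, OUTLIER_LOW


# ---------------------------------------------------------------- fixtures
def _uniform_cohort(n=400, K=2, seed=5):
    """Cohort with covariates but random (non-confounded) attendance."""
    rng = np.random.default_rng(seed)
    cov = ps.generate_cohort(ps.CaseMixConfig(), n, rng)
    provider = np.tile(np.arange(1, K + 1), n // K)
    return ps.AssignedCohort(
        covariates=cov, provider=provider, volumes=np.full(K, n // K), K=K
    )


# ---------------------------------------------------------------- LR_F
def test_lrf_no_outliers_on_exchangeable_providers(small_dataset):
    _, truth, cohort, y = small_dataset
    # shuffle outcomes across providers: removes any provider signal
    rng = np.random.default_rng(0)
    res = classify_lrf(cohort, rng.permutation(y))
    assert res.method == "LR_F"
    assert len(res.labels) == cohort.K
    # most providers unflagged when there is no signal (5% nominal rate)
    assert res.flagged.mean() <= 0.5


def test_lrf_flags_extreme_provider_with_direction():
    rng = np.random.default_rng(8)
    cohort = _uniform_cohort(n=3000, K=3, seed=8)
    p = np.full(cohort.N, 0.10)
    p[cohort.provider == 3] = 0.45  # grossly elevated mortality
    y = (rng.random(cohort.N) < p).astype(float)
    res = classify_lrf(cohort, y)
    assert res.labels[2] == OUTLIER_LOW  # higher mortality = below average
    # the pooled intercept sits above the other providers' rates, so they can
    # only be flagged as better than average, never as worse
    assert OUTLIER_LOW not in res.labels[:2]


def test_lrf_separation_is_a_method_failure():
    cohort = _uniform_cohort(n=200, K=2)
    y = (cohort.provider == 2).astype(float)  # provider perfectly predicts y
    with pytest.raises(MethodFailure):
        classify_lrf(cohort, y)


def test_outcome_flip_swaps_direction_not_status(small_dataset):
    _, truth, cohort, y = small_dataset
    a = classify_lrf(cohort, y)
    b = classify_lrf(cohort, 1 - y)
    assert np.array_equal(a.flagged, b.flagged)
    swap = {NORMAL: NORMAL, OUTLIER_LOW: OUTLIER_HIGH, OUTLIER_HIGH: OUTLIER_LOW}
    assert np.array_equal(np.array([swap[l] for l in a.labels]), b.labels)


# ---------------------------------------------------------------- LR_R
def test_lrr_two_sd_rule(small_dataset):
    _, truth, cohort, y = small_dataset
    res = classify_lrr(cohort, y)
    sigma = res.info["sigma"]
    for est, lab in zip(res.estimate, res.labels):
        if abs(est) > 2 * sigma:
            assert lab == (OUTLIER_LOW if est > 0 else OUTLIER_HIGH)
        else:
            assert lab == NORMAL


def test_lrr_eb_sd_rule_variant(small_dataset):
    _, truth, cohort, y = small_dataset
    res = classify_lrr(cohort, y, rule="eb_sd")
    assert np.allclose(res.threshold, 2 * res.info["eb_sd"])


# ---------------------------------------------------------------- gPS
def test_gps_rows_sum_to_one(small_dataset):
    _, _, cohort, _ = small_dataset
    gps = estimate_gps(cohort)
    assert gps.probs.shape == (cohort.N, cohort.K)
    assert np.allclose(gps.probs.sum(axis=1), 1.0, atol=1e-10)


def test_gps_k2_equals_binary_logit():
    m = ps.draw_assignment_model(2, seed=31)
    cohort = ps.fill_quotas(m, ps.CaseMixConfig(), (800, 800), seed=32)
    gps = estimate_gps(cohort, tol=1e-10)
    Z = cohort.covariates.to_numpy(float)
    oracle = sm.Logit((cohort.provider == 2).astype(float), sm.add_constant(Z)).fit(
        disp=0, method="newton", tol=1e-12
    )
    assert np.allclose(gps.probs[:, 1], oracle.predict(), atol=1e-6)


def test_gps_a_constant_columns_reduce_to_providers_only(small_dataset):
    _, _, cohort, y = small_dataset
    const = GPSMatrix(probs=np.full((cohort.N, cohort.K), 1 / cohort.K))
    a = classify_gps_a(cohort, y, const)
    b = classify_weighted(cohort, y, np.ones(cohort.N), "gPS_W")
    assert np.allclose(a.estimate, b.estimate, atol=1e-6)
    assert a.info["sigma"] == pytest.approx(b.info["sigma"], abs=1e-6)
    assert np.array_equal(a.labels, b.labels)


def test_gps_a_agrees_with_lrr_on_shared_covariates(small_dataset):
    # the attendance and outcome models share the same eight covariates, so
    # adjusting for the gPS or for raw case-mix flags (almost) the same
    # providers
    _, _, cohort, y = small_dataset
    gps = estimate_gps(cohort)
    a = classify_gps_a(cohort, y, gps)
    b = classify_lrr(cohort, y)
    assert np.array_equal(a.labels, b.labels)


# ---------------------------------------------------------------- weights
def test_ipw_reciprocal_and_uniform():
    probs = np.array([[0.25, 0.75], [0.5, 0.5]])
    w = ipw_weights(GPSMatrix(probs=probs), np.array([1, 2]))
    assert np.allclose(w, [4.0, 2.0])
    uni = GPSMatrix(probs=np.full((6, 3), 1 / 3))
    assert np.allclose(ipw_weights(uni, np.array([1, 2, 3, 1, 2, 3])), 3.0)


def test_ipw_positivity_violation():
    probs = np.array([[1.0, 0.0]])
    with pytest.raises(PositivityError):
        ipw_weights(GPSMatrix(probs=probs), np.array([2]))


def test_ipw_pseudo_population_identity():
    # enumeration oracle: over all possible attendance vectors weighted by
    # their probability, the expected total IPW weight is N * K
    rng = np.random.default_rng(3)
    raw = rng.uniform(0.2, 1.0, size=(4, 3))
    probs = raw / raw.sum(axis=1, keepdims=True)
    gps = GPSMatrix(probs=probs)
    total = 0.0
    for combo in itertools.product(range(3), repeat=4):
        pr = np.prod(probs[np.arange(4), combo])
        w = ipw_weights(gps, np.asarray(combo) + 1)
        total += pr * w.sum()
    assert total == pytest.approx(4 * 3, abs=1e-10)


def test_trim_weights_caps_extremes():
    w = np.concatenate([np.linspace(1, 2, 98), [50.0, 80.0]])
    cap = np.quantile(w, 0.98)
    t = trim_weights(w)
    assert np.all(t <= cap + 1e-12)
    assert np.allclose(np.sort(t)[-2:], cap)
    assert np.array_equal(t[:97], w[:97])  # small weights untouched


@given(
    st.lists(st.floats(0.0, 100.0), min_size=5, max_size=60),
    st.floats(0.01, 0.2),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_trim_weights_properties(wlist, frac):
    w = np.asarray(wlist)
    t = trim_weights(w, frac)
    assert t.max() <= np.quantile(w, 1 - frac) + 1e-9
    assert np.all(t <= w + 1e-12)
    assert np.all(t[w <= np.quantile(w, 1 - frac)] == w[w <= np.quantile(w, 1 - frac)])


def test_trim_weights_noop_when_equal():
    w = np.full(10, 3.0)
    assert np.array_equal(trim_weights(w), w)


def test_mmws_balanced_case_gives_unit_weights():
    # attendance proportional to the marginal share within every stratum
    gps1 = np.linspace(0.3, 0.7, 100)
    probs = np.column_stack([gps1, 1 - gps1])
    attended = np.tile([1, 2], 50)  # alternating: 10 of each per 20-block
    w = mmws_weights(GPSMatrix(probs=probs), attended)
    assert np.allclose(w, 1.0)


def test_mmws_direct_formula():
    # 10 patients, K=2, 5 strata of 2 on provider-1's gPS; hand evaluation
    gps1 = np.array([0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5, 0.55])
    probs = np.column_stack([gps1, 1 - gps1])
    attended = np.array([1, 2, 2, 2, 1, 2, 2, 2, 1, 1])  # share(1) = 0.4
    w = mmws_weights(GPSMatrix(probs=probs), attended)
    # patient 0: stratum {0,1} of provider 1, 1 attendee of 1 -> 2*0.4/1
    assert w[0] == pytest.approx(0.8)
    # patient 8,9: stratum {8,9}, both attend 1 -> 2*0.4/2
    assert w[8] == pytest.approx(0.4) and w[9] == pytest.approx(0.4)
    # patient 1: stratum {0,1} of provider 2's gPS is {8,9}? use identity below


def test_mmws_volume_identity():
    # with every stratum populated, MMW weights of provider k's attendees
    # sum to that provider's observed volume; non-confounded attendance
    # guarantees populated strata
    cohort = _uniform_cohort(n=3000, K=3, seed=77)
    gps = estimate_gps(cohort)
    w = mmws_weights(gps, cohort.provider)
    for k in range(cohort.K):
        mask = cohort.provider == k + 1
        assert w[mask].sum() == pytest.approx(mask.sum(), rel=1e-9)


# ---------------------------------------------------------------- weighted fit
def test_unit_weights_match_unweighted_providers_only(small_dataset):
    _, _, cohort, y = small_dataset
    res = classify_weighted(cohort, y, np.ones(cohort.N), "gPS_W")
    X = np.ones((cohort.N, 1))
    fit = ps.fit_random_intercept_logistic(y, X, cohort.provider, compute_se=False)
    assert np.allclose(res.estimate, fit.eb, atol=1e-7)
    assert res.info["sigma"] == pytest.approx(fit.sigma, abs=1e-7)


def test_trimming_noop_below_cap(small_dataset):
    _, _, cohort, y = small_dataset
    gps = estimate_gps(cohort)
    w = ipw_weights(gps, cohort.provider)
    capped = np.minimum(w, np.quantile(w, 0.98))
    a = classify_weighted(cohort, y, capped, "gPS_WT")
    b = classify_weighted(cohort, y, trim_weights(w), "gPS_WT")
    assert np.array_equal(a.labels, b.labels)
    assert np.allclose(a.estimate, b.estimate)


# ---------------------------------------------------------------- dispatcher
def test_run_all_methods_shared_dataset(small_dataset):
    _, truth, cohort, y = small_dataset
    results, failures = run_all_methods(cohort, y)
    assert set(results) | set(failures) == set(ps.METHOD_NAMES)
    for name, res in results.items():
        assert len(res.labels) == cohort.K


def test_run_all_methods_records_failures(small_dataset):
    _, _, cohort, _ = small_dataset
    y = (cohort.provider == 1).astype(float)  # separation for LR_F
    results, failures = run_all_methods(cohort, y, methods=("LR_F",))
    assert "LR_F" in failures and not results
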