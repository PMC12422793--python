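"""Doubly-ranked stratification, Rubin pooling, trend test, FP curve."""

import shutil
import subprocess

import numpy as np
import pytest

from stratmr import (
    DoseResponseSpec,
    NlmrConfig,
    StratumResult,
    bootstrap_average,
    doubly_ranked_strata,
    fractional_polynomial_fit,
    heterogeneity_q,
    rubin_rules,
    run_nlmr,
    stratum_estimates,
    trend_meta_regression,
    two_stage_estimate,
)


# ---------------------------------------------------------------------------
# stratification

def test_doubly_ranked_toy_instance():
    """Pre-strata {1,2},{3,4} by score; exposure slices within each."""
    score = np.array([1.0, 2.0, 3.0, 4.0])
    exposure = np.array([5.0, 9.0, 8.0, 6.0])
    a = doubly_ranked_strata(score, exposure, n_strata=2, prestratum_size=2, seed=0)
    assert a.tolist() == [1, 2, 2, 1]


def test_doubly_ranked_preserves_exposure_order():
    rng = np.random.default_rng(3)
    score = rng.standard_normal(500)
    exposure = 2.0 * score  # strictly increasing in score
    a = doubly_ranked_strata(score, exposure, n_strata=5, prestratum_size=50, seed=1)
    means = [exposure[a == k].mean() for k in range(1, 6)]
    assert np.all(np.diff(means) > 0)


def test_doubly_ranked_seed_and_tie_contract():
    rng = np.random.default_rng(4)
    score = rng.standard_normal(250)
    exposure = np.full(250, 7.0)  # all tied
    a = doubly_ranked_strata(score, exposure, n_strata=5, prestratum_size=50, seed=9)
    b = doubly_ranked_strata(score, exposure, n_strata=5, prestratum_size=50, seed=9)
    np.testing.assert_array_equal(a, b)
    # ties are split randomly but strata stay exactly balanced
    assert [int((a == k).sum()) for k in range(1, 6)] == [50] * 5


def test_doubly_ranked_remainder_assigns_everyone():
    rng = np.random.default_rng(5)
    n = 237  # 4 full pre-strata of 50 + remainder 37
    a = doubly_ranked_strata(rng.standard_normal(n), rng.standard_normal(n),
                             n_strata=5, prestratum_size=50, seed=2)
    assert set(np.unique(a)) == {1, 2, 3, 4, 5}
    assert (a > 0).all()
    sizes = np.bincount(a)[1:]
    assert sizes.max() - sizes.min() <= 2  # remainder-handling allowance


def test_doubly_ranked_preconditions():
    v = np.arange(100.0)
    with pytest.raises(ValueError, match="divisible"):
        doubly_ranked_strata(v, v, n_strata=5, prestratum_size=7)
    with pytest.raises(ValueError, match="fewer"):
        doubly_ranked_strata(v[:30], v[:30], n_strata=5, prestratum_size=50)


def test_strata_uncorrelated_with_score_and_monotone(scored_cohort_factory, linear_spec):
    from scipy.stats import f_oneway

    c = scored_cohort_factory(5_000, linear_spec, seed=61)
    ph = c.phenotypes[c.included_mask]
    s = ph["grs"].to_numpy()
    x = ph["reported_exposure"].to_numpy()
    a = doubly_ranked_strata(s, x, seed=3)
    means = [x[a == k].mean() for k in range(1, 6)]
    assert np.all(np.diff(means) >= 0)
    _, p = f_oneway(*[s[a == k] for k in range(1, 6)])
    assert p > 1e-3  # score is homogeneous across strata


# ---------------------------------------------------------------------------
# Rubin's rules

def test_rubin_rules_hand_example():
    pooled, total = rubin_rules([1.0, 3.0], [1.0, 1.0])
    assert pooled == 2.0
    assert total == 4.0  # W=1, B=2, 1 + (1 + 1/2)*2


def test_rubin_rules_degenerate_cases():
    assert rubin_rules([5.0], [0.25]) == (5.0, 0.25)  # B = 1
    pooled, total = rubin_rules([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
    assert pooled == 2.0 and total == 2.0  # identical estimates: total = W
    with pytest.raises(ValueError):
        rubin_rules([1.0, 2.0], [1.0, -0.5])


def test_rubin_total_variance_dominates_within():
    rng = np.random.default_rng(11)
    q = rng.standard_normal(30)
    v = rng.uniform(0.5, 2.0, 30)
    _, total = rubin_rules(q, v)
    assert total >= v.mean()


# ---------------------------------------------------------------------------
# per-stratum estimation and pooling

def test_single_stratum_reproduces_overall_estimate(scored_cohort_factory, linear_spec):
    c = scored_cohort_factory(2_000, linear_spec, seed=62)
    overall = two_stage_estimate(c, "age_accel", "grs")
    a = np.ones(overall.n_used, dtype=np.int64)
    strata = stratum_estimates(c, "age_accel", "grs", None, a)
    assert len(strata) == 1
    assert strata[0].lace_beta == pytest.approx(overall.beta, abs=1e-12)
    assert strata[0].lace_se == pytest.approx(overall.se, abs=1e-12)


def test_stratum_estimates_homogeneous_under_linear_effect(scored_cohort_factory):
    spec = DoseResponseSpec(shape="linear", params={"slope": -0.3})
    c = scored_cohort_factory(25_000, spec, seed=63)
    ph = c.phenotypes[c.included_mask]
    a = doubly_ranked_strata(ph["grs"], ph["reported_exposure"], seed=4)
    strata = stratum_estimates(c, "age_accel", "grs", None, a)
    for s in strata:
        assert abs(s.lace_beta - (-0.3)) < 4 * s.lace_se
    q, p = heterogeneity_q(strata)
    assert p > 1e-3


def test_bootstrap_no_perturbation_equals_single_shot(scored_cohort_factory, linear_spec):
    c = scored_cohort_factory(1_500, linear_spec, seed=64)
    pooled = bootstrap_average(c, "age_accel", "grs", n_remove=0, reps=3, seed=7)
    ph = c.phenotypes[c.included_mask]
    a = doubly_ranked_strata(ph["grs"], ph["reported_exposure"], seed=7)
    single = stratum_estimates(c, "age_accel", "grs", None, a)
    for p_s, s_s in zip(pooled, single):
        assert p_s.lace_beta == pytest.approx(s_s.lace_beta, abs=1e-12)
        assert p_s.lace_se == pytest.approx(s_s.lace_se, abs=1e-12)  # between-variance 0


def test_bootstrap_single_rep_total_equals_within(scored_cohort_factory, linear_spec):
    c = scored_cohort_factory(1_500, linear_spec, seed=65)
    pooled = bootstrap_average(c, "age_accel", "grs", n_remove=12, reps=1, seed=8)
    assert all(np.isfinite(s.lace_beta) for s in pooled)


def test_bootstrap_stabilizes_threshold_estimates(scored_cohort_factory):
    spec = DoseResponseSpec(
        shape="threshold", params={"breakpoint": 7.0, "left_slope": -1.0, "right_slope": 0.0}
    )
    c = scored_cohort_factory(10_000, spec, seed=66)
    pooled = bootstrap_average(c, "age_accel", "grs", n_remove=12, reps=50, seed=9)
    ph = c.phenotypes[c.included_mask]
    a = doubly_ranked_strata(ph["grs"], ph["reported_exposure"], seed=9)
    single = stratum_estimates(c, "age_accel", "grs", None, a)
    for p_s, s_s in zip(pooled, single):
        assert abs(p_s.lace_beta - s_s.lace_beta) < 4 * p_s.lace_se
        assert p_s.lace_se >= 0.8 * s_s.lace_se  # pooled SE not spuriously shrunk


# ---------------------------------------------------------------------------
# trend meta-regression

def _strata_from(xs, betas, ses):
    return [
        StratumResult(i + 1, 100, x, b, s, b - 1.96 * s, b + 1.96 * s)
        for i, (x, b, s) in enumerate(zip(xs, betas, ses))
    ]


def test_trend_recovers_exact_collinear_slope():
    xs = [5.0, 6.0, 7.0, 8.0, 9.0]
    betas = [0.3 + 0.11 * x for x in xs]
    res = trend_meta_regression(_strata_from(xs, betas, [0.2] * 5))
    assert abs(res[0] - 0.11) < 1e-10


def test_trend_null_and_preconditions():
    slope, se, p = trend_meta_regression(_strata_from([5, 6, 7, 8], [0.4] * 4, [0.1] * 4))
    assert abs(slope) < 1e-12 and p > 1 - 1e-9
    with pytest.raises(ValueError, match="3 usable"):
        trend_meta_regression(_strata_from([5, 6], [0.1, 0.2], [0.1, 0.1]))


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_trend_matches_metafor_fixed_effect():
    """Independent oracle: R metafor rma(..., method='FE', mods=~x)."""
    xs = [5.2, 6.1, 7.0, 7.9, 8.8]
    betas = [-0.9, -0.55, -0.2, 0.03, 0.1]
    ses = [0.25, 0.2, 0.22, 0.18, 0.3]
    slope, se, p = trend_meta_regression(_strata_from(xs, betas, ses))
    rcode = f"""
    suppressMessages(library(metafor))
    fit <- rma(yi=c({','.join(map(str, betas))}), sei=c({','.join(map(str, ses))}),
               mods=~x, data=data.frame(x=c({','.join(map(str, xs))})), method="FE")
    cat(coef(fit)[2], fit$se[2], fit$pval[2], sep="\\n")
    """
    out = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True, check=True)
    r_slope, r_se, r_p = map(float, out.stdout.strip().split())
    assert slope == pytest.approx(r_slope, rel=1e-6)
    assert se == pytest.approx(r_se, rel=1e-6)
    assert p == pytest.approx(r_p, rel=1e-4, abs=1e-12)


# ---------------------------------------------------------------------------
# fractional polynomials

def test_fp_constant_derivative_gives_straight_line():
    strata = _strata_from([5, 6, 7, 8, 9], [0.4] * 5, [0.1] * 5)
    fp = fractional_polynomial_fit(strata)
    assert fp.powers == ()
    g = np.array([3.0, 7.0, 11.0])
    np.testing.assert_allclose(fp.curve(g), 0.4 * (g - 7.0), atol=1e-10)
    assert fp.p_nonlinearity > 0.5


def test_fp_curve_is_anchored_at_reference():
    strata = _strata_from([5, 6, 7, 8, 9], [-1.0, -0.6, -0.2, 0.0, 0.1], [0.1] * 5)
    fp = fractional_polynomial_fit(strata)
    assert abs(fp.curve(np.array([7.0]))[0]) < 1e-12


def test_fp_recovers_inverse_power_derivative():
    """h'(x) = -2/x with tiny errors selects power -1 with theta ~ -2."""
    xs = np.array([4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
    strata = _strata_from(xs, -2.0 / xs, [0.01] * 6)
    fp = fractional_polynomial_fit(strata)
    assert fp.powers == (-1.0,)
    theta_se = 0.01 / np.sqrt(np.sum((1 / xs) ** 2) / 1e-4) * 100  # WLS se of theta
    assert abs(fp.coefficients[0] - (-2.0)) < 4 * max(theta_se, 1e-3)
    # integrated curve follows -2*ln(x/7)
    g = np.array([4.0, 7.0, 10.0])
    np.testing.assert_allclose(fp.curve(g), -2.0 * np.log(g / 7.0), rtol=1e-2, atol=1e-3)


def test_fp_rejects_nonpositive_exposures_and_short_input():
    with pytest.raises(ValueError, match="positive"):
        fractional_polynomial_fit(_strata_from([-1, 6, 7], [0, 0, 0.1], [0.1] * 3))
    with pytest.raises(ValueError, match="usable"):
        fractional_polynomial_fit(_strata_from([6, 7], [0.0, 0.1], [0.1, 0.1]))


def test_fp_degree_two_search_runs():
    xs = np.array([4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
    strata = _strata_from(xs, 0.5 * xs - 3.0 / xs, [0.02] * 6)
    fp = fractional_polynomial_fit(strata, degree=2)
    assert len(fp.powers) in (0, 1, 2)
    assert abs(fp.curve(np.array([7.0]))[0]) < 1e-12


# ---------------------------------------------------------------------------
# orchestration

def test_run_nlmr_is_deterministic(scored_cohort_factory, linear_spec):
    c = scored_cohort_factory(1_500, linear_spec, seed=67)
    cfg = NlmrConfig(reps=5, seed=12)
    r1 = run_nlmr(c, "age_accel", "grs", None, cfg)
    r2 = run_nlmr(c, "age_accel", "grs", None, cfg)
    assert r1.to_json() == r2.to_json()
    assert 0.0 <= r1.p_nonlinearity_trend <= 1.0
    means = [s.mean_exposure for s in r1.strata]
    assert np.all(np.diff(means) >= 0)
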