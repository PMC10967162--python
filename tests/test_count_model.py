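"""First-stage NB2 regression: level coding, fitting, prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fallmeta import (
    ConvergenceError,
    FallRateModel,
    categorize_prior_falls,
    filter_complete_cases,
    fit_negative_binomial,
    generate_cohort,
    inject_missingness,
    predict_expected_falls,
    rate_ratio_table,
)
from fallmeta.count_model import categorize_series

from conftest import make_spec


# -- level coding -----------------------------------------------------------

@pytest.mark.parametrize(
    "count, level",
    [(0, "0"), (1, "1"), (2, "2"), (3, "3"), (4, "4"), (5, "5+"), (7, "5+"), (100, "5+")],
)
def test_categorize_prior_falls(count, level):
    assert categorize_prior_falls(count) == level


@pytest.mark.parametrize("bad", [-1, 2.5, True])
def test_categorize_rejects_invalid(bad):
    with pytest.raises(ValueError):
        categorize_prior_falls(bad)


@given(st.lists(st.integers(min_value=0, max_value=30), min_size=1, max_size=50))
@settings(deadline=None, derandomize=True)
def test_categorize_series_matches_scalar(counts):
    s = pd.Series(counts)
    assert list(categorize_series(s)) == [categorize_prior_falls(c) for c in counts]


# -- complete cases ---------------------------------------------------------

def test_complete_cases_passthrough_and_degenerate():
    t = generate_cohort(make_spec(n=20))
    out, n_dropped = filter_complete_cases(t)
    assert n_dropped == 0 and len(out) == 20
    with pytest.raises(ValueError, match="no complete cases"):
        filter_complete_cases(inject_missingness(t, 1.0))


# -- fitting ----------------------------------------------------------------

def _make_model(alpha=0.0, beta=None, se=0.1, theta=1.0):
    beta = beta or {}
    levels = list(beta)
    ses = np.full(1 + len(levels), se)
    return FallRateModel(
        label="manual", alpha=alpha, se_alpha=se,
        beta=beta, se_beta={lv: se for lv in levels},
        vcov=np.diag(ses**2), theta=theta, se_theta=0.1,
        n_fitted=0, converged=True,
    )


def test_intercept_only_fit_recovers_log_sample_mean():
    """Intercept-only NB2 equates the fitted and sample means exactly,
    so exp(alpha) must equal the mean outcome (Poisson ML closed form)."""
    spec = make_spec(n=3000, category_probs=(1.0, 0, 0, 0, 0, 0), seed=5)
    t = generate_cohort(spec)
    m = fit_negative_binomial(t)
    assert np.exp(m.alpha) == pytest.approx(t["incident_falls"].mean(), rel=1e-6)
    assert m.converged and m.dropped_levels == ("1", "2", "3", "4", "5+")


def test_all_zero_outcomes_raise():
    t = generate_cohort(make_spec(baseline_rate=1e-9, n=100))
    with pytest.raises(ConvergenceError, match="zero"):
        fit_negative_binomial(t)


def test_fit_rejects_missing_values():
    t = inject_missingness(generate_cohort(make_spec(n=100)), 0.1, seed=1)
    with pytest.raises(ValueError, match="complete cases"):
        fit_negative_binomial(t)


def test_offset_exposure_scaling_shifts_intercept_only():
    """Multiplying every exposure by c shifts alpha by -ln(c) exactly and
    leaves the rate ratios untouched when the offset is on."""
    spec = make_spec(n=2000, exposure_model="uniform", exposure_range=(0.25, 1.0), seed=8)
    t = generate_cohort(spec)
    m1 = fit_negative_binomial(t, use_offset=True)
    t2 = t.copy()
    t2["exposure_years"] = t2["exposure_years"] * 3.0
    m2 = fit_negative_binomial(t2, use_offset=True)
    assert m2.alpha == pytest.approx(m1.alpha - np.log(3.0), abs=1e-6)
    for lv in m1.beta:
        assert m2.beta[lv] == pytest.approx(m1.beta[lv], abs=1e-6)
    assert m2.theta == pytest.approx(m1.theta, rel=1e-5)


def test_saturated_factor_fit_matches_poisson_oracle():
    """With a saturated one-way factor design and equal exposure, NB2 and
    Poisson ML both equate fitted and observed cell means, so the link-scale
    coefficients agree (the theta -> infinity limit holds exactly here)."""
    import statsmodels.api as sm

    t = generate_cohort(make_spec(n=4000, seed=13))
    m = fit_negative_binomial(t)
    lev = categorize_series(t["prior_falls_12m"])
    nonref = [lv for lv in ("1", "2", "3", "4", "5+") if lv in m.beta]
    X = np.column_stack([np.ones(len(t))] + [(lev == lv).to_numpy(float) for lv in nonref])
    pois = sm.Poisson(t["incident_falls"].to_numpy(int), X).fit(disp=0)
    assert m.alpha == pytest.approx(pois.params[0], abs=1e-4)
    for j, lv in enumerate(nonref, start=1):
        assert m.beta[lv] == pytest.approx(pois.params[j], abs=1e-4)


def test_fit_is_local_maximum(gerico_like_10k):
    """Log-likelihood at the estimate beats a surrounding grid perturbation."""
    _, t = gerico_like_10k
    t = t.iloc[:2000]
    m = fit_negative_binomial(t)
    y = t["incident_falls"].to_numpy(int)
    lev = np.minimum(t["prior_falls_12m"].to_numpy(int), 5)

    def loglike(alpha, beta, theta):
        coefs = np.array([0.0] + [beta[lv] for lv in ("1", "2", "3", "4", "5+")])
        mu = np.exp(alpha + coefs[lev])
        return stats.nbinom.logpmf(y, theta, theta / (theta + mu)).sum()

    ll_hat = loglike(m.alpha, m.beta, m.theta)
    for d in (-0.05, 0.05):
        assert loglike(m.alpha + d, m.beta, m.theta) < ll_hat
        assert loglike(m.alpha, m.beta, max(m.theta + d, 1e-3)) < ll_hat
        for lv in m.beta:
            b = dict(m.beta)
            b[lv] += d
            assert loglike(m.alpha, b, m.theta) < ll_hat


def test_parameter_recovery_within_wald_99_ci(gerico_like_10k):
    spec, t = gerico_like_10k
    m = fit_negative_binomial(t, label="recovery")
    z = stats.norm.ppf(0.995)
    truth_alpha = np.log(spec.baseline_rate)
    assert abs(m.alpha - truth_alpha) < z * m.se_alpha
    for lv, rr in zip(("1", "2", "3", "4", "5+"), spec.rate_ratios[1:]):
        assert abs(m.beta[lv] - np.log(rr)) < z * m.se_beta[lv]
    assert abs(m.theta - spec.theta) < z * m.se_theta
    m.validate()  # vcov symmetric PSD, SEs positive


# -- response-scale summaries ----------------------------------------------

def test_rate_ratio_table_closed_form():
    m = _make_model(alpha=np.log(0.5), beta={"1": 0.0}, se=0.1)
    tab = rate_ratio_table(m).set_index("coefficient")
    row = tab.loc["prior_falls_1"]
    assert row["estimate"] == pytest.approx(1.0)
    assert row["ci_low"] == pytest.approx(np.exp(-1.96 * 0.1), abs=1e-6)  # 0.8217
    assert row["ci_high"] == pytest.approx(np.exp(1.96 * 0.1), abs=1e-6)  # 1.2170
    base = tab.loc["baseline_rate_per_year"]
    assert base["estimate"] == pytest.approx(0.5)


def test_rate_ratio_table_degenerate_se_collapses_ci():
    m = _make_model(alpha=np.log(2.0), beta={"1": np.log(3.0)}, se=0.0)
    tab = rate_ratio_table(m).set_index("coefficient")
    row = tab.loc["prior_falls_1"]
    assert row["ci_low"] == row["estimate"] == row["ci_high"] == pytest.approx(3.0)


def test_predict_expected_falls_published_overall_model():
    """The pooled model's printed values: baseline 0.59/year, RR(5+) 8.48,
    so a 5+ faller is expected to fall 0.59 * 8.48 = 5.0032 times a year."""
    m = _make_model(alpha=np.log(0.59), beta={"5+": np.log(8.48)})
    assert predict_expected_falls(m, "0", 1.0) == pytest.approx(0.59)
    assert predict_expected_falls(m, "5+", 1.0) == pytest.approx(5.0032)
    assert predict_expected_falls(m, "5+", 0.5) == pytest.approx(5.0032 / 2)


def test_predict_monotone_in_exposure_and_rejects_bad_input():
    m = _make_model(alpha=0.0, beta={"1": 0.5})
    ex = np.linspace(0.1, 3.0, 30)
    preds = [predict_expected_falls(m, "1", e) for e in ex]
    assert np.all(np.diff(preds) > 0)
    with pytest.raises(ValueError, match="level"):
        predict_expected_falls(m, "9", 1.0)
    with pytest.raises(ValueError, match="exposure"):
        predict_expected_falls(m, "1", 0.0)


def test_model_json_round_trip(tmp_path, fitted_cohorts):
    _, _, models = fitted_cohorts
    m = models[0]
    path = tmp_path / "m.json"
    m.to_json(path)
    back = FallRateModel.from_json(path)
    assert back.alpha == m.alpha and back.beta == m.beta
    assert np.allclose(back.vcov, m.vcov)
    assert back.theta == m.theta and back.n_fitted == m.n_fitted
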