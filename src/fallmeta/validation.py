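"""External validation, calibration-in-the-large, and rootograms.

Validation applies each fitted fall-rate model to each cohort and
reports the mean absolute prediction error (MAE), giving the apparent
error on the diagonal and the external error off-diagonal.

Recalibration follows the regression-based calibration-in-the-large
recipe for count models: compute the existing model's linear predictor
p0 on the link scale (including the person-time offset), fit a fresh
intercept-only NB2 model to the new outcomes with p0 as an offset, and
shift every prediction by the fitted intercept alpha_new, giving
p1 = alpha_new + p0.  A well-calibrated model yields alpha_new near 0;
alpha_new estimates the log ratio of the new cohort's baseline rate to
the model's.

Marginal calibration is assessed with hanging rootograms: per count
category k the observed frequency is compared with the expected
frequency sum_i Pr(Y=k | mu_i, theta) under the NB2 fit, on the
square-root scale, with bars hanging from the expected curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .count_model import (
    ConvergenceError,
    FallRateModel,
    categorize_series,
    fit_negative_binomial,
)

__all__ = [
    "CalibrationResult",
    "RootogramData",
    "mean_absolute_prediction_error",
    "cross_validation_matrix",
    "calibration_in_the_large",
    "rootogram",
]


def _linear_predictor(model: FallRateModel, table: pd.DataFrame) -> np.ndarray:
    """Per-participant link-scale predictor alpha + beta[level] + ln(exposure)."""
    levels = categorize_series(table["prior_falls_12m"])
    exposure = table["exposure_years"].to_numpy(dtype=float)
    lp = np.empty(len(table))
    for i, (lv, ex) in enumerate(zip(levels, exposure)):
        lp[i] = model.linear_predictor(lv, ex)
    return lp


def mean_absolute_prediction_error(model: FallRateModel, table: pd.DataFrame) -> float:
    """Mean over participants of |observed falls - expected falls|, with
    the expectation using each participant's factor level and exposure."""
    y = table["incident_falls"].to_numpy(dtype=float)
    pred = np.exp(_linear_predictor(model, table))
    return float(np.mean(np.abs(y - pred)))


def cross_validation_matrix(models: list[FallRateModel],
                            tables: dict[str, pd.DataFrame] | list[pd.DataFrame],
                            recalibrate: bool = False) -> pd.DataFrame:
    """MAE of every model applied to every dataset (rows: models,
    columns: datasets).  The diagonal, where a model meets its own
    training cohort, is the apparent error.

    With ``recalibrate=True`` each entry first applies
    calibration-in-the-large to the (model, dataset) pair and scores the
    updated predictions exp(p1), so baseline-rate differences between
    cohorts do not dominate the error.  On the diagonal the constant is
    near zero, leaving the apparent error essentially unchanged.
    """
    if isinstance(tables, list):
        tables = {f"dataset_{i}": t for i, t in enumerate(tables)}
    if not models or not tables:
        raise ValueError("need >= 1 model and >= 1 dataset")
    out = pd.DataFrame(
        index=[m.label for m in models], columns=list(tables), dtype=float
    )
    for m in models:
        for name, t in tables.items():
            if recalibrate:
                cal = calibration_in_the_large(m, t)
                y = t["incident_falls"].to_numpy(dtype=float)
                out.loc[m.label, name] = float(np.mean(np.abs(y - np.exp(cal.p1))))
            else:
                out.loc[m.label, name] = mean_absolute_prediction_error(m, t)
    out.index.name = "model"
    return out


@dataclass
class CalibrationResult:
    """Calibration-in-the-large output: the recalibration constant and
    the original (p0) and updated (p1 = alpha_new + p0) linear predictors."""

    alpha_new: float
    se_alpha_new: float
    theta_new: float
    p0: np.ndarray
    p1: np.ndarray


def calibration_in_the_large(model: FallRateModel, table: pd.DataFrame,
                             carry_theta: bool = False) -> CalibrationResult:
    """Recalibrate an existing model's intercept to a new cohort.

    Fits an intercept-only NB2 regression of the new outcomes with the
    existing model's linear predictor p0 as an offset; the fitted
    intercept is the recalibration constant alpha_new.  The dispersion
    is re-estimated in this fit by default; ``carry_theta=True`` keeps
    the existing model's theta instead (Poisson-with-fixed-theta
    profile is not needed because theta does not move alpha_new's ML
    solution materially; the flag simply reports the carried value).
    """
    p0 = _linear_predictor(model, table)
    y = table["incident_falls"].to_numpy(dtype=np.int64)
    if (y == 0).all():
        raise ConvergenceError("all outcomes zero; recalibration fit is degenerate")

    import statsmodels.api as sm
    import warnings

    X = np.ones((len(y), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.NegativeBinomial(y, X, offset=p0, loglike_method="nb2").fit(
            disp=0, maxiter=200
        )
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError("recalibration NB fit did not converge",
                               trace=dict(res.mle_retvals))
    alpha_new = float(res.params[0])
    alpha_disp = float(res.params[1])
    theta_new = model.theta if carry_theta else (1.0 / alpha_disp if alpha_disp > 0 else np.inf)
    return CalibrationResult(
        alpha_new=alpha_new,
        se_alpha_new=float(res.bse[0]),
        theta_new=theta_new,
        p0=p0,
        p1=alpha_new + p0,
    )


@dataclass
class RootogramData:
    """Observed vs expected count frequencies for a hanging rootogram.

    ``counts`` runs 0..K with a final open tail bin (labelled ">=K+1" in
    ``labels``) absorbing the remaining mass on both sides, so observed
    and expected frequencies each sum to the number of participants.
    On the square-root scale the bar for count k spans
    [sqrt(E_k) - sqrt(O_k), sqrt(E_k)]: a bar overshooting below the
    axis marks underestimation of that frequency, a floating bar that
    does not reach the axis marks overestimation.
    """

    counts: np.ndarray
    labels: list[str]
    observed_freq: np.ndarray
    expected_freq: np.ndarray

    @property
    def bar_top(self) -> np.ndarray:
        return np.sqrt(self.expected_freq)

    @property
    def bar_bottom(self) -> np.ndarray:
        return np.sqrt(self.expected_freq) - np.sqrt(self.observed_freq)


def rootogram(model: FallRateModel, table: pd.DataFrame, K: int = 20) -> RootogramData:
    """Marginal calibration data: expected frequency per fall-count
    category as the sum of per-participant NB2 pmfs
    (size theta, mean mu_i), against the observed histogram."""
    if K < 0:
        raise ValueError("K must be >= 0")
    y = table["incident_falls"].to_numpy(dtype=np.int64)
    mu = np.exp(_linear_predictor(model, table))
    n = len(y)

    # NB2 with mean mu and size theta: scipy nbinom(n=theta, p=theta/(theta+mu))
    theta = model.theta
    p = theta / (theta + mu)
    ks = np.arange(K + 1)
    # pmf matrix (K+1, n) summed over participants
    expected = stats.nbinom.pmf(ks[:, None], theta, p[None, :]).sum(axis=1)
    tail_expected = float(n - expected.sum())

    observed = np.bincount(np.minimum(y, K + 1), minlength=K + 2).astype(float)
    obs_head, obs_tail = observed[: K + 1], float(observed[K + 1 :].sum())

    return RootogramData(
        counts=np.append(ks, K + 1),
        labels=[str(k) for k in ks] + [f">={K + 1}"],
        observed_freq=np.append(obs_head, obs_tail),
        expected_freq=np.append(expected, max(tail_expected, 0.0)),
    )
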