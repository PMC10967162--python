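"""First-stage negative-binomial fall-rate regression.

One model per cohort: incident falls ~ fall-history factor with six
levels {0,1,2,3,4,5+} (reference 0), log link, optional log person-time
offset.  The NB2 parameterisation is used throughout: for mean ``mu``
the variance is ``mu + mu**2 / theta``, with ``theta`` the dispersion
(size) parameter as in R's ``glm.nb``.  Coefficients and ``theta`` are
estimated by joint maximum likelihood; standard errors are Wald, from
the observed information (``se(theta)`` by the delta method from the
information on ``1/theta``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "LEVELS",
    "FallRateModel",
    "ConvergenceError",
    "categorize_prior_falls",
    "categorize_series",
    "filter_complete_cases",
    "fit_negative_binomial",
    "rate_ratio_table",
    "predict_expected_falls",
]

LEVELS = ("0", "1", "2", "3", "4", "5+")

_MODEL_VARS = ["prior_falls_12m", "incident_falls", "exposure_years"]


class ConvergenceError(RuntimeError):
    """NB fit failed to converge; carries the optimiser trace."""

    def __init__(self, message: str, trace: dict | None = None):
        super().__init__(message)
        self.trace = trace or {}


def categorize_prior_falls(count: int) -> str:
    """Map a raw prior-fall count to its factor level ('0'..'4', '5+')."""
    if isinstance(count, bool) or not float(count).is_integer():
        raise ValueError(f"prior-fall count must be an integer, got {count!r}")
    count = int(count)
    if count < 0:
        raise ValueError(f"prior-fall count must be non-negative, got {count}")
    return "5+" if count >= 5 else str(count)


def categorize_series(counts: pd.Series) -> pd.Series:
    """Vectorised level coding for a column of raw prior-fall counts."""
    arr = counts.to_numpy(dtype=np.int64)
    if (arr < 0).any():
        raise ValueError("prior-fall counts must be non-negative")
    idx = np.minimum(arr, 5)
    return pd.Series(np.asarray(LEVELS, dtype=object)[idx], index=counts.index)


def filter_complete_cases(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows missing any model variable (complete-case analysis).

    Returns the filtered table and the number of rows removed; raises if
    nothing survives.
    """
    mask = table[_MODEL_VARS].notna().all(axis=1)
    n_dropped = int((~mask).sum())
    out = table.loc[mask].reset_index(drop=True)
    if out.empty:
        raise ValueError("no complete cases remain after filtering")
    return out, n_dropped


@dataclass
class FallRateModel:
    """A fitted first-stage NB2 fall-rate model.

    ``alpha`` is the log baseline rate per person-year (level 0 at one
    year of exposure); ``beta`` maps each non-reference level to its log
    rate ratio.  ``vcov`` covers (alpha, betas) in the order
    ``["0"] + fitted non-reference levels``.  Levels absent from the
    training data are listed in ``dropped_levels`` and have no
    coefficient.
    """

    label: str
    alpha: float
    se_alpha: float
    beta: dict[str, float]
    se_beta: dict[str, float]
    vcov: np.ndarray
    theta: float
    se_theta: float
    n_fitted: int
    converged: bool
    use_offset: bool = False
    dropped_levels: tuple[str, ...] = ()
    reference_level: str = "0"

    def validate(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.se_alpha <= 0 or any(s <= 0 for s in self.se_beta.values()):
            raise ValueError("all standard errors must be > 0")
        v = np.asarray(self.vcov, float)
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("vcov must be symmetric")
        eig = np.linalg.eigvalsh((v + v.T) / 2)
        if eig.min() < -1e-8 * max(1.0, eig.max()):
            raise ValueError("vcov must be positive semi-definite")

    def linear_predictor(self, level: str, exposure_years: float = 1.0) -> float:
        """alpha + beta[level] + log(exposure) on the link scale."""
        if exposure_years <= 0:
            raise ValueError("exposure_years must be > 0")
        if level == self.reference_level:
            b = 0.0
        elif level in self.beta:
            b = self.beta[level]
        else:
            raise ValueError(f"unknown or unfitted factor level {level!r}")
        return self.alpha + b + float(np.log(exposure_years))

    # -- JSON round trip ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        d = {
            "label": self.label,
            "alpha": self.alpha,
            "se_alpha": self.se_alpha,
            "beta": self.beta,
            "se_beta": self.se_beta,
            "vcov": np.asarray(self.vcov).tolist(),
            "theta": self.theta,
            "se_theta": self.se_theta,
            "n_fitted": self.n_fitted,
            "converged": self.converged,
            "use_offset": self.use_offset,
            "dropped_levels": list(self.dropped_levels),
            "reference_level": self.reference_level,
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "FallRateModel":
        d = json.loads(Path(path).read_text())
        d["vcov"] = np.asarray(d["vcov"], float)
        d["dropped_levels"] = tuple(d["dropped_levels"])
        return cls(**d)


def fit_negative_binomial(table: pd.DataFrame, use_offset: bool = False,
                          label: str = "model") -> FallRateModel:
    """Fit the six-level fall-history NB2 model to one cohort.

    Expects complete cases (raises otherwise).  Factor levels with no
    participants are dropped with a warning and recorded on the model so
    downstream pooling can skip them.  Raises :class:`ConvergenceError`
    when the joint ML optimisation fails, including the degenerate
    all-zero-outcome case where theta is unidentifiable.
    """
    if table[_MODEL_VARS].isna().any().any():
        raise ValueError("fit requires complete cases; run filter_complete_cases first")

    y = table["incident_falls"].to_numpy(dtype=np.int64)
    levels = categorize_series(table["prior_falls_12m"])
    exposure = table["exposure_years"].to_numpy(dtype=float)
    if (exposure <= 0).any():
        raise ValueError("exposure_years must be > 0 for every participant")

    if (y == 0).all():
        raise ConvergenceError(
            "all incident-fall counts are zero: the dispersion parameter is "
            "unidentifiable and the baseline rate lies on the boundary",
            trace={"n": len(y), "outcome_sum": 0},
        )

    present = [lv for lv in LEVELS if (levels == lv).any()]
    dropped = tuple(lv for lv in LEVELS if lv not in present)
    if dropped:
        warnings.warn(f"factor levels with no participants dropped: {dropped}")
    nonref = [lv for lv in present if lv != "0"]
    if "0" not in present:
        raise ValueError("reference level '0' has no participants; cannot anchor the model")

    X = np.zeros((len(y), 1 + len(nonref)))
    X[:, 0] = 1.0
    for j, lv in enumerate(nonref, start=1):
        X[:, j] = (levels == lv).to_numpy()

    offset = np.log(exposure) if use_offset else None
    model = sm.NegativeBinomial(y, X, offset=offset, loglike_method="nb2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=200, gtol=1e-8)
        except Exception as exc:  # singular Hessian etc.
            raise ConvergenceError(f"NB fit failed: {exc}") from exc
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        # one retry from a Poisson warm start with nelder-mead polish
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pois = sm.Poisson(y, X, offset=offset).fit(disp=0)
            start = np.append(pois.params, 0.5)
            res = model.fit(start_params=start, disp=0, maxiter=500, method="bfgs")
        converged = bool(res.mle_retvals.get("converged", False))
        if not converged:
            raise ConvergenceError("NB fit did not converge", trace=dict(res.mle_retvals))

    params = np.asarray(res.params, float)
    bse = np.asarray(res.bse, float)
    ncoef = 1 + len(nonref)
    alpha_disp = params[-1]           # statsmodels alpha = 1/theta
    if alpha_disp <= 0:
        raise ConvergenceError(
            "dispersion estimate on the boundary (alpha <= 0); data show no overdispersion",
            trace=dict(res.mle_retvals),
        )
    theta = 1.0 / alpha_disp
    se_theta = float(bse[-1] / alpha_disp**2)  # delta method, d(1/a)/da = -1/a^2

    vcov = np.asarray(res.cov_params(), float)[:ncoef, :ncoef]

    return FallRateModel(
        label=label,
        alpha=float(params[0]),
        se_alpha=float(bse[0]),
        beta={lv: float(params[j]) for j, lv in enumerate(nonref, start=1)},
        se_beta={lv: float(bse[j]) for j, lv in enumerate(nonref, start=1)},
        vcov=vcov,
        theta=float(theta),
        se_theta=se_theta,
        n_fitted=len(y),
        converged=converged,
        use_offset=use_offset,
        dropped_levels=dropped,
    )


def rate_ratio_table(model: FallRateModel, z: float = 1.96) -> pd.DataFrame:
    """Response-scale summary: baseline rate per year, then the per-level
    rate ratios with Wald CIs (``exp(beta +/- z*se)``)."""
    rows = [
        {
            "coefficient": "baseline_rate_per_year",
            "estimate": float(np.exp(model.alpha)),
            "ci_low": float(np.exp(model.alpha - z * model.se_alpha)),
            "ci_high": float(np.exp(model.alpha + z * model.se_alpha)),
        }
    ]
    for lv in LEVELS[1:]:
        if lv not in model.beta:
            continue
        b, s = model.beta[lv], model.se_beta[lv]
        rows.append(
            {
                "coefficient": f"prior_falls_{lv}",
                "estimate": float(np.exp(b)),
                "ci_low": float(np.exp(b - z * s)),
                "ci_high": float(np.exp(b + z * s)),
            }
        )
    rows.append(
        {
            "coefficient": "theta",
            "estimate": model.theta,
            "ci_low": model.theta - z * model.se_theta,
            "ci_high": model.theta + z * model.se_theta,
        }
    )
    return pd.DataFrame(rows)


def predict_expected_falls(model: FallRateModel, level: str, exposure_years: float) -> float:
    """Expected number of falls for a factor level over a follow-up period:
    ``exp(alpha + beta[level]) * exposure_years``."""
    return float(np.exp(model.linear_predictor(level, exposure_years)))
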