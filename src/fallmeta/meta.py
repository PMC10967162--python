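"""Second stage: per-coefficient random-effects meta-analysis.

Each first-stage coefficient (log baseline rate, the five log rate
ratios, and the dispersion theta on the linear scale) is pooled across
cohorts with inverse-variance weights under the additive random-effects
model

    y_i ~ Normal(mu, se_i**2 + tau2),

where tau2, the between-study variance, is estimated by restricted
maximum likelihood (Fisher scoring, floored at zero).  Heterogeneity is
summarised by Higgins I^2 in its tau2-based (Higgins-Thompson) form,

    I2 = 100 * tau2 / (tau2 + s2),

with s2 the typical within-study variance
``s2 = (k-1) * sum(w) / (sum(w)^2 - sum(w^2))`` built from fixed-effect
weights ``w_i = 1/se_i^2``.  The Q-based form (Q - df)/Q is exposed for
comparison but is not the default, since tau2 is REML-estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .count_model import LEVELS, FallRateModel

__all__ = [
    "StudyEstimate",
    "MetaResult",
    "log_scale_from_ci",
    "linear_scale_from_ci",
    "reml_tau2",
    "reml_loglik",
    "pool_random_effects",
    "higgins_i2",
    "i2_from_q",
    "meta_analyze_models",
]

Z95 = 1.96


@dataclass(frozen=True)
class StudyEstimate:
    """One coefficient from one study, on its analysis scale
    (log for rates and rate ratios, linear for theta)."""

    study: str
    y: float
    se: float

    def __post_init__(self):
        if not np.isfinite(self.y):
            raise ValueError(f"estimate must be finite, got {self.y}")
        if not (np.isfinite(self.se) and self.se > 0):
            raise ValueError(f"standard error must be finite and > 0, got {self.se}")


@dataclass(frozen=True)
class MetaResult:
    """Pooled coefficient with heterogeneity summaries."""

    mu: float
    se_mu: float
    ci95: tuple[float, float]
    tau2: float
    i2: float
    Q: float
    k: int


def log_scale_from_ci(study: str, point: float, ci_low: float, ci_high: float,
                      z: float = Z95) -> StudyEstimate:
    """Recover a log-scale estimate and SE from a published ratio with its
    95% CI: ``y = ln(point)``, ``se = (ln hi - ln lo) / (2 z)``."""
    if not (0 < ci_low <= point <= ci_high):
        raise ValueError(
            f"CI ordering violated: need 0 < low <= point <= high, got "
            f"({point}, {ci_low}, {ci_high})"
        )
    se = (np.log(ci_high) - np.log(ci_low)) / (2 * z)
    return StudyEstimate(study=study, y=float(np.log(point)), se=float(se))


def linear_scale_from_ci(study: str, point: float, ci_low: float, ci_high: float,
                         z: float = Z95) -> StudyEstimate:
    """As :func:`log_scale_from_ci` but for a coefficient reported with a
    symmetric (linear-scale) CI, e.g. the dispersion theta."""
    if not (ci_low <= point <= ci_high):
        raise ValueError("CI ordering violated")
    se = (ci_high - ci_low) / (2 * z)
    return StudyEstimate(study=study, y=float(point), se=float(se))


def _arrays(estimates: list[StudyEstimate]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([e.y for e in estimates], dtype=float)
    v = np.array([e.se for e in estimates], dtype=float) ** 2
    return y, v


def reml_loglik(tau2: float, estimates: list[StudyEstimate]) -> float:
    """Restricted log-likelihood of the random-effects model at tau2
    (additive constants dropped)."""
    y, v = _arrays(estimates)
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return float(-0.5 * np.sum(np.log(v + tau2)) - 0.5 * np.log(np.sum(w))
                 - 0.5 * np.sum(w * (y - mu) ** 2))


def reml_tau2(estimates: list[StudyEstimate], tol: float = 1e-10,
              max_iter: int = 100) -> float:
    """REML estimate of the between-study variance tau2.

    Fisher scoring on tau2, floored at zero; falls back to a bounded
    scalar maximisation of the restricted likelihood if scoring cycles
    without meeting the tolerance.
    """
    if len(estimates) < 2:
        raise ValueError("meta-analysis requires >= 2 studies")
    y, v = _arrays(estimates)
    tau2 = max(float(np.var(y, ddof=1) - v.mean()), 0.0)
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        sw = np.sum(w)
        mu = np.sum(w * y) / sw
        resid2 = (y - mu) ** 2
        score = 0.5 * (np.sum(w**2 * resid2) - sw + np.sum(w**2) / sw)
        info = 0.5 * (np.sum(w**2) - 2 * np.sum(w**3) / sw + (np.sum(w**2) / sw) ** 2)
        if info <= 0:
            break
        new = max(tau2 + score / info, 0.0)
        if abs(new - tau2) < tol * (1.0 + tau2):
            return new
        tau2 = new
    # fallback: direct bounded maximisation
    hi = max(10.0 * float(np.var(y, ddof=1)) + v.max(), 1.0)
    res = optimize.minimize_scalar(
        lambda t: -reml_loglik(t, estimates), bounds=(0.0, hi), method="bounded",
        options={"xatol": 1e-12},
    )
    return max(float(res.x), 0.0)


def higgins_i2(estimates: list[StudyEstimate], tau2: float) -> float:
    """Higgins I^2 (percent), tau2-based form with the typical
    within-study variance from fixed-effect weights; clamped to [0, 100]."""
    if len(estimates) < 2:
        raise ValueError("I^2 requires >= 2 studies")
    _, v = _arrays(estimates)
    w = 1.0 / v
    k = len(estimates)
    s2 = (k - 1) * np.sum(w) / (np.sum(w) ** 2 - np.sum(w**2))
    i2 = 100.0 * tau2 / (tau2 + s2)
    return float(np.clip(i2, 0.0, 100.0))


def i2_from_q(estimates: list[StudyEstimate]) -> float:
    """The alternative (Q - df)/Q form of I^2 (percent), for comparison."""
    y, v = _arrays(estimates)
    w = 1.0 / v
    mu_f = np.sum(w * y) / np.sum(w)
    Q = float(np.sum(w * (y - mu_f) ** 2))
    df = len(estimates) - 1
    if Q <= 0:
        return 0.0
    return float(np.clip(100.0 * (Q - df) / Q, 0.0, 100.0))


def pool_random_effects(estimates: list[StudyEstimate], tau2: float,
                        knapp_hartung: bool = False) -> MetaResult:
    """Inverse-variance pooled estimate under the random-effects model.

    Weights are ``1/(se_i^2 + tau2)``.  The 95% CI uses the plain normal
    quantile by default; ``knapp_hartung=True`` switches to the
    Knapp-Hartung small-sample adjustment (scaled SE, t quantile).
    Cochran's Q is computed with fixed-effect weights.
    """
    if not estimates:
        raise ValueError("pooling requires >= 1 study")
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    y, v = _arrays(estimates)
    k = len(estimates)

    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se_mu = float(np.sum(w) ** -0.5)

    wf = 1.0 / v
    mu_f = np.sum(wf * y) / np.sum(wf)
    Q = float(np.sum(wf * (y - mu_f) ** 2))

    if knapp_hartung and k >= 2:
        q = float(np.sum(w * (y - mu) ** 2) / (k - 1))
        se_ci = se_mu * np.sqrt(max(q, 1.0))
        crit = float(stats.t.ppf(0.975, k - 1))
    else:
        se_ci, crit = se_mu, Z95

    i2 = higgins_i2(estimates, tau2) if k >= 2 else 0.0
    return MetaResult(
        mu=mu,
        se_mu=se_mu,
        ci95=(mu - crit * se_ci, mu + crit * se_ci),
        tau2=float(tau2),
        i2=i2,
        Q=Q,
        k=k,
    )


#: Coefficient names in pooling order: intercept, the five factor levels,
#: then the dispersion (pooled on the linear scale).
COEFFICIENTS = ("baseline",) + tuple(f"prior_falls_{lv}" for lv in LEVELS[1:]) + ("theta",)


def meta_analyze_models(models: list[FallRateModel], knapp_hartung: bool = False,
                        theta_log_scale: bool = False,
                        ) -> tuple[FallRateModel, dict[str, MetaResult]]:
    """Pool first-stage models coefficient-by-coefficient into an overall model.

    alpha and each beta are pooled on the log scale; theta on the linear
    scale by default (``theta_log_scale=True`` pools ln theta instead).
    A coefficient present in fewer than two models is left unpooled and
    recorded in the overall model's ``dropped_levels``.
    """
    if len(models) < 2:
        raise ValueError("meta-analysis requires >= 2 studies")

    per_coefficient: dict[str, MetaResult] = {}
    not_pooled: list[str] = []

    def _pool(name: str, ests: list[StudyEstimate]) -> MetaResult | None:
        if len(ests) < 2:
            not_pooled.append(name)
            return None
        tau2 = reml_tau2(ests)
        res = pool_random_effects(ests, tau2, knapp_hartung=knapp_hartung)
        per_coefficient[name] = res
        return res

    alpha_res = _pool(
        "baseline", [StudyEstimate(m.label, m.alpha, m.se_alpha) for m in models]
    )

    beta: dict[str, float] = {}
    se_beta: dict[str, float] = {}
    for lv in LEVELS[1:]:
        ests = [
            StudyEstimate(m.label, m.beta[lv], m.se_beta[lv])
            for m in models if lv in m.beta
        ]
        res = _pool(f"prior_falls_{lv}", ests)
        if res is not None:
            beta[lv] = res.mu
            se_beta[lv] = res.se_mu

    if theta_log_scale:
        theta_ests = [
            StudyEstimate(m.label, float(np.log(m.theta)), m.se_theta / m.theta)
            for m in models
        ]
    else:
        theta_ests = [StudyEstimate(m.label, m.theta, m.se_theta) for m in models]
    theta_res = _pool("theta", theta_ests)
    if theta_res is None:
        raise ValueError("theta could not be pooled")
    theta_mu = float(np.exp(theta_res.mu)) if theta_log_scale else theta_res.mu
    se_theta = theta_mu * theta_res.se_mu if theta_log_scale else theta_res.se_mu

    if alpha_res is None:
        raise ValueError("baseline rate could not be pooled")

    ses = [alpha_res.se_mu] + [se_beta[lv] for lv in LEVELS[1:] if lv in beta]
    overall = FallRateModel(
        label="overall",
        alpha=alpha_res.mu,
        se_alpha=alpha_res.se_mu,
        beta=beta,
        se_beta=se_beta,
        vcov=np.diag(np.array(ses) ** 2),  # coefficients pooled independently
        theta=theta_mu,
        se_theta=se_theta,
        n_fitted=sum(m.n_fitted for m in models),
        converged=all(m.converged for m in models),
        use_offset=any(m.use_offset for m in models),
        dropped_levels=tuple(not_pooled),
    )
    return overall, per_coefficient
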