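"""Synthetic participant-level fall cohorts.

The combined analysis operates on participant tables with a prior-fall
count (12-month recall), an incident-fall count over follow-up, and the
person-time of follow-up.  The original study data are not publicly
deposited, so this module generates cohorts with the same statistical
structure: incident falls are overdispersed counts (NB2, gamma-Poisson
mixture) driven by a six-level fall-history factor {0,1,2,3,4,5+} on a
log-rate scale with a person-time offset.

A cohort table is a plain :class:`pandas.DataFrame` with columns
``id, prior_falls_12m, incident_falls, exposure_years`` (missing counts
are pandas NA; the CSV encoding is an empty field).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CohortSpec",
    "COHORT_COLUMNS",
    "generate_cohort",
    "default_specs",
    "inject_missingness",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_spec_yaml",
    "write_spec_yaml",
    "bundled_spec",
]

COHORT_COLUMNS = ["id", "prior_falls_12m", "incident_falls", "exposure_years"]

#: Raw prior-fall counts inside the open-ended "5+" level are drawn as
#: 5 + Geometric(p) failures (support 5, 6, 7, ...; mean 5 + (1-p)/p).
#: Only the level enters the model, so this choice is cosmetic.
FIVE_PLUS_GEOMETRIC_P = 0.5


@dataclass
class CohortSpec:
    """Generative parameters for one synthetic cohort.

    Parameters
    ----------
    label : str
        Cohort name, used as id prefix and in output tables.
    n : int
        Number of participants.
    category_probs : sequence of 6 floats
        Probabilities of the prior-fall levels {0,1,2,3,4,5+}; sum to 1.
    baseline_rate : float
        Falls per person-year at the reference level (exp of the model
        intercept).
    rate_ratios : sequence of 6 floats
        Multiplicative effect per level; entry 0 (the reference) is 1.
    theta : float
        NB2 dispersion; the count variance is ``mu + mu**2 / theta``.
    exposure_model : {"fixed", "uniform"}
        Fixed follow-up of ``exposure_years`` years, or per-participant
        follow-up drawn uniformly from ``exposure_range``.
    exposure_years : float
        Follow-up length under the "fixed" model (years).
    exposure_range : (float, float)
        Lower/upper bound of follow-up under the "uniform" model.
    seed : int
        Seed for the cohort's private random stream.
    """

    label: str
    n: int
    category_probs: tuple[float, ...]
    baseline_rate: float
    rate_ratios: tuple[float, ...]
    theta: float
    exposure_model: str = "fixed"
    exposure_years: float = 1.0
    exposure_range: tuple[float, float] = (1.0 / 12.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.category_probs = tuple(float(p) for p in self.category_probs)
        self.rate_ratios = tuple(float(r) for r in self.rate_ratios)
        self.exposure_range = tuple(float(x) for x in self.exposure_range)

    def validate(self) -> None:
        """Raise ``ValueError`` naming the first violated invariant."""
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if len(self.category_probs) != 6:
            raise ValueError("category_probs must have 6 entries (levels 0..5+)")
        if any(p < 0 for p in self.category_probs):
            raise ValueError("category_probs must all be >= 0")
        if abs(sum(self.category_probs) - 1.0) > 1e-12:
            raise ValueError(
                f"category_probs must sum to 1 within 1e-12, got {sum(self.category_probs)!r}"
            )
        if len(self.rate_ratios) != 6:
            raise ValueError("rate_ratios must have 6 entries (levels 0..5+)")
        if self.rate_ratios[0] != 1.0:
            raise ValueError("rate_ratios[0] (reference level) must equal 1 exactly")
        if any(r <= 0 for r in self.rate_ratios):
            raise ValueError("rate_ratios must all be > 0")
        if self.baseline_rate <= 0:
            raise ValueError(f"baseline_rate must be > 0, got {self.baseline_rate}")
        if self.theta <= 0:
            raise ValueError(f"theta must be > 0, got {self.theta}")
        if self.exposure_model not in ("fixed", "uniform"):
            raise ValueError(f"exposure_model must be 'fixed' or 'uniform', got {self.exposure_model!r}")
        if self.exposure_model == "fixed" and self.exposure_years <= 0:
            raise ValueError("exposure_years must be > 0")
        if self.exposure_model == "uniform":
            lo, hi = self.exposure_range
            if not (0 < lo <= hi):
                raise ValueError(f"exposure_range must satisfy 0 < lo <= hi, got {self.exposure_range}")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate one cohort table from a :class:`CohortSpec`.

    Incident falls follow the NB2 gamma-Poisson construction: the
    participant's rate is ``baseline_rate * rate_ratio[level] * exposure``
    multiplied by a Gamma(shape=theta, mean=1) frailty, and the observed
    count is Poisson with that rate.  Fully reproducible from
    ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n

    level = rng.choice(6, size=n, p=np.asarray(spec.category_probs))
    prior = level.astype(np.int64)
    in_tail = level == 5
    if in_tail.any():
        # rng.geometric has support {1, 2, ...}; shift to failures-before-success
        prior[in_tail] = 5 + (rng.geometric(FIVE_PLUS_GEOMETRIC_P, size=int(in_tail.sum())) - 1)

    if spec.exposure_model == "fixed":
        exposure = np.full(n, float(spec.exposure_years))
    else:
        lo, hi = spec.exposure_range
        exposure = rng.uniform(lo, hi, size=n)

    mu = spec.baseline_rate * np.asarray(spec.rate_ratios)[level] * exposure
    frailty = rng.gamma(shape=spec.theta, scale=1.0 / spec.theta, size=n)
    falls = rng.poisson(mu * frailty)

    return pd.DataFrame(
        {
            "id": [f"{spec.label}-{i + 1:05d}" for i in range(n)],
            "prior_falls_12m": pd.array(prior, dtype="Int64"),
            "incident_falls": pd.array(falls, dtype="Int64"),
            "exposure_years": exposure,
        }
    )


def _cohort_seed(global_seed: int, index: int) -> int:
    """Stable per-cohort substream: SeedSequence(global_seed, spawn_key=(index,))."""
    state = np.random.SeedSequence(global_seed, spawn_key=(index,)).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


def default_specs(seed: int = 0) -> list[CohortSpec]:
    """The three bundled cohort specifications (GERICO-, SCT- and KFPS-like).

    Sample sizes, baseline rates, rate ratios and dispersions are the
    published per-cohort estimates; the SCT-like cohort uses variable
    follow-up (at least one month, at most a year), so its model needs a
    person-time offset.  The prior-fall level probabilities are not
    published; the defaults approximate the reported mean prior-fall
    counts (1.03 / 1.45 / 0.73 per cohort).
    """
    specs = [
        CohortSpec(
            label="gerico",
            n=630,
            category_probs=(0.577, 0.18, 0.10, 0.05, 0.03, 0.063),
            baseline_rate=0.43,
            rate_ratios=(1.0, 1.64, 1.13, 2.55, 2.33, 10.02),
            theta=1.06,
            exposure_model="fixed",
            exposure_years=1.0,
        ),
        CohortSpec(
            label="sct",
            n=370,
            category_probs=(0.432, 0.22, 0.13, 0.08, 0.05, 0.088),
            baseline_rate=0.83,
            rate_ratios=(1.0, 1.00, 1.07, 2.18, 3.09, 7.39),
            theta=0.66,
            exposure_model="uniform",
            exposure_range=(1.0 / 12.0, 1.0),
        ),
        CohortSpec(
            label="kfps",
            n=855,
            category_probs=(0.644, 0.18, 0.09, 0.035, 0.02, 0.031),
            baseline_rate=0.61,
            rate_ratios=(1.0, 1.46, 1.65, 2.98, 6.24, 7.40),
            theta=1.18,
            exposure_model="fixed",
            exposure_years=1.0,
        ),
    ]
    for i, spec in enumerate(specs):
        spec.seed = _cohort_seed(seed, i)
    return specs


def inject_missingness(table: pd.DataFrame, fraction: float, seed: int = 0) -> pd.DataFrame:
    """Set ``incident_falls`` missing for a fraction of rows (rounded to
    the nearest count), reproducibly.  Returns a copy."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    out = table.copy()
    n_missing = int(round(fraction * len(out)))
    if n_missing:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        rows = rng.choice(len(out), size=n_missing, replace=False)
        col = out.columns.get_loc("incident_falls")
        out.iloc[rows, col] = pd.NA
    return out


# ---------------------------------------------------------------------------
# I/O

def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"id": str, "prior_falls_12m": "Int64", "incident_falls": "Int64", "exposure_years": float},
    )
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    return df[COHORT_COLUMNS]


def write_spec_yaml(spec: CohortSpec, path: str | Path) -> None:
    d = asdict(spec)
    d["category_probs"] = list(spec.category_probs)
    d["rate_ratios"] = list(spec.rate_ratios)
    d["exposure_range"] = list(spec.exposure_range)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_spec_yaml(path: str | Path) -> CohortSpec:
    d = yaml.safe_load(Path(path).read_text())
    spec = CohortSpec(**d)
    spec.validate()
    return spec


def bundled_spec(name: str) -> CohortSpec:
    """Load one of the bundled specs by name ('gerico', 'sct', 'kfps')."""
    ref = importlib.resources.files("fallmeta") / "specs" / f"{name}.yaml"
    with importlib.resources.as_file(ref) as p:
        return read_spec_yaml(p)
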