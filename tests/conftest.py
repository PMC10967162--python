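import numpy as np
import pytest

from fallmeta import (
    CohortSpec,
    default_specs,
    filter_complete_cases,
    fit_negative_binomial,
    generate_cohort,
)


def make_spec(**overrides) -> CohortSpec:
    """A small, well-behaved cohort spec with overridable fields."""
    base = dict(
        label="toy",
        n=500,
        category_probs=(0.55, 0.18, 0.10, 0.06, 0.04, 0.07),
        baseline_rate=0.5,
        rate_ratios=(1.0, 1.5, 1.2, 2.5, 2.5, 8.0),
        theta=1.0,
        exposure_model="fixed",
        exposure_years=1.0,
        seed=42,
    )
    base.update(overrides)
    return CohortSpec(**base)


@pytest.fixture(scope="session")
def gerico_like_10k():
    """Large GERICO-like cohort for recovery/calibration checks."""
    spec = default_specs(seed=1)[0]
    spec.n = 10_000
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def fitted_cohorts():
    """The three default cohorts with their first-stage fits (seed 0)."""
    specs = default_specs(seed=0)
    tables, models = {}, []
    for spec in specs:
        t, _ = filter_complete_cases(generate_cohort(spec))
        tables[spec.label] = t
        models.append(
            fit_negative_binomial(t, use_offset=spec.exposure_model != "fixed",
                                  label=spec.label)
        )
    return specs, tables, models
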