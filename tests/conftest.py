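import numpy as np
import pytest

from ogtt_persona import (
    FitConfig,
    MealInput,
    generate_cohort,
    reference_constants,
    reference_parameters,
    selection_benchmark_priors,
)


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture(scope="session")
def ref_constants():
    return reference_constants()


@pytest.fixture(scope="session")
def meal():
    return MealInput(75.0)


@pytest.fixture(scope="session")
def small_cohort(ref_params, ref_constants):
    """Six noisy synthetic individuals with heterogeneity in k1,k5,k6,k8."""
    return generate_cohort(
        6, selection_benchmark_priors(ref_params), ref_constants, seed=3,
        reference=ref_params,
    )


@pytest.fixture(scope="session")
def quick_fit_config():
    return FitConfig(("k1", "k5", "k6", "k8"), n_starts=10, seed=0)


def product_model_refit(x, y, theta2_bounds=(1e-3, 1e3)):
    """Refit closure for a two-parameter toy model y = a*b*x whose
    parameters enter only as a product: fixing ``a`` and re-optimizing ``b``
    reproduces any product exactly (closed form), so both parameters are
    structurally non-identifiable."""

    def make(a_fixed):
        # least squares over b in closed form: b* = sum(a x y)/sum(a^2 x^2)
        def refit(value, warm):
            num = np.sum(value * x * y)
            den = np.sum(value**2 * x**2)
            b = np.clip(num / den, *theta2_bounds)
            r = value * b * x - y
            return float(r @ r), np.array([b])

        return refit

    return make
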