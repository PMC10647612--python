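"""Shared fixtures and first-principles oracles for the test suite."""

from __future__ import annotations

import math

import pytest

from sweetval import GeneratorConfig


# ---------------------------------------------------------------------------
# brute-force oracles: explicit sums, independent of the implementation
# ---------------------------------------------------------------------------

def brute_mean(xs):
    return sum(xs) / len(xs)


def brute_sd(xs):
    m = brute_mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def brute_rsd(xs):
    return 100.0 * brute_sd(xs) / brute_mean(xs)


def brute_ols(xy):
    """Normal-equation OLS: returns (slope, intercept, r_squared)."""
    n = len(xy)
    sx = sum(x for x, _ in xy)
    sy = sum(y for _, y in xy)
    sxx = sum(x * x for x, _ in xy)
    sxy = sum(x * y for x, y in xy)
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    sse = sum((y - slope * x - intercept) ** 2 for x, y in xy)
    sst = sum((y - sy / n) ** 2 for _, y in xy)
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    return slope, intercept, r2


# ---------------------------------------------------------------------------
# generator configurations
# ---------------------------------------------------------------------------

@pytest.fixture
def noiseless_config():
    """Exactly linear detector, no matrix effect, no recovery loss."""
    return GeneratorConfig(
        seed=0, noise_cv=0.0, rt_jitter_sd=0.0,
        me_factors={"beverage": 1.0, "yogurt": 1.0, "snack": 1.0},
        recovery_factors={"beverage": 1.0, "yogurt": 1.0, "snack": 1.0},
        survey_samples={},
    )


@pytest.fixture
def small_config():
    """One analyte, one matrix, no survey: fast repeated simulation."""
    return GeneratorConfig(
        seed=0, analytes=("rebaudioside A",), matrices=("beverage",),
        survey_samples={},
    )


def small_grid_config(seed, me, rec):
    return GeneratorConfig(
        seed=seed, analytes=("rebaudioside A",), matrices=("beverage",),
        me_factors={"beverage": me}, recovery_factors={"beverage": rec},
        survey_samples={},
    )
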