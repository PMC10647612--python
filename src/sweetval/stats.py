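"""Method-validation statistics for targeted LC-MS/MS quantitation.

The statistics implemented here are the standard single-laboratory
validation toolkit: retention-time agreement as a relative percent
difference, repeatability as %RSD, the Horwitz predicted RSD and the
HorRat ratio, spike recovery, the absolute matrix effect (ionization
suppression/enhancement), replicate-SD based detection and quantitation
limits (LOD/LOQ), and the lower/middle/upper-bound substitution rules
for left-censored concentration results.

All standard deviations are sample standard deviations (n-1 denominator).
Reported values are rounded half away from zero: 2 decimals for
concentrations and percentages, 3 for detection limits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "Matrix",
    "CensorScenario",
    "Censored",
    "AcceptanceBands",
    "RetentionPair",
    "MatrixEffectPair",
    "SpikeExperiment",
    "FoundSummary",
    "relative_percent_difference",
    "percent_rsd",
    "horwitz_prsd",
    "horrat",
    "recovery_percent",
    "absolute_matrix_effect",
    "lod_loq",
    "substitute_censored",
    "summarize_found",
    "evaluate_bands",
    "round_reported",
    "sample_sd",
    "mg_per_l_to_mass_fraction",
]

#: Recognised sample-matrix kinds.  "solvent" denotes neat standards.
Matrix = str
KNOWN_MATRICES = ("beverage", "yogurt", "snack", "solvent", "other")


class CensorScenario(str, Enum):
    """Substitution scenario for left-censored (sub-LOD/LOQ) results."""

    LOWER = "lower"
    MIDDLE = "middle"
    UPPER = "upper"


class Censored(str, Enum):
    """Status tags for non-detected results."""

    BELOW_LOD = "below_lod"
    BELOW_LOQ = "below_loq"


def round_reported(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching how results tables are printed.

    Goes through the shortest decimal repr of the float so that e.g. a
    computed mean of 2.075 (stored as 2.074999...) rounds up to 2.08.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def sample_sd(values: Sequence[float]) -> float:
    """Sample standard deviation (n-1 denominator)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InvalidInputError("sample SD requires at least 2 values")
    return float(np.std(arr, ddof=1))


def mg_per_l_to_mass_fraction(c_mg_per_l: float) -> float:
    """Convert mg L^-1 to a dimensionless mass fraction (density 1 assumed,
    so mg L^-1 == mg kg^-1 and the fraction is c * 1e-6)."""
    return c_mg_per_l * 1e-6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RetentionPair:
    """Two retention times (minutes) to compare for specificity."""

    rt_a: float
    rt_b: float

    def __post_init__(self) -> None:
        if not (self.rt_a > 0 and self.rt_b > 0):
            raise InvalidInputError("retention times must be positive")


@dataclass(frozen=True)
class MatrixEffectPair:
    """Paired detector responses of one analyte at one level: spiked into a
    sample matrix vs in pure solvent."""

    analyte: str
    matrix: Matrix
    level: float            # mg L^-1
    area_matrix: float      # detector response, arbitrary units
    area_solvent: float     # same units

    def __post_init__(self) -> None:
        if not math.isfinite(self.area_matrix) or not math.isfinite(self.area_solvent):
            raise InvalidInputError("areas must be finite")
        if self.area_solvent <= 0:
            raise InvalidInputError("solvent area must be positive")


@dataclass(frozen=True)
class SpikeExperiment:
    """Replicate measurements of one analyte spiked at one level into one
    matrix.

    ``replicate_values`` are usually back-calculated concentrations in
    mg L^-1 (``value_unit='mg_per_L'``) but may be raw areas.  ``n_report``
    is the number of replicate observations averaged when a result is
    reported, which enters the LOD/LOQ denominator.
    """

    analyte: str
    matrix: Matrix
    spike_level: float                  # mg L^-1, the added concentration
    replicate_values: tuple[float, ...]
    blank_mean: float = 0.0
    n_report: int = 1
    value_unit: str = "mg_per_L"

    def __post_init__(self) -> None:
        object.__setattr__(self, "replicate_values", tuple(self.replicate_values))
        if len(self.replicate_values) == 0:
            raise InvalidInputError("replicate_values must be non-empty")
        if self.spike_level <= 0:
            raise InvalidInputError("spike_level must be positive")
        if self.n_report < 1:
            raise InvalidInputError("n_report must be >= 1")
        vals = np.asarray(self.replicate_values, dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise InvalidInputError("replicate values must be finite and >= 0")

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_values))

    @property
    def sd(self) -> float:
        return sample_sd(self.replicate_values)


@dataclass(frozen=True)
class AcceptanceBands:
    """Acceptance criteria for each validation parameter.

    Defaults follow the usual single-laboratory guidance: R^2 > 0.99 for
    linearity with per-level %RSD under 15%, repeatability %RSD under 20%,
    recovery within 70-120%, matrix effect within 80-120%, HorRat below
    2.0 and retention-time %RPD below 5%.
    """

    r2_min: float = 0.99
    rsd_linearity_max: float = 15.0
    rsd_precision_max: float = 20.0
    recovery_range: tuple[float, float] = (70.0, 120.0)
    me_range: tuple[float, float] = (80.0, 120.0)
    horrat_max: float = 2.0
    rpd_max: float = 5.0

    def __post_init__(self) -> None:
        for name in ("r2_min", "rsd_linearity_max", "rsd_precision_max",
                     "horrat_max", "rpd_max"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        for name in ("recovery_range", "me_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise InvalidInputError(f"{name} must satisfy 0 < lower < upper")


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def relative_percent_difference(pair: RetentionPair | tuple[float, float]) -> float:
    """Relative percent difference between two retention times.

    %RPD = 100 * |RT1 - RT2| / ((RT1 + RT2) / 2).  Symmetric in its
    arguments and invariant to a common rescaling of both times; 0 iff
    the two times are equal; bounded above by 200 for positive inputs.
    """
    if not isinstance(pair, RetentionPair):
        pair = RetentionPair(*pair)
    mean = (pair.rt_a + pair.rt_b) / 2.0
    return 100.0 * abs(pair.rt_a - pair.rt_b) / mean


def percent_rsd(values: Sequence[float]) -> float:
    """Relative standard deviation in percent: 100 * SD / mean.

    Sample SD (n-1).  Requires at least two values and a nonzero mean;
    invariant under positive rescaling of all values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InvalidInputError("%RSD requires at least 2 values")
    mean = float(np.mean(arr))
    if mean == 0.0:
        raise InvalidInputError("%RSD undefined for zero mean")
    return 100.0 * float(np.std(arr, ddof=1)) / mean


def horwitz_prsd(c_mass_fraction: float) -> float:
    """Horwitz predicted relative standard deviation, in percent.

    PRSD = 2^(1 - 0.5 * log10 C) with C the analyte concentration as a
    dimensionless mass fraction (0 < C <= 1).  Strictly decreasing in C:
    PRSD(1) = 2, PRSD(0.01) = 4, PRSD(1e-4) = 8.
    """
    if not (0.0 < c_mass_fraction <= 1.0):
        raise InvalidInputError("mass fraction must be in (0, 1]")
    return float(2.0 ** (1.0 - 0.5 * math.log10(c_mass_fraction)))


def horrat(rsd: float, c_mass_fraction: float) -> float:
    """Horwitz ratio: observed %RSD divided by the Horwitz PRSD at the
    same mass fraction.  Values below 2.0 are conventionally acceptable."""
    if rsd < 0:
        raise InvalidInputError("%RSD must be >= 0")
    return rsd / horwitz_prsd(c_mass_fraction)


def recovery_percent(exp: SpikeExperiment) -> float:
    """Spike recovery in percent: 100 * (mean(spiked) - mean(blank)) / added."""
    return 100.0 * (exp.mean - exp.blank_mean) / exp.spike_level


def absolute_matrix_effect(pair: MatrixEffectPair) -> float:
    """Absolute matrix effect in percent: 100 * signal in spiked matrix /
    signal in solvent.  100 means no effect; below 100 is ionization
    suppression, above 100 enhancement."""
    return 100.0 * pair.area_matrix / pair.area_solvent


def lod_loq(exp: SpikeExperiment, *, sqrt_n: bool = True) -> tuple[float, float]:
    """Detection and quantitation limits from low-level replicates.

    S0 is the sample SD of the replicates at the lowest spiked level;
    S0' = S0 / sqrt(n_report) where n_report is the number of replicate
    observations averaged when reporting a result.  LOD = 3 * S0',
    LOQ = 10 * S0', so LOQ / LOD = 10/3 identically before rounding.

    ``sqrt_n=False`` divides by n_report instead of its square root.
    Returned in the same units as the replicates, unrounded.
    """
    if len(exp.replicate_values) < 2:
        raise InvalidInputError("LOD/LOQ requires at least 2 replicates")
    s0 = exp.sd
    denom = math.sqrt(exp.n_report) if sqrt_n else float(exp.n_report)
    s0_prime = s0 / denom
    return 3.0 * s0_prime, 10.0 * s0_prime


def substitute_censored(
    value: float | Censored,
    lod: float,
    loq: float,
    scenario: CensorScenario | str,
) -> float:
    """Apply a left-censoring substitution rule to one result.

    Detected values (numbers) pass through unchanged.  A result below the
    LOD substitutes 0 / LOD/2 / LOD and a result below the LOQ substitutes
    0 / LOQ/2 / LOQ under the lower / middle / upper-bound scenario.
    """
    if lod > loq:
        raise InvalidInputError("LOD must not exceed LOQ")
    scenario = CensorScenario(scenario)
    if not isinstance(value, Censored):
        return float(value)
    limit = lod if value is Censored.BELOW_LOD else loq
    if scenario is CensorScenario.LOWER:
        return 0.0
    if scenario is CensorScenario.MIDDLE:
        return 0.5 * limit
    return limit


@dataclass(frozen=True)
class FoundSummary:
    """Summary over detected samples: mean +/- SD (min-max), n."""

    mean: float
    sd: float | None
    min: float
    max: float
    n: int

    def render(self) -> str:
        if self.sd is None:
            return f"{self.mean:.2f}({self.min:.2f}-{self.max:.2f})"
        return f"{self.mean:.2f} ± {self.sd:.2f}({self.min:.2f}-{self.max:.2f})"


def summarize_found(values: Sequence[float]) -> FoundSummary:
    """Mean, SD, min, max and count over detected concentrations.

    SD is reported only for n >= 2 (sample SD); all values are rounded
    half away from zero to 2 decimals, the convention of concentration
    summary tables.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("summary of detected values requires n >= 1")
    sd = round_reported(float(np.std(arr, ddof=1)), 2) if arr.size >= 2 else None
    return FoundSummary(
        mean=round_reported(float(np.mean(arr)), 2),
        sd=sd,
        min=round_reported(float(np.min(arr)), 2),
        max=round_reported(float(np.max(arr)), 2),
        n=int(arr.size),
    )


# ---------------------------------------------------------------------------
# acceptance-band evaluation
# ---------------------------------------------------------------------------

_NOT_EVALUATED = {"pass": None, "value": None, "evaluated": False}


def _verdict(value: float, ok: bool) -> dict:
    return {"pass": bool(ok), "value": float(value), "evaluated": True}


def evaluate_bands(report_values: dict, bands: AcceptanceBands | None = None) -> dict:
    """Evaluate validation results against acceptance bands.

    ``report_values`` may contain any of: ``rpd`` (%), ``r_squared``,
    ``linearity_rsd`` (max per-level %RSD), ``precision_rsd`` (%),
    ``recovery`` (%), ``matrix_effect`` (%), ``horrat``.  Each present
    key yields a deterministic pass/fail verdict carrying the value;
    missing keys are reported as not evaluated.
    """
    bands = bands or AcceptanceBands()
    checks = {
        "rpd": lambda v: v < bands.rpd_max,
        "r_squared": lambda v: v > bands.r2_min,
        "linearity_rsd": lambda v: v < bands.rsd_linearity_max,
        "precision_rsd": lambda v: v < bands.rsd_precision_max,
        "recovery": lambda v: bands.recovery_range[0] <= v <= bands.recovery_range[1],
        "matrix_effect": lambda v: bands.me_range[0] <= v <= bands.me_range[1],
        "horrat": lambda v: v < bands.horrat_max,
    }
    out: dict[str, dict] = {}
    for key, check in checks.items():
        v = report_values.get(key)
        out[key] = dict(_NOT_EVALUATED) if v is None else _verdict(v, check(v))
    return out
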