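"""Linear calibration: external (solvent) and matrix-matched fits.

Calibration standards at 3+ levels, each injected in replicate, are fit by
unweighted ordinary least squares on the individual (level, response)
points (replicates are not averaged, so per-level %RSD is preserved).
The fit reports slope, intercept, R^2 (coefficient of determination) and
per-level response %RSD; a series is judged linear when R^2 exceeds the
band minimum and every level's %RSD is under the linearity limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _scipy_stats

from .errors import InvalidInputError
from .stats import AcceptanceBands, percent_rsd

__all__ = ["CalibrationSeries", "CalibrationFit", "fit_calibration", "back_calculate"]


@dataclass(frozen=True)
class CalibrationSeries:
    """Level/response pairs for one analyte in one matrix.

    ``points`` maps each concentration level (mg L^-1) to its replicate
    detector responses (area units).  ``matrix='solvent'`` denotes an
    external calibration with neat standards.
    """

    analyte: str
    matrix: str
    points: tuple[tuple[float, tuple[float, ...]], ...]

    def __post_init__(self) -> None:
        pts = tuple((float(lvl), tuple(float(r) for r in reps))
                    for lvl, reps in self.points)
        object.__setattr__(self, "points", pts)
        levels = [lvl for lvl, _ in pts]
        if len(set(levels)) < 3:
            raise InvalidInputError("calibration requires >= 3 distinct levels")
        if any(lvl <= 0 for lvl in levels):
            raise InvalidInputError("calibration levels must be positive")
        if any(len(reps) == 0 for _, reps in pts):
            raise InvalidInputError("each level needs >= 1 response")

    @property
    def levels(self) -> tuple[float, ...]:
        return tuple(lvl for lvl, _ in self.points)

    def flatten(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.array([lvl for lvl, reps in self.points for _ in reps])
        y = np.array([r for _, reps in self.points for r in reps])
        return x, y


@dataclass(frozen=True)
class CalibrationFit:
    """Result of a linear calibration fit: y = slope * x + intercept."""

    analyte: str
    matrix: str
    slope: float            # area per mg L^-1
    intercept: float        # area
    r_squared: float
    level_rsd: dict[float, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise InvalidInputError("slope must be finite")
        if not (-1e-12 <= self.r_squared <= 1.0 + 1e-12):
            raise InvalidInputError("R^2 must lie in [0, 1]")

    def is_linear(self, bands: AcceptanceBands | None = None) -> bool:
        bands = bands or AcceptanceBands()
        rsds = [v for v in self.level_rsd.values() if v is not None]
        return self.r_squared > bands.r2_min and all(
            v < bands.rsd_linearity_max for v in rsds
        )

    def equation(self) -> str:
        sign = "+" if self.intercept >= 0 else "-"
        return f"y = {self.slope:.6g}x {sign} {abs(self.intercept):.6g}"


def fit_calibration(series: CalibrationSeries,
                    weighting: str | None = None) -> CalibrationFit:
    """Least-squares fit of response on concentration.

    Unweighted OLS by default; ``weighting='1/x'`` applies inverse-
    concentration weights.  Replicates enter as individual points.  R^2
    is 1 - SSE/SST, which for OLS with an intercept equals the squared
    Pearson correlation of fitted and observed responses.  Per-level
    %RSD is computed over the replicate responses at each level (absent
    for single-replicate levels or zero mean response).
    """
    x, y = series.flatten()
    if np.var(x) == 0:
        raise InvalidInputError("levels have zero variance")
    if weighting is None:
        res = _scipy_stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
    elif weighting == "1/x":
        slope, intercept = (float(v) for v in
                            np.polyfit(x, y, 1, w=1.0 / np.sqrt(x)))
    else:
        raise InvalidInputError(f"unknown weighting {weighting!r}")
    sse = float(np.sum((y - (slope * x + intercept)) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if sst == 0 else 1.0 - sse / sst
    r2 = min(max(r2, 0.0), 1.0)
    level_rsd: dict[float, float | None] = {}
    for lvl, reps in series.points:
        if len(reps) >= 2 and np.mean(reps) != 0:
            level_rsd[lvl] = percent_rsd(reps)
        else:
            level_rsd[lvl] = None
    return CalibrationFit(
        analyte=series.analyte, matrix=series.matrix,
        slope=slope, intercept=intercept, r_squared=r2, level_rsd=level_rsd,
    )


def back_calculate(fit: CalibrationFit, response: float) -> float:
    """Concentration from a detector response: (response - intercept) / slope.

    Negative results are returned as-is; downstream censoring decides how
    to treat them.
    """
    if fit.slope == 0:
        raise InvalidInputError("cannot back-calculate with zero slope")
    return (response - fit.intercept) / fit.slope
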