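"""Seeded generator of instrument-like validation and survey tables.

Emulates the detector response of a triple-quadrupole SRM assay so every
downstream stage (identification, calibration, validation statistics,
survey summaries) can be exercised without instrument data:

* linear response with intercept:  y = slope * C + intercept
* per-matrix multiplicative ionization suppression/enhancement
  (``me_factor``; applied to the whole detected signal)
* per-matrix multiplicative recovery loss through sample preparation
  (``recovery_factor``; applied to the concentration reaching the
  detector)
* proportional (heteroscedastic) noise with coefficient of variation
  ``noise_cv``
* retention-time jitter around each analyte's reference RT.

A spiked-matrix replicate therefore responds as

    y = me * (slope * C * rec + intercept) * (1 + eps),  eps ~ N(0, cv)

while solvent standards omit both factors and post-extraction matrix
standards (matrix-matched calibration, matrix-effect experiments) carry
``me`` but not ``rec``.  Blank injections emit zero-mean noise only.

The experimental design defaults mirror a single-laboratory validation:
nine analytes, three food matrices, calibration at 0.2/0.3/0.4/0.5/0.8/1.0
mg L^-1 in triplicate, spikes at 0.2/0.5/1.0 mg L^-1 in seven replicates.
Output is byte-identical for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .transitions import ANALYTES, DEFAULT_TRANSITIONS, REFERENCE_RT

__all__ = ["GeneratorConfig", "generate_validation_dataset", "generate_peak_list"]

LONG_COLUMNS = [
    "analyte", "matrix", "role", "level_mg_per_L", "replicate",
    "sample", "value", "value_unit", "rt_min",
]

#: Plausible detector parameters (area per mg L^-1, area) for the nine
#: analytes on a solvent calibration of an electrospray triple quadrupole.
DEFAULT_SLOPES = {
    "rebaudioside A": 79846.0,
    "rebaudioside B": 23115.0,
    "rebaudioside C": 79357.0,
    "rebaudioside D": 26518.0,
    "rebaudioside F": 76473.0,
    "rubusoside": 29488.0,
    "dulcoside A": 22672.0,
    "stevioside": 48117.0,
    "steviolbioside": 32307.0,
}
DEFAULT_INTERCEPTS = {
    "rebaudioside A": 3076.4,
    "rebaudioside B": 1642.3,
    "rebaudioside C": 4082.3,
    "rebaudioside D": 1389.7,
    "rebaudioside F": 4149.0,
    "rubusoside": 1149.0,
    "dulcoside A": 2313.8,
    "stevioside": 4517.9,
    "steviolbioside": 3114.2,
}

#: Default per-matrix suppression/enhancement and recovery factors,
#: magnitudes typical of beverage / dairy / snack extracts (dairy shows
#: the strongest ion suppression, snacks mild enhancement).
DEFAULT_ME_FACTORS = {"beverage": 1.02, "yogurt": 0.85, "snack": 1.05}
DEFAULT_RECOVERY_FACTORS = {"beverage": 0.95, "yogurt": 0.88, "snack": 1.00}

DEFAULT_SURVEY_SAMPLES = {"beverage": 20, "yogurt": 10, "snack": 8}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic instrument and experimental design."""

    seed: int = 0
    analytes: tuple[str, ...] = ANALYTES
    matrices: tuple[str, ...] = ("beverage", "yogurt", "snack")
    calibration_levels: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.8, 1.0)
    spike_levels: tuple[float, ...] = (0.2, 0.5, 1.0)
    spike_replicates: int = 7
    calibration_replicates: int = 3
    slopes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SLOPES))
    intercepts: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_INTERCEPTS))
    me_factors: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ME_FACTORS))
    recovery_factors: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RECOVERY_FACTORS))
    noise_cv: float = 0.03          # proportional noise CV
    noise_floor_sd: float = 0.0     # additive area-noise floor (off by default)
    rt_jitter_sd: float = 0.01      # minutes
    blank_replicates: int = 3
    # survey design
    survey_samples: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SURVEY_SAMPLES))
    survey_replicates: int = 3
    survey_detect_prob: float = 0.5
    survey_lognormal_mu: float = -0.7   # log mg L^-1; median ~0.5 mg L^-1
    survey_lognormal_sigma: float = 0.6

    def __post_init__(self) -> None:
        if self.noise_cv < 0 or self.noise_floor_sd < 0:
            raise ConfigurationError("noise parameters must be >= 0")
        if self.rt_jitter_sd < 0:
            raise ConfigurationError("rt_jitter_sd must be >= 0")
        for m in self.matrices:
            if self.me_factor(m) <= 0 or self.recovery_factor(m) <= 0:
                raise ConfigurationError(
                    f"me/recovery factors for {m!r} must be positive")
        for a in self.analytes:
            if a not in self.slopes or a not in self.intercepts:
                raise ConfigurationError(f"no detector parameters for {a!r}")
        if self.spike_replicates < 2 or self.calibration_replicates < 1:
            raise ConfigurationError("replicate counts too small")

    def me_factor(self, matrix: str) -> float:
        return self.me_factors.get(matrix, 1.0)

    def recovery_factor(self, matrix: str) -> float:
        return self.recovery_factors.get(matrix, 1.0)

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


def _noise(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    return 1.0 + rng.normal(0.0, cv, size=n) if cv > 0 else np.ones(n)


def _rt(rng: np.random.Generator, analyte: str, sd: float, n: int) -> np.ndarray:
    ref = REFERENCE_RT.get(analyte, 5.0)
    return ref + (rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n))


def generate_validation_dataset(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the long-format observation table for a full validation.

    Rows carry roles: ``calibration`` (solvent and matrix-matched),
    ``spike``, ``blank``, ``me_solvent``/``me_matrix`` (matrix-effect
    pairs) and ``sample`` (survey specimens measured in replicate).
    Areas are in arbitrary detector units (``value_unit='area'``).
    """
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []

    def emit(analyte, matrix, role, level, replicate, sample, value, rt):
        if config.noise_floor_sd > 0 and role != "blank":
            value = value + rng.normal(0.0, config.noise_floor_sd)
        rows.append(dict(
            analyte=analyte, matrix=matrix, role=role,
            level_mg_per_L=level, replicate=replicate, sample=sample,
            value=float(value), value_unit="area", rt_min=rt,
        ))

    for analyte in config.analytes:
        a = config.slopes[analyte]
        b = config.intercepts[analyte]

        # solvent (external) calibration
        for level in config.calibration_levels:
            eps = _noise(rng, config.noise_cv, config.calibration_replicates)
            rts = _rt(rng, analyte, config.rt_jitter_sd, config.calibration_replicates)
            for r, (e, rt) in enumerate(zip(eps, rts), start=1):
                emit(analyte, "solvent", "calibration", level, r, None,
                     (a * level + b) * e, float(rt))

        for matrix in config.matrices:
            me = config.me_factor(matrix)
            rec = config.recovery_factor(matrix)

            # matrix-matched calibration (post-extraction standards)
            for level in config.calibration_levels:
                eps = _noise(rng, config.noise_cv, config.calibration_replicates)
                rts = _rt(rng, analyte, config.rt_jitter_sd,
                          config.calibration_replicates)
                for r, (e, rt) in enumerate(zip(eps, rts), start=1):
                    emit(analyte, matrix, "calibration", level, r, None,
                         me * (a * level + b) * e, float(rt))

            # matrix-effect pairs (same levels/replicates in both arms)
            for level in config.spike_levels:
                eps_m = _noise(rng, config.noise_cv, config.spike_replicates)
                eps_s = _noise(rng, config.noise_cv, config.spike_replicates)
                for r in range(1, config.spike_replicates + 1):
                    emit(analyte, matrix, "me_matrix", level, r, None,
                         me * (a * level + b) * eps_m[r - 1], None)
                    emit(analyte, matrix, "me_solvent", level, r, None,
                         (a * level + b) * eps_s[r - 1], None)

            # spikes through the whole procedure (recovery loss applies)
            for level in config.spike_levels:
                eps = _noise(rng, config.noise_cv, config.spike_replicates)
                rts = _rt(rng, analyte, config.rt_jitter_sd, config.spike_replicates)
                for r, (e, rt) in enumerate(zip(eps, rts), start=1):
                    emit(analyte, matrix, "spike", level, r, None,
                         me * (a * level * rec + b) * e, float(rt))

            # blank injections: zero-mean noise only
            blank_sd = config.noise_cv * b
            for r in range(1, config.blank_replicates + 1):
                emit(analyte, matrix, "blank", None, r, None,
                     rng.normal(0.0, blank_sd) if blank_sd > 0 else 0.0, None)

    # survey specimens
    for matrix in config.matrices:
        me = config.me_factor(matrix)
        rec = config.recovery_factor(matrix)
        n_samples = config.survey_samples.get(matrix, 0)
        for s in range(1, n_samples + 1):
            sample_id = f"{matrix}-{s:02d}"
            for analyte in config.analytes:
                a = config.slopes[analyte]
                b = config.intercepts[analyte]
                present = rng.random() < config.survey_detect_prob
                conc = float(rng.lognormal(config.survey_lognormal_mu,
                                           config.survey_lognormal_sigma)) if present else 0.0
                eps = _noise(rng, config.noise_cv, config.survey_replicates)
                rts = _rt(rng, analyte, config.rt_jitter_sd, config.survey_replicates)
                for r, (e, rt) in enumerate(zip(eps, rts), start=1):
                    emit(analyte, matrix, "sample", None, r, sample_id,
                         me * (a * conc * rec + b) * e, float(rt))

    return pd.DataFrame(rows, columns=LONG_COLUMNS)


def generate_peak_list(
    config: GeneratorConfig,
    n_samples: int = 3,
    include_qualifiers: bool = True,
    n_decoys: int = 0,
) -> pd.DataFrame:
    """Generate an SRM peak-observation table for identification tests.

    One quantifier (and optionally one qualifier) peak per analyte per
    sample, with retention-time jitter; optional decoy peaks at m/z
    values offset from every transition so they can never match.
    Columns: sample, precursor_mz, product_mz, rt_min, area.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for s in range(1, n_samples + 1):
        sample_id = f"sample-{s:02d}"
        for rec in DEFAULT_TRANSITIONS:
            if rec.analyte not in config.analytes:
                continue
            a = config.slopes[rec.analyte]
            b = config.intercepts[rec.analyte]
            rt = float(_rt(rng, rec.analyte, config.rt_jitter_sd, 1)[0])
            area = float((a * 0.5 + b) * _noise(rng, config.noise_cv, 1)[0])
            rows.append(dict(sample=sample_id, precursor_mz=rec.precursor_mz,
                             product_mz=rec.quantifier_mz, rt_min=rt, area=area))
            if include_qualifiers:
                rows.append(dict(sample=sample_id, precursor_mz=rec.precursor_mz,
                                 product_mz=rec.qualifier_mzs[0], rt_min=rt,
                                 area=0.4 * area))
        for d in range(n_decoys):
            # offsets keep decoys > 0.5 m/z away from every real transition
            rows.append(dict(sample=sample_id, precursor_mz=500.0 + 17.3 * d,
                             product_mz=222.2 + 5.1 * d,
                             rt_min=float(rng.uniform(1.0, 12.0)),
                             area=float(rng.uniform(1e3, 1e5))))
    return pd.DataFrame(rows, columns=["sample", "precursor_mz", "product_mz",
                                       "rt_min", "area"])
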