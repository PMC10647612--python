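"""Steviol-equivalent conversion and per-sample aggregation.

Steviol glycosides share the steviol aglycone but differ in molecular
weight, so amounts are made comparable by rescaling each glycoside
concentration with a conversion factor:

    [SE] = CF * [SG]

The shipped default factors are the molecular-weight ratio
MW(steviol) / MW(glycoside) — the JECFA convention — computed from the
glycoside formulas; users may override them with their own table
(CSV columns: analyte, cf).
"""

from __future__ import annotations

import re
from typing import Mapping

import pandas as pd

from .errors import ConfigurationError, InvalidInputError
from .stats import Censored, CensorScenario, substitute_censored
from .transitions import FORMULAS

__all__ = [
    "molecular_weight",
    "default_conversion_factors",
    "load_conversion_factors",
    "steviol_equivalent",
    "aggregate_sample",
    "STEVIOL_FORMULA",
]

# IUPAC 2021 standard atomic weights (abridged)
_ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999}

STEVIOL_FORMULA = "C20H30O3"

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def molecular_weight(formula: str) -> float:
    """Average molecular weight from a Hill-style formula like C44H70O23."""
    mw = 0.0
    consumed = 0
    for m in _FORMULA_RE.finditer(formula):
        if not m.group(0):
            continue
        el, count = m.group(1), int(m.group(2) or 1)
        if el not in _ATOMIC_MASS:
            raise ConfigurationError(f"unknown element {el!r} in formula {formula!r}")
        mw += _ATOMIC_MASS[el] * count
        consumed += len(m.group(0))
    if consumed != len(formula) or mw == 0.0:
        raise ConfigurationError(f"cannot parse formula {formula!r}")
    return mw


def default_conversion_factors() -> dict[str, float]:
    """Molecular-weight-ratio conversion factors for the nine glycosides."""
    steviol_mw = molecular_weight(STEVIOL_FORMULA)
    return {name: steviol_mw / molecular_weight(f) for name, f in FORMULAS.items()}


def load_conversion_factors(path) -> dict[str, float]:
    """Read a conversion-factor table (CSV columns: analyte, cf)."""
    df = pd.read_csv(path)
    missing = {"analyte", "cf"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"CF table missing columns: {sorted(missing)}")
    cfs = dict(zip(df["analyte"], df["cf"].astype(float)))
    bad = [a for a, cf in cfs.items() if not cf > 0]
    if bad:
        raise ConfigurationError(f"non-positive CF for: {bad}")
    return cfs


def steviol_equivalent(conc: float, cf: float) -> float:
    """Rescale one glycoside concentration to steviol equivalents."""
    if conc < 0:
        raise InvalidInputError("concentration must be >= 0")
    if cf <= 0:
        raise InvalidInputError("conversion factor must be positive")
    return cf * conc


def _lookup_cf(cf_table: Mapping[str, float], analyte: str) -> float:
    try:
        return cf_table[analyte]
    except KeyError:
        raise ConfigurationError(
            f"no conversion factor for analyte {analyte!r}"
        ) from None


def aggregate_sample(
    concentrations: Mapping[str, float | Censored],
    cf_table: Mapping[str, float],
    scenario: CensorScenario | str = CensorScenario.MIDDLE,
    lod: Mapping[str, float] | None = None,
    loq: Mapping[str, float] | None = None,
) -> tuple[float, dict[str, float]]:
    """Per-sample steviol-equivalent total and per-analyte SE values.

    Left-censored entries (``Censored.BELOW_LOD`` / ``BELOW_LOQ``) are
    substituted according to ``scenario`` using the per-analyte LOD/LOQ
    maps before conversion.  Totals satisfy lower <= middle <= upper.
    """
    scenario = CensorScenario(scenario)
    lod = lod or {}
    loq = loq or {}
    per_analyte: dict[str, float] = {}
    for analyte, value in concentrations.items():
        cf = _lookup_cf(cf_table, analyte)
        if isinstance(value, Censored):
            a_lod = lod.get(analyte, 0.0)
            a_loq = loq.get(analyte, a_lod)
            conc = substitute_censored(value, a_lod, a_loq, scenario)
        else:
            conc = max(float(value), 0.0)
        per_analyte[analyte] = steviol_equivalent(conc, cf)
    return sum(per_analyte.values()), per_analyte
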