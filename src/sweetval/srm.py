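"""SRM peak-to-analyte assignment and identity confirmation.

A peak observation (precursor m/z, product m/z, retention time, area) is
assigned to an analyte when both m/z values match a transition within an
m/z tolerance and the retention time agrees with the analyte's reference
within a relative-percent-difference window (default 5%).  Isobaric pairs
(stevioside / rebaudioside B; rubusoside / steviolbioside) are resolved
by retention time alone.  Identity is confirmed when, besides the
quantifier transition, at least one qualifier transition is observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import InvalidInputError
from .stats import relative_percent_difference

__all__ = [
    "TransitionRecord",
    "PeakObservation",
    "Assignment",
    "match_peak",
    "assign_peaks",
    "confirm_identity",
]

DEFAULT_MZ_TOL = 0.5          # unit-resolution triple quadrupole
DEFAULT_RT_TOL_PERCENT = 5.0  # max %RPD of observed vs reference RT


@dataclass(frozen=True)
class TransitionRecord:
    """One analyte's SRM definition: precursor, quantifier and qualifier
    product ions, collision energies and reference retention time."""

    analyte: str
    formula: str
    reference_rt: float                 # minutes
    precursor_mz: float
    quantifier_mz: float
    qualifier_mzs: tuple[float, ...] = ()
    collision_energies: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "qualifier_mzs", tuple(self.qualifier_mzs))
        object.__setattr__(self, "collision_energies", tuple(self.collision_energies))
        if self.reference_rt <= 0:
            raise InvalidInputError("reference RT must be positive")
        products = (self.quantifier_mz, *self.qualifier_mzs)
        if any(p >= self.precursor_mz for p in products):
            raise InvalidInputError("precursor m/z must exceed all product m/z")

    @property
    def product_mzs(self) -> tuple[float, ...]:
        return (self.quantifier_mz, *self.qualifier_mzs)


@dataclass(frozen=True)
class PeakObservation:
    """One integrated SRM peak from the instrument's peak list."""

    sample: str
    precursor_mz: float
    product_mz: float
    rt: float       # minutes
    area: float     # detector units

    def __post_init__(self) -> None:
        if self.area < 0:
            raise InvalidInputError("peak area must be >= 0")
        if not (0 < self.rt <= 13.0):
            raise InvalidInputError("RT must lie within the 13-min run")


@dataclass(frozen=True)
class Assignment:
    """A peak assigned to an analyte through one of its transitions."""

    peak: PeakObservation
    analyte: str
    role: str           # "quantifier" or "qualifier"
    rt_rpd: float       # %RPD of observed vs reference RT
    mz_error: float     # |observed - transition| precursor m/z


def _match_products(peak: PeakObservation, rec: TransitionRecord, mz_tol: float) -> str | None:
    if abs(peak.product_mz - rec.quantifier_mz) <= mz_tol:
        return "quantifier"
    if any(abs(peak.product_mz - q) <= mz_tol for q in rec.qualifier_mzs):
        return "qualifier"
    return None


def match_peak(
    peak: PeakObservation,
    table: Sequence[TransitionRecord],
    mz_tol: float = DEFAULT_MZ_TOL,
    rt_tol_percent: float = DEFAULT_RT_TOL_PERCENT,
) -> Assignment | None:
    """Assign one peak to the best-matching analyte, or None.

    A candidate must match the precursor m/z and at least one product m/z
    within ``mz_tol`` and have RT %RPD to the reference within
    ``rt_tol_percent``.  Ties break on smallest RT %RPD, then smallest
    precursor m/z error, then analyte name (for determinism).
    """
    if len(table) == 0:
        raise InvalidInputError("transition table is empty")
    if mz_tol <= 0:
        raise InvalidInputError("mz_tol must be positive")
    candidates: list[Assignment] = []
    for rec in table:
        mz_err = abs(peak.precursor_mz - rec.precursor_mz)
        if mz_err > mz_tol:
            continue
        role = _match_products(peak, rec, mz_tol)
        if role is None:
            continue
        rpd = relative_percent_difference((peak.rt, rec.reference_rt))
        if rpd > rt_tol_percent:
            continue
        candidates.append(Assignment(peak, rec.analyte, role, rpd, mz_err))
    if not candidates:
        return None
    return min(candidates, key=lambda a: (a.rt_rpd, a.mz_error, a.analyte))


def assign_peaks(
    peaks: Iterable[PeakObservation],
    table: Sequence[TransitionRecord],
    mz_tol: float = DEFAULT_MZ_TOL,
    rt_tol_percent: float = DEFAULT_RT_TOL_PERCENT,
) -> list[Assignment]:
    """Assign every peak independently; unmatched peaks are dropped.

    Per-peak matching makes the result independent of input order up to
    the order of the returned list, which follows the input.
    """
    out = []
    for p in peaks:
        a = match_peak(p, table, mz_tol, rt_tol_percent)
        if a is not None:
            out.append(a)
    return out


@dataclass(frozen=True)
class Confirmation:
    analyte: str
    sample: str
    confirmed: bool
    quantifier_area: float | None
    n_qualifiers: int
    warning: str | None = None


def confirm_identity(assignments: Sequence[Assignment]) -> Confirmation:
    """Confirm one analyte in one sample from its assigned peaks.

    Quantitation uses the quantifier transition (the most intense ion
    pair); identity is confirmed when at least one qualifier transition
    was also observed.  A quantifier without qualifiers remains
    quantifiable but carries a warning.
    """
    if not assignments:
        raise InvalidInputError("no assignments to confirm")
    analytes = {a.analyte for a in assignments}
    samples = {a.peak.sample for a in assignments}
    if len(analytes) != 1 or len(samples) != 1:
        raise InvalidInputError("confirm_identity expects one analyte in one sample")
    quant = [a for a in assignments if a.role == "quantifier"]
    if not quant:
        raise InvalidInputError("no quantifier assignment present")
    n_qual = sum(1 for a in assignments if a.role == "qualifier")
    confirmed = n_qual >= 1
    return Confirmation(
        analyte=analytes.pop(),
        sample=samples.pop(),
        confirmed=confirmed,
        quantifier_area=quant[0].peak.area,
        n_qualifiers=n_qual,
        warning=None if confirmed else "quantifier only: identity unconfirmed",
    )
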