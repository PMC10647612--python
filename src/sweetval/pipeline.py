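"""Orchestration: identification -> calibration -> quantitation ->
validation statistics -> steviol equivalents -> report.

``run_validation`` consumes the long-format observation table and
produces, per analyte x matrix: retention-time agreement (%RPD),
matrix-matched linearity (R^2, per-level %RSD), matrix effect per level
(mean +/- SD), recovery / repeatability %RSD / HorRat per spike level,
LOD/LOQ (native units and steviol equivalents), and a pass/fail verdict
against the acceptance bands.  ``run_survey`` quantifies survey
specimens against the fits, applies left-censoring substitution and
summarizes detected samples per analyte and food group.

Spiked samples are quantified against the matrix-matched calibration
when one is present (it compensates ionization suppression/enhancement),
falling back to the external solvent calibration otherwise.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationFit, CalibrationSeries, back_calculate, fit_calibration
from .equivalents import aggregate_sample, default_conversion_factors
from .errors import ConfigurationError, InvalidInputError
from .io import markdown_table
from .stats import (
    AcceptanceBands,
    Censored,
    CensorScenario,
    MatrixEffectPair,
    SpikeExperiment,
    absolute_matrix_effect,
    evaluate_bands,
    horrat,
    lod_loq,
    mg_per_l_to_mass_fraction,
    percent_rsd,
    recovery_percent,
    relative_percent_difference,
    round_reported,
    summarize_found,
)

log = logging.getLogger("sweetval")

__all__ = ["ValidationReport", "run_validation", "run_survey", "build_series"]


@dataclass
class ValidationReport:
    """Per-analyte, per-matrix validation results plus run metadata."""

    results: dict = field(default_factory=dict)   # analyte -> matrix -> dict
    fits: dict = field(default_factory=dict)      # (analyte, matrix) -> CalibrationFit
    metadata: dict = field(default_factory=dict)

    def all_pass(self) -> bool:
        for matrices in self.results.values():
            for res in matrices.values():
                for verdict in res["verdicts"].values():
                    if verdict["evaluated"] and not verdict["pass"]:
                        return False
        return True

    def to_dict(self) -> dict:
        return {"metadata": self.metadata, "results": self.results}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_markdown(self) -> str:
        parts = ["# Validation report\n"]
        meta = ", ".join(f"{k}={v}" for k, v in sorted(self.metadata.items()))
        parts.append(f"_{meta}_\n")
        header = ["analyte", "matrix", "RPD %", "R2", "recovery % (by level)",
                  "RSD % (by level)", "HorRat max", "LOD", "LOQ", "pass"]
        rows = []
        for analyte, matrices in sorted(self.results.items()):
            for matrix, res in sorted(matrices.items()):
                ok = all(v["pass"] for v in res["verdicts"].values() if v["evaluated"])
                rows.append([
                    analyte, matrix, res.get("rpd"), res.get("r_squared"),
                    "/".join(f"{v:.1f}" for v in res["recovery"].values()),
                    "/".join(f"{v:.1f}" for v in res["precision_rsd"].values()),
                    max(res["horrat"].values()) if res["horrat"] else None,
                    res.get("lod_se"), res.get("loq_se"), "yes" if ok else "NO",
                ])
        parts.append(markdown_table(header, rows))
        return "\n".join(parts)


def build_series(df: pd.DataFrame, analyte: str, matrix: str) -> CalibrationSeries:
    """Assemble a CalibrationSeries from calibration rows of the table."""
    sel = df[(df["role"] == "calibration") & (df["analyte"] == analyte)
             & (df["matrix"] == matrix)]
    if sel.empty:
        raise InvalidInputError(f"no calibration rows for {analyte!r} in {matrix!r}")
    points = []
    for level, grp in sel.groupby("level_mg_per_L", sort=True):
        points.append((float(level), tuple(grp["value"].astype(float))))
    return CalibrationSeries(analyte=analyte, matrix=matrix, points=tuple(points))


def _config_hash(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _matrix_effect_by_level(df, analyte, matrix):
    """Per-level %ME mean +/- SD from paired me_matrix / me_solvent rows."""
    me_m = df[(df["role"] == "me_matrix") & (df["analyte"] == analyte)
              & (df["matrix"] == matrix)]
    me_s = df[(df["role"] == "me_solvent") & (df["analyte"] == analyte)
              & (df["matrix"] == matrix)]
    if me_m.empty or me_s.empty:
        return None
    merged = me_m.merge(
        me_s, on=["analyte", "matrix", "level_mg_per_L", "replicate"],
        suffixes=("_matrix", "_solvent"))
    out = {}
    for level, grp in merged.groupby("level_mg_per_L", sort=True):
        ratios = [
            absolute_matrix_effect(MatrixEffectPair(
                analyte=analyte, matrix=matrix, level=float(level),
                area_matrix=float(r.value_matrix), area_solvent=float(r.value_solvent)))
            for r in grp.itertuples()
        ]
        out[float(level)] = {
            "mean": float(np.mean(ratios)),
            "sd": float(np.std(ratios, ddof=1)) if len(ratios) > 1 else None,
            "n": len(ratios),
        }
    return out


def run_validation(
    df: pd.DataFrame,
    bands: AcceptanceBands | None = None,
    cf_table: Mapping[str, float] | None = None,
    n_report: int = 1,
    seed: int | None = None,
    sqrt_n: bool = True,
) -> ValidationReport:
    """Compute the full validation report from a long-format table.

    Missing roles degrade gracefully: each criterion that cannot be
    computed is reported as not evaluated rather than raising.
    """
    bands = bands or AcceptanceBands()
    cf_table = dict(cf_table) if cf_table is not None else default_conversion_factors()
    report = ValidationReport()
    report.metadata = {
        "seed": seed,
        "config_hash": _config_hash({
            "bands": bands.__dict__ | {
                "recovery_range": list(bands.recovery_range),
                "me_range": list(bands.me_range)},
            "n_report": n_report, "sqrt_n": sqrt_n,
        }),
        "version": __version__,
        "n_rows": int(len(df)),
    }

    analytes = sorted(df["analyte"].dropna().unique())
    matrices = sorted(m for m in df["matrix"].dropna().unique() if m != "solvent")

    solvent_fits: dict[str, CalibrationFit] = {}
    for analyte in analytes:
        try:
            solvent_fits[analyte] = fit_calibration(build_series(df, analyte, "solvent"))
            report.fits[(analyte, "solvent")] = solvent_fits[analyte]
        except InvalidInputError:
            pass

    for analyte in analytes:
        report.results[analyte] = {}
        for matrix in matrices:
            res: dict = {
                "rpd": None, "r_squared": None, "linearity_rsd": {},
                "matrix_effect": None, "recovery": {}, "precision_rsd": {},
                "horrat": {}, "lod": None, "loq": None,
                "lod_se": None, "loq_se": None,
            }

            # matrix-matched calibration; solvent fit is the fallback
            fit = None
            try:
                fit = fit_calibration(build_series(df, analyte, matrix))
                report.fits[(analyte, matrix)] = fit
                res["r_squared"] = fit.r_squared
                res["linearity_rsd"] = {
                    lvl: v for lvl, v in fit.level_rsd.items() if v is not None}
            except InvalidInputError:
                fit = solvent_fits.get(analyte)

            spikes = df[(df["role"] == "spike") & (df["analyte"] == analyte)
                        & (df["matrix"] == matrix)]

            # retention-time agreement: spiked sample vs solvent standard
            solvent_rt = df[(df["role"] == "calibration") & (df["analyte"] == analyte)
                            & (df["matrix"] == "solvent")]["rt_min"].dropna()
            spike_rt = spikes["rt_min"].dropna()
            if len(solvent_rt) and len(spike_rt):
                res["rpd"] = relative_percent_difference(
                    (float(spike_rt.mean()), float(solvent_rt.mean())))

            res["matrix_effect"] = _matrix_effect_by_level(df, analyte, matrix)

            # quantitation of spikes, then accuracy/precision/LOD
            conc_by_level: dict[float, list[float]] = {}
            if fit is not None and not spikes.empty:
                for level, grp in spikes.groupby("level_mg_per_L", sort=True):
                    conc_by_level[float(level)] = [
                        back_calculate(fit, float(v)) for v in grp["value"]]
            for level, concs in conc_by_level.items():
                exp = SpikeExperiment(
                    analyte=analyte, matrix=matrix, spike_level=level,
                    replicate_values=tuple(max(c, 0.0) for c in concs),
                    n_report=n_report)
                res["recovery"][level] = recovery_percent(exp)
                if len(concs) >= 2:
                    rsd = percent_rsd(concs)
                    res["precision_rsd"][level] = rsd
                    res["horrat"][level] = horrat(
                        rsd, mg_per_l_to_mass_fraction(level))
            if conc_by_level:
                lowest = min(conc_by_level)
                if len(conc_by_level[lowest]) >= 2:
                    exp = SpikeExperiment(
                        analyte=analyte, matrix=matrix, spike_level=lowest,
                        replicate_values=tuple(
                            max(c, 0.0) for c in conc_by_level[lowest]),
                        n_report=n_report)
                    lod, loq = lod_loq(exp, sqrt_n=sqrt_n)
                    res["lod"], res["loq"] = lod, loq
                    cf = cf_table.get(analyte)
                    if cf:
                        res["lod_se"] = round_reported(lod * cf, 3)
                        res["loq_se"] = round_reported(loq * cf, 3)

            me_means = ([v["mean"] for v in res["matrix_effect"].values()]
                        if res["matrix_effect"] else [])
            worst_me = (max(me_means, key=lambda v: abs(v - 100.0))
                        if me_means else None)
            worst_rec = (max(res["recovery"].values(),
                             key=lambda v: abs(v - 95.0))
                         if res["recovery"] else None)
            res["verdicts"] = evaluate_bands({
                "rpd": res["rpd"],
                "r_squared": res["r_squared"],
                "linearity_rsd": (max(res["linearity_rsd"].values())
                                  if res["linearity_rsd"] else None),
                "precision_rsd": (max(res["precision_rsd"].values())
                                  if res["precision_rsd"] else None),
                "recovery": worst_rec,
                "matrix_effect": worst_me,
                "horrat": max(res["horrat"].values()) if res["horrat"] else None,
            }, bands)
            report.results[analyte][matrix] = res
            log.info("validated analyte=%s matrix=%s rows=%d seed=%s",
                     analyte, matrix, len(spikes), seed)

    return report


# ---------------------------------------------------------------------------
# survey
# ---------------------------------------------------------------------------

def run_survey(
    df: pd.DataFrame,
    report: ValidationReport,
    cf_table: Mapping[str, float] | None = None,
    scenario: CensorScenario | str = CensorScenario.MIDDLE,
    bands: AcceptanceBands | None = None,
) -> dict:
    """Quantify survey specimens and summarize per analyte and food group.

    Each specimen is measured in replicate; the replicate mean is the
    sample result.  Results below the analyte's LOD/LOQ are censored and
    substituted under the requested scenario for the steviol-equivalent
    totals; the detected-only summary (mean +/- SD, min-max, n) uses
    uncensored detects.  Replicate %RSD per specimen is the QC flag
    (limit: the linearity RSD band).
    """
    bands = bands or AcceptanceBands()
    cf_table = dict(cf_table) if cf_table is not None else default_conversion_factors()
    scenario = CensorScenario(scenario)
    samples = df[df["role"] == "sample"]
    if samples.empty:
        raise InvalidInputError("no sample rows in table")

    out: dict = {"scenario": scenario.value, "groups": {}}
    for matrix, grp_m in samples.groupby("matrix", sort=True):
        group: dict = {"analytes": {}, "samples": {}}
        sample_ids = sorted(grp_m["sample"].dropna().unique())
        per_sample_conc: dict[str, dict] = {s: {} for s in sample_ids}

        for analyte, grp_a in grp_m.groupby("analyte", sort=True):
            fit = (report.fits.get((analyte, matrix))
                   or report.fits.get((analyte, "solvent")))
            if fit is None:
                raise ConfigurationError(f"no calibration fit for {analyte!r}")
            res = report.results.get(analyte, {}).get(matrix, {})
            lod = res.get("lod") or 0.0
            loq = res.get("loq") or 0.0
            detected, qc_rsd = [], {}
            for sample_id, grp_s in grp_a.groupby("sample", sort=True):
                concs = [back_calculate(fit, float(v)) for v in grp_s["value"]]
                mean_c = float(np.mean(concs))
                # replicate %RSD is a meaningful QC only for detects
                if len(concs) >= 2 and mean_c >= loq and mean_c > 0:
                    qc_rsd[sample_id] = percent_rsd(concs)
                if mean_c < lod:
                    per_sample_conc[sample_id][analyte] = Censored.BELOW_LOD
                elif mean_c < loq:
                    per_sample_conc[sample_id][analyte] = Censored.BELOW_LOQ
                else:
                    cf = cf_table.get(analyte, 1.0)
                    per_sample_conc[sample_id][analyte] = mean_c
                    detected.append(mean_c * cf)   # report in steviol equivalents
            entry: dict = {"n_detected": len(detected)}
            if detected:
                s = summarize_found(detected)
                entry["summary"] = {"mean": s.mean, "sd": s.sd, "min": s.min,
                                    "max": s.max, "n": s.n}
                entry["rendered"] = s.render()
            else:
                entry["rendered"] = "ND"
            if qc_rsd:
                entry["qc_rsd_range"] = [round_reported(min(qc_rsd.values())),
                                         round_reported(max(qc_rsd.values()))]
                entry["qc_rsd_pass"] = all(
                    v < bands.rsd_linearity_max for v in qc_rsd.values())
            group["analytes"][analyte] = entry

        # per-sample steviol-equivalent totals, all three scenarios
        for sample_id, concs in per_sample_conc.items():
            lods = {a: (report.results.get(a, {}).get(matrix, {}).get("lod") or 0.0)
                    for a in concs}
            loqs = {a: (report.results.get(a, {}).get(matrix, {}).get("loq") or 0.0)
                    for a in concs}
            totals = {}
            for sc in CensorScenario:
                total, _ = aggregate_sample(concs, cf_table, sc, lods, loqs)
                totals[sc.value] = round_reported(total, 3)
            group["samples"][sample_id] = {"se_total": totals}
        out["groups"][matrix] = group
        log.info("surveyed matrix=%s samples=%d", matrix, len(sample_ids))
    return out
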