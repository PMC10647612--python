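"""SRM peak assignment and identity-confirmation tests."""

from __future__ import annotations

import pytest

from sweetval import (
    GeneratorConfig,
    PeakObservation,
    assign_peaks,
    confirm_identity,
    generate_peak_list,
    match_peak,
)
from sweetval.errors import InvalidInputError
from sweetval.srm import TransitionRecord
from sweetval.transitions import DEFAULT_TRANSITIONS


def peak(prec, prod, rt, area=1e4, sample="s1"):
    return PeakObservation(sample=sample, precursor_mz=prec, product_mz=prod,
                           rt=rt, area=area)


class TestMatchPeak:
    def test_reb_a_quantifier(self):
        a = match_peak(peak(965.5, 803.45, 4.856), DEFAULT_TRANSITIONS)
        assert a is not None and a.analyte == "rebaudioside A"
        assert a.role == "quantifier"

    def test_unknown_precursor_returns_none(self):
        assert match_peak(peak(500.0, 300.0, 5.0), DEFAULT_TRANSITIONS) is None

    def test_isobars_resolved_by_retention_time(self):
        # stevioside and rebaudioside B share precursor 803.458 and have
        # quantifier ions 0.1 m/z apart; only RT separates them.
        a = match_peak(peak(803.458, 641.29, 6.30), DEFAULT_TRANSITIONS)
        assert a is not None and a.analyte == "rebaudioside B"
        b = match_peak(peak(803.458, 641.39, 4.90), DEFAULT_TRANSITIONS)
        assert b is not None and b.analyte == "stevioside"

    def test_rt_outside_window_returns_none(self):
        assert match_peak(peak(965.5, 803.45, 9.0), DEFAULT_TRANSITIONS) is None

    def test_empty_table_rejected(self):
        with pytest.raises(InvalidInputError):
            match_peak(peak(965.5, 803.45, 4.856), [])

    def test_tolerance_shrink_never_adds_assignments(self):
        peaks = [peak(rec.precursor_mz + 0.2, rec.quantifier_mz - 0.3,
                      rec.reference_rt * 1.01)
                 for rec in DEFAULT_TRANSITIONS]
        wide = {(a.peak.precursor_mz, a.analyte)
                for a in assign_peaks(peaks, DEFAULT_TRANSITIONS, 0.5, 5.0)}
        for mz_tol, rt_tol in [(0.25, 5.0), (0.5, 0.5), (0.1, 0.1)]:
            narrow = {(a.peak.precursor_mz, a.analyte)
                      for a in assign_peaks(peaks, DEFAULT_TRANSITIONS, mz_tol, rt_tol)}
            assert narrow <= wide

    def test_order_independence(self):
        cfg = GeneratorConfig(seed=5)
        peaks = [
            PeakObservation(sample=r.sample, precursor_mz=r.precursor_mz,
                            product_mz=r.product_mz, rt=r.rt_min, area=r.area)
            for r in generate_peak_list(cfg, n_samples=2).itertuples()
        ]
        fwd = assign_peaks(peaks, DEFAULT_TRANSITIONS)
        rev = assign_peaks(list(reversed(peaks)), DEFAULT_TRANSITIONS)
        key = lambda a: (a.peak.sample, a.peak.precursor_mz, a.peak.product_mz)
        assert sorted(((key(a), a.analyte) for a in fwd)) == \
               sorted(((key(a), a.analyte) for a in rev))


class TestRecall:
    @staticmethod
    def to_peaks(df):
        return [PeakObservation(sample=r.sample, precursor_mz=r.precursor_mz,
                                product_mz=r.product_mz, rt=r.rt_min, area=r.area)
                for r in df.itertuples()]

    def test_full_recall_and_no_isobar_crossing_at_low_jitter(self):
        cfg = GeneratorConfig(seed=11, rt_jitter_sd=0.01)
        df = generate_peak_list(cfg, n_samples=3)
        # ground truth by the exact transition each peak was generated from
        truth = {}
        for rec in DEFAULT_TRANSITIONS:
            truth[(rec.precursor_mz, rec.quantifier_mz)] = rec.analyte
            truth[(rec.precursor_mz, rec.qualifier_mzs[0])] = rec.analyte
        assignments = assign_peaks(self.to_peaks(df), DEFAULT_TRANSITIONS)
        assert len(assignments) == len(df)  # every generated peak assigned
        for a in assignments:
            assert a.analyte == truth[(a.peak.precursor_mz, a.peak.product_mz)]

    def test_decoys_never_assigned(self):
        cfg = GeneratorConfig(seed=3)
        df = generate_peak_list(cfg, n_samples=2, n_decoys=5)
        decoys = df[df["precursor_mz"] < 590.0]
        assert len(decoys) == 10
        assert assign_peaks(self.to_peaks(decoys), DEFAULT_TRANSITIONS) == []

    def test_large_jitter_loses_recall(self):
        # jitter at ~3x the RT tolerance window: recall drops below 100%
        lost = 0
        total = 0
        for s in range(100):
            cfg = GeneratorConfig(seed=3000 + s, rt_jitter_sd=0.75)
            df = generate_peak_list(cfg, n_samples=1, include_qualifiers=False)
            n = len(assign_peaks(self.to_peaks(df), DEFAULT_TRANSITIONS))
            total += len(df)
            lost += len(df) - n
        assert lost > 0


class TestConfirmation:
    def make(self, with_qualifier):
        peaks = [peak(965.5, 803.45, 4.86)]
        if with_qualifier:
            peaks.append(peak(965.5, 641.36, 4.86, area=4e3))
        return assign_peaks(peaks, DEFAULT_TRANSITIONS)

    def test_quantifier_plus_qualifier_confirms(self):
        c = confirm_identity(self.make(True))
        assert c.confirmed and c.n_qualifiers == 1 and c.warning is None

    def test_quantifier_only_warns_but_quantifies(self):
        c = confirm_identity(self.make(False))
        assert not c.confirmed
        assert c.quantifier_area == pytest.approx(1e4)
        assert c.warning is not None

    def test_isobars_confirm_independently(self):
        sv = assign_peaks([peak(803.458, 641.39, 4.90),
                           peak(803.458, 479.22, 4.90)], DEFAULT_TRANSITIONS)
        rb = assign_peaks([peak(803.458, 641.29, 6.35),
                           peak(803.458, 413.08, 6.35)], DEFAULT_TRANSITIONS)
        assert confirm_identity(sv).confirmed
        assert confirm_identity(sv).analyte == "stevioside"
        assert confirm_identity(rb).confirmed
        assert confirm_identity(rb).analyte == "rebaudioside B"

    def test_transition_invariant(self):
        with pytest.raises(InvalidInputError):
            TransitionRecord(analyte="x", formula="C1", reference_rt=5.0,
                             precursor_mz=300.0, quantifier_mz=400.0)
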