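"""Unit and property tests for the validation statistics."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweetval import (
    AcceptanceBands,
    Censored,
    CensorScenario,
    MatrixEffectPair,
    SpikeExperiment,
    absolute_matrix_effect,
    evaluate_bands,
    horrat,
    horwitz_prsd,
    lod_loq,
    percent_rsd,
    recovery_percent,
    relative_percent_difference,
    substitute_censored,
    summarize_found,
)
from sweetval.errors import InvalidInputError
from sweetval.stats import RetentionPair, round_reported

from conftest import brute_mean, brute_rsd, brute_sd

finite_rt = st.floats(min_value=0.1, max_value=13.0)
positive = st.floats(min_value=1e-3, max_value=1e6)


class TestRetentionRPD:
    @pytest.mark.parametrize("a, b, expected", [
        (5.214, 5.214, 0.0),
        (5.0, 4.9, 100 * 0.1 / 4.95),
        (4.9, 5.0, 100 * 0.1 / 4.95),
    ])
    def test_examples(self, a, b, expected):
        assert relative_percent_difference((a, b)) == pytest.approx(expected)

    @given(a=finite_rt, b=finite_rt, k=st.floats(min_value=0.1, max_value=10))
    @settings(derandomize=True, max_examples=100)
    def test_symmetric_scale_invariant_bounded(self, a, b, k):
        rpd = relative_percent_difference((a, b))
        assert rpd == relative_percent_difference((b, a))
        assert relative_percent_difference((k * a, k * b)) == pytest.approx(rpd)
        assert 0.0 <= rpd < 200.0
        assert (rpd == 0.0) == (a == b)

    def test_rejects_nonpositive_rt(self):
        with pytest.raises(InvalidInputError):
            RetentionPair(0.0, 5.0)


class TestPercentRSD:
    @pytest.mark.parametrize("values, expected", [
        ([0.5, 0.5, 0.5], 0.0),
        ([1.0, 2.0, 3.0], 50.0),
    ])
    def test_examples(self, values, expected):
        assert percent_rsd(values) == pytest.approx(expected)

    @given(
        values=st.lists(st.floats(min_value=0.1, max_value=100), min_size=2, max_size=8),
        k=st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(derandomize=True, max_examples=100)
    def test_scale_invariance(self, values, k):
        assert percent_rsd([k * v for v in values]) == pytest.approx(
            percent_rsd(values), rel=1e-9)

    def test_rejects_degenerate(self):
        with pytest.raises(InvalidInputError):
            percent_rsd([1.0])
        with pytest.raises(InvalidInputError):
            percent_rsd([-1.0, 1.0])


class TestHorwitz:
    @pytest.mark.parametrize("c, expected", [
        (1.0, 2.0), (0.01, 4.0), (1e-4, 8.0),
        (2e-7, 2 ** (1 - 0.5 * math.log10(2e-7))),
    ])
    def test_closed_form(self, c, expected):
        assert horwitz_prsd(c) == pytest.approx(expected)

    @given(st.floats(min_value=1e-9, max_value=0.5))
    @settings(derandomize=True, max_examples=100)
    def test_strictly_decreasing(self, c):
        assert horwitz_prsd(c) > horwitz_prsd(2 * c)

    @pytest.mark.parametrize("bad", [0.0, -1.0, 1.5])
    def test_domain(self, bad):
        with pytest.raises(InvalidInputError):
            horwitz_prsd(bad)

    def test_horrat(self):
        assert horrat(4.0, 0.01) == pytest.approx(1.0)
        assert horrat(0.0, 0.01) == 0.0
        # 0.2 mg/L spike as a mass fraction of 2e-7
        assert horrat(8.10, 2e-7) == pytest.approx(0.397, abs=5e-4)


class TestRecoveryAndMatrixEffect:
    @pytest.mark.parametrize("mean, blank, spike, expected", [
        (0.19, 0.0, 0.2, 95.0),
        (0.02, 0.02, 0.2, 0.0),
        (0.22, 0.02, 0.2, 100.0),
    ])
    def test_recovery(self, mean, blank, spike, expected):
        exp = SpikeExperiment(
            analyte="a", matrix="beverage", spike_level=spike,
            replicate_values=(mean,), blank_mean=blank)
        assert recovery_percent(exp) == pytest.approx(expected)

    def test_recovery_rejects_zero_spike(self):
        with pytest.raises(InvalidInputError):
            SpikeExperiment(analyte="a", matrix="beverage", spike_level=0.0,
                            replicate_values=(0.1,))

    @pytest.mark.parametrize("am, asol, expected", [
        (1000.0, 1000.0, 100.0),
        (80.0, 100.0, 80.0),
    ])
    def test_matrix_effect(self, am, asol, expected):
        pair = MatrixEffectPair(analyte="a", matrix="snack", level=0.2,
                                area_matrix=am, area_solvent=asol)
        assert absolute_matrix_effect(pair) == pytest.approx(expected)

    def test_matrix_effect_out_of_band(self):
        # an enhancement of 125.14% violates the 80-120% criterion
        verdict = evaluate_bands({"matrix_effect": 125.14})["matrix_effect"]
        assert verdict["evaluated"] and not verdict["pass"]

    def test_matrix_effect_rejects_zero_solvent(self):
        with pytest.raises(InvalidInputError):
            MatrixEffectPair(analyte="a", matrix="snack", level=0.2,
                             area_matrix=10.0, area_solvent=0.0)


class TestLodLoq:
    def test_constant_replicates(self):
        exp = SpikeExperiment(analyte="a", matrix="beverage", spike_level=0.2,
                              replicate_values=(0.2,) * 7)
        lod, loq = lod_loq(exp)
        assert lod == pytest.approx(0.0, abs=1e-12)
        assert loq == pytest.approx(0.0, abs=1e-12)

    def test_direct_arithmetic(self):
        # replicates engineered to have sample SD exactly 0.02
        exp = SpikeExperiment(analyte="a", matrix="beverage", spike_level=0.2,
                              replicate_values=(0.18, 0.22), n_report=1)
        assert exp.sd == pytest.approx(0.02 * math.sqrt(2))
        lod, loq = lod_loq(exp)
        assert lod == pytest.approx(3 * 0.02 * math.sqrt(2))
        assert loq == pytest.approx(10 * 0.02 * math.sqrt(2))

    @given(
        values=st.lists(st.floats(min_value=0.0, max_value=10), min_size=2, max_size=9),
        n_report=st.integers(min_value=1, max_value=10),
    )
    @settings(derandomize=True, max_examples=100)
    def test_ratio_identity_and_sd_scaling(self, values, n_report):
        exp = SpikeExperiment(analyte="a", matrix="beverage", spike_level=0.2,
                              replicate_values=tuple(values), n_report=n_report)
        lod, loq = lod_loq(exp)
        assert loq == pytest.approx((10.0 / 3.0) * lod, rel=1e-12, abs=1e-300)
        assert lod == pytest.approx(
            3.0 * brute_sd(values) / math.sqrt(n_report), rel=1e-9, abs=1e-12)

    def test_plain_n_divisor_switch(self):
        exp = SpikeExperiment(analyte="a", matrix="beverage", spike_level=0.2,
                              replicate_values=(0.1, 0.2, 0.3), n_report=4)
        lod_sqrt, _ = lod_loq(exp, sqrt_n=True)
        lod_plain, _ = lod_loq(exp, sqrt_n=False)
        assert lod_plain == pytest.approx(lod_sqrt / 2.0)


class TestCensoring:
    @pytest.mark.parametrize("value, scenario, expected", [
        (Censored.BELOW_LOD, "lower", 0.0),
        (Censored.BELOW_LOD, "middle", 0.03),
        (Censored.BELOW_LOD, "upper", 0.06),
        (Censored.BELOW_LOQ, "lower", 0.0),
        (Censored.BELOW_LOQ, "middle", 0.10),
        (Censored.BELOW_LOQ, "upper", 0.20),
        (0.42, "lower", 0.42),
        (0.42, "upper", 0.42),
    ])
    def test_substitution(self, value, scenario, expected):
        assert substitute_censored(value, 0.06, 0.20, scenario) == pytest.approx(expected)

    @given(lod=st.floats(min_value=0, max_value=1),
           extra=st.floats(min_value=0, max_value=1),
           status=st.sampled_from([Censored.BELOW_LOD, Censored.BELOW_LOQ]))
    @settings(derandomize=True, max_examples=100)
    def test_scenario_ordering(self, lod, extra, status):
        loq = lod + extra
        subs = [substitute_censored(status, lod, loq, s) for s in CensorScenario]
        assert subs[0] <= subs[1] <= subs[2]

    def test_rejects_inverted_limits(self):
        with pytest.raises(InvalidInputError):
            substitute_censored(Censored.BELOW_LOD, 0.2, 0.1, "lower")


class TestSummaries:
    def test_two_value_summary(self):
        s = summarize_found([1.83, 2.32])
        assert (s.mean, s.min, s.max, s.n) == (2.08, 1.83, 2.32, 2)

    def test_single_value_has_no_sd(self):
        s = summarize_found([0.42])
        assert s.mean == 0.42 and s.sd is None and s.n == 1

    def test_wide_range_mean(self):
        assert summarize_found([1.64, 15.95]).mean == 8.80

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            summarize_found([])

    def test_rounding_half_away_from_zero(self):
        assert round_reported(2.075, 2) == 2.08
        assert round_reported(-2.075, 2) == -2.08
        assert round_reported(0.0615, 3) == 0.062


class TestBands:
    def test_pass_fail_and_not_evaluated(self):
        out = evaluate_bands({"matrix_effect": 100.0, "recovery": 65.0,
                              "horrat": 0.48})
        assert out["matrix_effect"]["pass"]
        assert not out["recovery"]["pass"]
        assert out["horrat"]["pass"]
        assert not out["rpd"]["evaluated"]

    def test_band_invariants(self):
        with pytest.raises(InvalidInputError):
            AcceptanceBands(recovery_range=(120.0, 70.0))


class TestOracleEquivalence:
    """All statistics agree with explicit-sum recomputation on tiny fixtures."""

    @pytest.mark.parametrize("values", [
        [0.21, 0.19, 0.22], [1.0, 2.0, 3.0, 4.0], [0.5, 0.51, 0.49, 0.52, 0.48],
    ])
    def test_rsd_recovery_lod(self, values):
        assert percent_rsd(values) == pytest.approx(brute_rsd(values), rel=1e-12)
        exp = SpikeExperiment(analyte="a", matrix="beverage", spike_level=0.5,
                              replicate_values=tuple(values), n_report=2)
        assert recovery_percent(exp) == pytest.approx(
            100 * brute_mean(values) / 0.5, rel=1e-12)
        lod, loq = lod_loq(exp)
        s0p = brute_sd(values) / math.sqrt(2)
        assert lod == pytest.approx(3 * s0p, rel=1e-12)
        assert loq == pytest.approx(10 * s0p, rel=1e-12)
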