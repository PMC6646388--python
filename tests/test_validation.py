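"""Peak integration, co-elution, dotp and the detection decision rules."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrmpanel.proteome_io import ReferencePattern
from mrmpanel.validation import (
    IntegratedTransition,
    PeakGroup,
    Thresholds,
    TransitionTrace,
    ValidationVerdict,
    check_coelution,
    dotp,
    integrate_traces,
    spikein_check,
    validate_detection,
)

PEP = "AAADDEEGGHQQR"


def gaussian_trace(label, amp, apex, sigma=0.05, t0=None, t1=None, dt=1 / 64):
    # dyadic sampling step: grid points (and hence apex RTs) are fp-exact
    t0 = apex - 0.5 if t0 is None else t0
    t1 = apex + 0.5 if t1 is None else t1
    t = np.arange(t0, t1 + dt / 2, dt)
    return TransitionTrace(label, t, amp * np.exp(-0.5 * ((t - apex) / sigma) ** 2))


def rect_trace(label, amp, start, width, dt=1 / 64, pad=0.5):
    t = np.arange(start - pad, start + width + pad + dt / 2, dt)
    y = np.where((t >= start) & (t <= start + width), amp, 0.0)
    return TransitionTrace(label, t, y)


def group(traces, run="r1", idx=0):
    return PeakGroup(run_id=run, peptide=PEP, traces=traces, technical_replicate_index=idx)


def reference(ratios, labels=None, rt=10.0):
    labels = labels or [f"y{i + 3}" for i in range(len(ratios))]
    return ReferencePattern(PEP, labels, np.asarray(ratios, float), rt)


class TestIntegration:
    def test_unit_rectangle_area_in_intensity_seconds(self):
        g = group([rect_trace("y3", 1.0, 10.0, 1.0), rect_trace("y4", 1.0, 10.0, 1.0)])
        integ = integrate_traces(g)
        # unit height over 1 min = 60 intensity*s (trapezoid edges ~1 sample)
        assert integ[0].area == pytest.approx(60.0, rel=0.02)

    def test_symmetric_gaussian_apex_at_center(self):
        g = group([gaussian_trace("y3", 100, 10.0), gaussian_trace("y4", 50, 10.0)])
        for it in integrate_traces(g):
            assert it.apex_rt == pytest.approx(10.0, abs=1 / 60)

    def test_gaussian_area_matches_closed_form(self):
        amp, sigma = 500.0, 0.05
        g = group(
            [gaussian_trace("y3", amp, 10.0, sigma), gaussian_trace("y4", amp, 10.0, sigma)]
        )
        expected = amp * sigma * np.sqrt(2 * np.pi) * 60  # intensity*seconds
        for it in integrate_traces(g):
            assert it.area == pytest.approx(expected, rel=0.02)

    def test_short_trace_errors(self):
        tr = TransitionTrace("y3", np.array([1.0, 2.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="fewer than 3"):
            integrate_traces(group([tr, tr]))

    def test_flat_trace_marked_absent(self):
        flat = TransitionTrace("y3", np.linspace(9, 11, 100), np.full(100, 50.0))
        peak = gaussian_trace("y4", 1000, 10.0)
        integ = integrate_traces(group([flat, peak]))
        assert not integ[0].present and integ[1].present


class TestCoelution:
    def _integ(self, apexes, present=None):
        present = present or [True] * len(apexes)
        return [
            IntegratedTransition(f"y{i + 3}", 100.0, rt, p)
            for i, (rt, p) in enumerate(zip(apexes, present))
        ]

    def test_identical_apexes_pass_with_zero_spread(self):
        ok, spread, reasons = check_coelution(self._integ([10.0, 10.0, 10.0]))
        assert ok and spread == 0.0 and reasons == ()

    def test_shifted_apex_fails(self):
        ok, spread, _ = check_coelution(self._integ([10.0, 15.0]))
        assert not ok and spread == pytest.approx(5.0)

    def test_missing_transition_reason(self):
        ok, _, reasons = check_coelution(self._integ([10.0, 10.0], [True, False]))
        assert not ok and "missing_transition" in reasons

    def test_spread_matches_brute_force_under_jitter(self, rng):
        for _ in range(50):
            apexes = 10.0 + rng.normal(0, 0.03, size=5)
            ok, spread, _ = check_coelution(self._integ(list(apexes)))
            brute = max(abs(a - b) for a in apexes for b in apexes)
            assert spread == pytest.approx(brute)
            assert ok == (brute <= 0.2)


class TestDotp:
    def test_proportional_vectors_give_one(self):
        assert dotp([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)

    def test_orthogonal_vectors_give_zero(self):
        assert dotp([1, 0], [0, 1]) == 0.0

    def test_hand_value_three_four(self):
        assert dotp([3, 4], [4, 3]) == pytest.approx(24 / 25)

    def test_zero_observed_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert dotp([0, 0], [1, 2]) == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            dotp([-1, 2], [1, 2])

    def test_sqrt_transform_changes_weighting(self):
        raw = dotp([100, 1], [1, 100])
        transformed = dotp([100, 1], [1, 100], sqrt_transform=True)
        assert transformed > raw

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(min_value=0, max_value=1e6), min_size=2, max_size=8),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance_property(self, vec, c):
        ref = np.arange(1.0, len(vec) + 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = dotp(vec, ref)
            b = dotp([c * v for v in vec], ref)
        assert a == pytest.approx(b, abs=1e-9)
        assert 0.0 <= a <= 1.0


class TestValidateDetection:
    def _faithful_group(self, ratios, run="r1", idx=0, apex=10.0, amp=1e5):
        traces = [
            gaussian_trace(f"y{i + 3}", amp * r, apex) for i, r in enumerate(ratios)
        ]
        return group(traces, run=run, idx=idx)

    def test_faithful_replicates_detected(self):
        ratios = [0.4, 0.3, 0.2, 0.1]
        ref = reference(ratios)
        groups = [self._faithful_group(ratios, run=f"r{i}", idx=i) for i in range(3)]
        verdict = validate_detection(groups, ref)
        assert verdict.detected
        assert verdict.dotp > 0.99
        assert verdict.coelution_pass and verdict.replicate_pass

    def test_signal_in_two_of_three_replicates_not_detected(self):
        ratios = [0.5, 0.3, 0.2]
        ref = reference(ratios)
        groups = [self._faithful_group(ratios, run=f"r{i}", idx=i) for i in range(2)]
        absent = group(
            [gaussian_trace(f"y{i + 3}", 0.0, 10.0) for i in range(3)], run="r2", idx=2
        )
        verdict = validate_detection(groups + [absent], ref)
        assert not verdict.detected and not verdict.replicate_pass

    def test_pattern_mismatch_fails_criterion_b(self):
        ref = reference([0.516, 0.258, 0.129, 0.065, 0.032])  # skewed pattern
        permuted = [0.032, 0.516, 0.258, 0.129, 0.065]
        groups = [self._faithful_group(permuted, run=f"r{i}", idx=i) for i in range(3)]
        verdict = validate_detection(groups, ref)
        assert not verdict.dotp_pass and not verdict.detected

    def test_mean_dotp_at_threshold_not_detected(self):
        """dotp of exactly 0.80 must fail the strict > 0.80 criterion."""
        ref = reference([2.0, 1.0])
        groups = [self._faithful_group([1.0, 2.0], run=f"r{i}", idx=i) for i in range(2)]
        verdict = validate_detection(groups, ref)
        assert verdict.dotp == pytest.approx(0.8, abs=1e-9)
        assert not verdict.dotp_pass and not verdict.detected

    def test_detection_monotone_in_dotp_threshold(self):
        ratios = [0.45, 0.3, 0.15, 0.1]
        ref = reference(ratios)
        groups = [self._faithful_group(ratios, run=f"r{i}", idx=i) for i in range(3)]
        detected = [
            validate_detection(groups, ref, Thresholds(dotp_threshold=th)).detected
            for th in (0.5, 0.8, 0.95, 0.999999)
        ]
        assert detected == sorted(detected, reverse=True)

    def test_missing_reference_errors(self):
        other = ReferencePattern("OTHERPEPK", ["y3", "y4"], np.array([1.0, 1.0]), 5.0)
        with pytest.raises(ValueError):
            validate_detection([self._faithful_group([0.5, 0.5])], other)

    def test_verdict_invariant_detected_implies_all_passes(self):
        v = ValidationVerdict(
            peptide=PEP, run_id="r", coelution_pass=True, max_apex_spread_min=0.0,
            dotp=0.99, dotp_pass=True, replicate_pass=False,
        )
        assert not v.detected


class TestSpikein:
    def _pair(self, endo_amp, spike_extra, rt_shift=0.0, ratios=(0.5, 0.3, 0.2)):
        endo = group(
            [gaussian_trace(f"y{i + 3}", endo_amp * r, 10.0) for i, r in enumerate(ratios)]
        )
        spiked = group(
            [
                gaussian_trace(f"y{i + 3}", (endo_amp + spike_extra) * r, 10.0 + rt_shift)
                for i, r in enumerate(ratios)
            ],
            run="r2",
        )
        return endo, spiked

    def test_rt_difference_exactly_three_minutes_passes(self):
        endo, spiked = self._pair(1e5, 1e5, rt_shift=3.0)
        rec = spikein_check(endo, spiked, reference([0.5, 0.3, 0.2]))
        assert rec.rt_diff_min == pytest.approx(3.0, abs=1e-6)
        assert rec.passed

    def test_rt_difference_above_three_minutes_fails(self):
        endo, spiked = self._pair(1e5, 1e5, rt_shift=3.1)
        rec = spikein_check(endo, spiked, reference([0.5, 0.3, 0.2]))
        assert not rec.passed

    def test_no_area_increase_reason(self):
        endo, spiked = self._pair(1e5, -5e4)
        rec = spikein_check(endo, spiked, reference([0.5, 0.3, 0.2]))
        assert not rec.passed and "no_area_increase" in rec.reasons

    def test_area_ratio_matches_analytic_amplitude_addition(self):
        # spiking doubles every amplitude: (spiked - endo)/endo == 1
        endo, spiked = self._pair(2e5, 2e5)
        rec = spikein_check(endo, spiked, reference([0.5, 0.3, 0.2]))
        assert rec.area_ratio == pytest.approx(1.0, rel=1e-6)
        assert rec.passed

    def test_mismatched_transition_sets_rejected(self):
        endo, _ = self._pair(1e5, 1e5)
        other = group(
            [gaussian_trace("y5", 1.0, 10.0), gaussian_trace("y6", 1.0, 10.0)], run="r2"
        )
        with pytest.raises(ValueError):
            spikein_check(endo, other, reference([0.5, 0.5], labels=["y5", "y6"]))
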