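"""FRET-style trace calibration and per-assay quantity extraction."""

import numpy as np
import pytest

from cheradapt import fret, mwc
from cheradapt.fret import FretTrace, StimulusEvent, StepResponseResult
from cheradapt.synth import (GroundTruth, generate_step_experiment,
                             generate_zero_activity_assay)


def make_cycle_trace(a0=0.5, strain="tar-only", noise=0.0, seed=0,
                     a_peak=1.0):
    """Idealised full add/adapt/remove cycle: baseline a0, zero during the
    saturating stimulus, peak a_peak after removal, decay back."""
    t = np.arange(0.0, 1000.0)
    a = np.full(t.size, a0)
    a[(t >= 200) & (t < 700)] = 0.0
    post = (t >= 700) & (t < 760)
    a[post] = a_peak
    a[t >= 760] = a0
    ratio = 0.8 + 0.2 * a
    if noise:
        ratio = ratio + np.random.default_rng(seed).normal(0, noise, t.size)
    events = [StimulusEvent(200.0, "add", 0.25),
              StimulusEvent(700.0, "remove", 0.0)]
    return FretTrace(t=t, ratio=ratio, events=events, strain=strain)


class TestTraceValidation:
    def test_event_alternation_enforced(self):
        t = np.arange(0.0, 10.0)
        with pytest.raises(ValueError):
            FretTrace(t=t, ratio=np.ones_like(t),
                      events=[StimulusEvent(2.0, "add", 0.1),
                              StimulusEvent(4.0, "add", 0.1)])

    def test_events_must_lie_within_trace(self):
        t = np.arange(0.0, 10.0)
        with pytest.raises(ValueError):
            FretTrace(t=t, ratio=np.ones_like(t),
                      events=[StimulusEvent(50.0, "add", 0.1)])


class TestCalibration:
    def test_anchor_points(self):
        trace = make_cycle_trace(a0=0.35)
        a = fret.calibrate_activity(trace, a0=0.35)
        pre = a[trace.t < 200]
        np.testing.assert_allclose(pre, 0.35, atol=1e-12)
        during = a[(trace.t > 210) & (trace.t < 690)]
        np.testing.assert_allclose(during, 0.0, atol=1e-12)

    def test_affine_invariance(self):
        trace = make_cycle_trace(a0=0.35)
        a_ref = fret.calibrate_activity(trace, a0=0.35)
        shifted = FretTrace(t=trace.t, ratio=3.0 * trace.ratio + 7.0,
                            events=trace.events, strain=trace.strain)
        np.testing.assert_allclose(
            fret.calibrate_activity(shifted, a0=0.35), a_ref, atol=1e-10)

    def test_recovers_a0_from_noisy_synthetic_trace(self):
        truth = GroundTruth(seed=5)
        trace, record = generate_step_experiment(truth, 0.25)
        a0 = fret.extract_a0(trace)
        a = fret.calibrate_activity(trace, a0=a0)
        pre = a[trace.t < 190]
        assert abs(np.mean(pre) - record["a0"]) < 0.02

    def test_inverted_signal_rejected(self):
        trace = make_cycle_trace(a0=0.35)
        flipped = FretTrace(t=trace.t, ratio=-trace.ratio,
                            events=trace.events)
        with pytest.raises(fret.CalibrationError):
            fret.calibrate_activity(flipped, a0=0.35)

    def test_requires_saturating_addition(self):
        t = np.arange(0.0, 400.0)
        trace = FretTrace(t=t, ratio=np.ones_like(t),
                          events=[StimulusEvent(200.0, "add", 0.005)])
        with pytest.raises(fret.CalibrationError):
            fret.calibrate_activity(trace, a0=0.3)


class TestExtractA0:
    def test_noise_free_cycle_exact(self):
        assert fret.extract_a0(make_cycle_trace(a0=0.5)) == pytest.approx(
            0.5, abs=1e-12)

    def test_no_overshoot_flagged(self, caplog):
        import logging
        trace = make_cycle_trace(a0=0.5, a_peak=0.5)
        with caplog.at_level(logging.WARNING, logger="cheradapt.fret"):
            a0 = fret.extract_a0(trace)
        assert a0 >= 1.0
        assert any("suspicious" in r.message for r in caplog.records)

    def test_noisy_cycle_within_tolerance(self):
        trace = make_cycle_trace(a0=0.35, noise=0.004, seed=3)
        assert abs(fret.extract_a0(trace) - 0.35) < 0.03


class TestAdaptedActivity:
    @staticmethod
    def _step_trace(plateau):
        """Baseline 0.2, zero-activity spell after the saturating
        addition, then the given plateau until removal at 900 s."""
        t = np.arange(0.0, 1000.0)
        a_true = np.full(t.size, 0.2)
        a_true[(t >= 200) & (t < 280)] = 0.0
        hold = (t >= 280) & (t < 900)
        a_true[hold] = plateau(t[hold])
        return FretTrace(t=t, ratio=0.8 + 0.2 * a_true,
                         events=[StimulusEvent(200.0, "add", 0.25),
                                 StimulusEvent(900.0, "remove", 0.0)])

    def test_constant_plateau(self):
        trace = self._step_trace(lambda t: 0.05)
        res = fret.adapted_activity(trace, 1, a0=0.2)
        assert res.a_star == pytest.approx(0.05, abs=1e-10)
        assert res.steady

    def test_drifting_plateau_flagged(self):
        trace = self._step_trace(lambda t: 0.05 + 5e-4 * (t - 280))
        assert not fret.adapted_activity(trace, 1, a0=0.2).steady

    def test_synthetic_step_response_recovery(self):
        truth = GroundTruth(seed=9)
        cal_trace, _ = generate_step_experiment(truth, 0.25)
        a0 = fret.extract_a0(cal_trace)
        trace, record = generate_step_experiment(truth, 0.025)
        res = fret.adapted_activity(trace, 1, a0=a0,
                                    f_sat=fret._f_sat(cal_trace))
        assert abs(res.a_star - record["a_star"]) < 0.02

    def test_wrong_event_kind_rejected(self):
        trace = make_cycle_trace()
        with pytest.raises(ValueError):
            fret.adapted_activity(trace, 0, a0=0.5)


class TestRemovalPeak:
    @pytest.mark.parametrize("strain,cap", [("wild-type", 114.0),
                                            ("tar-only", 257.0)])
    def test_strain_duration_caps(self, strain, cap):
        assert fret.DELTA_T_CAPS[strain] == cap

    def test_long_zero_activity_flagged_for_tar_only(self):
        t = np.arange(0.0, 1000.0)
        a_true = np.full(t.size, 0.3)
        a_true[(t >= 300) & (t < 600)] = 0.0  # 300 s > 257 s cap
        a_true[(t >= 600) & (t < 650)] = 0.8
        trace = FretTrace(t=t, ratio=0.8 + 0.2 * a_true,
                          events=[StimulusEvent(300.0, "add", 0.25),
                                  StimulusEvent(600.0, "remove", 0.0)],
                          strain="tar-only")
        res = fret.removal_peak(trace, 1, a0=0.3)
        assert res.cap_exceeded
        assert res.zero_activity_duration == pytest.approx(300.0, abs=2.0)

    def test_peak_maps_back_to_methylation_level(self, tar_params):
        """Round trip through the MWC inverse: the synthetic assay's
        post-removal peak recovers the hidden methylation level."""
        truth = GroundTruth(seed=13)
        assays = generate_zero_activity_assay(truth, [15.0])
        trace, record = assays[0]
        res = fret.removal_peak(trace, 1, a0=record["a0"])
        m_est = mwc.invert_activity_to_m(min(res.a_r, 0.999), 0.0,
                                         truth.mwc)
        assert abs(m_est - record["m_r"]) < 0.05
        assert not res.a_r_capped


class TestPrecisionPairs:
    def test_perfect_adaptation_slope_minus_one(self, tar_params):
        """m-independent rates: a* identical at every dose, so fm = -fL
        up to a constant and the precision slope is exactly -1."""
        a_star = 0.25
        results = []
        for L in (0.005, 0.025, 0.1, 0.25):
            m = mwc.invert_activity_to_m(a_star, L, tar_params)
            results.append(StepResponseResult(
                L=L, a0=0.3, a_star=a_star, m=m,
                fm=mwc.methylation_free_energy(m, tar_params),
                fL=mwc.ligand_free_energy(L, tar_params)))
        _, fit = fret.precision_pairs(results)
        assert fit.slope == pytest.approx(-1.0, abs=1e-10)

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError):
            fret.precision_pairs([])
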