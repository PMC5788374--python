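"""Phase gating, 5-beat phase averages, and pause-pressure extrapolation."""

import numpy as np
import pytest

from lvdiastole.trace import PressureTrace
from lvdiastole.ventilation import (
    Segment,
    VentilationSchedule,
    build_schedule,
    classify_beats,
    estimate_pause_pressure,
    phase_average,
    schedule_from_labels,
)

FS = 1000.0


class TestSchedule:
    def test_cycle_layout_at_study_operating_point(self):
        # 6.5 cycles/min at I:E 1:2 -> 9.23 s cycles with ~3.08 s inspiratory part
        sched = build_schedule(60.0, 6.5, 0.5, pause_fraction=0.0)
        insp = sched.phase_segments("inspiration")[0]
        cycle_len = 60.0 / 6.5
        assert cycle_len == pytest.approx(9.2308, abs=1e-3)
        assert insp.end - insp.start == pytest.approx(cycle_len / 3.0, abs=1e-9)

    def test_segments_tile_the_record(self):
        sched = build_schedule(30.0, 8.0, 0.5)
        assert sched.span == (0.0, 30.0)
        for a, b in zip(sched.segments, sched.segments[1:]):
            assert a.end == b.start

    def test_label_roundtrip(self, noiseless_sim):
        t = noiseless_sim.traces["lv"].times()
        rebuilt = schedule_from_labels(t, noiseless_sim.vent_phase)
        orig = noiseless_sim.schedule
        assert len(rebuilt.segments) == len(orig.segments)
        for a, b in zip(rebuilt.segments, orig.segments):
            assert a.phase == b.phase
            assert a.start == pytest.approx(b.start, abs=1.5 / FS)


class TestClassification:
    def test_beat_inside_inspiration_segment(self, noiseless_analysis, noiseless_sim):
        sched = noiseless_sim.schedule
        phase_of = classify_beats(noiseless_analysis.beats, sched, FS)
        for i, b in enumerate(noiseless_analysis.beats):
            seg = sched.segment_at(b.ed_index / FS)
            expected = "pause" if seg.phase.endswith("_pause") else seg.phase
            assert phase_of[i] == expected

    def test_agrees_with_ground_truth_for_every_beat(self, noiseless_sim, noiseless_analysis):
        gt_phase = noiseless_sim.ground_truth["phase"].to_numpy()
        phase_of = classify_beats(noiseless_analysis.beats, noiseless_sim.schedule, FS)
        assert len(phase_of) == gt_phase.size
        assert all(phase_of[i] == gt_phase[i] for i in range(gt_phase.size))

    def test_every_beat_gets_exactly_one_phase(self, noisy_analysis):
        phases = noisy_analysis.beat_table["phase"]
        assert phases.notna().all()
        counts = phases.value_counts()
        assert counts.sum() == len(noisy_analysis.beats)

    def test_beat_outside_schedule_is_unclassified(self, noiseless_analysis):
        short = VentilationSchedule([Segment(0.0, 1.0, "inspiration", 0)])
        with pytest.warns(UserWarning, match="outside"):
            phase_of = classify_beats(noiseless_analysis.beats, short, FS)
        assert None in phase_of.values()


class TestPhaseAverage:
    def _setup(self, sim, analysis):
        metrics = analysis.metrics
        sched = sim.schedule
        phase_of = classify_beats(analysis.beats, sched, FS)
        return metrics, sched, phase_of

    def test_k1_returns_single_beat_metrics(self, noiseless_sim, noiseless_analysis):
        metrics, sched, phase_of = self._setup(noiseless_sim, noiseless_analysis)
        pa = phase_average(noiseless_analysis.beats, metrics, phase_of, "expiration", sched, FS, k=1)
        (i,) = pa.beat_indices
        assert pa.means == metrics[i]

    def test_mean_of_constant_metric_is_the_constant(self, noiseless_sim, noiseless_analysis):
        metrics, sched, phase_of = self._setup(noiseless_sim, noiseless_analysis)
        const = {i: {"x": 4.2} for i in metrics}
        pa = phase_average(noiseless_analysis.beats, const, phase_of, "expiration", sched, FS, k=5)
        assert pa.means["x"] == pytest.approx(4.2)

    def test_mean_shift_commutes_with_constant_offset(self, noiseless_sim, noiseless_analysis):
        metrics, sched, phase_of = self._setup(noiseless_sim, noiseless_analysis)
        shifted = {i: {k: v + 2.5 for k, v in m.items()} for i, m in metrics.items()}
        a = phase_average(noiseless_analysis.beats, metrics, phase_of, "expiration", sched, FS)
        b = phase_average(noiseless_analysis.beats, shifted, phase_of, "expiration", sched, FS)
        for key in a.means:
            if np.isfinite(a.means[key]):
                assert b.means[key] == pytest.approx(a.means[key] + 2.5)

    def test_deficit_is_reported(self, noiseless_sim, noiseless_analysis):
        metrics, sched, phase_of = self._setup(noiseless_sim, noiseless_analysis)
        with pytest.raises(ValueError, match="beats"):
            phase_average(noiseless_analysis.beats, metrics, phase_of, "expiration", sched, FS, k=10**4)

    def test_programmed_lvedp_offset_recovered(self):
        from lvdiastole.pipeline import RunConfig, analyze_traces
        from lvdiastole.simulate import SimConfig, simulate

        res = simulate(SimConfig(duration=60.0, noise_sd=0.25, seed=21))
        ar = analyze_traces(res.traces, res.vent_phase, RunConfig())
        ph = ar.phase_table.set_index("phase")
        diff = ph.loc["inspiration", "lvedp"] - ph.loc["expiration", "lvedp"]
        assert diff == pytest.approx(1.18, abs=0.1)


class TestPausePressure:
    def test_constant_segment_recovered_exactly(self):
        seg = PressureTrace(FS, np.full(200, 15.0), unit="cmH2O")
        est = estimate_pause_pressure(seg)
        assert est.pause_pressure == 15.0
        assert est.amplitude == 0.0

    def test_damped_sinusoid_recovered(self):
        t = np.arange(int(1.5 * FS)) / FS
        y = 12.0 + 4.0 * np.exp(-5.0 * t) * np.cos(2 * np.pi * 3.0 * t)
        est = estimate_pause_pressure(PressureTrace(FS, y, unit="cmH2O"))
        assert est.pause_pressure == pytest.approx(12.0, abs=0.05)
        assert est.damping == pytest.approx(5.0, rel=0.1)
        assert est.frequency == pytest.approx(3.0, rel=0.05)

    def test_recovery_error_shrinks_with_segment_length(self):
        errs = []
        for dur in (0.5, 1.0, 2.0):
            t = np.arange(int(dur * FS)) / FS
            y = 10.0 + 3.0 * np.exp(-4.0 * t) * np.cos(2 * np.pi * 2.5 * t + 0.4)
            est = estimate_pause_pressure(PressureTrace(FS, y, unit="cmH2O"))
            errs.append(abs(est.pause_pressure - 10.0))
        assert errs[-1] < 0.02
        assert errs[-1] <= errs[0] + 1e-9

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="10 samples"):
            estimate_pause_pressure(PressureTrace(FS, np.arange(5.0), unit="cmH2O"))

    def test_simulated_plateaus_recovered_from_pipeline(self, noisy_analysis):
        by_end = noisy_analysis.pause_table.groupby("end")["pause_cmH2O"].mean()
        assert by_end["inspiratory"] == pytest.approx(18.0, abs=0.3)
        assert by_end["expiratory"] == pytest.approx(12.0, abs=0.3)
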