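"""Synthetic cardiopulmonary waveforms with fully known ground truth.

The study's raw lamb recordings are not deposited, so every downstream stage
is exercised against a simulator that embeds the quantities the analysis is
supposed to recover: an LV pressure built beat-by-beat with an *exact*
monoexponential relaxation of known tau, a programmed LVEDP, slow
liquid-ventilation cycles (6-10/min, I:E 1:2) that impose additive
inspiratory offsets on CVP, LVEDP and tau, and ventilator pause plateaus
carrying exponentially damped oscillations around known pause pressures.

Each beat is piecewise: a flat-ended raised-cosine systolic upstroke from the
beat's effective LVEDP to the systolic peak, a raised-cosine descent to the
pressure at which dP/dt is most negative (P0), an exact decay
``P(t) = P0 * exp(-t / tau_beat)`` from that sample, an undershoot below the
next LVEDP, and a smooth filling ramp back up to the next beat's LVEDP. The
upstroke/descent shapes are unconstrained by the measurements (only
relaxation and end-diastole are analysed); any smooth monotone segment
suffices. Gaussian measurement noise is added to every channel last;
the ground-truth tables record the pre-noise per-beat values.

Offsets are imposed, not emergent: there is no closed-loop physiology here
(no baroreflex, no ventricular interaction, no perfluorocarbon fluid
dynamics).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .trace import PressureTrace
from .ventilation import VentilationSchedule, build_schedule, coarse_phase

CHANNEL_ORDER = ("lv", "cvp", "art", "pap", "vent")


@dataclass
class SimConfig:
    """Simulation parameters. Defaults are the study's operating point:
    pre-liquid-ventilation means tau 21.5 ms and LVEDP 9.3 mmHg, newborn-lamb
    heart rate 160/min, ventilation at 6.5 cycles/min with I:E 1:2,
    inspiratory offsets of +2.6 mmHg on CVP and +1.18 mmHg on LVEDP, and
    initial pause pressures of 18 / 12 cmH2O."""

    duration: float = 60.0  # s
    sampling_rate: float = 1000.0  # Hz
    heart_rate: float = 160.0  # beats/min
    tau_true: float = 21.5  # ms
    lvedp_true: float = 9.3  # mmHg
    lv_peak_pressure: float = 60.0  # mmHg
    p_at_dpdt_min: float = 50.0  # mmHg (P0 of the embedded decay)
    cvp_baseline: float = 8.5  # mmHg
    map_baseline: float = 48.0  # mmHg
    mpap_baseline: float = 31.3  # mmHg
    vent_rate: float = 6.5  # cycles/min
    ie_ratio: float = 0.5  # inspiratory / expiratory duration (1:2)
    insp_offset_cvp: float = 2.6  # mmHg
    insp_offset_lvedp: float = 1.18  # mmHg
    insp_offset_tau: float = 1.5  # ms
    pause_pressure_insp: float = 18.0  # cmH2O
    pause_pressure_exp: float = 12.0  # cmH2O
    oscillation_freq: float = 3.0  # Hz, ringing after flow stop
    oscillation_damping: float = 5.0  # 1/s
    oscillation_amplitude: float = 4.0  # cmH2O
    noise_sd: float = 0.25  # added to every channel, in its own unit
    seed: int = 0
    # waveform-shape knobs (not stated by any measurement; fixed once)
    rise_fraction: float = 0.30  # systolic upstroke, fraction of cardiac period
    descent_fraction: float = 0.25  # peak -> P0 descent, fraction of period
    diastolic_undershoot: float = 4.0  # mmHg below the next LVEDP before filling
    pause_fraction: float = 0.08  # each pause, fraction of ventilation cycle
    drive_pressure_insp: float = 54.0  # cmH2O, proximal pressure during instillation
    drive_pressure_exp: float = -20.0  # cmH2O, during active fluid withdrawal
    cvp_ripple: float = 0.4  # mmHg, cardiac-synchronous CVP ripple amplitude
    drift_amplitude: float = 0.0  # mmHg, optional slow baseline drift (robustness)
    drift_freq: float = 0.02  # Hz

    def __post_init__(self) -> None:
        if self.sampling_rate < 250:
            raise ValueError("sampling_rate must be at least 250 Hz")
        if self.duration <= 0 or self.heart_rate <= 0 or self.tau_true <= 0:
            raise ValueError("duration, heart_rate and tau_true must be positive")
        if not 0 < self.lvedp_true < self.p_at_dpdt_min < self.lv_peak_pressure:
            raise ValueError("need 0 < lvedp_true < p_at_dpdt_min < lv_peak_pressure")
        if self.ie_ratio <= 0:
            raise ValueError("both parts of the I:E ratio must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        period = 60.0 / self.heart_rate
        if self.duration < period:
            raise ValueError("duration too short: shorter than one cardiac cycle")
        if period * self.sampling_rate < 20:
            raise ValueError("heart period not resolvable at sampling_rate")
        if min(self.lvedp_true, self.lvedp_true + self.insp_offset_lvedp) <= self.diastolic_undershoot:
            raise ValueError("diastolic undershoot would push pressure to or below zero")
        if self.diastolic_undershoot <= abs(self.insp_offset_lvedp):
            raise ValueError(
                "diastolic undershoot must exceed the LVEDP offset so relaxation "
                "always crosses the previous beat's LVEDP"
            )
        # every segment must fit inside the cardiac period, worst case
        tau_max_s = (self.tau_true + max(self.insp_offset_tau, 0.0)) / 1000.0
        p_min = min(self.lvedp_true, self.lvedp_true + self.insp_offset_lvedp) - self.diastolic_undershoot
        t_decay = tau_max_s * np.log(self.p_at_dpdt_min / p_min)
        if (self.rise_fraction + self.descent_fraction) * period + t_decay > 0.95 * period:
            raise ValueError("cardiac period too short for the configured beat segments")


@dataclass
class SimulationResult:
    traces: dict[str, PressureTrace]
    schedule: VentilationSchedule
    ground_truth: pd.DataFrame  # one row per complete beat
    pause_truth: pd.DataFrame  # one row per pause plateau
    vent_phase: np.ndarray  # per-sample schedule label
    config: SimConfig = field(repr=False)


def _raised_cosine(u: np.ndarray, width: float, lo: float, hi: float) -> np.ndarray:
    return lo + (hi - lo) * 0.5 * (1.0 - np.cos(np.pi * u / width))


def simulate(config: SimConfig) -> SimulationResult:
    """Generate the multi-channel record, its ventilation schedule and the
    per-beat / per-pause ground truth. Identical config (including seed)
    yields bit-identical output."""
    c = config
    fs = c.sampling_rate
    n = int(round(c.duration * fs))
    t = np.arange(n) / fs
    period = 60.0 / c.heart_rate

    schedule = build_schedule(c.duration, c.vent_rate, c.ie_ratio, c.pause_fraction)

    # per-sample fine phase labels
    labels = np.empty(n, dtype=object)
    insp_mask = np.zeros(n, dtype=bool)
    for seg in schedule.segments:
        i0 = int(np.ceil(seg.start * fs - 1e-9))
        i1 = min(int(np.ceil(seg.end * fs - 1e-9)), n)
        labels[i0:i1] = seg.phase
        if seg.phase == "inspiration":
            insp_mask[i0:i1] = True

    # per-beat effective parameters, decided by the phase at each beat's
    # end-diastolic time (matches the analysis-side gating rule)
    n_beats_total = int(np.ceil(c.duration / period))  # incl. trailing partial beat
    ed_times = np.arange(n_beats_total + 1) * period
    beat_phase = [coarse_phase(schedule.phase_at(min(tk, c.duration)) or "expiration")
                  for tk in ed_times]
    is_insp = np.array([p == "inspiration" for p in beat_phase])
    lvedp_eff = c.lvedp_true + np.where(is_insp, c.insp_offset_lvedp, 0.0)
    tau_eff_ms = c.tau_true + np.where(is_insp, c.insp_offset_tau, 0.0)

    # LV pressure, beat by beat
    lv = np.empty(n)
    t_rise = c.rise_fraction * period
    t_desc = c.descent_fraction * period
    for k in range(n_beats_total):
        t_k = k * period
        i0 = int(np.ceil(t_k * fs - 1e-9))
        i1 = min(int(np.ceil((t_k + period) * fs - 1e-9)), n)
        if i0 >= i1:
            continue
        u = t[i0:i1] - t_k
        tau_s = tau_eff_ms[k] / 1000.0
        p_edp, p_edp_next = lvedp_eff[k], lvedp_eff[k + 1]
        p_min = p_edp_next - c.diastolic_undershoot
        u_ds = t_rise + t_desc
        t_decay = tau_s * np.log(c.p_at_dpdt_min / p_min)
        u_fill = u_ds + t_decay
        y = np.empty_like(u)
        m = u < t_rise
        y[m] = _raised_cosine(u[m], t_rise, p_edp, c.lv_peak_pressure)
        m = (u >= t_rise) & (u < u_ds)
        y[m] = _raised_cosine(u[m] - t_rise, t_desc, c.lv_peak_pressure, c.p_at_dpdt_min)
        m = (u >= u_ds) & (u < u_fill)
        y[m] = c.p_at_dpdt_min * np.exp(-(u[m] - u_ds) / tau_s)
        m = u >= u_fill
        y[m] = _raised_cosine(u[m] - u_fill, period - u_fill, p_min, p_edp_next)
        lv[i0:i1] = y

    f_hr = c.heart_rate / 60.0
    cvp = (
        c.cvp_baseline
        + c.insp_offset_cvp * insp_mask
        + c.cvp_ripple * np.sin(2 * np.pi * f_hr * t)
    )
    art = c.map_baseline + 10.0 * np.sin(2 * np.pi * f_hr * t)
    pap = c.mpap_baseline + 4.0 * np.sin(2 * np.pi * f_hr * t)

    # ventilator proximal pressure (cmH2O): flow-phase ramps and ringing pauses
    vent = np.empty(n)
    pause_rows = []
    for seg in schedule.segments:
        i0 = int(np.ceil(seg.start * fs - 1e-9))
        i1 = min(int(np.ceil(seg.end * fs - 1e-9)), n)
        if i0 >= i1:
            continue
        u = t[i0:i1] - seg.start
        width = seg.end - seg.start
        ramp = min(0.3 * width, width)
        if seg.phase == "inspiration":
            y = np.where(
                u < ramp,
                _raised_cosine(np.minimum(u, ramp), ramp, c.pause_pressure_exp, c.drive_pressure_insp),
                c.drive_pressure_insp,
            )
        elif seg.phase == "expiration":
            y = np.where(
                u < ramp,
                _raised_cosine(np.minimum(u, ramp), ramp, c.pause_pressure_insp, c.drive_pressure_exp),
                c.drive_pressure_exp,
            )
        else:
            plateau = (
                c.pause_pressure_insp if seg.phase == "inspiratory_pause" else c.pause_pressure_exp
            )
            y = plateau + c.oscillation_amplitude * np.exp(-c.oscillation_damping * u) * np.cos(
                2 * np.pi * c.oscillation_freq * u
            )
            pause_rows.append(
                {
                    "cycle": seg.cycle,
                    "end": "inspiratory" if seg.phase == "inspiratory_pause" else "expiratory",
                    "pause_cmH2O": plateau,
                    "start_s": seg.start,
                    "end_s": seg.end,
                }
            )
        vent[i0:i1] = y

    if c.drift_amplitude:
        drift = c.drift_amplitude * np.sin(2 * np.pi * c.drift_freq * t)
        lv = lv + drift
        cvp = cvp + drift

    channels = {"lv": lv, "cvp": cvp, "art": art, "pap": pap, "vent": vent}
    rng = np.random.default_rng(c.seed)
    if c.noise_sd > 0:
        for name in CHANNEL_ORDER:
            channels[name] = channels[name] + rng.normal(0.0, c.noise_sd, n)
    traces = {
        name: PressureTrace(fs, channels[name], unit="cmH2O" if name == "vent" else "mmHg",
                            label=name)
        for name in CHANNEL_ORDER
    }

    # a beat is complete only if its closing end-diastolic time is inside the
    # record (beats truncated by the record edge are not recoverable)
    n_complete = max(int(np.ceil(c.duration / period - 1e-9)) - 1, 0)
    gt = pd.DataFrame(
        {
            "beat": np.arange(n_complete),
            "ed_time_s": ed_times[:n_complete],
            "tau_ms": tau_eff_ms[:n_complete],
            "lvedp_mmHg": lvedp_eff[:n_complete],
            "phase": beat_phase[:n_complete],
        }
    )
    pause_truth = pd.DataFrame(
        pause_rows, columns=["cycle", "end", "pause_cmH2O", "start_s", "end_s"]
    )
    return SimulationResult(
        traces=traces, schedule=schedule, ground_truth=gt, pause_truth=pause_truth,
        vent_phase=labels, config=c,
    )


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> SimConfig:
    return SimConfig(**d)
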