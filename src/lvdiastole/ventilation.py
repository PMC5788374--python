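"""Ventilation-cycle timing, phase-gated beat averaging, and pause pressures.

Total liquid ventilation cycles slowly (6-10 cycles/min) compared with the
cardiac cycle, so several heart beats fall inside each inspiratory or
expiratory segment. Diastolic metrics are contrasted between phases by
averaging a fixed number of beats (k = 5 by default) per phase. When fluid
flow stops at end-inspiration or end-expiration, the proximal airway pressure
rings: it oscillates around the alveolar "pause pressure", which is recovered
here by fitting an exponentially damped sinusoid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .beats import Beat
from .trace import PressureTrace

PHASES = ("inspiration", "inspiratory_pause", "expiration", "expiratory_pause")
#: coarse labels used for beat classification: both pauses collapse to "pause"
COARSE_PHASES = ("inspiration", "expiration", "pause")


def coarse_phase(phase: str) -> str:
    """Map a schedule phase to the three-way label used for beat gating."""
    return "pause" if phase.endswith("_pause") else phase


@dataclass(frozen=True)
class Segment:
    start: float  # s
    end: float  # s
    phase: str  # one of PHASES
    cycle: int


@dataclass
class VentilationSchedule:
    """Contiguous, non-overlapping segments tiling each ventilation cycle.

    Within a cycle the order is inspiration, inspiratory pause, expiration,
    expiratory pause; the inspiration:expiration duration ratio equals the
    configured I:E ratio.
    """

    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.segments, self.segments[1:]):
            if not np.isclose(a.end, b.start):
                raise ValueError("schedule segments must be contiguous")
            if b.start < a.start:
                raise ValueError("schedule segments must be ordered")

    @property
    def span(self) -> tuple[float, float]:
        return self.segments[0].start, self.segments[-1].end

    @property
    def n_cycles(self) -> int:
        return len({s.cycle for s in self.segments})

    def segment_at(self, t: float) -> Segment | None:
        """Segment containing time ``t`` (half-open intervals; last is closed)."""
        for seg in self.segments:
            if seg.start <= t < seg.end:
                return seg
        last = self.segments[-1]
        if t == last.end:
            return last
        return None

    def phase_at(self, t: float) -> str | None:
        seg = self.segment_at(t)
        return None if seg is None else seg.phase

    def phase_segments(self, phase: str) -> list[Segment]:
        return [s for s in self.segments if s.phase == phase]


def build_schedule(
    duration: float,
    vent_rate: float,
    ie_ratio: float,
    pause_fraction: float = 0.08,
) -> VentilationSchedule:
    """Lay out ventilation segments over ``duration`` seconds.

    Parameters
    ----------
    vent_rate : float
        Cycles per minute.
    ie_ratio : float
        Inspiratory over expiratory duration (1:2 -> 0.5).
    pause_fraction : float
        Fraction of the cycle spent in *each* pause (inspiratory and
        expiratory), so flow phases share ``1 - 2 * pause_fraction``.
    """
    if vent_rate <= 0 or ie_ratio <= 0:
        raise ValueError("vent_rate and ie_ratio must be positive")
    if not 0 <= pause_fraction < 0.5:
        raise ValueError("pause_fraction must be in [0, 0.5)")
    cycle_len = 60.0 / vent_rate
    flow = 1.0 - 2.0 * pause_fraction
    t_insp = cycle_len * flow * ie_ratio / (1.0 + ie_ratio)
    t_exp = cycle_len * flow / (1.0 + ie_ratio)
    t_pause = cycle_len * pause_fraction
    order = [
        ("inspiration", t_insp),
        ("inspiratory_pause", t_pause),
        ("expiration", t_exp),
        ("expiratory_pause", t_pause),
    ]
    segments: list[Segment] = []
    t = 0.0
    cycle = 0
    while t < duration:
        for phase, dt in order:
            if t >= duration:
                break
            end = min(t + dt, duration)
            segments.append(Segment(t, end, phase, cycle))
            t = end
        cycle += 1
    return VentilationSchedule(segments)


def schedule_from_labels(times: np.ndarray, labels: np.ndarray) -> VentilationSchedule:
    """Reconstruct a schedule from a per-sample phase-label column.

    Cycle indices restart at each inspiration onset; a record beginning
    mid-cycle counts the leading partial cycle as cycle 0.
    """
    times = np.asarray(times, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if times.size != labels.size or times.size == 0:
        raise ValueError("times and labels must be equal-length and non-empty")
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    dt = times[1] - times[0]
    segments: list[Segment] = []
    cycle = 0
    for k, (i, j) in enumerate(zip(starts, ends)):
        phase = str(labels[i])
        if phase not in PHASES:
            raise ValueError(f"unknown ventilation phase label {phase!r}")
        if phase == "inspiration" and k > 0:
            cycle += 1
        end = times[j - 1] + dt if j == labels.size else times[j]
        segments.append(Segment(times[i], end, phase, cycle))
    return VentilationSchedule(segments)


def classify_beats(
    beats: list[Beat], schedule: VentilationSchedule, sampling_rate: float
) -> dict[int, str | None]:
    """Assign each beat the coarse phase of the segment containing its
    end-diastolic time; beats outside the schedule span are unclassified
    (``None``) with a warning."""
    out: dict[int, str | None] = {}
    for i, b in enumerate(beats):
        t_ed = b.ed_index / sampling_rate
        seg = schedule.segment_at(t_ed)
        if seg is None:
            warnings.warn(f"beat {i} at t={t_ed:.3f}s lies outside the ventilation schedule")
            out[i] = None
        else:
            out[i] = coarse_phase(seg.phase)
    return out


@dataclass
class PhaseAveragedMetrics:
    """Unweighted mean of each metric over exactly k beats of one phase."""

    phase: str
    k: int
    means: dict[str, float]
    beat_indices: list[int]


def phase_average(
    beats: list[Beat],
    metrics: dict[int, dict[str, float]],
    phase_of: dict[int, str | None],
    phase: str,
    schedule: VentilationSchedule,
    sampling_rate: float,
    k: int = 5,
) -> PhaseAveragedMetrics:
    """Average metrics over the ``k`` beats of ``phase`` nearest the temporal
    midpoints of that phase's segments.

    ``metrics`` maps beat index -> metric dict; beats with any non-finite
    metric are excluded. Raises ``ValueError`` naming the deficit when fewer
    than ``k`` valid beats are available.
    """
    segs = schedule.phase_segments(phase) or [
        s for s in schedule.segments if coarse_phase(s.phase) == phase
    ]
    if not segs:
        raise ValueError(f"schedule contains no {phase!r} segments")

    candidates: list[tuple[float, int]] = []
    for i, b in enumerate(beats):
        if phase_of.get(i) != coarse_phase(phase) and phase_of.get(i) != phase:
            continue
        m = metrics.get(i)
        if m is None or not all(np.isfinite(v) for v in m.values()):
            continue
        t_ed = b.ed_index / sampling_rate
        seg = schedule.segment_at(t_ed)
        mid = (seg.start + seg.end) / 2 if seg is not None else np.inf
        candidates.append((abs(t_ed - mid), i))
    if len(candidates) < k:
        raise ValueError(
            f"phase {phase!r} has only {len(candidates)} beats with valid metrics; "
            f"{k} required"
        )
    candidates.sort()
    chosen = sorted(i for _, i in candidates[:k])
    keys = metrics[chosen[0]].keys()
    means = {key: float(np.mean([metrics[i][key] for i in chosen])) for key in keys}
    return PhaseAveragedMetrics(phase=phase, k=k, means=means, beat_indices=chosen)


@dataclass
class PausePressureEstimate:
    """Extrapolated alveolar pause pressure from an oscillating plateau."""

    cycle: int
    end: str  # "inspiratory" | "expiratory"
    pause_pressure: float  # cmH2O
    residual_rms: float
    amplitude: float
    damping: float  # 1/s, >= 0
    frequency: float  # Hz
    phase: float  # rad
    fallback: bool = False


def _damped_cosine(t, p_pause, amp, zeta, omega, phi):
    return p_pause + amp * np.exp(-zeta * t) * np.cos(omega * t + phi)


def estimate_pause_pressure(
    segment: PressureTrace, cycle: int = 0, end: str = "inspiratory"
) -> PausePressureEstimate:
    """Fit ``P(t) = P_pause + A exp(-zeta t) cos(omega t + phi)`` to a
    post-flow-stop plateau and return the asymptote ``P_pause``.

    Initialisation: P_pause from the segment mean, omega from the dominant
    non-DC FFT frequency, A and zeta from a log-envelope line. A segment with
    no variation returns its mean exactly (A = 0). A non-convergent fit falls
    back to the mean of the final quartile of the segment, flagged.
    """
    y = segment.values
    if y.size < 10:
        raise ValueError("pause segment needs at least 10 samples")
    t = segment.times()
    c0 = float(np.mean(y))
    r = y - c0
    if np.ptp(r) == 0.0:
        return PausePressureEstimate(cycle, end, c0, 0.0, 0.0, 0.0, 0.0, 0.0)

    # dominant oscillation frequency, excluding DC
    spec = np.abs(np.fft.rfft(r))
    freqs = np.fft.rfftfreq(r.size, d=1.0 / segment.sampling_rate)
    k = int(np.argmax(spec[1:])) + 1
    f0 = max(freqs[k], 1e-3)

    # amplitude/damping from the log of the analytic-signal envelope
    env = np.abs(signal.hilbert(r))
    core = slice(r.size // 10, -max(r.size // 10, 1))  # trim Hilbert edge artefacts
    env_core = np.clip(env[core], 1e-9, None)
    slope, intercept = np.polyfit(t[core], np.log(env_core), 1)
    a0 = float(np.exp(intercept))
    zeta0 = float(max(-slope, 0.0))
    phi0 = float(np.arctan2(-r[0] * 0.0, r[0]) if r[0] != 0 else 0.0)

    p0 = [c0, a0, zeta0, 2 * np.pi * f0, phi0]
    try:
        res = optimize.least_squares(
            lambda p: _damped_cosine(t, *p) - y,
            p0,
            bounds=([-np.inf, 0.0, 0.0, 0.0, -np.pi], [np.inf, np.inf, np.inf, np.inf, np.pi]),
            max_nfev=2000,
        )
        ok = res.success and np.isfinite(res.x).all()
    except Exception:
        ok = False
    if not ok:
        tail = y[3 * y.size // 4 :]
        return PausePressureEstimate(
            cycle, end, float(np.mean(tail)), float(np.std(y)), 0.0, 0.0, 0.0, 0.0, fallback=True
        )
    p_pause, amp, zeta, omega, phi = res.x
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return PausePressureEstimate(
        cycle, end, float(p_pause), rms, float(amp), float(zeta), float(omega / (2 * np.pi)),
        float(phi),
    )
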