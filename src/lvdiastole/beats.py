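"""Beat segmentation and landmark detection on LV pressure traces.

The left-ventricular pressure signal is turned into a list of located beats,
each carrying its dP/dt-maximum and dP/dt-minimum indices, its end-diastolic
index and the LVEDP read there. dP/dt is the plain central-difference
derivative of the pressure curve; for noisy catheter signals an optional
Savitzky-Golay pre-smoothing is available (off by default — the simplest
consistent estimator is the baseline).

End-diastole is located from pressure alone (no ECG channel exists in this
data model): it is the last sample before the rapid upstroke at which dP/dt
is still below a fraction (default 10%) of that beat's peak positive dP/dt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .trace import DerivativeTrace, PressureTrace


def smooth_trace(trace: PressureTrace, window: int = 31, polyorder: int = 3) -> PressureTrace:
    """Savitzky-Golay smoothed copy of a trace (for high-noise input)."""
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and larger than polyorder")
    sm = signal.savgol_filter(trace.values, window, polyorder)
    return PressureTrace(trace.sampling_rate, sm, unit=trace.unit, label=trace.label)


def compute_derivative(trace: PressureTrace) -> DerivativeTrace:
    """dP/dt by central differences (one-sided at the record edges), in
    (unit)/s. Requires at least 3 samples."""
    if trace.n_samples < 3:
        raise ValueError("derivative needs at least 3 samples")
    d = np.gradient(trace.values, 1.0 / trace.sampling_rate)
    return DerivativeTrace(trace.sampling_rate, d, source=trace)


@dataclass
class Beat:
    """One cardiac cycle on a trace: [end-diastolic index, next end-diastolic
    index), half-open so every sample belongs to exactly one beat."""

    start: int
    end: int
    dpdt_max_index: int
    dpdt_min_index: int
    ed_index: int
    lvedp: float  # mmHg, trace value at ed_index
    dpdt_max: float  # mmHg/s
    dpdt_min: float  # mmHg/s
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid:
            if not (self.start <= self.ed_index < self.dpdt_max_index < self.dpdt_min_index <= self.end):
                raise ValueError("beat landmark ordering violated")
            if not (self.dpdt_min < 0 < self.dpdt_max):
                raise ValueError("beat requires dpdt_min < 0 < dpdt_max")


def _ed_index_before(
    deriv: np.ndarray, peak: int, lower_bound: int, threshold_fraction: float
) -> int | None:
    """Last index in (lower_bound, peak) where dP/dt < fraction * dP/dt(peak)."""
    thr = threshold_fraction * deriv[peak]
    for j in range(peak - 1, lower_bound, -1):
        if deriv[j] < thr:
            return j
    return None


def detect_lvedp(
    trace: PressureTrace,
    deriv: DerivativeTrace,
    dpdt_max_index: int,
    search_start: int = 0,
    threshold_fraction: float = 0.1,
    refine: bool = True,
) -> tuple[int, float] | None:
    """End-diastolic index and LVEDP for the beat whose upstroke peaks at
    ``dpdt_max_index``.

    The candidate is the last sample before the dP/dt maximum at which dP/dt
    is below ``threshold_fraction`` of the peak value. Because any threshold
    fires a little way *into* the upstroke, ``refine`` then extrapolates the
    local dP/dt tangent back to zero (the intersecting-tangent foot-detection
    rule) and reads LVEDP at that onset sample instead; the backward shift is
    bounded to stay physiologic. Returns ``(ed_index, lvedp)``, or ``None``
    when no sub-threshold sample exists before the upstroke (malformed beat).
    """
    d = deriv.values
    ed = _ed_index_before(d, dpdt_max_index, search_start - 1, threshold_fraction)
    if ed is None:
        return None
    if refine and 1 <= ed < d.size - 1:
        slope = (d[ed + 1] - d[ed - 1]) / 2.0  # per sample
        if slope > 0 and d[ed] > 0:
            back = d[ed] / slope
            max_back = max(int(round(0.02 * trace.sampling_rate)), 1)  # <= 20 ms
            shift = min(int(round(back)), max_back)
            ed = max(ed - shift, search_start + 1, 0)
    return ed, float(trace.values[ed])


def segment_beats(
    trace: PressureTrace,
    deriv: DerivativeTrace,
    min_rate: float = 60.0,
    max_rate: float = 300.0,
    threshold_fraction: float = 0.5,
    ed_threshold_fraction: float = 0.1,
    min_rise: float = 5.0,
) -> list[Beat]:
    """Locate complete beats as successive dP/dt-maximum events.

    Upstroke events are peaks of dP/dt exceeding an adaptive threshold
    (``threshold_fraction`` of the 90th percentile of positive dP/dt,
    default 50%), separated by at least ``60 / max_rate`` seconds. Each beat
    spans from its end-diastolic index to the next beat's; beats truncated by
    the record edges are discarded. No detectable beat returns an empty list.

    ``min_rise`` (mmHg) is an amplitude criterion: a candidate upstroke must
    raise pressure by at least this much between end-diastole and the dP/dt
    maximum. LV pulse amplitudes are tens of mmHg, so the default 5 mmHg
    floor rejects incoherent noise excursions without touching real beats.
    """
    if deriv.n_samples != trace.n_samples or deriv.sampling_rate != trace.sampling_rate:
        raise ValueError("trace and derivative are not aligned")
    if not 0 < min_rate < max_rate:
        raise ValueError("need 0 < min_rate < max_rate")
    d = deriv.values
    pos = d[d > 0]
    if pos.size == 0:
        return []
    height = threshold_fraction * np.percentile(pos, 90)
    distance = max(int(round(trace.sampling_rate * 60.0 / max_rate)), 1)
    peaks, _ = signal.find_peaks(d, height=height, distance=distance)
    if peaks.size < 2:
        return []

    # plausibility guard: median spacing must correspond to a credible rate
    med_rate = 60.0 * trace.sampling_rate / np.median(np.diff(peaks))
    if not (min_rate <= med_rate <= max_rate):
        return []

    eds: list[int | None] = []
    prev_peak = 0
    for p in peaks:
        res = detect_lvedp(trace, deriv, p, search_start=prev_peak,
                           threshold_fraction=ed_threshold_fraction)
        eds.append(None if res is None else res[0])
        prev_peak = p

    beats: list[Beat] = []
    for i in range(len(peaks) - 1):
        ed, nxt = eds[i], eds[i + 1]
        if ed is None or nxt is None:
            continue
        pk = int(peaks[i])
        seg = d[pk:nxt]
        if seg.size == 0:
            continue
        min_idx = pk + int(np.argmin(seg))
        dpdt_min = float(d[min_idx])
        dpdt_max = float(d[pk])
        if not (dpdt_min < 0 < dpdt_max) or not (ed < pk < min_idx <= nxt):
            continue
        if trace.values[pk] - trace.values[ed] < min_rise:
            continue
        beats.append(
            Beat(
                start=int(ed),
                end=int(nxt),
                dpdt_max_index=pk,
                dpdt_min_index=int(min_idx),
                ed_index=int(ed),
                lvedp=float(trace.values[ed]),
                dpdt_max=dpdt_max,
                dpdt_min=dpdt_min,
            )
        )
    return beats
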