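"""Isovolumic relaxation time constant (tau) by windowed monoexponential fit.

The relaxation period of a beat runs from the time of minimum dP/dt to the
point where LV pressure drops below the previous beat's LVEDP. Within that
window the zero-asymptote (Weiss-type) model

    P(t) = P0 * exp(-t / tau)

is fitted by a Nelder-Mead simplex search over tau alone: P0 is *fixed* at
the measured LV pressure at the dP/dt-minimum sample and t is shifted so that
t = 0 there, making the fit one-dimensional. A log-linear regression of
ln(P) on t provides the initial estimate (and an independent estimator), and
an exhaustive grid search provides a brute-force oracle. A free-P0 variant
exists behind a flag for sensitivity analysis; it is not the default. No
baseline-pressure (non-zero asymptote) term is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .beats import Beat
from .trace import PressureTrace

#: fits hitting this ceiling are flagged, not silently reported
TAU_MAX_MS = 500.0
MIN_WINDOW_SAMPLES = 5


@dataclass
class RelaxationWindow:
    """Relaxation-period samples of one beat, with t = 0 at dP/dt minimum."""

    start: int  # index of the beat's dP/dt minimum
    end: int  # index of the first sample strictly below the previous LVEDP (inclusive)
    t: np.ndarray  # seconds, t[0] = 0
    pressure: np.ndarray  # mmHg
    usable: bool = True
    reason: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.usable:
            if self.start >= self.end:
                raise ValueError("window start must precede end")
            if self.t.size and self.t[0] != 0.0:
                raise ValueError("window time axis must start at 0")
            if self.t.size < MIN_WINDOW_SAMPLES:
                raise ValueError("usable window shorter than the minimum sample count")

    @property
    def p0(self) -> float:
        """LV pressure at the dP/dt-minimum sample (the fixed model amplitude)."""
        return float(self.pressure[0])

    @property
    def n_samples(self) -> int:
        return int(self.t.size)


@dataclass
class TauFit:
    tau: float  # ms
    p0: float  # mmHg, fixed
    sse: float  # mmHg^2
    n_samples: int
    converged: bool
    method: str  # "simplex" | "loglinear" | "grid"
    at_bound: bool = False

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.sse < 0:
            raise ValueError("sse must be non-negative")


def extract_relaxation_window(
    trace: PressureTrace, beats: list[Beat], i: int
) -> RelaxationWindow:
    """Relaxation window of beat ``i``: from its dP/dt-minimum index to the
    first subsequent sample *strictly below* beat ``i-1``'s LVEDP (that
    crossing sample included).

    The first beat of a record has no previous LVEDP and raises; a beat whose
    decay never crosses before the beat ends comes back flagged unusable, as
    does a window shorter than the minimum sample count.
    """
    if i == 0:
        raise ValueError("no previous LVEDP: the first beat of a record carries no tau")
    if not 0 < i < len(beats):
        raise IndexError(f"beat index {i} out of range")
    beat = beats[i]
    prev_lvedp = beats[i - 1].lvedp
    start = beat.dpdt_min_index
    seg = trace.values[start : beat.end + 1]
    below = np.flatnonzero(seg < prev_lvedp)
    fs = trace.sampling_rate
    if below.size == 0:
        return RelaxationWindow(
            start, start, np.array([]), np.array([]), usable=False,
            reason="pressure never drops below previous LVEDP",
        )
    end = start + int(below[0])
    n = end - start + 1
    if n < MIN_WINDOW_SAMPLES:
        return RelaxationWindow(
            start, end, np.array([]), np.array([]), usable=False,
            reason=f"window of {n} samples is below the {MIN_WINDOW_SAMPLES}-sample minimum",
        )
    t = np.arange(n) / fs
    return RelaxationWindow(start, end, t, trace.values[start : end + 1].copy())


def _sse(tau_ms: float, t: np.ndarray, p: np.ndarray, p0: float) -> float:
    model = p0 * np.exp(-t / (tau_ms / 1000.0))
    r = p - model
    return float(r @ r)


def fit_tau_loglinear(window: RelaxationWindow) -> TauFit:
    """tau from the least-squares line of ln(P) on t (zero-asymptote model
    only: valid because the fitted exponential decays to zero)."""
    if not window.usable:
        raise ValueError(f"window unusable: {window.reason}")
    p = window.pressure
    if np.any(p <= 0):
        raise ValueError("log-linear fit requires strictly positive pressures")
    slope, _ = np.polyfit(window.t, np.log(p), 1)
    if slope >= -1e-9:  # flat windows regress to slope 0 up to rounding
        raise ValueError("non-decaying window: log-linear slope is non-negative")
    tau_ms = -1000.0 / slope
    return TauFit(
        tau=float(tau_ms), p0=window.p0, sse=_sse(tau_ms, window.t, p, window.p0),
        n_samples=window.n_samples, converged=True, method="loglinear",
    )


def fit_tau_simplex(
    window: RelaxationWindow, tau_max: float = TAU_MAX_MS, free_p0: bool = False
) -> TauFit:
    """tau minimising SSE = sum (P_k - P0 exp(-t_k/tau))^2 by Nelder-Mead
    simplex, initialised from the log-linear estimate (fallback 20 ms when no
    log-linear initialiser exists). Convergence tolerance 1e-6 ms; a solution
    at the tau ceiling is flagged ``at_bound``.

    With ``free_p0`` both tau and P0 are optimised (sensitivity analysis
    only; the canonical fit fixes P0 at the measured window-start pressure).
    """
    if not window.usable:
        raise ValueError(f"window unusable: {window.reason}")
    t, p, p0 = window.t, window.pressure, window.p0
    try:
        tau0 = fit_tau_loglinear(window).tau
        tau0 = min(max(tau0, 1e-3), tau_max)
    except ValueError:
        tau0 = 20.0  # physiologic mid-range fallback when ln(P) is undefined

    if free_p0:
        def objective(x):
            if x[0] <= 0 or x[0] > tau_max:
                return np.inf
            model = x[1] * np.exp(-t / (x[0] / 1000.0))
            r = p - model
            return float(r @ r)
        x0 = np.array([tau0, p0])
    else:
        def objective(x):
            if x[0] <= 0 or x[0] > tau_max:
                return np.inf
            return _sse(x[0], t, p, p0)
        x0 = np.array([tau0])

    res = optimize.minimize(
        objective, x0, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 10_000},
    )
    tau = float(res.x[0])
    fitted_p0 = float(res.x[1]) if free_p0 else p0
    if not np.isfinite(tau) or tau <= 0:
        raise RuntimeError("simplex optimizer failed to produce a positive tau")
    return TauFit(
        tau=tau, p0=fitted_p0, sse=float(res.fun), n_samples=window.n_samples,
        converged=bool(res.success), method="simplex",
        at_bound=bool(tau >= tau_max - 1e-3),
    )


def fit_tau_grid(
    window: RelaxationWindow, tau_lo: float = 1.0, tau_hi: float = 100.0, step: float = 0.01
) -> TauFit:
    """Exhaustive SSE evaluation on a tau grid (ms); brute-force oracle.
    Ties break toward smaller tau."""
    if not 0 < tau_lo < tau_hi or step <= 0:
        raise ValueError("need 0 < tau_lo < tau_hi and step > 0")
    if not window.usable:
        raise ValueError(f"window unusable: {window.reason}")
    taus = np.arange(tau_lo, tau_hi + step / 2, step)
    t, p, p0 = window.t, window.pressure, window.p0
    model = p0 * np.exp(-np.outer(1.0 / (taus / 1000.0), t))
    sse = ((p[None, :] - model) ** 2).sum(axis=1)
    k = int(np.argmin(sse))  # argmin returns the first (smallest-tau) minimiser
    return TauFit(
        tau=float(taus[k]), p0=p0, sse=float(sse[k]), n_samples=window.n_samples,
        converged=True, method="grid",
    )
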