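"""Uniformly sampled pressure channels and their time derivatives.

A :class:`PressureTrace` is the raw material of every analysis stage: one
channel of a multi-channel haemodynamic recording, sampled at a fixed rate,
tagged with its unit (vascular and intracardiac channels in mmHg, the
ventilator's proximal pressure in cmH2O; 1 cmH2O = 0.7355 mmHg, conversion is
never applied automatically).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_UNITS = ("mmHg", "cmH2O")


@dataclass
class PressureTrace:
    """One uniformly sampled pressure channel.

    Parameters
    ----------
    sampling_rate : float
        Samples per second (Hz).
    values : ndarray
        Pressure samples, in the unit given by ``unit``.
    unit : str
        ``"mmHg"`` or ``"cmH2O"``.
    label : str
        Channel label, e.g. ``"lv"`` or ``"vent"``.
    """

    sampling_rate: float
    values: np.ndarray
    unit: str = "mmHg"
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("a trace needs at least 2 samples in one dimension")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class DerivativeTrace:
    """dP/dt of a :class:`PressureTrace`, in (unit)/s, aligned sample-for-sample."""

    sampling_rate: float
    values: np.ndarray
    source: PressureTrace | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.source is not None:
            if self.values.size != self.source.n_samples:
                raise ValueError("derivative must have same length as its source")
            if self.sampling_rate != self.source.sampling_rate:
                raise ValueError("derivative must have same sampling rate as its source")

    @property
    def n_samples(self) -> int:
        return self.values.size
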