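import numpy as np
import pytest

from lvdiastole.pipeline import RunConfig, analyze_traces
from lvdiastole.relaxation import RelaxationWindow
from lvdiastole.simulate import SimConfig, simulate

HEART_PERIOD = 60.0 / 160.0  # s, default simulated heart rate


def make_window(
    tau_ms: float = 25.0,
    p0: float = 50.0,
    duration_ms: float = 40.0,
    fs: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RelaxationWindow:
    """Directly constructed monoexponential relaxation window."""
    t = np.arange(int(round(duration_ms / 1000.0 * fs))) / fs
    p = p0 * np.exp(-t / (tau_ms / 1000.0))
    if noise_sd > 0:
        p = p + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    return RelaxationWindow(start=0, end=t.size - 1, t=t, pressure=p)


@pytest.fixture(scope="session")
def noiseless_sim():
    """10 s noise-free recording: programmed LVEDP 9.0 mmHg, tau 25 ms,
    no inspiratory offsets on the diastolic parameters."""
    cfg = SimConfig(
        duration=10.0, tau_true=25.0, lvedp_true=9.0, noise_sd=0.0,
        insp_offset_lvedp=0.0, insp_offset_tau=0.0, seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def noiseless_analysis(noiseless_sim):
    return analyze_traces(
        noiseless_sim.traces, noiseless_sim.vent_phase, RunConfig(smoothing=False)
    )


@pytest.fixture(scope="session")
def noisy_sim():
    """60 s study-condition recording with measurement noise 0.5 mmHg."""
    cfg = SimConfig(
        duration=60.0, tau_true=25.0, lvedp_true=9.0, noise_sd=0.5,
        insp_offset_lvedp=0.0, insp_offset_tau=0.0, seed=42,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def noisy_analysis(noisy_sim):
    return analyze_traces(noisy_sim.traces, noisy_sim.vent_phase, RunConfig())
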