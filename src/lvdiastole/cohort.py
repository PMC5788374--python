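"""Multi-subject runs: simulate a small cohort and contrast ventilation phases.

The study design is paired within subject: each animal contributes one value
per metric per condition (here, inspiratory vs expiratory phase means), and
conditions are compared with a paired t-test across subjects. Between-subject
spread is modelled as Gaussian variation of the baseline parameters around
the cohort means; the programmed inspiratory offsets are common to all
subjects (they are the effects under test, not subject traits).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .pipeline import METRIC_KEYS, RunConfig, analyze_traces
from .simulate import SimConfig, SimulationResult, simulate


def cohort_configs(
    n_subjects: int = 8,
    base: SimConfig | None = None,
    seed: int = 0,
    tau_sd: float = 2.0,
    lvedp_sd: float = 1.0,
    heart_rate_sd: float = 10.0,
) -> list[SimConfig]:
    """Per-subject configs: baseline tau, LVEDP and heart rate vary between
    subjects; each subject gets its own noise seed."""
    base = base or SimConfig()
    rng = np.random.default_rng(seed)
    configs = []
    for _ in range(n_subjects):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        configs.append(
            replace(
                base,
                tau_true=float(max(base.tau_true + rng.normal(0.0, tau_sd), 5.0)),
                lvedp_true=float(max(base.lvedp_true + rng.normal(0.0, lvedp_sd),
                                     base.diastolic_undershoot + 1.0)),
                heart_rate=float(np.clip(base.heart_rate + rng.normal(0.0, heart_rate_sd),
                                         100.0, 220.0)),
                seed=sub_seed,
            )
        )
    return configs


def simulate_cohort(configs: list[SimConfig]) -> list[tuple[str, SimulationResult]]:
    return [(f"lamb{i + 1:02d}", simulate(cfg)) for i, cfg in enumerate(configs)]


def phase_summaries(
    cohort: list[tuple[str, SimulationResult]], run_config: RunConfig | None = None
) -> pd.DataFrame:
    """Per-subject 5-beat phase means, one row per (subject, phase).

    The returned table feeds :func:`lvdiastole.stats.compare_conditions`
    directly, with the phase as the condition label.
    """
    run_config = run_config or RunConfig()
    rows = []
    for subject, res in cohort:
        ar = analyze_traces(res.traces, res.vent_phase, run_config)
        for _, prow in ar.phase_table.iterrows():
            rows.append(
                {"subject": subject, "condition": prow["phase"],
                 **{m: prow[m] for m in METRIC_KEYS}}
            )
    return pd.DataFrame(rows)
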