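"""Stable plain-text table dialect shared by all stages.

Every table is comma-separated UTF-8 with a header row, '.' decimal and LF
line endings, preceded by a single dialect-declaration line. Parsers reject
unknown dialect versions loudly. Waveform-standard formats (WFDB/EDF) are
out of core scope.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SimConfig, SimulationResult, config_to_dict
from .trace import PressureTrace

DIALECT = "lvdiastole-table/1"

TRACE_COLUMNS = ["time_s", "lv_mmHg", "cvp_mmHg", "art_mmHg", "pap_mmHg", "vent_cmH2O", "vent_phase"]
_CHANNEL_TO_COLUMN = {
    "lv": "lv_mmHg", "cvp": "cvp_mmHg", "art": "art_mmHg", "pap": "pap_mmHg", "vent": "vent_cmH2O",
}


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# dialect: {DIALECT}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
    if not first.startswith("# dialect:"):
        raise ValueError(f"{path}: missing dialect declaration line")
    version = first.split(":", 1)[1].strip()
    if version != DIALECT:
        raise ValueError(f"{path}: unknown table dialect {version!r} (expected {DIALECT!r})")
    return pd.read_csv(path, skiprows=1)


def write_simulation(result: SimulationResult, outdir: str | Path) -> dict[str, Path]:
    """Write a simulation as trace.csv + ground_truth.csv + pause_truth.csv +
    config.json under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lv = result.traces["lv"]
    df = pd.DataFrame({"time_s": lv.times()})
    for name, col in _CHANNEL_TO_COLUMN.items():
        df[col] = result.traces[name].values
    df["vent_phase"] = result.vent_phase
    paths = {
        "trace": outdir / "trace.csv",
        "ground_truth": outdir / "ground_truth.csv",
        "pause_truth": outdir / "pause_truth.csv",
        "config": outdir / "config.json",
    }
    write_table(df, paths["trace"])
    write_table(result.ground_truth, paths["ground_truth"])
    write_table(result.pause_truth, paths["pause_truth"])
    with open(paths["config"], "w", encoding="utf-8") as fh:
        json.dump(config_to_dict(result.config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def read_trace_file(path: str | Path) -> tuple[dict[str, PressureTrace], np.ndarray]:
    """Parse a trace.csv into per-channel :class:`PressureTrace` objects plus
    the per-sample ventilation-phase labels. Errors name the missing column."""
    df = read_table(path)
    for col in TRACE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: trace file is missing required column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: trace needs at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: time_s column is not uniformly sampled")
    fs = 1.0 / dt[0]
    traces = {
        name: PressureTrace(
            fs, df[col].to_numpy(dtype=float),
            unit="cmH2O" if name == "vent" else "mmHg", label=name,
        )
        for name, col in _CHANNEL_TO_COLUMN.items()
    }
    return traces, df["vent_phase"].to_numpy(dtype=object)
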