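# lvdiastole

Left-ventricular diastolic function from catheter pressure waveforms, for
studies of cardiopulmonary interaction during (liquid) mechanical
ventilation. The package measures, per beat:

- **dP/dt max / min** from the derivative of LV pressure,
- **LVEDP** at the onset of the rapid systolic upstroke,
- **tau (τ)**, the isovolumic relaxation time constant, by fitting the
  zero-asymptote monoexponential **P(t) = P₀·e^(−t/τ)** over the relaxation
  window — from the time of minimum dP/dt to the sample where pressure drops
  below the previous beat's LVEDP — with a Nelder–Mead simplex search over τ
  (P₀ fixed at the pressure at minimum dP/dt, t = 0 there),

then gates beats by the phase of the slow ventilation cycle (averaging 5
beats per inspiratory/expiratory phase), extrapolates ventilator **pause
pressures** from damped plateau oscillations
(P_pause + A·e^(−ζt)·cos(ωt + φ)), and reports paired contrasts as
mean ± SEM with two-sided paired t-tests.

Because the original animal recordings are not publicly available, the
package ships a synthetic cardiopulmonary simulator
(`lvdiastole.simulate`) that embeds known τ, LVEDP, inspiratory offsets and
pause plateaus in multi-channel waveforms, so every stage is validated by
parameter recovery. See `docs/methods.md` for the model and its limits.

## Worked example

```python
from lvdiastole import SimConfig, simulate, RunConfig, analyze_traces

# 60 s record: tau 25 ms, LVEDP 9 mmHg, 0.5 mmHg noise, vent 6.5 cycles/min
cfg = SimConfig(duration=60.0, tau_true=25.0, lvedp_true=9.0, noise_sd=0.5,
                insp_offset_tau=0.0, insp_offset_lvedp=0.0, seed=42)
res = simulate(cfg)
ar = analyze_traces(res.traces, res.vent_phase, RunConfig())

taus = ar.tau_table.query("usable")["tau_ms"]
print(f"beats: {len(ar.beats)} (true {len(res.ground_truth)})")
print(f"tau:   {taus.mean():.2f} ms (true 25.00)")
print(f"LVEDP: {ar.beat_table['lvedp_mmHg'].mean():.2f} mmHg (true 9.00)")
```

prints

```
beats: 159 (true 159)
tau:   25.01 ms (true 25.00)
LVEDP: 9.05 mmHg (true 9.00)
```

i.e. every beat is found, the relaxation constant is recovered essentially
exactly on average, and detected end-diastolic pressure sits within
0.1 mmHg of the programmed value despite the noise.

The same chain is scriptable from a shell:

```sh
lvdiastole simulate --out sim/ --seed 42
lvdiastole analyze --input sim/trace.csv --out analysis/
lvdiastole compare --summaries results/phase_summaries.csv \
    --condition-a inspiration --condition-b expiration --out cmp/
```

## Analysis scripts

`analysis/` holds the narrative drivers, in order: `01_simulate_cohort.py`
(eight 60 s subjects with between-subject variation; waveforms under
`scratch/`, summaries under `results/`), `02_analyze_recordings.py` (per-
subject pipeline runs, recovery checks, pause pressures) and
`03_phase_effects.py` (inspiration-vs-expiration paired contrasts, e.g. the
programmed +1.18 mmHg inspiratory LVEDP offset recovered as
+1.157 ± 0.012 mmHg, t(7) = 97.7).

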