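# Methods

## The measurement problem

During total liquid ventilation (TLV) the lungs are filled with dense
perfluorocarbon and ventilated at 6–10 cycles/min, and a long-standing
concern is that the liquid-filled lung compresses the heart and impairs
left-ventricular (LV) diastolic function. The package implements the
measurement chain used to test that concern on high-fidelity LV pressure
recordings:

1. **dP/dt** — the time derivative of LV pressure; its maximum and minimum
   are systolic and diastolic function indices.
2. **LVEDP** — LV end-diastolic pressure, read at the onset of the rapid
   systolic upstroke.
3. **tau (τ)** — the isovolumic relaxation time constant. The relaxation
   period of a beat is the data from the time of minimum dP/dt to the point
   where LV pressure drops below the previous beat's LVEDP. Over that window
   the zero-asymptote (Weiss-type) monoexponential

       P(t) = P0 · exp(−t/τ)

   is fitted by a Nelder–Mead simplex search, with P0 *fixed* at the
   measured pressure at the dP/dt minimum and t = 0 there. Fixing P0 makes
   the search one-dimensional; a free-P0 variant exists behind a flag for
   sensitivity analysis only. No non-zero asymptote is modelled.
4. **Ventilation-phase gating** — because TLV cycles are slow relative to
   the cardiac cycle, diastolic metrics are averaged over 5 beats per
   inspiratory and expiratory phase and contrasted within subject.
5. **Pause pressures** — when fluid flow stops, proximal airway pressure
   rings around the alveolar pressure; the plateau is recovered by fitting
   P(t) = P_pause + A·e^(−ζt)·cos(ωt + φ) by least squares.
6. **Reporting** — mean ± SEM and two-sided paired t-tests across subjects,
   p values from the t distribution at full precision, no multiplicity
   correction (a deliberate match to the original reporting style, and a
   documented limitation).

## Synthetic recordings

No raw recordings are available, so a simulator generates multi-channel
records with fully known ground truth; every quantitative claim the tests
make is a recovery claim against that truth.

Each LV beat is piecewise: a raised-cosine upstroke from the beat's
effective LVEDP to the systolic peak over 30% of the cardiac period, a
raised-cosine descent to P0 over 25%, an *exact* monoexponential decay from
the P0 sample (so the estimand is embedded by construction), an undershoot
to 4 mmHg below the next LVEDP, and a raised-cosine filling ramp back up.
The undershoot is what lets the relaxation window terminate: a filling phase
flat at exactly LVEDP would never drop *strictly below* the previous LVEDP.
Its 4 mmHg default approximates a physiologic minimal diastolic pressure and
must exceed the inspiratory LVEDP offset (validated) so the crossing always
exists. Upstroke and descent shapes are unconstrained by any measurement —
only relaxation and end-diastole are analysed — and LV diastasis/atrial-kick
morphology is deliberately not modelled.

Defaults are the study operating point: τ 21.5 ms, LVEDP 9.3 mmHg, CVP
8.5 mmHg, systemic/pulmonary means 48/31.3 mmHg, ventilation 6.5 cycles/min
at I:E 1:2, inspiratory offsets +2.6 mmHg (CVP) and +1.18 mmHg (LVEDP), and
pause plateaus 18/12 cmH2O with a 4 cmH2O, 3 Hz oscillation damped at 5 s⁻¹.
Values the measurements do not pin down were fixed once at physiologic
choices for newborn lambs: heart rate 160/min, sampling 1000 Hz (typical
catheter acquisition), LV peak 60 mmHg, P0 50 mmHg, inspiratory tau offset
+1.5 ms (the inspiratory tau increase is reported as significant but without
a magnitude in text), each ventilator pause 8% of the cycle, driving
pressures +54/−20 cmH2O, CVP cardiac ripple 0.4 mmHg. Measurement noise is
i.i.d. Gaussian (default SD 0.25 mmHg per channel, in the channel's own
unit) added after waveform construction; optional slow sinusoidal baseline
drift exists for robustness work and is off by default. Vascular channels
are mmHg, the ventilator channel cmH2O; no automatic conversion is applied
(1 cmH2O = 0.7355 mmHg).

Per-beat parameters (effective LVEDP and τ) are decided by the ventilation
phase at the beat's end-diastolic time — the same rule the analysis side
uses for gating, so phase-classification accuracy is testable beat by beat.
Offsets apply during inspiration proper, not during pauses. A beat enters
the ground-truth table only if its closing end-diastolic time lies inside
the record; edge-truncated beats are not recoverable by any detector.

What the simulator does *not* emulate — and hence what passing tests do not
show about real data: no closed-loop physiology (offsets are imposed, not
emergent), no beat-to-beat heart-rate variability, no catheter artefacts
(whip, damping, drift beyond the optional sinusoid), no arrhythmia, no
perfluorocarbon fluid dynamics. Recovery results here certify the
algorithms, not the biology.

## Numerical and detection choices

- **Derivative**: plain central differences (one-sided at edges), no
  pre-smoothing — the simplest consistent estimator is the operator default.
  The file-level pipeline enables Savitzky–Golay smoothing (window 31,
  order 3) by default because a raw central difference at 1 kHz turns
  0.5 mmHg sample noise into ~350 mmHg/s derivative noise, comparable to the
  upstroke peak itself.
- **Beat detection**: dP/dt-maximum peaks above 50% of the 90th percentile
  of positive dP/dt, separated by at least 60/max_rate s, plus a 5 mmHg
  minimum ED-to-peak pressure rise (LV pulse amplitudes are tens of mmHg;
  the floor rejects incoherent noise excursions). Beats are half-open
  [ED index, next ED index), so every sample belongs to exactly one beat;
  edge-truncated beats are discarded. Indexing is 0-based everywhere.
- **LVEDP**: candidate = last sample before the dP/dt maximum with dP/dt
  below 10% of that beat's peak (pressure-only; no ECG channel exists in the
  data model), then refined by extrapolating the local dP/dt tangent back to
  zero — the intersecting-tangent foot rule — because any fixed threshold
  fires slightly into the upstroke. The backward shift is capped at 20 ms.
- **Tau fitting**: windows are extracted and fitted on the *raw* trace even
  when landmarks come from the smoothed one; smoothing blurs the
  descent-to-decay corner into the first window samples and measurably
  biases τ low, while the raw window is clean (any suffix of an exponential
  is an exponential). The simplex is initialised from the log-linear
  estimate (fallback 20 ms when ln P is undefined), tolerance 1e-6 ms,
  τ capped at 500 ms with boundary solutions flagged rather than reported.
  "Drops below" is read strictly; the crossing sample closes the window
  (one-sample ambiguity, sample-resolution end, both acknowledged). Windows
  shorter than 5 samples, or never crossing, are flagged unusable. The first
  beat of a record contributes no τ (no previous LVEDP exists).
- **Phase averaging**: k = 5 beats (configurable) nearest the temporal
  midpoints of the phase's segments, avoiding transition edges; pause-phase
  beats are excluded from the inspiration/expiration contrast.
- **Pause fitting**: initialised from the segment mean, the dominant non-DC
  FFT frequency and a log-envelope line (Hilbert envelope, edges trimmed);
  an exactly constant segment short-circuits to its mean (A = 0);
  non-convergence falls back to the mean of the final quartile, flagged.
- **Statistics**: paired t from the textbook formula with scipy's t
  distribution for p; all-equal differences are reported as degenerate with
  t and p withheld rather than fabricating a value.

## Problem sizes

Tests and the acceptance script use 10–60 s records at 1 kHz (≈26–160
beats), 8-subject cohorts, 20-window oracle sweeps and 200-replicate power
runs; the whole suite completes in seconds. These sizes were chosen because
recovery errors are already far inside the tolerance bands at one simulated
minute per subject; longer records only shrink standard errors further.

## Known limitations

- End-diastole is found from pressure alone; an ECG-gated rule could differ
  systematically on real data.
- The zero-asymptote τ model is the one implemented; non-zero-asymptote
  variants are out of scope, and on real data with elevated pericardial
  pressure the two can diverge.
- At heart rates whose period does not divide the record length, the
  detector may lose one trailing beat relative to the ground-truth count
  (the closing upstroke falls past the record edge).
- The pause-pressure model is a generic damped oscillation, not a
  ventilator-specific extrapolation algorithm.
- No multiplicity correction across metrics.
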