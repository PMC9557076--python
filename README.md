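# phaselge

Cardiac phase-resolved synthetic LGE (late gadolinium enhancement) in Python:

1. **Timing** (`phaselge.timing`) — plan the per-phase inversion-time (TI)
   sampling of a prospectively ECG-triggered Look-Locker FLASH scan with
   multiple inversion-pulse offsets, two samples per inversion (one per
   recovery beat), and dummy pulses filling the gap to the next R-wave.
2. **Simulation** (`phaselge.simulate`, `phaselge.phantom`) — event-by-event
   longitudinal Bloch simulation of the pulsed FLASH train (steady state,
   inversion, recovery), digital phantoms (two-sphere, bottle, short-axis
   cardiac with optional contraction), Rician-type noise, phase-resolved
   multi-TI magnitude stacks.
3. **Fitting** (`phaselge.fitting`) — voxel-wise magnitude polarity
   restoration (exhaustive sign-flip sweep) plus a two-parameter
   inversion-recovery fit `S(TI) = A (1 − 2 e^(−TI/T1*))`, producing per-phase
   A / T1* / residual / polarity maps.
4. **Synthesis** (`phaselge.synthesis`) — synthetic LGE images at a single
   virtual inversion time for all phases, chosen to null a reference tissue
   (`T_syn = T1* ln 2`) or set manually.
5. **Metrics** (`phaselge.metrics`) — apparent CNR from within-ROI spatial
   statistics, repetition-noise CNR, coefficient of variation, linear
   interpolation to a fixed number of reconstruction phases.

## CLI

The `phaselge` entry point chains the pipeline stages; images are NIfTI,
TI tables CSV, configuration YAML/JSON (unknown keys rejected), and every
output directory receives a `provenance.json` with the resolved
configuration and seed.

```bash
phaselge simulate  --config config.yaml --seed 1 --out out/sim
phaselge fit        --stack out/sim/stack_rep000.json --mask out/sim/mask.nii --out out/fit
phaselge synthesize --maps out/fit/maps.json --null-roi out/sim/roi_myocardium.nii --out out/synth
phaselge metrics    --synth out/synth/synth.json --myo-roi out/sim/roi_myocardium.nii \
                    --blood-roi out/sim/roi_blood.nii --out out/report
phaselge run-all    --config config.yaml --seed 1 --out out/all
```

Example configuration:

```yaml
sequence: {tr_ms: 5.0, flip_deg: 3.0, acq_window_fraction: 0.9, recovery_beats: 2}
timing:   {heart_rate_bpm: 60, phase_duration_ms: 50.0}
phantom:  {kind: two_sphere, shape: [128, 128], radius: 20.0,
           baseline_snr: 20.0, snr_reference: blood}
synth:    {null_compartment: myocardium}
metrics:  {myo_compartment: myocardium, blood_compartment: blood}
seed: 1
n_repetitions: 10
```

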