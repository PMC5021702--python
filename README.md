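# hdmea_eap

Somatic/neuritic classification and spike-shape adaptation analysis for
high-density microelectrode array (HDMEA) recordings — with a synthetic
ground-truth generator so the whole chain is testable without external
data.

## The problem

HDMEAs record extracellular action potentials (EAPs) at tens-of-μm
electrode pitch under dissociated neuronal cultures.  A
threshold-crossing event on an electrode can originate near a cell body
or from a distal neurite (usually an axon), and the two carry different
physiology.  Two signatures separate them:

- **waveform shape** — somatic EAPs are broad (half-width ~250 μs,
  trough–peak width ~900 μs) and mono- or biphasic; neuritic EAPs are
  narrow (~130 μs, ~420 μs) and triphasic;
- **spike-shape adaptation** — during bursts the instantaneous firing
  rate rises and somatic spike amplitudes shrink markedly, while distal
  axonal spikes barely change.

The package implements the full analysis: band-pass filtering and 5σ
threshold detection with 0.8 ms blanking → activity maps (0.2 Hz cut) →
per-electrode peak-aligned averaging and three-electrode spike sorting
(PCA → K-means → interface-energy aggregation) → spike-triggered-average
footprints from 320 kHz-oversampled wideband traces → shape features
(amplitude, half-width, trough–peak width, RSTD) → screening
(≥ 100 μV, RSTD < 1, > 100 spikes) → template matching by normalized
cross-correlation against four canonical types → the 50 μm
soma-distance rule → adaptation analysis.

## The model at the core

The continuous firing rate is updated at every spike,

    cFR(t) = d · cFR(t − Δt) + (1 − d)/Δt ,   d = e^{−Δt/τ},  τ = 100 ms,

and a shape feature y is fitted against it by least squares with

    g(x) = y_c · e^{bx} + y_∞ .

The adaptation rate,

    AR = ( y_∞ / (y_∞ + y_c) − 1 ) · 100 %,

is the percent change from the zero-rate baseline g(0) to the high-rate
asymptote y_∞: amplitude reduction during bursts gives negative AR,
spike widening positive AR.  Somatic (Types 1–2) and neuritic
(Types 3–4) AR distributions are compared with the two-tailed
Mann–Whitney U test.  See `docs/methods.md` for the synthetic-data
model, numerical choices and limitations.

## Worked example

The numbered scripts under `analysis/` run the chain end to end on
synthetic recordings and write their tables under `results/`:

```
$ python analysis/01_simulate_demo_recording.py
rendered 144 electrodes x 25 s
8 units (6 somatic), 1198 spikes

$ python analysis/02_run_pipeline_demo.py
events detected:      7400
active electrodes:    91
screened electrodes:  7
somatic fraction:     0.86
footprint units:      1
```

The demo plants 6 somatic and 2 neuritic units on a 144-electrode
block.  Detection finds their spikes (plus subthreshold neighbors'
activity on 91 electrodes); the 100 μV / RSTD / spike-count screen
keeps 7 electrodes — one neuritic unit fired too few spikes in 25 s —
and template matching classifies 6 of 7 as somatic (fraction 0.86).
The sorting path recovers one unit whose footprint's representative
electrode is correctly distance-labeled.

The full-scale study (`analysis/05_ground_truth_recovery.py`) renders
392 electrodes × 50 s holding 30 units with a known 80/20
somatic/neuritic mix:

```
screened electrodes:        30
somatic fraction:           0.80 (truth 0.80)
amplitude AR medians (%):   {'type_3': -10.7, 'type_4': 0.0, 'type_2': -29.0, 'type_1': -28.3}
generator AR truth (%):     {'somatic_type1': -30.0, 'somatic_type2': -30.0,
                             'neuritic_type3': -10.0, 'neuritic_type4': 0.0}
somatic vs neuritic p:      2.08e-04
```

All 30 planted units are screened and typed correctly; the fitted
amplitude adaptation rates recover the generator's per-type truth
(somatic ≈ −30%, Type 3 ≈ −10%, Type 4 ≈ 0), and the somatic-vs-neuritic
difference is highly significant.  `03_template_matching_accuracy.py`
(98.7% type accuracy at SNR 10, zero somatic/neuritic confusion over
1,000 draws) and `04_adaptation_recovery.py` (worst AR error 0.53
percentage points over 20 seeded runs) exercise the two core statistics
in isolation.

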