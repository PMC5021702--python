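# Methods

`hdmea_eap` implements the analysis chain used to decide whether an
extracellular action potential (EAP) recorded on a high-density
microelectrode array (HDMEA) originates near a cell body or from a
distal neurite, and to quantify how spike shape adapts with firing
rate.  Because public HDMEA raw data with ground-truth source labels do
not exist at package-test scale, the package ships a synthetic
generator whose output has known source labels, waveforms and
adaptation parameters; every quantitative claim the test suite makes is
a property of this generator–pipeline loop.

## Signal model

A recording is a set of voltage traces `v_e(t)` (μV, 20 kHz) on
electrodes at positions `x_e` (μm) packed hexagonally at 17.8 μm pitch
(rows `pitch·√3/2` apart, alternate rows offset `pitch/2`, so all
nearest-neighbor distances equal the pitch exactly).

Each ground-truth unit contributes, at every spike time `t_k`,

    v_e(t) += A · g_amp(cFR_k) · w((t − t_k)/g_w(cFR_k)) · exp(−d_e/λ)

where `w` is the unit's canonical waveform (trough depth −1 at t = 0),
`A` the trough depth at the signal origin, `d_e` the distance from the
origin to electrode `e`, and `λ = 25 μm` the spatial decay constant
(chosen so signals vanish beyond ~100 μm of the source, matching how
far single-cell activity is detectable from the soma).  The
exponential decay law is a stand-in: no quantitative amplitude-versus-
distance law is claimed for real tissue.

### Canonical waveform types

Four types are modeled as sums of Gaussian lobes over a 2.5 ms support
(Tukey-tapered, α = 0.15, so rendered spikes meet the trace smoothly):

| type | class    | shape                                   | lobes (amp @ center, σ) |
|------|----------|-----------------------------------------|--------------------------|
| 1    | somatic  | broad, monophasic (late hump ≤ 10%)     | −1 @ 0, 106.2 μs; +0.09 @ 900 μs, 300 μs |
| 2    | somatic  | broad, biphasic, late positive peak     | −1 @ 0, 106.2 μs; +0.45 @ 900 μs, 250 μs |
| 3    | neuritic | narrow triphasic, larger peak *before*  | +0.50 @ −380 μs, 110 μs; −1 @ 0, 55.2 μs; +0.25 @ 420 μs, 110 μs |
| 4    | neuritic | narrow, symmetric triphasic             | ±0.35 @ ∓420 μs, 120 μs; −1 @ 0, 55.2 μs |

The negative-lobe σ values are the analytic inversion of the Gaussian
FWHM (`2σ√(2 ln 2)`) at the class-median half-widths of 250 μs
(somatic) and 130 μs (neuritic); the positive-lobe centers sit at the
class-median trough–peak widths of 900/420 μs.  At 320 kHz the measured
features of the default templates reproduce all four medians within one
sample period.

### Spike trains and adaptation

Burst onsets are a Poisson process (default 0.7 bursts/s in the
population studies); each burst holds `L` spikes (default 8) whose ISIs
are a 2 ms refractory dead time plus an exponential of mean
`1/intra_rate` (default 50 Hz).  A dead-time-modified process is used
rather than a floored exponential because neurons do not fire at
near-refractory intervals even within bursts; with a bare 1 ms floor,
~2.4% of ISIs would fall inside the 1.5 ms refractory-violation
convention and structurally contaminate every sorted unit.

Shape adaptation follows the same law the analysis fits: per spike,
amplitude and width are scaled by `g(cFR)/g(0)` with
`g(x) = y_c·e^{bx} + y_∞`.  Defaults (normalized so `g(0) = 1`):
somatic types amplitude `(0.3, −0.05 Hz⁻¹, 0.7)` (AR −30%) and width
`(−0.1, −0.05, 1.1)` (AR +10%); Type 3 amplitude `(0.1, −0.05, 0.9)`
(AR −10%); Type 4 none (AR 0) — the distal-axon signature of
rate-invariant spike shape.

### Noise

Gaussian noise, band-limited to 25 Hz–3.5 kHz (an on-chip filter
emulation), is added independently per electrode.  `noise_sd`
(default 10 μV) is the in-band noise floor: the white input is scaled
by the filter's noise gain so the sd *after* band-limiting equals
`noise_sd`, which keeps a 100 μV spike at 10σ.  The clean signal is not
re-filtered — the Gaussian-lobe waveforms carry negligible energy
outside the band — so ground-truth waveforms stay exact for
spike-triggered-average equality checks.

## Detection

Traces are band-pass filtered 500–3,000 Hz with a 2nd-order Butterworth
applied forward–backward (zero phase, so trough timing is unbiased; the
order is a package choice).  Noise is estimated as `median(|x|)/0.6745`
(MAD), which a few percent of spike samples cannot inflate.  Events are
negative crossings of `−k·σ` (default k = 5); after a crossing the
detector is blind for 0.8 ms, the event time is the deepest sample in
that span (earliest on ties), and a 50-sample (2.5 ms) snippet is cut
centered on the trough.  Events whose snippet would cross a recording
edge are dropped.  Per-electrode firing rates over the whole recording
form the activity map; electrodes above 0.2 Hz (strict) are analyzed
further.

## Two classification paths

**Per-electrode path** (population statistics): all spikes detected on
an electrode are peak-aligned and averaged (wideband snippets at the
detected trough indices; the average is Fourier-oversampled ×16 to
320 kHz).  The averaged spike is screened — |amplitude| ≥ 100 μV,
RSTD < 1, > 100 spikes — and assigned to the template type with the
highest peak-to-peak-normalized cross-correlation (lags within
±0.25 ms; ties go to the lower type index and are logged).  Types 1–2
count as somatic, 3–4 as neuritic.

**Footprint path**: events from the three electrodes nearest the most
active electrode are merged into multichannel events (within 0.5 ms —
half the blanking time), aligned on the trough of the deepest channel,
and concatenated snippets are sorted: PCA (10 components) → K-means
overclustering (k = 8) → interface-energy aggregation.  Pairwise
similarity is a Gaussian kernel `exp(−d²/2σ²)` with σ the median
nearest-neighbor distance in PC space; the connection strength between
clusters is the mean cross-similarity normalized by the geometric mean
of the within-cluster similarities, and pairs above the 0.001 stop
criterion merge iteratively (recomputed after each merge).  The
Gaussian kernel (rather than `exp(−d/σ)`) is what makes the 0.001
criterion discriminating in 10-dimensional PC space: with a linear
kernel, clusters several noise-widths apart still connect at
0.005–0.08 and distinct units merge.  Units are kept when their
refractory-violation fraction (ISIs < 1.5 ms) is below 1% and they have
at least 100 spikes — a codified, reproducible stand-in for what is
conventionally a manual cluster-curation step.  The unit's footprint is
the per-electrode spike-triggered average of oversampled wideband
traces (averaging first and interpolating after are identical by
linearity; a 0.5 ms margin absorbs interpolation edge effects).  The
electrode with the deepest STA trough is the representative electrode;
it is labeled somatic when the nearest soma lies strictly within 50 μm,
neuritic otherwise (also when no soma is known).

## Waveform features

- amplitude: signed minimum of the averaged waveform (μV);
- half-width: contiguous duration below 50% of the trough, with linear
  interpolation at the crossings (sub-sample precision consistent with
  the 320 kHz oversampling);
- trough–peak width: time from the trough to the first strictly
  positive local maximum after it, requiring prominence ≥ 5% of the
  trough depth to ignore ripples; undefined (NaN) for monophasic
  waveforms;
- RSTD: per-sample population standard deviation across snippets after
  normalizing by the mean waveform's peak-to-peak amplitude, averaged
  over samples (the scalar reduction is a package choice; the mean is
  bounded and stable).

## Adaptation analysis

The continuous firing rate is the recursion
`cFR = d·cFR_prev + (1−d)/Δt`, `d = e^{−Δt/τ}`, `τ = 100 ms`.  The
first spike is initialized at 0 Hz and excluded from fitting (the
conservative choice for an unknown history).  The fixed point at
constant ISI is exactly `1/Δt`.

Per-spike amplitude is estimated by matched-filter projection: each
snippet is projected onto the electrode's mean spike and the scale is
multiplied by the mean-spike trough depth.  The projection is linear in
the data, so zero-mean noise cancels; a per-snippet minimum, by
contrast, is a biased order statistic whose ~10 μV spread the
exponential fit amplifies.  Per-spike half-width and trough–peak width
are measured directly on the snippets (NaN when undefined).

`g(x) = y_c·e^{bx} + y_∞` is fitted by least squares with five starts
over `b` (negative, scaled to the observed cFR range) and the asymptote
initialized at the high-cFR feature mean.  Two safeguards address the
degeneracy at `b → 0`, where only `y_c + y_∞` is identified:

1. model selection by BIC against the flat model — if two extra
   parameters are not supported, the feature does not adapt and AR = 0
   with `y_∞` at the feature mean;
2. an identifiability guard — a supported exponential whose asymptote
   falls outside the observed feature range (± one span) is flagged
   missing rather than reported.

The adaptation rate is `AR = (y_∞/(y_∞ + y_c) − 1)·100` — the percent
change from the zero-rate baseline `g(0)` to the high-rate asymptote;
amplitude reduction gives negative AR, widening positive AR (amplitude
is fitted on its absolute value so the signs hold).  Groups of AR
values (by template type or superclass) are compared with the
two-tailed Mann–Whitney U test; box summaries use Tukey 1.5·IQR
whiskers.

## Study scales

- End-to-end recovery: a 28×14 block (392 electrodes), 30 units
  (24 somatic / 6 neuritic — an 80/20 mix), 50 s at 20 kHz.  Units sit
  on a sparse lattice of electrode sites (every 3rd column of every 4th
  row; neuritic units on their own rows) so all units are ≥ 53 μm
  apart — far enough that a unit's spikes stay subthreshold on other
  units' electrodes — and every neuritic origin is > 50 μm from every
  soma by construction.  Somatic trough depths are drawn from
  U(150, 200) μV and neuritic from U(110, 140) μV so that only the
  origin electrode of each unit passes the 100 μV screen (the
  17.8 μm neighbor sees ≤ 49% of the origin amplitude).
- Type-4 zero-adaptation property: one unit on a 5×5 block, 300 s
  (~1,700 spikes, ~200 burst onsets) — enough low-cFR spikes that the
  fitted baseline's standard error is well below the ±2-point bound
  being asserted.
- AR parameter recovery: 20 seeded trains of ≥ 500 spikes with 2%
  amplitude noise.

## What the generator does and does not emulate

It emulates: hexagonal geometry, the four waveform classes with
calibrated feature medians, burst-structured trains, rate-dependent
amplitude/width modulation, spatially decaying footprints, band-limited
noise, and source/soma geometry for the 50 μm rule.  It does not
emulate: biophysical (cable-equation) forward models, electrode
impedance variation, drift, electrode failure, correlated network
bursts across units, overlapping-spike interference between nearby
units, or non-exponential spatial decay.  Passing tests therefore show
that the analysis chain recovers the structure it assumes, at realistic
noise levels — not that real tissue satisfies those assumptions.

## Known limitations

- Template matching uses the synthetic canonical shapes as the default
  template set; real recordings need measured templates (a CSV template
  set can be substituted).
- The per-electrode path counts electrodes, not neurons; the study
  geometry is designed so the two coincide, which real cultures do not
  guarantee.
- AR is an extrapolated quantity; for features with little dynamic
  range relative to noise it is reported as 0 (flat model) or flagged
  missing rather than estimated.
- The sorting stage handles one three-electrode group per block, as in
  the footprint workflow; it is not a general-purpose spike sorter.
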