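# Methods

## The measurement model

A cortical traveling wave is modeled, at the sensor level, as a plane
wave along an electrode axis: channel *c*, time *t* carries
`A·sin(2πft − c·Δ + φ)`, where Δ is the phase step per channel and its
sign the propagation direction (positive = the most posterior channel
leads = forward). The analysis makes no source-space claim; it
quantifies the spatial phase organization of the scalp signal itself.

Each axis is resampled to 7 virtual channels by linear interpolation
**on channel rank** (input channels at equally spaced positions on
[0, 1]), not on 3-D scalp distance. Rank spacing is the reproducible
choice when axes mix montages of 4, 5 and 6 electrodes; it is exact for
affine-in-rank profiles and the identity for 7-channel axes.

The 7 × n segment cut by the sliding window (500 ms length, 100 ms step
by default; both must be integer sample counts) is transformed by an
unpadded, untapered 2-D DFT. Conventions, all pinned by tests:

- **Quadrant → direction.** With positive temporal frequencies, forward
  waves concentrate at negative spatial frequencies (and conjugate).
  Rather than trusting an a-priori sign convention, the mapping is fixed
  operationally: a generated forward wave must yield FW_dB > BW_dB, and a
  unit test enforces this permanently.
- **Exclusions.** The zero-spatial-frequency row (standing waves) belongs
  to neither direction and is excluded from both quadrant maxima; the
  temporal DC column is excluded as well. With 7 rows each quadrant holds
  exactly 3 nonzero spatial bins (±1, ±2, ±3 cycles/array) and no spatial
  Nyquist.
- **Scaling.** 2-D power is divided by (n_channels)², so a perfectly
  coherent on-bin plane wave reaches FW_dB = 0, making the 0 dB baseline
  interpretable as "directional power at parity with mean temporal
  power". The dB value is invariant to segment rescaling (numerator and
  denominator scale together).
- **Normalization.** `FFT_f` is the 1-D temporal power at *f* of the
  *same* segment, averaged over its 7 rows, with the same transform
  length — never a trial- or condition-level average. An all-zero
  segment (zero `FFT_f`) is degenerate and rejected rather than patched;
  a zero numerator against positive `FFT_f` maps to −inf dB.
- **Bands.** Per-bin dB first, band average second. Band membership is a
  closed interval on bin centers; with 500 ms windows the grid is 2 Hz,
  so alpha = {8, 10, 12} Hz, theta = {4, 6}, beta = {14 … 30}.
- **Windows.** Only fully contained windows are emitted, starting at the
  epoch start; timestamps are window centers. Interval membership
  downstream (retention averaging, BF time courses) is "center in closed
  interval" — the least ambiguous anchor when a window straddles a
  boundary.

Detrending, tapering and zero-padding are deliberately absent (a taper
would change `FFT_f` and hence the baseline); they can be added upstream
by the caller if ever needed.

The conventional stationary band power uses the same windowing: one-sided
per-bin signal power summed over band bins, averaged over channels, so a
unit-amplitude on-bin sinusoid gives 1/2 and white noise approximates
(band width / Nyquist) × total power.

## Aggregation and inference

The analysis unit is the condition cell: participant × condition ×
axis-role (midline / contralateral / ipsilateral to the items of
interest) × direction × band, aggregated as the mean (default) or median
(robustness variant) across trials of the retention-window average
(0.2–1.2 s for the distractor-load template, 0.25–1.55 s for the
set-size template). Missing cells stay missing — they are flagged by
layout validation, never imputed, because silent imputation would bias
the Bayes factors. Visual input projects contralaterally, so items in
the left hemifield make the right-hemisphere axis "contra"; when the
items of interest are the non-lateralized cluster of a trial, the roles
flip sides.

Inference is fully Bayesian with default priors:

- **Paired t tests**: JZS Bayes factor — Cauchy(0, r) prior on the
  standardized effect, r = 1/√2 by default — computed by adaptive
  quadrature of the marginal-likelihood integral after substituting the
  inverse-gamma mixing variable to a Gamma(1/2, 1) integrand (numerically
  well-conditioned for any t). Tests pin agreement with an independent
  high-resolution fixed-grid quadrature and with an independent
  implementation to within 0.5%.
- **Repeated-measures ANOVA**: the model space enumerates main effects
  and interactions respecting marginality, every model carrying a
  participant blocking term, equal prior mass over models. Per-model
  evidence uses a BIC approximation of the marginal likelihood
  (deterministic, the default) or Monte Carlo Zellner–Siow g-prior
  integration over dummy-coded effect columns with the common block
  projected out (seeded; the relative MC error is reported). The
  inclusion BF follows the matched-models rule: models containing the
  effect (for a main effect, excluding models with interactions
  involving it) against the same models with the effect removed.
- **Capacity analysis**: per-participant least-squares slopes of wave
  power against load/set size, regressed on Cowan's
  K = set size × (hit − false alarm) under a Zellner–Siow regression
  prior (r = √2/4).
- The per-window BF10 series applies no multiplicity correction; the
  BF10 > 3 column is annotation, not a gate.

Because default prior scales are a convention, BF magnitudes from other
software with other priors will differ; orderings and qualitative
conclusions are the stable quantities.

## The synthetic-data generator

The generator emulates the two study layouts end to end: montage, epoch
span and sampling rate per template (32 channels / 1 kHz / −0.8–1.6 s;
20 channels / 250 Hz / −1.4–1.548 s), fully crossed condition tables
(lateral side × arrangement × load 2/4/6, or side × set size 1/3/6), and
per-condition plane-wave "effects" injected directly on the channels of
each analysis axis over 1/f^β background noise (β = 1, unit sample SD by
default). Real alpha SNR is not established in the literature this
package draws on; the default unit-amplitude wave against unit-SD noise
is a documented convention chosen so that direction recovery is reliable
but not trivial, not an empirical value.

Design choices with a rationale:

- **No volume conduction.** Waves are synthesized on the axis channels
  themselves; the measurement operates on axis stacks, and adjudicating
  scalp-projection artifacts is out of scope. Consequently the generator
  cannot probe artifact-vs-veridical questions about real EEG.
- **Random initial phase per trial** (default): the measure is a
  phase-gradient measure, not a phase-locked one, and fixed phases would
  produce spurious across-trial coherence.
- **Effects are amplitude (or phase-step) changes of a directional
  component.** When an effect entry repeats a base component's shape,
  the amplitudes add coherently into one wave. Summing two
  independent-phase waves at the same frequency instead would yield a
  zero *median* log-power gain (Jensen's formula) and destroy the
  monotone ground truth the effect map promises — this is enforced in
  the generator, not left to the caller.
- **Determinism**: one seed sequence per design, spawned per
  participant; identical seeds regenerate bit-identical tensors.

What the generator does not emulate — and hence what green tests do not
establish about real recordings: volume conduction and reference
effects, eye/muscle artifacts, non-stationary alpha (waxing/waning
spindles), inter-individual montage variation, and any genuine
brain–behavior coupling (simulated capacity values are independent of
the simulated EEG by construction).

Note one coupling inherent to the *measure*, visible in synthetic runs:
because both directions share the `FFT_f` denominator, raising forward
amplitude alone also lowers backward dB. This is a property of
normalized directional power, not of the generator.

## Problem sizes and numerics

The test suite and the acceptance script run on deliberately small
problems — hundreds of segments, 100 seeded replicates for calibration
checks, ~12 simulated participants for end-to-end runs — sizes at which
every targeted property (direction recovery margins > 1 dB, null
calibration within 0.1 dB, BF detection/false-alarm rates) is already
stable. Exact symmetries (channel-flip antisymmetry, time-reversal swap,
oracle equivalence) are asserted at 1e−10 relative tolerance or tighter;
statistical checks state their margins explicitly in the tests.

Known numerical edges: a phase step whose implied spatial frequency
falls between the 3 spatial bins (e.g. π/7 on a 7-channel stack = 0.5
cycles/array) leaks energy into both quadrants and caps the FW/BW ratio
near 8 rather than orders of magnitude; interpolation from 4-channel
axes compresses extreme phase gradients; both effects are direction-
preserving and covered by tests.

## Limitations

Sensor-level only; no wavelet/Hilbert phase-gradient alternative; no
preprocessing (inputs are assumed clean, re-referenced, epoched); BF
magnitudes depend on prior-scale conventions; the BIC route treats the
participant term as a fixed blocking factor, a standard approximation
that can differ from full mixed-model marginal likelihoods at small n.
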