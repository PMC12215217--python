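# Methods

## Model and estimands

The EEG power spectrum is modelled as a fractal (aperiodic) component
following a power law `P(f) ∝ f^α` plus narrowband oscillatory peaks. The
estimand throughout is the slope of `log10 P` against `log10 f` of the
*fractal* component in two bands: low (2–30 Hz, with a 5–30 Hz control
band) and high (30–48 Hz). Slopes are negative in sleep; "steeper" means
more negative. Phasic REM is expected to be steeper in the low band and
flatter in the high band relative to tonic REM, and those state contrasts —
not absolute exponent recovery in the high band (see *Known limitations*) —
are what the cohort statistics test.

## IRASA decomposition

For each factor `h` in 1.10, 1.15, …, 1.90 the signal is resampled by `h`
and `1/h` (polyphase, anti-aliased, rational factor approximation) and both
resampled series are treated as if they still ran at the original sample
rate. This stretches their spectra by `1/h` and `h`: a power law is
invariant under the geometric mean of such a pair, while an oscillatory
peak is displaced to `f0/h` and `f0·h` and suppressed by the median across
the 17 factors. Spectra are single-taper (Hann) periodograms evaluated on
the original frequency grid by linear interpolation; the usable grid ends
at `fs / (2·max(h))`, which is why a 30–48 Hz band with `h ≤ 1.9` requires
a sample rate above ~183 Hz (we use 250 Hz throughout).

Per 4-s epoch the grid resolution is 0.25 Hz, so band edges (2, 30, 48 Hz)
fall exactly on bins; edges are inclusive. Slopes are ordinary least
squares in log10–log10 with no robust weighting; r² is exposed for quality
control. Epochs whose decomposition or fit fails carry NaN, never a silent
zero. Slopes are fitted **per epoch and then averaged**, not fitted on
epoch-averaged spectra; a `which="total"` switch fits the raw spectrum
instead of the fractal one, which exists only to demonstrate the
oscillation-rejection contrast.

The single-epoch periodogram is noisy (χ² with two degrees of freedom per
bin), so per-bin fractal estimates fluctuate; all claims are about medians
or means over ≥100 epochs, where the fitted-slope error is well under 0.05.

## Synthetic polysomnography

The generator's purpose is parameter recovery with known truth, not
physiological realism.

- **EEG.** Gaussian noise shaped in the frequency domain so the *expected*
  one-sided PSD equals the target spectrum exactly at every FFT bin: a
  piecewise power law with exponent `α_low` up to 30 Hz and `α_high` above
  (continuous at the break), flat below 1 Hz to bound spectral leakage into
  the 2-Hz band edge, scaled to 5 µV²/Hz at 10 Hz. A 5-Hz oscillation
  (Gaussian PSD bump, peak equal to the local fractal power) is
  superimposed by default so the fractal/oscillatory separation is always
  exercised. Defaults: tonic −2.1 / −3.9 and phasic −2.25 / −3.5
  (low / high band), i.e. a −0.15 low-band and +0.4 high-band state
  difference, matching the direction and order of magnitude of the REM
  microstate literature.
- **State switching.** Two independent shaped-noise streams (tonic and
  phasic spectra) are combined with an equal-power crossfade (0.5-s raised
  cosine) driven by the EM burst schedule, so fully phasic or tonic epochs
  carry the exact target spectrum and there are no boundary artefacts.
  Channels within a topographical area duplicate the area-level source:
  independent per-channel noise would add a white floor that distorts the
  high-band spectrum.
- **EOG.** Scripted EM events are one-cycle biphasic waves (two opposite
  sine lobes of equal duration, 0.1–0.5 s each), rendered anti-phase on the
  two EOG channels (95 % gain on the right, random polarity). The zero net
  area is deliberate: an area-unbalanced wave leaves a slow baseline tail
  after the 0.3-Hz high-pass that corrupts duration measurements.
  Amplitudes are log-normal (median 180 µV, σ_log 0.3) truncated at 150 µV
  so every scripted event satisfies the phasic criterion; background noise
  is 5 µV white, keeping tonic windows under the 25-µV quiescence bound
  with high probability. Bursts recur every ~2 min (the infra-slow EM
  timescale), last 16 s, with inter-event intervals jittered around
  1/0.7 s so consecutive events fall in adjacent 2-s windows.
- **Cohorts.** One normal baseline offset per participant (SD 0.15) shifts
  all four exponents together — between-subject variation in broadband
  slope is shared across bands — leaving the within-subject state
  difference constant, as in a within-subject design. The binary-pipeline
  study scale is 12 participants × 30 min of REM; real overnight studies
  have several times more REM per participant, so this is a conservative
  data volume chosen to keep runs fast.

What the generator does **not** emulate: NREM architecture, spindles,
K-complexes, sawtooth waves, EMG/ECG, volume-conduction topography, real
EOG artefact structure, or non-stationary exponent drift. Passing tests
therefore demonstrate that the estimation chain is correct and calibrated,
not that it is robust to every artefact of real polysomnography.

## Segmentation and EM detection

Segmentation follows the binary rules exactly (2-s windows; phasic = both
subwindows contain a >150 µV deflection shorter than 500 ms; tonic = epoch
and flanking windows below 25 µV; everything else unclassified). Deflection
duration is the contiguous above-threshold extent. The 8-s separation is
resolved greedily in time order (edge-to-edge gaps), which the rules leave
open; dropped epochs become `excluded` without changing class. An EM on
either EOG channel suffices; conjugacy is the event detector's job.

The detector band-passes both channels to 0.3–10 Hz, thresholds the
running-maximum envelope (0.15-s window, which also bridges the envelope
dip at the mid-wave zero crossing) at 50 µV, requires anti-phase channels
at the extremum, and measures: duration as the extent above
max(0.15 × peak, 20 µV); dominant frequency as `1/(2·half-period)` using
twice the distance from the extremum to the *nearest* zero crossing (robust
to one-sided filter tails); amplitude as the maximum absolute excursion.
Adjacent single-polarity candidates of opposite sign are merged before the
duration bound is applied, so a slow biphasic artefact is judged as one
overlong complex rather than two acceptable lobes. Events are assigned to
the 4-s epoch containing their extremum; event-free epochs carry amplitude
0 and stay in the series (the rank transform absorbs the ties).

## Within-episode analysis

Episodes are maximal contiguous REM runs strictly longer than 10 min. Both
epoch series are ranked once over their full length (mid-ranks), then
correlated with Pearson's formula on overlapping segments at lags −300 to
+300 s in 4-s steps (151 lags, truncation, no wraparound). Negative lags
mean the slope series leads. The per-lag CI half-width is
`1.96/√(n_ℓ − 3)` on the Fisher-z scale mapped back through `tanh`, with
`n_ℓ = n − |lag|` the overlap length (a `ci_n="full"` switch uses the full
series length, reproducing a single pooled threshold). Lags with overlap
below 5 epochs are NaN. Pooling averages z per lag across episodes.
Episode-centred effect sizes count episodes with a significant correlation
of the hypothesised sign at lag 0 by default.

Bayesian prevalence: each episode is significant with probability
`θ = γ + (1 − γ)·α`, where γ is the population prevalence of true effects
(within-episode sensitivity taken as 1) and α = 0.05 the test level. With a
uniform prior on γ the posterior is evaluated on a γ grid of step 5×10⁻⁴;
the MAP (closed form `max(0, (k/n − α)/(1 − α))`) and the 96 % highest-
density interval are read off the grid by water-filling.

## Cohort statistics

Per participant and band, epoch-level slopes from all areas and both states
are pooled into one vector, z-transformed (ddof 1), and averaged per
(area, state); a `level="mean"` switch z-transforms the eight cell means
instead. Paired contrasts are two-tailed Student's t on tonic-minus-phasic
participant means with Cohen's d on difference scores, so positive low-band
d means phasic is steeper and negative high-band d means phasic is flatter.
AUC uses the Mann–Whitney identity with half credit for ties, the class
with the larger mean as positive, a pooled-median cutoff for
sensitivity/specificity, and the Hanley–McNeil standard error (descriptive
only). Benjamini–Hochberg adjustment is applied across the area × band
family of contrasts at q = 0.05. Participants lacking kept epochs of either
state are dropped with a machine-readable reason.

## Numerical and degenerate-input choices

Resampling factors are approximated by rationals with denominator ≤ 50
(exact for the default hset). Constant series yield NaN correlations;
all-zero epochs and non-finite samples yield NaN slopes; `arctanh` is
clipped away from ±1. EDF output quantizes to 16 bits over a symmetric
per-channel range (relative error < 10⁻³); analysis stages are seed-free
and byte-deterministic given inputs.

## Known limitations

- **Knee bias.** IRASA evaluates the fractal spectrum at `f` using content
  from `f/h` and `f·h`; near the 30-Hz break of the synthetic piecewise
  spectrum this mixes the shallow low-band law into the 30–48 Hz fit,
  biasing high-band slopes flatter (by roughly +0.5 here) and compressing
  the generative +0.4 state difference to about +0.2. The bias is
  deterministic for a fixed spectral shape, so state contrasts keep their
  sign and ranking; absolute high-band exponent recovery should not be
  expected near a sharp knee, and the exponent-recovery guarantees are
  stated for single-power-law signals.
- Per-lag significance is not corrected across the 151 lags, mirroring the
  standard usage this package reproduces.
- The detector validates against scripted waveforms, not human-scored EMs;
  agreement with synthetic ground truth substitutes for inter-rater
  validation.
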