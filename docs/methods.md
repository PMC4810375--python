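# Methods

## Estimator

Sample entropy of a series (or segment collection) is `ln(B/A)`, where `B`
counts unordered pairs of length-`m` templates whose samples agree
component-wise within a tolerance, and `A` counts pairs whose length-`m+1`
extensions also agree. Conventions, all fixed:

- **Template set.** Templates start at within-segment positions
  `1 … len − m`, so every `m`-template has a same-start `(m+1)`-template.
  This (Richman–Moorman) convention guarantees `A ≤ B` and hence
  `SampEn ≥ 0` whenever defined, and makes both counts range over one
  template population.
- **Match rule.** Chebyshev distance with an *inclusive* comparison
  (`|x_i − y_i| ≤ tol`); this is the only supported rule. Self-pairs are
  excluded; each unordered pair is counted once.
- **Tolerance.** `tol = r · SD`, computed once from the native (scale-1)
  data and reused at every coarse-graining scale, so coarse-scale entropy
  is measured relative to the overall variability of the signal. For
  segmented data the default policy pools all native-scale samples across
  segments (sample SD, `ddof = 1`); an `external` policy accepts a
  caller-supplied SD (e.g. the SD of the longer recording the segments were
  cut from, which removes the short-series SD shrinkage discussed under
  Limitations).
- **Segmented data.** Coarse-graining is applied per segment, and templates
  never span a segment border; counts from all segments (within- and
  cross-segment pairs alike) are pooled. Each coarse-graining window of `s`
  samples is averaged; a trailing remainder that does not fill a window is
  dropped. The largest admissible scale for segments of `n` samples is
  `⌊n/(m+1)⌋` — the coarsest series that still holds one `(m+1)`-template.
- **Undefined values.** If `A = 0` (or `B = 0`) the entropy is reported as
  NaN together with the raw counts, never as infinity; ensemble summaries
  drop undefined replicates and report their fraction.
- **Defaults.** `m = 2`, `r = 0.50` — the settings conventional for
  neurophysiological signals. `r = 0.15` or `0.30` are ordinary parameter
  choices with no special handling.

The pair enumeration is a numba kernel that scans templates in ascending
order of their first component and abandons each inner scan as soon as the
first-component gap exceeds the tolerance; results are exactly equal to
brute-force enumeration (the test suite asserts bit-level equality on small
inputs, and the continuous path is asserted bit-equal to an independent
vectorised implementation).

## Noise model

White noise is i.i.d. standard normal. 1/f noise is synthesised by
spectral shaping: the rFFT of a white series is scaled by `f^(−α/2)`
(α = 1), the DC bin zeroed, and the series transformed back — the target
power spectrum is exact by construction, and a periodogram-slope property
test (slope −1 ± 0.15 between the filter cutoff and Nyquist/4) is the
contract. Each series is standardised to zero mean and unit SD, then
optionally high-pass filtered with a 4th-order Butterworth applied
forward–backward (zero phase, SOS form) at a cutoff of
`sampling_rate / 2^10`. The filter equates the low-frequency content of
ensembles of different lengths; standardisation order (standardise, then
filter) is a documented choice and is immaterial to the entropy values,
which use each series' own SD.

## Accuracy / precision harness

*Accuracy* (Δ) of an estimation condition is the absolute deviation of its
ensemble-mean entropy from the mean of a benchmark ensemble of 2^16-point
continuous series; *precision* is the SD of the estimates across
replicates. Both are reported per `(j, n, scale)` cell with log10 views.
Every replicate generates a fresh series and draws one segment set from it
(fresh-per-replicate keeps the precision estimate independent); draws are
consecutive blocks by default, with a seeded random non-overlapping-window
policy as an alternative. The benchmark's tolerance is recomputed per
replicate from each series' own SD, matching the per-series convention
used everywhere else. Continuous and segmented conditions are compared at
an equal number of pattern comparisons: a continuous series of
`(n − m)·j + m` points offers the same `(n − m)·j` templates as `j`
segments of `n` points. Grid cells are evaluable only when
`scale ≤ ⌊n/(m+1)⌋` and `j·n` does not exceed the total-data cap
(default 20 × 1024 points); other cells are emitted flagged. Cell summaries
across scales use the median.

## Group statistics and planning

- **Condition contrasts.** Point-wise paired t-tests (df = N − 1,
  two-sided) over aligned (subject × unit × scale) entropy maps. Cells with
  zero difference variance give `t = 0, p = 1` when the mean difference is
  zero and are flagged NaN otherwise; no multiple-testing correction is
  applied by default (cell-wise α is the convention this workflow targets).
- **Sensitivity / specificity.** Of the cells significant (resp.
  non-significant) in a benchmark map, the fraction still significant
  (resp. non-significant) in a reduced-data map. Empty denominators yield
  NaN flags.
- **Sample-size planning.** The precision of an entropy estimate is the SD
  entering a two-independent-group normal-approximation power formula:
  `N = 2·((z_{1−α/2} + z_{power}) · precision / Δ)²`, rounded up; values
  above 1000 carry a cap flag (printed `>1000`). The unrounded value is
  exposed for exact scaling laws (halving Δ quadruples N exactly). Cells of
  the published planning table that are robust to the two-decimal rounding
  of its precision column reproduce exactly; a statsmodels power solver is
  used in the tests as an independent cross-check, never as the
  implementation.
- **Accuracy-bias test.** Per unit,
  `t = (unit accuracy − overall accuracy) / (unit precision / √N)` with
  df = N − 1; the count of units exceeding an uncorrected p = 0.001 is
  reported next to the count expected by chance.

## Synthetic two-condition fixture

Per subject and channel, 1/f background segments; condition A adds an
alpha-like sinusoid (10 Hz at 250 Hz sampling, random phase per segment,
subject-varying amplitude) to a known subset of channels. It emulates the
*shape* of an eyes-closed/eyes-open contrast — a within-subject effect
confined to known cells over a 1/f background — which suffices to exercise
contrast statistics against a ground truth. It does not emulate real EEG
topography, artifact structure, inter-channel correlation, or individual
spectral differences, so passing tests demonstrate correct statistical
behaviour of the pipeline, not field performance on real recordings.
Defaults: 19 subjects, 12 channels, 20 segments of 256 samples, effect
amplitude 1.0 × background SD with 0.2 jitter on the first third of the
channels.

## Problem sizes used by the tests and the acceptance script

Monte-Carlo sizes were chosen as the smallest that leave the assertions
far from their noise floors: the white/1f separation uses 100 replicates
of 2^14 points per noise type; the length sweep uses a 2^16-point benchmark
(50 replicates in the acceptance script, 12 in the test suite) and 8–200
replicates per reduced length (more where estimates vary most); the
closed-form multiscale check uses 40 replicates of 20 × 1024-point segment
sets; the data-reduction trend uses 12 pseudo-subjects × 8 channels. The
replicate structure, not the per-cell sizes, is what the conclusions rest
on.

## Numerical and design notes

- Counting is integer-exact; entropy values are deterministic for a given
  input regardless of segment order (pair counting is order-free; the
  sorted scan only changes enumeration order).
- Unequal segment lengths are rejected unless explicitly allowed; when
  allowed, the maximal scale follows the shortest segment.
- All randomness flows through one seeded generator per run; replicate
  streams are derived deterministically from it.
- Sample SD (`ddof = 1`) is used for tolerances throughout; for the series
  lengths of interest the distinction from the population SD is far below
  every tolerance asserted.

## Known limitations

- **Finite-sample bias.** `E[ln(B/A)]` carries an `O(1/templates)` negative
  bias relative to the asymptotic value even for a correct implementation;
  at 2^14 white-noise points it is ≈ −0.004. Analytic-limit checks
  therefore use an absolute 0.01 tolerance rather than a band that shrinks
  with replicate count.
- **Short-series overestimation.** With the tolerance taken from a short
  series' own SD, 1/f signals lose slow-fluctuation variance and SampEn is
  overestimated — by ≈ 0.3 at 32 samples, and still ≈ 0.1 at 32 samples
  for white noise. The length sweep reports this honestly; pooling the SD
  across segments (or supplying an external SD) removes most of the effect
  for segmented estimation, which is a key advantage of the segmented
  workflow over truly short continuous recordings.
- The power calculation is a normal approximation for two independent
  groups; it is not a substitute for design-specific power analysis in
  paired or hierarchical designs.
- The 1/f generator produces Gaussian, strictly 1/f^α-spectrum signals;
  real neural recordings have oscillatory peaks, nonstationarities and
  non-Gaussian features the harness does not model.
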