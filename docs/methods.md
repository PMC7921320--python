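# Methods

This note documents the models, estimators and numerical conventions used
in `stimdecode`, the defaults and why they were chosen, and what the
synthetic-data generator does and does not emulate.

## Synthetic neurons

### Rate model

A simulated neuron is an inhomogeneous renewal process.  During a trial of
pattern $p$ the instantaneous rate is

$$r_p(t) = \lambda_0 + s \sum_{(c,\,t_i) \in p} g_c \,
           \frac{1}{\tau_d} e^{-(t - t_i - \ell)/\tau_d}
           \; \mathbb{1}[t > t_i + \ell],$$

with baseline rate $\lambda_0$ (`baseline_rate_hz`, default 10 Hz — a
typical thalamic spontaneous rate), per-channel gain $g_c$
(`response_gain`, expected extra spikes per pulse at $s=1$), response
latency $\ell$ (`response_latency_ms`), decay constant $\tau_d$
(`response_decay_ms`, default 10 ms) and the separability scalar $s$.
Because each pattern is a different set of pulse times over the four
channels, $s$ scales all pattern-to-pattern differences of the rate
profile; $s = 0$ makes every pattern evoke the identical homogeneous
baseline process (the pure-noise condition).  The causal-exponential bump
shape was chosen because it reproduces the sharp-onset/exponential-decay
morphology of observed peristimulus histograms while giving analytic
control of latency, evoked spike count and separability.

### Spike generation

Spikes are drawn by time rescaling: interspike intervals on the rescaled
axis $u = \Lambda(t) = \int_0^t r(t')\,dt'$ are gamma distributed with
shape $\kappa$ (`isi_shape`) and mean 1, and event times are mapped back
through $\Lambda^{-1}$.  This factorisation makes the rate profile and the
ISI regularity independently controllable: $\kappa = 1$ is a Poisson
process ($CV \approx CV2 \approx 1$, firing regularity $\approx 0$),
$\kappa > 1$ regular firing, $\kappa < 1$ bursty firing.

$\Lambda$ is evaluated in closed form at the points of a 0.25 ms grid
(baseline ramp plus saturating exponentials per pulse) and inverted by
linear interpolation.  Evaluating the closed form — rather than
numerically integrating the sampled rate — keeps the onset discontinuity
exactly at pulse time + latency; a trapezoidal rule would smear evoked
probability mass one grid step before the onset, which is enough to bias
the 2 ms-bin latency estimator by one bin.  The renewal process starts
"ordinary" (first interval drawn like all others) at trial onset.

### Spontaneous activity and waveforms

Spontaneous activity is the same renewal process at baseline rate,
generated in segments of the inter-trial relaxation duration (1.8 s), 180 s
in total by default — enough for several thousand ISIs at 10 Hz and for
the latency baseline statistics.

Synthetic spike waveforms are noisy copies of a unimodal template (flat
baseline, kinked onset, linear rise, linear decay) sampled at 100 kHz.
The template is parametrised directly by the quantities the shape metrics
estimate — amplitude, 10 %-to-peak rise time, half-height duration — which
have closed forms in the ramp durations, so recovery can be asserted
against exact ground truth.  Gaussian white noise of configurable SD is
added per sample.

### What the generator does not emulate

Real recordings have slow non-stationarities (anesthesia-state drift),
cross-trial correlations, bursting structure beyond a renewal process,
electrode drift in spike amplitude, and genuinely unknown evoked-response
shapes.  Passing tests therefore demonstrate that the *analysis* is
correct and calibrated under its stated assumptions, not that any
particular biological population decodes at a given level.

## Decoding pipeline

Defaults (all in `DecodingConfig`): kernel $\tau = 5$ ms, window 1,000 ms,
sampling grid 2 ms (500 samples — fine relative to $\tau$ and cheap for
PCA; the step is a config knob), 200 bootstrapped responses per pattern
per set, 95 % variance retained, $k = 9$ neighbours, 50 iterations.

Conventions the analysis fixes where the procedure is underdetermined:

- **Kernel normalisation**: unit area, so a response integrates to its
  spike count.  The F1 score is invariant to a global scale.
- **Bootstrap count**: "200 resamples per data set" is read as 200
  bootstrapped responses *per pattern* per set (1,600 train / 1,600 test
  points).  Each bootstrapped response is the elementwise sum of $N$
  responses drawn with replacement, $N$ = pattern group size.  The draw is
  realised as multinomial counts times the response matrix, which is
  distributionally identical to index resampling and much faster.
- **Splitting** is stratified per pattern (guaranteeing class presence on
  both sides); odd groups give the extra response to training.
- **PCA** centres on the training-set mean; the stored mean is reused to
  project test responses.  Components come from an eigendecomposition of
  the feature covariance, which is numerically robust on the
  near-rank-deficient matrices that strongly separable bootstrapped
  responses produce.  The component count is the smallest whose cumulative
  explained-variance fraction reaches the threshold.
- **Projection** is least squares on the centred response; for the
  orthonormal component basis this is the inner product, and it is
  cross-checked against a generic least-squares solver in the tests.
- **kNN tie-breaking**: relative majority; ties by smaller summed distance
  to the tied label's neighbours, then by the single nearest neighbour
  among tied labels.  Deterministic and order-invariant.
- **F1 aggregation** is macro (unweighted mean over the 8 classes), the
  natural choice for this balanced design (macro ≈ micro here).  Classes
  with an empty prediction column get precision 0 by convention.
- **Averaging**: the confusion matrix is the mean over iterations, so each
  row sums to the per-pattern test-set size; scores are computed from the
  averaged matrix.
- **RNG discipline**: one master seed; per-iteration sub-streams derived
  with `SeedSequence.spawn`, so any iteration is reproducible in
  isolation.

### Shuffled-label null

The null re-runs the pipeline with pattern labels randomly permuted over
all responses, and the decoder criterion is the null population's
mean + 2 SD.  The permutation is redrawn at every iteration, immediately
before that iteration's split.  A permutation fixed across all 50
iterations would leave each relabelled group with a constant composition
of true patterns; for a strongly separable neuron that compositional
signature survives averaging and biases the null upward (measured ≈ 17 %
F1 for a perfect decoder, versus ≈ 12.5–13 % with per-iteration
re-shuffling, consistent with a reported null of 12.42 ± 0.85 %).  The
single fixed pre-split shuffle remains available via
`shuffled_null(..., reshuffle_each_iteration=False)`.

## Spike-shape metrics

All metrics are read off the mean waveform (pointwise mean of the overlaid
traces), optionally pre-filtered with the 50 µs (5-sample at 100 kHz)
moving average used for raw-signal post-processing.  The amplitude is
measured from the inflection point at the spike foot to the peak.  The
foot is located as the last non-strict local minimum of the trace before
the rising flank crosses 10 % of the pre-peak range: on clean traces this
coincides with the maximum-convexity onset kink, but it remains stable
when low-pass filtering has flattened the kink's curvature signature.
Rise time runs from the 10 %-of-amplitude crossing to the peak, and the
half-height duration between the rising and falling crossings of half the
amplitude; all crossings are located by linear interpolation between
samples.  Traces with no identifiable peak or missing crossings return a
result flagged unmeasurable rather than raising.

Note that the 5-sample filter clips sharp (piecewise-linear) synthetic
peaks by roughly `slope × 1.2 samples`; on the smooth extracellular spikes
it is meant for, the distortion is negligible.

## Firing-behaviour metrics

- CV uses the sample SD (ddof = 1); immaterial at realistic ISI counts but
  fixed for reproducibility.
- CV2 is the mean over adjacent ISI pairs; each term lies in [0, 2].
- Firing regularity is the natural logarithm of the maximum-likelihood
  gamma shape factor (`scipy.stats.gamma.fit` with location fixed at 0):
  0 for Poisson, positive for regular firing.  Natural log is the
  convention of the measure's source literature.  All-equal ISIs (where
  the MLE diverges) return `inf`; fewer than 10 ISIs return NaN.
- All three are invariant under uniform time rescaling, which the tests
  assert property-based.

## Latency analysis

The response latency is the left edge of the first bin of the earliest run
of two consecutive PSTH bins strictly exceeding the spontaneous
mean + 2 SD ("strictly", so a zero-variance synthetic baseline does not
trigger on bins equal to the mean).  Left-edge onset semantics were chosen
over bin centres because the rule detects the earliest evidence of a rate
change.  Pattern stimulation pools all trials (8 × 100) into a 500 ms,
2 ms-bin PSTH; single-pulse stimulation pools 4 × 100 trials into a 300 ms
PSTH; 5 and 10 ms bins are supported for the sensitivity analysis (wider
bins raise the absolute mean + 2 SD threshold, so weak diffuse responses
are lost first).

The spontaneous mean and SD are computed from the stimulus-free relaxation
segments chopped into pseudo-trials of the stimulus-PSTH duration.  The SD
is the single-trial bin-count SD (estimated from all pseudo-trial × bin
counts pooled) divided by √n, with n the stimulus PSTH's trial count: a
PSTH averaged over n trials has exactly that per-bin null dispersion, so
the threshold is calibrated to the stimulus PSTH regardless of how much
spontaneous data is available.  Estimating the SD directly from the bins
of a spontaneous PSTH with a different trial count either inflates the
false-positive rate (more pseudo-trials than stimulus trials) or loses
sensitivity (fewer), and the pooled estimator removes most of the
threshold's own sampling noise.

Identified latencies at or below 10 ms set a "presumed direct input" flag
(configurable threshold).  Absence of a qualifying run is a value
("not identified"), not an error.  The rule retains the false-positive
rate inherent to mean + 2 SD thresholding (~3 % per bin under Poisson
baselines), which the tests bound by the run-statistics prediction.

## Problem sizes used in the test suite

The behavioural suite runs the full standard configuration (8 × 100
trials, 200 bootstraps, 50 iterations) for the chance-level and ceiling
checks, and a reduced configuration (30 trials/pattern, 50 bootstraps, 10
iterations, per-pulse gain 0.5) for the 60-run separability-monotonicity
sweep, sized so the F1 range spans chance to ceiling across the
separability grid {0, 0.25, 0.5, 1, 2, 4}.  Latency recovery uses the
single-pulse design (pulse at t = 0), where the injected latency maps
directly onto the PSTH onset.

## Known limitations

- The eight surrogate stimulation patterns are random draws with the
  documented structure, not the published pulse sequences (which are not
  tabulated in text form).
- The generator's renewal assumption means CV2 ≈ CV for all synthetic
  neurons; real neurons with rate drift dissociate the two.
- Serialisation targets delimited text and JSON; at the trial counts of
  this paradigm (≤ 10^3 trials, ≤ 10^5 spikes per neuron) text formats are
  ample.
- The decoder is strictly single-neuron; no population decoding, and no
  alternative classifiers.
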