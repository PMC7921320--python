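# stimdecode

Single-neuron decoding of patterned tactile stimulation from spike trains.

## The problem

In awake and anesthetized animals, patterned electrotactile stimulation of
the skin (here: eight named spatiotemporal pulse patterns delivered through
four electrode pairs in a digit, each pattern presented 100 times with a
1.8 s relaxation phase between trials) evokes trial-by-trial spike responses
in individual neurons.  The scientific question is whether the spike train
of a *single* neuron carries enough information to identify which of the
eight patterns was delivered — and, alongside that, what the neuron's spike
shape, firing regularity and response latency look like.

`stimdecode` implements the complete analysis pipeline for this paradigm,
driven either by recorded trial tables or by its own synthetic spike-train
generator (a time-rescaled gamma renewal process with controllable baseline
rate, ISI regularity, response latency and pattern separability), so every
stage is testable against known ground truth.

## The decoder

For one neuron with responses $s_{p,t}$ (spike times of trial $t$ of
pattern $p$), one iteration of the decoding analysis is:

1. **Convolution** — each spike train in the 1,000 ms window after stimulus
   onset is convolved with a causal exponential kernel
   $k(u) = \tau^{-1} e^{-u/\tau}$, $\tau = 5$ ms, and sampled on a 2 ms grid,
   giving a continuous response function $r_{p,t}$.
2. **Split** — responses are assigned at random, half to a training and
   half to a test set (stratified per pattern).
3. **Bootstrap and PCA** — per pattern and per set, 200 bootstrapped
   responses are formed, each the elementwise sum of $N$ responses drawn
   with replacement ($N$ = group size).  PCA on the bootstrapped training
   set retains the leading components explaining 95 % of the variance.
4. **Projection** — every bootstrapped response is placed in the component
   space by least-squares projection onto the retained components.
5. **Classification** — each bootstrapped test response takes the label
   with a relative majority among its $k = 9$ nearest training responses
   (Euclidean distance; ties broken by smaller summed distance).

Steps 1–5 are repeated 50 times with fresh splits; the confusion matrices
are averaged and the decoding performance is the macro F1 score

$$\mathrm{Precision}_c = \frac{TP_c}{TP_c+FP_c},\quad
  \mathrm{Recall}_c = \frac{TP_c}{TP_c+FN_c},\quad
  F1 = \frac{1}{8}\sum_c \frac{2\,\mathrm{P}_c \mathrm{R}_c}{\mathrm{P}_c+\mathrm{R}_c}.$$

Pure noise yields $F1 = 1/8 = 12.5\,\%$.  The chance distribution is
estimated by re-running the pipeline with pattern labels shuffled before
each split; a neuron counts as a **decoder** when its F1 exceeds the
shuffled population's mean + 2 SD.

The package also computes, per neuron:

- **Spike-shape metrics** from the mean waveform (amplitude from the
  inflection point to the peak, 10 %-to-peak rise time, half-height
  duration), with a 50 µs moving-average pre-filter for 100 kHz recordings;
- **Firing-behaviour metrics** from the interspike intervals: CV
  ($\sigma_{ISI}/\mu_{ISI}$), mean CV2
  ($2|ISI_{i+1}-ISI_i|/(ISI_{i+1}+ISI_i)$), the firing regularity (natural
  log of the ML gamma shape factor) and the firing frequency;
- **Response latency** by the PSTH rate-change method: the first run of two
  consecutive 2 ms bins exceeding the spontaneous mean + 2 SD (500 ms /
  800-trial PSTH for pattern stimulation, 300 ms / 400-trial PSTH for
  single pulses; 5 and 10 ms bins supported for sensitivity analysis).
  Latencies ≤ 10 ms flag presumed direct afferent input.

## Worked example

```python
import stimdecode as sd

protocol = sd.generate_protocol(seed=1)        # 8 patterns x 100 trials
config = sd.DecodingConfig(seed=0)             # tau=5ms, 200 boots, k=9, 50 iters
for sep in (0.0, 0.3, 2.0):
    model = sd.NeuronModel(baseline_rate_hz=10.0, separability=sep,
                           response_gain=0.5, response_latency_ms=8.0, seed=5)
    trials = sd.simulate_neuron(protocol, model)
    result = sd.run_decoding(trials, config)
    null = sd.shuffled_null(trials, config)
    lat = sd.pattern_latency(trials)
    print(f"separability {sep:>3}: F1 = {result.f1_score*100:5.1f} %   "
          f"shuffled = {null.f1_score*100:5.1f} %   "
          f"latency = {lat.latency_ms if lat.identified else 'n.i.'} ms")
```

prints

```
separability 0.0: F1 =   8.1 %   shuffled =  12.8 %   latency = n.i. ms
separability 0.3: F1 =  54.2 %   shuffled =  12.5 %   latency = 32.0 ms
separability 2.0: F1 = 100.0 %   shuffled =  12.8 %   latency = 16.0 ms
```

A neuron whose responses are statistically identical across patterns
(separability 0) decodes at chance (the shuffled null sits at ~12.5 % in
every case), a weakly modulated neuron decodes at 54 %, and a strongly
separable neuron reaches the 100 % ceiling.  The rate-change latency is
only identified once an evoked response exists, and tightens toward the
true onset (first pulse + 8 ms) as the response strengthens.

The same pipeline is available from the shell:

```sh
stimdecode simulate --seed 1 --neurons 5 --separability 1 --out run/
stimdecode decode run/ --shuffle
stimdecode metrics run/
stimdecode latency run/ --bins 2,5,10
stimdecode summarise run/
```

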