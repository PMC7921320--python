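"""Synthetic spike trains and spike waveforms with known ground truth.

Spike trains are drawn from a time-rescaled gamma renewal process.  The
instantaneous firing rate of a simulated neuron during a trial is

    r(t) = baseline + separability * sum_pulses gain[channel]
           * expkernel(t - t_pulse - latency; tau_decay)

where ``expkernel`` is the causal unit-area exponential
``exp(-s/tau)/tau`` for ``s >= 0``.  Spikes are then generated by drawing
unit-mean gamma(kappa) interspike intervals on the rescaled time axis
``u = Lambda(t)`` (the integral of ``r``) and mapping the event times back
through ``Lambda^{-1}``.  This factorisation makes the rate profile
(hence response latency and pattern separability) and the ISI regularity
independently controllable: ``kappa = 1`` gives a Poisson process,
``kappa > 1`` regular firing, ``kappa < 1`` bursty firing.

With ``separability = 0`` the evoked term vanishes and every pattern
evokes the identical homogeneous baseline process -- the pure-noise
condition under which a stimulus classifier must fall to chance.

Spontaneous activity (the inter-trial relaxation phases, during which the
neuron is free from stimulus input) is simulated as the same renewal
process at baseline rate.

Waveforms: :func:`simulate_waveforms` produces noisy copies of a unimodal
template (flat baseline, kinked onset, linear rise, linear decay) whose
amplitude, 10 %-to-peak rise time and half-height duration are exactly the
requested ground-truth values, sampled at 100 kHz to match the recording
hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocols import StimulationProtocol

__all__ = [
    "NeuronModel",
    "TrialResponseSet",
    "WaveformSet",
    "simulate_neuron",
    "simulate_waveforms",
]


@dataclass(frozen=True)
class NeuronModel:
    """Generative parameters of one synthetic neuron.

    Parameters
    ----------
    baseline_rate_hz
        Spontaneous firing rate in spikes/s; must be positive.
    isi_shape
        Gamma shape factor ``kappa`` of the interspike intervals on the
        rescaled time axis.  ``kappa = 1`` yields a Poisson process.
    response_latency_ms
        Delay from each stimulation pulse to the onset of the evoked rate
        increase.
    response_gain
        Per-channel amplitude of the evoked rate bump: expected number of
        extra spikes per pulse at ``separability = 1``.  A scalar is
        broadcast to all channels.
    response_decay_ms
        Decay time constant of the evoked rate bump.
    separability
        Non-negative scalar multiplying all evoked responses; 0 removes
        every pattern-dependent rate modulation.
    seed
        RNG seed; the simulation is a pure function of (inputs, seed).
    """

    baseline_rate_hz: float = 10.0
    isi_shape: float = 1.0
    response_latency_ms: float = 6.0
    response_gain: float | tuple[float, ...] = 1.0
    response_decay_ms: float = 10.0
    separability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate_hz <= 0:
            raise ValueError("baseline_rate_hz must be > 0")
        if self.isi_shape <= 0:
            raise ValueError("isi_shape must be > 0")
        if self.response_decay_ms <= 0:
            raise ValueError("response_decay_ms must be > 0")
        if self.separability < 0:
            raise ValueError("separability must be >= 0")

    def gain_for_channel(self, channel: int) -> float:
        if np.isscalar(self.response_gain):
            return float(self.response_gain)
        gains = tuple(self.response_gain)  # type: ignore[arg-type]
        return float(gains[(channel - 1) % len(gains)])


@dataclass
class TrialResponseSet:
    """Trial-aligned spike times for one neuron.

    ``trials`` maps ``(pattern_name, trial_index)`` (trial indices are
    1-based) to a sorted array of spike times in ms relative to trial
    onset, restricted to ``[0, analysis_window_ms)``.
    ``spontaneous_segments`` holds spike-time arrays from stimulus-free
    relaxation periods, each of duration ``spontaneous_segment_ms``.
    """

    neuron_id: str
    trials: dict[tuple[str, int], np.ndarray]
    analysis_window_ms: float = 1000.0
    spontaneous_segments: list[np.ndarray] = field(default_factory=list)
    spontaneous_segment_ms: float = 1800.0

    def __post_init__(self) -> None:
        for key, spikes in self.trials.items():
            spikes = np.asarray(spikes, dtype=float)
            if spikes.size and (
                np.any(np.diff(spikes) < 0)
                or spikes[0] < 0
                or spikes[-1] >= self.analysis_window_ms
            ):
                raise ValueError(
                    f"trial {key}: spike times must be sorted and within "
                    f"[0, {self.analysis_window_ms})"
                )
            self.trials[key] = spikes

    @property
    def pattern_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for name, _ in self.trials:
            seen.setdefault(name)
        return tuple(seen)

    def trials_for_pattern(self, pattern: str) -> list[np.ndarray]:
        """Spike-time arrays for one pattern, ordered by trial index."""
        items = sorted(
            ((idx, s) for (name, idx), s in self.trials.items() if name == pattern)
        )
        return [s for _, s in items]

    def all_trials(self) -> list[tuple[str, int, np.ndarray]]:
        return [(name, idx, s) for (name, idx), s in sorted(self.trials.items())]

    def spontaneous_isis_ms(self) -> np.ndarray:
        """Interspike intervals pooled within spontaneous segments."""
        isis = [np.diff(seg) for seg in self.spontaneous_segments if len(seg) >= 2]
        return np.concatenate(isis) if isis else np.empty(0)

    def spontaneous_duration_s(self) -> float:
        return len(self.spontaneous_segments) * self.spontaneous_segment_ms / 1000.0

    def spontaneous_spike_count(self) -> int:
        return int(sum(len(seg) for seg in self.spontaneous_segments))


def _evoked_rate_profile(
    pattern_pulses: tuple[tuple[int, float], ...],
    model: NeuronModel,
    grid_ms: np.ndarray,
) -> np.ndarray:
    """Evoked rate (spikes/ms) on the grid, excluding baseline."""
    rate = np.zeros_like(grid_ms)
    tau = model.response_decay_ms
    for channel, t_pulse in pattern_pulses:
        onset = t_pulse + model.response_latency_ms
        s = grid_ms - onset
        active = s >= 0
        rate[active] += model.gain_for_channel(channel) * np.exp(-s[active] / tau) / tau
    return model.separability * rate


def _cumulative_rate(
    pattern_pulses: tuple[tuple[int, float], ...],
    model: NeuronModel,
    grid_ms: np.ndarray,
) -> np.ndarray:
    """Integrated rate Lambda(t) on the grid, in closed form.

    Each causal-exponential bump integrates to
    ``gain * (1 - exp(-(t - onset)/tau))``; evaluating the closed form at
    the grid points (rather than integrating the sampled rate
    numerically) keeps the onset discontinuity exactly at the onset
    instead of smearing probability mass into the preceding grid step.
    """
    cum = (model.baseline_rate_hz / 1000.0) * grid_ms
    tau = model.response_decay_ms
    for channel, t_pulse in pattern_pulses:
        onset = t_pulse + model.response_latency_ms
        s = grid_ms - onset
        active = s > 0
        cum[active] += (
            model.separability
            * model.gain_for_channel(channel)
            * (1.0 - np.exp(-s[active] / tau))
        )
    return cum


def _gamma_renewal_times(
    rng: np.random.Generator, total_mass: float, shape: float
) -> np.ndarray:
    """Event times of a unit-rate gamma renewal process on [0, total_mass]."""
    if total_mass <= 0:
        return np.empty(0)
    # Draw ISI batches until the cumulative sum exceeds the interval.
    n_guess = max(8, int(total_mass + 4.0 * np.sqrt(total_mass / shape) + 8))
    isis = rng.gamma(shape, 1.0 / shape, size=n_guess)
    times = np.cumsum(isis)
    while times[-1] < total_mass:
        extra = rng.gamma(shape, 1.0 / shape, size=n_guess)
        times = np.concatenate([times, times[-1] + np.cumsum(extra)])
    return times[times <= total_mass]


def _simulate_trial(
    rng: np.random.Generator,
    grid_ms: np.ndarray,
    cum_rate: np.ndarray,
    shape: float,
) -> np.ndarray:
    """One trial of the time-rescaled renewal process.

    ``cum_rate`` is the integrated rate Lambda(t) (expected spike count up
    to t) on ``grid_ms``; event times in rescaled time are mapped back
    through linear interpolation of the inverse.
    """
    total = cum_rate[-1]
    rescaled = _gamma_renewal_times(rng, total, shape)
    if rescaled.size == 0:
        return np.empty(0)
    return np.interp(rescaled, cum_rate, grid_ms)


def simulate_neuron(
    protocol: StimulationProtocol,
    model: NeuronModel,
    analysis_window_ms: float = 1000.0,
    spontaneous_duration_s: float = 180.0,
    grid_step_ms: float = 0.25,
) -> TrialResponseSet:
    """Simulate trial responses and spontaneous activity for one neuron.

    For each pattern the evoked-rate profile is computed once on a fine
    grid; every trial then draws an independent realisation of the
    time-rescaled gamma renewal process.  Spontaneous activity is the same
    renewal process at baseline rate, chopped into segments matching the
    inter-trial relaxation duration.

    Deterministic given ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    base_ms = model.baseline_rate_hz / 1000.0  # spikes per ms
    grid = np.arange(0.0, analysis_window_ms + grid_step_ms, grid_step_ms)

    trials: dict[tuple[str, int], np.ndarray] = {}
    for pat in protocol.patterns:
        # Lambda(t) in closed form; strictly increasing since baseline > 0,
        # so the inverse interpolation is well defined.
        cum = _cumulative_rate(pat.pulses, model, grid)
        for trial_idx in range(1, protocol.repetitions + 1):
            spikes = _simulate_trial(rng, grid, cum, model.isi_shape)
            trials[(pat.name, trial_idx)] = spikes[spikes < analysis_window_ms]

    seg_ms = protocol.inter_trial_interval_ms
    n_segments = max(1, int(round(spontaneous_duration_s * 1000.0 / seg_ms)))
    segments = []
    for _ in range(n_segments):
        rescaled = _gamma_renewal_times(rng, base_ms * seg_ms, model.isi_shape)
        segments.append(rescaled / base_ms)

    return TrialResponseSet(
        neuron_id=f"synthetic-seed{model.seed}",
        trials=trials,
        analysis_window_ms=analysis_window_ms,
        spontaneous_segments=segments,
        spontaneous_segment_ms=seg_ms,
    )


@dataclass
class WaveformSet:
    """A set of equal-length spike waveform traces (mV).

    ``ground_truth`` records the template's shape parameters
    (``amplitude_mv``, ``rise_time_ms``, ``half_width_ms``) when the set is
    synthetic.
    """

    traces: np.ndarray  # (n_traces, n_samples)
    sampling_rate_hz: float = 100_000.0
    ground_truth: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.traces = np.atleast_2d(np.asarray(self.traces, dtype=float))
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")


def _spike_template(
    amplitude_mv: float,
    rise_time_ms: float,
    half_width_ms: float,
    sampling_rate_hz: float,
    baseline_ms: float,
    tail_ms: float,
) -> np.ndarray:
    """Unimodal template: flat baseline, linear rise, linear decay.

    The 10 %-to-peak rise time of a linear ramp is 90 % of the full ramp
    duration and its half-height width is half the rise plus half the fall,
    so both ground-truth values have closed forms in the ramp durations.
    """
    rise_full = rise_time_ms / 0.9
    fall_full = 2.0 * half_width_ms - rise_full
    if fall_full <= 0:
        raise ValueError("half_width_ms too small for the requested rise time")
    dt_ms = 1000.0 / sampling_rate_hz
    t = np.arange(0.0, baseline_ms + rise_full + fall_full + tail_ms, dt_ms)
    onset = baseline_ms
    peak_t = onset + rise_full
    v = np.zeros_like(t)
    rising = (t >= onset) & (t <= peak_t)
    v[rising] = amplitude_mv * (t[rising] - onset) / rise_full
    falling = (t > peak_t) & (t <= peak_t + fall_full)
    v[falling] = amplitude_mv * (1.0 - (t[falling] - peak_t) / fall_full)
    return v


def simulate_waveforms(
    n: int,
    amplitude_mv: float = 3.0,
    rise_time_ms: float = 0.27,
    half_width_ms: float = 0.35,
    noise_sd_mv: float = 0.0,
    seed: int = 0,
    sampling_rate_hz: float = 100_000.0,
    baseline_ms: float = 0.5,
    tail_ms: float = 0.5,
) -> WaveformSet:
    """Generate ``n`` noisy copies of a spike-shaped template.

    Defaults match the population means of thalamic spike shapes
    (about 3 mV half-height amplitude x 2, 0.27 ms rise, 0.35 ms width).
    Gaussian white noise of SD ``noise_sd_mv`` is added independently to
    every sample; ``noise_sd_mv = 0`` reproduces the template exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_sd_mv < 0:
        raise ValueError("noise_sd_mv must be >= 0")
    template = _spike_template(
        amplitude_mv, rise_time_ms, half_width_ms, sampling_rate_hz, baseline_ms, tail_ms
    )
    rng = np.random.default_rng(seed)
    traces = np.tile(template, (n, 1))
    if noise_sd_mv > 0:
        traces = traces + rng.normal(0.0, noise_sd_mv, size=traces.shape)
    return WaveformSet(
        traces=traces,
        sampling_rate_hz=sampling_rate_hz,
        ground_truth={
            "amplitude_mv": amplitude_mv,
            "rise_time_ms": rise_time_ms,
            "half_width_ms": half_width_ms,
        },
    )
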