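"""Stimulation protocols: named spatiotemporal pulse patterns over skin electrodes.

The experimental paradigm emulated here delivers patterned electrotactile
stimulation through four pairs of electrodes in the skin of the second
forepaw digit.  Eight distinct spatiotemporal pulse patterns (named after
the object curvatures whose afferent activation they mimic: ``0.5 fa`` ...
``flat sa``) are each presented 100 times in pseudo-random order; a pattern
lasts less than 340 ms and consecutive presentations are separated by a
1.8 s relaxation phase during which the neuron fires spontaneously.  Single
pulse stimulation through one electrode pair at a time (100 repetitions per
pair) is used for response-latency estimation.

The published pulse times of the eight named patterns are not tabulated in
text form, so :func:`generate_protocol` draws reproducible surrogate
patterns with the same structure (channel set, pattern count, duration and
trial timing) under a seeded RNG.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: Names of the eight standard stimulation patterns (four simulated object
#: curvatures x two afferent adaptation types, fast/slow adapting).
PATTERN_NAMES = (
    "0.5 fa", "0.5 sa", "1.0 fa", "1.0 sa",
    "2.0 fa", "2.0 sa", "flat fa", "flat sa",
)

MAX_PATTERN_DURATION_MS = 340.0


@dataclass(frozen=True)
class Pattern:
    """One spatiotemporal stimulation pattern.

    Parameters
    ----------
    name
        Pattern label, e.g. ``"0.5 fa"``.
    pulses
        Sequence of ``(channel, time_ms)`` pairs; channels are 1-based
        electrode-pair indices, times are ms from trial onset.
    """

    name: str
    pulses: tuple[tuple[int, float], ...]

    def pulse_times(self, channel: int | None = None) -> np.ndarray:
        """Pulse times in ms, optionally restricted to one channel."""
        times = [t for c, t in self.pulses if channel is None or c == channel]
        return np.sort(np.asarray(times, dtype=float))


@dataclass(frozen=True)
class StimulationProtocol:
    """A full stimulation protocol: patterns plus trial timing.

    Invariants enforced on construction: exactly ``n_patterns`` distinct
    pattern names (8 for the standard protocol), all pulse times within
    ``[0, pattern_duration_ms)`` and ``pattern_duration_ms`` below 340 ms.
    """

    patterns: tuple[Pattern, ...]
    pattern_duration_ms: float = 330.0
    inter_trial_interval_ms: float = 1800.0
    repetitions: int = 100
    n_channels: int = 4

    def __post_init__(self) -> None:
        names = [p.name for p in self.patterns]
        if len(set(names)) != len(names):
            raise ValueError("pattern names must be distinct")
        if not 0 < self.pattern_duration_ms < MAX_PATTERN_DURATION_MS:
            raise ValueError(
                f"pattern_duration_ms must lie in (0, {MAX_PATTERN_DURATION_MS})"
            )
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        for p in self.patterns:
            for ch, t in p.pulses:
                if not 1 <= ch <= self.n_channels:
                    raise ValueError(f"pattern {p.name!r}: channel {ch} out of range")
                if not 0 <= t < self.pattern_duration_ms:
                    raise ValueError(f"pattern {p.name!r}: pulse time {t} outside pattern window")

    @property
    def pattern_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.patterns)

    def pattern(self, name: str) -> Pattern:
        for p in self.patterns:
            if p.name == name:
                return p
        raise KeyError(name)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["patterns"] = [
            {"name": p.name, "pulses": [[c, t] for c, t in p.pulses]} for p in self.patterns
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulationProtocol":
        patterns = tuple(
            Pattern(p["name"], tuple((int(c), float(t)) for c, t in p["pulses"]))
            for p in d["patterns"]
        )
        return cls(
            patterns=patterns,
            pattern_duration_ms=float(d.get("pattern_duration_ms", 330.0)),
            inter_trial_interval_ms=float(d.get("inter_trial_interval_ms", 1800.0)),
            repetitions=int(d.get("repetitions", 100)),
            n_channels=int(d.get("n_channels", 4)),
        )


def generate_protocol(
    seed: int,
    n_channels: int = 4,
    pulses_per_pattern: tuple[int, int] = (4, 16),
    pattern_duration_ms: float = 330.0,
    inter_trial_interval_ms: float = 1800.0,
    repetitions: int = 100,
    names: tuple[str, ...] = PATTERN_NAMES,
) -> StimulationProtocol:
    """Draw a surrogate 8-pattern stimulation protocol.

    Each pattern receives a uniformly drawn pulse count in
    ``pulses_per_pattern`` (inclusive range), each pulse a uniform channel
    and a uniform time within the pattern window.  Deterministic given
    ``seed``.

    Returns
    -------
    StimulationProtocol
        Eight distinct named patterns satisfying all protocol invariants.
    """
    lo, hi = pulses_per_pattern
    if lo < 1 or hi < lo:
        raise ValueError("pulses_per_pattern must be an increasing range with lower bound >= 1")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rng = np.random.default_rng(seed)
    patterns = []
    for name in names:
        n_pulses = int(rng.integers(lo, hi + 1))
        channels = rng.integers(1, n_channels + 1, size=n_pulses)
        times = np.sort(rng.uniform(0.0, pattern_duration_ms, size=n_pulses))
        patterns.append(Pattern(name, tuple((int(c), float(t)) for c, t in zip(channels, times))))
    return StimulationProtocol(
        patterns=tuple(patterns),
        pattern_duration_ms=pattern_duration_ms,
        inter_trial_interval_ms=inter_trial_interval_ms,
        repetitions=repetitions,
        n_channels=n_channels,
    )


def single_pulse_protocol(
    n_channels: int = 4,
    repetitions: int = 100,
    pattern_duration_ms: float = 1.0,
    inter_trial_interval_ms: float = 1800.0,
) -> StimulationProtocol:
    """Protocol variant for single-pulse stimulation.

    One pattern per electrode channel with a single pulse at t = 0,
    ``repetitions`` trials each, mirroring the latency-estimation paradigm
    (one electrode pair at a time, 100 repetitions per pair).
    """
    patterns = tuple(
        Pattern(f"pulse ch{c}", ((c, 0.0),)) for c in range(1, n_channels + 1)
    )
    return StimulationProtocol(
        patterns=patterns,
        pattern_duration_ms=pattern_duration_ms,
        inter_trial_interval_ms=inter_trial_interval_ms,
        repetitions=repetitions,
        n_channels=n_channels,
    )
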