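"""Serialisation of spike tables, protocols and result summaries.

Formats:

* Spike tables -- delimited text with header
  ``neuron_id,pattern,trial,spike_time_ms`` (one row per spike; trials
  without spikes are declared in the sidecar), plus a JSON sidecar
  (``<table>.json``) holding the analysis window, trial roster and
  spontaneous segments.  All times are ms, 0-aligned to trial onset.
* Protocols -- a JSON document mirroring the protocol dataclasses.
* Results -- JSON per neuron plus delimited population tables; scores are
  stored as fractions and rendered as percentages in summaries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .protocols import StimulationProtocol
from .simulate import TrialResponseSet, WaveformSet

__all__ = [
    "read_trials",
    "write_trials",
    "read_protocol",
    "write_protocol",
    "read_waveforms",
    "write_waveforms",
    "summarise_population",
    "PopulationSummary",
]

SPIKE_COLUMNS = ["neuron_id", "pattern", "trial", "spike_time_ms"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trials(trials: TrialResponseSet, path: str | Path) -> None:
    """Write a trial table and its JSON sidecar."""
    path = Path(path)
    rows = [
        (trials.neuron_id, name, idx, t)
        for name, idx, spikes in trials.all_trials()
        for t in spikes
    ]
    df = pd.DataFrame(rows, columns=SPIKE_COLUMNS)
    df.to_csv(path, index=False)
    sidecar = {
        "neuron_id": trials.neuron_id,
        "analysis_window_ms": trials.analysis_window_ms,
        "trial_roster": [[name, idx] for name, idx, _ in trials.all_trials()],
        "spontaneous_segment_ms": trials.spontaneous_segment_ms,
        "spontaneous_segments": [list(map(float, seg)) for seg in trials.spontaneous_segments],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))


def read_trials(path: str | Path) -> TrialResponseSet:
    """Read a trial table written by :func:`write_trials`.

    Validates the schema and the spike-table invariants; malformed rows
    are reported with their (1-based, header-exclusive) line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    neuron_ids = df["neuron_id"].unique()
    if len(neuron_ids) > 1:
        raise ValueError(f"{path}: multiple neuron_ids {list(neuron_ids)}")

    sidecar_file = _sidecar_path(path)
    if sidecar_file.exists():
        sidecar = json.loads(sidecar_file.read_text())
    else:
        sidecar = {}
    window = float(sidecar.get("analysis_window_ms", 1000.0))

    trials: dict[tuple[str, int], list[float]] = {}
    for name, idx in sidecar.get("trial_roster", []):
        trials[(str(name), int(idx))] = []
    prev_key, prev_t = None, -math.inf
    for line, row in enumerate(df.itertuples(index=False), start=1):
        key = (str(row.pattern), int(row.trial))
        t = float(row.spike_time_ms)
        if not 0 <= t < window:
            raise ValueError(f"{path} row {line}: spike time {t} outside [0, {window})")
        if key == prev_key and t < prev_t:
            raise ValueError(f"{path} row {line}: unsorted spike times in trial {key}")
        if key != prev_key and key in trials and trials[key] and prev_key is not None:
            raise ValueError(f"{path} row {line}: duplicate trial block for {key}")
        trials.setdefault(key, []).append(t)
        prev_key, prev_t = key, t

    neuron_id = str(neuron_ids[0]) if len(neuron_ids) else sidecar.get("neuron_id", "unknown")
    return TrialResponseSet(
        neuron_id=neuron_id,
        trials={k: np.asarray(v) for k, v in trials.items()},
        analysis_window_ms=window,
        spontaneous_segments=[np.asarray(s) for s in sidecar.get("spontaneous_segments", [])],
        spontaneous_segment_ms=float(sidecar.get("spontaneous_segment_ms", 1800.0)),
    )


def write_waveforms(waveforms: WaveformSet, path: str | Path) -> None:
    """Write a waveform set as a delimited trace matrix (one trace per row).

    The sampling rate (and ground truth, when synthetic) goes into the
    JSON sidecar.
    """
    path = Path(path)
    np.savetxt(path, waveforms.traces, delimiter=",")
    sidecar = {"sampling_rate_hz": waveforms.sampling_rate_hz}
    if waveforms.ground_truth is not None:
        sidecar["ground_truth"] = waveforms.ground_truth
    _sidecar_path(path).write_text(json.dumps(sidecar))


def read_waveforms(path: str | Path) -> WaveformSet:
    """Read a waveform set written by :func:`write_waveforms`."""
    path = Path(path)
    traces = np.loadtxt(path, delimiter=",", ndmin=2)
    sidecar_file = _sidecar_path(path)
    sidecar = json.loads(sidecar_file.read_text()) if sidecar_file.exists() else {}
    return WaveformSet(
        traces=traces,
        sampling_rate_hz=float(sidecar.get("sampling_rate_hz", 100_000.0)),
        ground_truth=sidecar.get("ground_truth"),
    )


def write_protocol(protocol: StimulationProtocol, path: str | Path) -> None:
    Path(path).write_text(json.dumps(protocol.to_dict(), indent=1))


def read_protocol(path: str | Path) -> StimulationProtocol:
    return StimulationProtocol.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PopulationSummary:
    """Per-neuron rows and population aggregates of the full analysis."""

    per_neuron: pd.DataFrame
    aggregates: dict[str, tuple[float, float]]  # column -> (mean, sd); sd NaN for n=1
    decoder_fraction: float
    n_neurons: int

    def to_text(self) -> str:
        lines = [f"Population summary ({self.n_neurons} neurons)"]
        for col, (mean, sd) in self.aggregates.items():
            shown_mean, shown_sd = mean, sd
            unit = ""
            if col in ("f1_score", "shuffled_f1"):
                shown_mean, shown_sd = 100 * mean, 100 * sd
                unit = " %"
            lines.append(f"  {col}: {shown_mean:.4g} +/- {shown_sd:.4g}{unit}")
        lines.append(
            f"  decoders: {self.decoder_fraction * 100:.1f}% "
            f"({int(round(self.decoder_fraction * self.n_neurons))}/{self.n_neurons})"
        )
        return "\n".join(lines)


def summarise_population(per_neuron: pd.DataFrame) -> PopulationSummary:
    """Aggregate per-neuron result rows into population mean +/- SD.

    Expects at least the columns ``f1_score`` and ``shuffled_f1``; the
    decoder threshold (shuffled mean + 2 SD) is recomputed from the
    population of shuffled scores and the decoder fraction counted
    against it.  SD entries are NaN for a single neuron.
    """
    if per_neuron.empty:
        raise ValueError("no neurons to summarise")
    from .decoding import decoder_threshold

    df = per_neuron.copy()
    if "shuffled_f1" in df and len(df) >= 2:
        threshold = decoder_threshold(df["shuffled_f1"].to_numpy())
    else:
        threshold = math.nan
    if "f1_score" in df:
        df["is_decoder"] = df["f1_score"] > threshold
        decoder_fraction = float(df["is_decoder"].mean()) if not math.isnan(threshold) else math.nan
    else:
        decoder_fraction = math.nan

    aggregates: dict[str, tuple[float, float]] = {}
    for col in df.columns:
        if df[col].dtype.kind in "fi" and col != "is_decoder":
            vals = df[col].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            sd = float(np.std(vals, ddof=1)) if vals.size > 1 else math.nan
            aggregates[col] = (float(vals.mean()), sd)
    return PopulationSummary(
        per_neuron=df,
        aggregates=aggregates,
        decoder_fraction=decoder_fraction,
        n_neurons=len(df),
    )
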