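"""In-memory containers and plain-text IO for traces, line scans and experiments.

Voltage traces are uniformly sampled somatic recordings in mV; line scans are
two-structure (spine, shaft) fluorescence series at the scan rate; experiment
records hold the pre/post test-pulse EPSP amplitude series for one cell.
Synthetic objects carry their generator ground truth so downstream recovery
can be tested against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["VoltageTrace", "LineScan", "ExperimentRecord"]


@dataclass
class VoltageTrace:
    """Uniformly sampled somatic voltage (mV, relative to rest).

    ``annotations`` maps event names (stimulus, induction, ...) to lists of
    event times in ms within the trace.
    """

    samples: np.ndarray
    sampling_rate: float = 10_000.0
    annotations: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        dur = self.duration_ms
        for name, times in self.annotations.items():
            for t in np.atleast_1d(times):
                if not (0 <= t <= dur):
                    raise ValueError(f"annotation {name!r} at {t} ms outside trace [0, {dur}] ms")

    @property
    def duration_ms(self) -> float:
        return len(self.samples) / self.sampling_rate * 1000.0

    def time_ms(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate * 1000.0

    def window_slice(self, window_ms: tuple[float, float]) -> slice:
        """Index slice covering a [start, stop) window given in ms."""
        start, stop = window_ms
        if stop <= start:
            raise ValueError(f"empty window {window_ms}")
        if start < 0 or stop > self.duration_ms + 1e-9:
            raise ValueError(f"window {window_ms} outside trace [0, {self.duration_ms:.1f}] ms")
        i0 = int(round(start / 1000.0 * self.sampling_rate))
        i1 = int(round(stop / 1000.0 * self.sampling_rate))
        return slice(i0, max(i1, i0 + 1))

    def to_csv(self, path: str | Path) -> None:
        t = np.arange(len(self.samples)) / self.sampling_rate
        pd.DataFrame({"time_s": t, "v_mV": self.samples}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "VoltageTrace":
        df = pd.read_csv(path)
        if not {"time_s", "v_mV"}.issubset(df.columns):
            raise ValueError(f"{path}: expected columns time_s,v_mV")
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise ValueError(f"{path}: trace too short")
        rate = 1.0 / float(np.median(np.diff(t)))
        return cls(samples=df["v_mV"].to_numpy(), sampling_rate=rate)


@dataclass
class LineScan:
    """Two-channel 500 Hz fluorescence line scan through a spine and its shaft."""

    spine_f: np.ndarray
    shaft_f: np.ndarray
    rate: float = 500.0
    baseline_window: tuple[int, int] = (0, 50)
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spine_f = np.asarray(self.spine_f, dtype=float)
        self.shaft_f = np.asarray(self.shaft_f, dtype=float)
        if self.spine_f.shape != self.shaft_f.shape:
            raise ValueError("spine and shaft series must have equal length")
        if np.any(self.spine_f <= 0) or np.any(self.shaft_f <= 0):
            raise ValueError("fluorescence must be positive")
        i0, i1 = self.baseline_window
        if not (0 <= i0 < i1 <= len(self.spine_f)):
            raise ValueError("baseline window must be a non-empty index range in the scan")

    def to_csv(self, path: str | Path) -> None:
        t = np.arange(len(self.spine_f)) / self.rate
        pd.DataFrame(
            {"t_s": t, "spine_f": self.spine_f, "shaft_f": self.shaft_f}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, baseline_window: tuple[int, int] = (0, 50)) -> "LineScan":
        df = pd.read_csv(path)
        if not {"t_s", "spine_f", "shaft_f"}.issubset(df.columns):
            raise ValueError(f"{path}: expected columns t_s,spine_f,shaft_f")
        t = df["t_s"].to_numpy()
        rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 500.0
        return cls(
            spine_f=df["spine_f"].to_numpy(),
            shaft_f=df["shaft_f"].to_numpy(),
            rate=rate,
            baseline_window=baseline_window,
        )


@dataclass
class ExperimentRecord:
    """One cell's pre/post test-pulse EPSP amplitudes and RMP series.

    ``truth`` holds the synthetic ground truth (baseline, per-cell
    potentiation factor) when the record came from the generator; loaded
    experimental records leave it empty.
    """

    cell_id: str
    condition: str
    pre_amplitudes: np.ndarray
    post_amplitudes: np.ndarray
    rmp_series: np.ndarray = field(default_factory=lambda: np.array([]))
    included: bool = True
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pre_amplitudes = np.asarray(self.pre_amplitudes, dtype=float)
        self.post_amplitudes = np.asarray(self.post_amplitudes, dtype=float)
        self.rmp_series = np.asarray(self.rmp_series, dtype=float)
        if self.included and (len(self.pre_amplitudes) == 0 or len(self.post_amplitudes) == 0):
            raise ValueError("included records need non-empty pre and post amplitude series")
        if np.any(self.pre_amplitudes < 0) or np.any(self.post_amplitudes < 0):
            raise ValueError("EPSP amplitudes must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("pre_amplitudes", "post_amplitudes", "rmp_series"):
            d[key] = np.asarray(d[key]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentRecord":
        return cls(
            cell_id=d["cell_id"],
            condition=d["condition"],
            pre_amplitudes=np.asarray(d["pre_amplitudes"], dtype=float),
            post_amplitudes=np.asarray(d["post_amplitudes"], dtype=float),
            rmp_series=np.asarray(d.get("rmp_series", []), dtype=float),
            included=bool(d.get("included", True)),
            truth=dict(d.get("truth", {})),
        )


def save_records(records: list[ExperimentRecord], path: str | Path) -> None:
    """Write a list of experiment records as JSON."""
    Path(path).write_text(json.dumps([r.to_dict() for r in records], indent=1))


def load_records(path: str | Path) -> list[ExperimentRecord]:
    """Read a list of experiment records from JSON."""
    return [ExperimentRecord.from_dict(d) for d in json.loads(Path(path).read_text())]
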