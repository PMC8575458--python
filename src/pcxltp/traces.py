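"""Feature extraction from voltage traces and fluorescence line scans.

EPSP peak amplitude, all-or-none input–output threshold detection,
NMDA-spike (plateau) amplitude/area/classification, spike counting in 4 Hz
trains, and ΔF/F for two-channel line scans.  Measurement windows are
explicit parameters: baseline 0–50 ms and response 50–150 ms by default for
EPSPs; spikes integrate the full post-baseline epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .records import LineScan, VoltageTrace

__all__ = [
    "SpikeFeatures",
    "IOCurve",
    "DffResult",
    "measure_epsp_amplitude",
    "detect_allornone_threshold",
    "extract_spike_features",
    "count_spikes_in_train",
    "compute_dff",
]

DEFAULT_BASELINE_MS = (0.0, 50.0)
DEFAULT_RESPONSE_MS = (50.0, 150.0)
#: Somatic depolarisation classifying a response as an NMDA-spike (mV).
DEFAULT_SPIKE_THRESHOLD_MV = 10.2


@dataclass(frozen=True)
class SpikeFeatures:
    """Baseline-subtracted plateau features of one trace."""

    is_spike: bool
    peak_amplitude: float
    area: float
    onset_time: Optional[float]

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("area must be >= 0")


@dataclass(frozen=True)
class IOCurve:
    """Input–output curve with the detected all-or-none threshold (if any)."""

    intensities: np.ndarray
    peak_responses: np.ndarray
    detected_threshold: Optional[float]
    jump_size: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "intensities", np.asarray(self.intensities, dtype=float))
        object.__setattr__(self, "peak_responses", np.asarray(self.peak_responses, dtype=float))
        if self.intensities.shape != self.peak_responses.shape:
            raise ValueError("intensities and peak_responses must have equal length")
        if self.detected_threshold is not None and self.detected_threshold not in self.intensities:
            raise ValueError("detected_threshold must be one of the intensities")


@dataclass(frozen=True)
class DffResult:
    """ΔF/F series and summary statistics per structure."""

    spine_dff: np.ndarray
    shaft_dff: np.ndarray
    spine_peak: float
    shaft_peak: float
    spine_mean: float
    shaft_mean: float


def _window_mean(trace: VoltageTrace, window_ms) -> float:
    return float(np.mean(trace.samples[trace.window_slice(window_ms)]))


def measure_epsp_amplitude(
    trace: VoltageTrace,
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_MS,
    response_window: tuple[float, float] = DEFAULT_RESPONSE_MS,
) -> float:
    """EPSP peak: max of the response window minus the baseline-window mean."""
    if baseline_window[1] > response_window[0]:
        raise ValueError("baseline window must precede the response window")
    base = _window_mean(trace, baseline_window)
    resp = trace.samples[trace.window_slice(response_window)]
    return float(np.max(resp) - base)


def detect_allornone_threshold(
    intensities: Sequence[float],
    peaks: Sequence[float],
    min_jump_fraction: float = 0.4,
) -> IOCurve:
    """Locate the all-or-none jump in a peak-vs-intensity curve.

    Finds the largest adjacent-peak increase; a threshold is declared at the
    upper intensity of that pair when the jump is at least
    ``min_jump_fraction`` of the maximum peak, otherwise no threshold.
    """
    intensities = np.asarray(intensities, dtype=float)
    peaks = np.asarray(peaks, dtype=float)
    if intensities.shape != peaks.shape:
        raise ValueError("intensities and peaks must have equal length")
    if len(intensities) < 3:
        raise ValueError("need at least 3 curve points")
    if np.any(np.diff(intensities) <= 0):
        raise ValueError("intensities must be strictly increasing")
    jumps = np.diff(peaks)
    i = int(np.argmax(jumps))
    jump = float(jumps[i])
    thr = float(intensities[i + 1]) if jump >= min_jump_fraction * float(np.max(peaks)) else None
    return IOCurve(
        intensities=intensities,
        peak_responses=peaks,
        detected_threshold=thr,
        jump_size=jump,
    )


def extract_spike_features(
    trace: VoltageTrace,
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_MS,
    voltage_threshold: float = DEFAULT_SPIKE_THRESHOLD_MV,
    response_window: Optional[tuple[float, float]] = None,
) -> SpikeFeatures:
    """Baseline-subtracted peak, positive-part trapezoidal area and
    spike classification (peak >= ``voltage_threshold``).

    The response epoch defaults to everything after the baseline window.
    Onset is the first crossing of 5% of the peak within the epoch.
    """
    base = _window_mean(trace, baseline_window)
    if response_window is None:
        response_window = (baseline_window[1], trace.duration_ms)
    sl = trace.window_slice(response_window)
    v = trace.samples[sl] - base
    peak = float(np.max(v)) if len(v) else 0.0
    peak = max(peak, 0.0)
    dt_ms = 1000.0 / trace.sampling_rate
    area = float(np.trapezoid(np.maximum(v, 0.0), dx=dt_ms))
    onset = None
    if peak > 0:
        above = np.nonzero(v >= 0.05 * peak)[0]
        if len(above):
            onset = response_window[0] + above[0] * dt_ms
    return SpikeFeatures(
        is_spike=peak >= voltage_threshold,
        peak_amplitude=peak,
        area=area,
        onset_time=onset,
    )


def count_spikes_in_train(
    trace: VoltageTrace,
    voltage_threshold: float = DEFAULT_SPIKE_THRESHOLD_MV,
    refractory_ms: float = 100.0,
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_MS,
) -> int:
    """Count upward threshold crossings separated by >= ``refractory_ms``.

    The default refractory of 100 ms sits below the 250 ms inter-burst
    interval of a 4 Hz train, so consecutive spikes are resolved while
    within-plateau fluctuations are not double counted.
    """
    if refractory_ms <= 0:
        raise ValueError("refractory_ms must be > 0")
    base = _window_mean(trace, baseline_window)
    v = trace.samples - base
    above = v >= voltage_threshold
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    dt_ms = 1000.0 / trace.sampling_rate
    count = 0
    last = -np.inf
    for idx in crossings:
        t = idx * dt_ms
        if t - last >= refractory_ms:
            count += 1
            last = t
    return count


def compute_dff(
    scan: LineScan, response_window: Optional[tuple[int, int]] = None
) -> DffResult:
    """ΔF/F = (F − F0)/F0 per structure, F0 the baseline-window mean.

    Peak and mean are reported over the response epoch (default: everything
    after the baseline window).  Invariant under multiplicative gain.
    """
    i0, i1 = scan.baseline_window
    if response_window is None:
        response_window = (i1, len(scan.spine_f))
    r0, r1 = response_window
    if not (0 <= r0 < r1 <= len(scan.spine_f)):
        raise ValueError("response window must be a non-empty index range in the scan")

    def one(f: np.ndarray) -> tuple[np.ndarray, float, float]:
        f0 = float(np.mean(f[i0:i1]))
        if f0 <= 0:
            raise ValueError("non-positive baseline fluorescence")
        dff = (f - f0) / f0
        return dff, float(np.max(dff[r0:r1])), float(np.mean(dff[r0:r1]))

    spine_dff, spine_peak, spine_mean = one(scan.spine_f)
    shaft_dff, shaft_peak, shaft_mean = one(scan.shaft_f)
    return DffResult(
        spine_dff=spine_dff,
        shaft_dff=shaft_dff,
        spine_peak=spine_peak,
        shaft_peak=shaft_peak,
        spine_mean=spine_mean,
        shaft_mean=shaft_mean,
    )
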