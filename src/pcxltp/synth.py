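"""Synthetic electrophysiology generators with known ground truth.

Emulates the stimulation protocols and effect sizes of focal-stimulation LTP
experiments in piriform cortex layer II pyramidal neurons:

* EPSP voltage traces (difference-of-exponentials kernel, default peak
  1.88 mV) with additive recording noise,
* all-or-none NMDA-spike input–output curves: graded EPSPs below the
  stimulus-intensity threshold, plateau-like spikes (default somatic
  amplitude 27.2 mV, area 2999.5 mV·ms) at and above it,
* 4 Hz NMDA-spike trains for spike counting,
* per-cell LTP experiment series: 0.033 Hz test-pulse EPSP amplitudes
  before and after an induction event, with a condition-specific step
  potentiation factor, lognormal trial noise, between-cell factor
  variability and optional resting-potential drift,
* 500 Hz two-channel (spine/shaft) fluorescence line scans with a
  calcium-transient of known ΔF/F peak.

Condition presets encode the published per-condition potentiation point
estimates (e.g. 213.98% of control for LOT layer Ia inputs under the
NMDA-spike protocol at n = 26) and calibrate between-cell variability so
that simulated cohort SEMs match the printed ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .records import ExperimentRecord, LineScan, VoltageTrace

__all__ = [
    "EPSPKernel",
    "NMDASpikeModel",
    "ProtocolSpec",
    "ExperimentSpec",
    "ConditionPreset",
    "CONDITION_PRESETS",
    "CONDITION_ORDER",
    "calibrated_between_cell_sd",
    "spec_for_condition",
    "make_epsp_trace",
    "make_plateau_trace",
    "make_io_curve",
    "make_train_trace",
    "simulate_ltp_experiment",
    "make_linescan",
]


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _lognormal_mean_cv(rng: np.random.Generator, mean, cv, size=None):
    """Lognormal draws parameterised by arithmetic mean and CV (exact)."""
    mean = np.asarray(mean, dtype=float)
    if np.any(mean < 0):
        raise ValueError("lognormal mean must be >= 0")
    if cv == 0:
        return np.broadcast_to(mean, size if size is not None else mean.shape).copy()
    sigma2 = math.log(1.0 + cv * cv)
    mu = np.log(np.where(mean > 0, mean, 1.0)) - 0.5 * sigma2
    out = rng.lognormal(mu, math.sqrt(sigma2), size=size)
    return np.where(mean > 0, out, 0.0)


# ---------------------------------------------------------------------------
# waveforms


@dataclass(frozen=True)
class EPSPKernel:
    """Difference-of-exponentials EPSP waveform, normalised to its peak.

    ``amplitude`` is the noiseless peak in mV (default 1.88, the typical
    single-input EPSP used as the test pulse); ``onset`` the stimulus time
    within the trace in ms.
    """

    amplitude: float = 1.88
    rise_tau: float = 2.0
    decay_tau: float = 20.0
    onset: float = 50.0

    def __post_init__(self) -> None:
        if not (self.decay_tau > self.rise_tau > 0):
            raise ValueError("need decay_tau > rise_tau > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")

    @property
    def peak_time(self) -> float:
        """Time-to-peak after onset, ms (closed form for two exponentials)."""
        tr, td = self.rise_tau, self.decay_tau
        return tr * td / (td - tr) * math.log(td / tr)

    def waveform(self, t_ms: np.ndarray) -> np.ndarray:
        """Evaluate the kernel at times ``t_ms`` (noiseless, peak = amplitude)."""
        t = np.asarray(t_ms, dtype=float) - self.onset
        shape = np.where(
            t >= 0,
            np.exp(-np.maximum(t, 0) / self.decay_tau)
            - np.exp(-np.maximum(t, 0) / self.rise_tau),
            0.0,
        )
        tp = self.peak_time
        norm = math.exp(-tp / self.decay_tau) - math.exp(-tp / self.rise_tau)
        return self.amplitude * shape / norm


@dataclass(frozen=True)
class NMDASpikeModel:
    """Somatic signature of a dendritic NMDA-spike (plateau potential).

    Defaults follow basal-dendrite measurements: classification threshold
    10.2 mV depolarisation, amplitude 27.2 ± 2.5 mV, area 2999.5 ±
    434.7 mV·ms.  ``intensity_threshold`` is the stimulus intensity at which
    the all-or-none jump occurs; ``plateau_duration`` is the plateau length
    used when no area is drawn.
    """

    voltage_threshold: float = 10.2
    amplitude_mean: float = 27.2
    amplitude_sd: float = 2.5
    area_mean: float = 2999.5
    area_sd: float = 434.7
    intensity_threshold: float = 5.0
    plateau_duration: float = 50.0
    ramp_ms: float = 4.0

    def __post_init__(self) -> None:
        if self.amplitude_mean <= self.voltage_threshold:
            raise ValueError("amplitude_mean must exceed voltage_threshold")
        if min(self.amplitude_sd, self.area_sd) < 0:
            raise ValueError("spread parameters must be >= 0")
        if self.plateau_duration <= 0 or self.ramp_ms <= 0:
            raise ValueError("durations must be positive")

    def draw_spike(self, rng: np.random.Generator) -> tuple[float, float]:
        """Draw (amplitude mV, area mV·ms); both truncated to stay positive."""
        amp = max(rng.normal(self.amplitude_mean, self.amplitude_sd), self.voltage_threshold)
        area = max(rng.normal(self.area_mean, self.area_sd), amp * self.ramp_ms)
        return amp, area


def _plateau_waveform(
    t_ms: np.ndarray, onset: float, amplitude: float, area: float, ramp_ms: float
) -> np.ndarray:
    """Plateau with half-cosine ramps; exact area = amplitude*(flat + ramp)."""
    flat = area / amplitude - ramp_ms
    if flat < 0:
        raise ValueError("area too small for the requested amplitude and ramp")
    t = np.asarray(t_ms, dtype=float) - onset
    y = np.zeros_like(t)
    rise = (t >= 0) & (t < ramp_ms)
    y[rise] = 0.5 * (1 - np.cos(np.pi * t[rise] / ramp_ms))
    top = (t >= ramp_ms) & (t < ramp_ms + flat)
    y[top] = 1.0
    fall = (t >= ramp_ms + flat) & (t < 2 * ramp_ms + flat)
    y[fall] = 0.5 * (1 + np.cos(np.pi * (t[fall] - ramp_ms - flat) / ramp_ms))
    return amplitude * y


def make_epsp_trace(
    kernel: EPSPKernel,
    noise_sd: float = 0.0,
    duration_ms: float = 300.0,
    rng=0,
    sampling_rate: float = 10_000.0,
) -> VoltageTrace:
    """Synthesise one EPSP trace: kernel waveform plus white recording noise."""
    if duration_ms < kernel.onset + 5 * kernel.decay_tau:
        raise ValueError(
            f"duration {duration_ms} ms too short; need >= onset + 5*decay_tau = "
            f"{kernel.onset + 5 * kernel.decay_tau} ms"
        )
    rng = _as_rng(rng)
    n = int(round(duration_ms / 1000.0 * sampling_rate))
    t = np.arange(n) / sampling_rate * 1000.0
    v = kernel.waveform(t)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=n)
    return VoltageTrace(
        samples=v,
        sampling_rate=sampling_rate,
        annotations={"stimulus": [kernel.onset]},
        meta={"kind": "epsp", "truth_amplitude": kernel.amplitude},
    )


def make_plateau_trace(
    nmda: NMDASpikeModel,
    amplitude: Optional[float] = None,
    area: Optional[float] = None,
    noise_sd: float = 0.0,
    onset: float = 50.0,
    duration_ms: float = 400.0,
    rng=0,
    sampling_rate: float = 10_000.0,
) -> VoltageTrace:
    """Synthesise a plateau-spike trace with given (or drawn) amplitude/area."""
    rng = _as_rng(rng)
    if amplitude is None or area is None:
        a, ar = nmda.draw_spike(rng)
        amplitude = amplitude if amplitude is not None else a
        area = area if area is not None else ar
    n = int(round(duration_ms / 1000.0 * sampling_rate))
    t = np.arange(n) / sampling_rate * 1000.0
    end = onset + area / amplitude + nmda.ramp_ms
    if end > duration_ms:
        raise ValueError("duration too short for plateau; increase duration_ms")
    v = _plateau_waveform(t, onset, amplitude, area, nmda.ramp_ms)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=n)
    return VoltageTrace(
        samples=v,
        sampling_rate=sampling_rate,
        annotations={"stimulus": [onset]},
        meta={"kind": "nmda_spike", "truth_amplitude": amplitude, "truth_area": area},
    )


def make_io_curve(
    nmda: NMDASpikeModel,
    intensities: Sequence[float],
    rng=0,
    noise_sd: float = 0.3,
    sampling_rate: float = 10_000.0,
    duration_ms: float = 400.0,
    kernel: Optional[EPSPKernel] = None,
) -> list[VoltageTrace]:
    """Input–output curve traces: graded EPSPs below the intensity threshold,
    all-or-none plateau spikes at and above it.

    Sub-threshold peaks grow linearly with intensity up to 80% of the
    classification voltage threshold, so the peak-vs-intensity curve has a
    single dominant jump at ``nmda.intensity_threshold``.
    """
    intensities = list(intensities)
    if not intensities:
        raise ValueError("intensity list is empty")
    if any(b <= a for a, b in zip(intensities, intensities[1:])):
        raise ValueError("intensities must be strictly increasing")
    rng = _as_rng(rng)
    kernel = kernel or EPSPKernel()
    traces = []
    for inten in intensities:
        if inten < nmda.intensity_threshold:
            peak = 0.8 * nmda.voltage_threshold * inten / nmda.intensity_threshold
            k = replace(kernel, amplitude=peak)
            tr = make_epsp_trace(k, noise_sd=noise_sd, duration_ms=duration_ms,
                                 rng=rng, sampling_rate=sampling_rate)
            tr.meta.update(kind="io_point", is_spike_truth=False)
        else:
            tr = make_plateau_trace(nmda, noise_sd=noise_sd, duration_ms=duration_ms,
                                    rng=rng, sampling_rate=sampling_rate)
            tr.meta.update(kind="io_point", is_spike_truth=True)
        tr.meta["intensity"] = inten
        traces.append(tr)
    return traces


def make_train_trace(
    nmda: NMDASpikeModel,
    n_bursts: int,
    burst_rate_hz: float = 4.0,
    suprathreshold: Optional[Sequence[bool]] = None,
    noise_sd: float = 0.0,
    rng=0,
    sampling_rate: float = 10_000.0,
) -> VoltageTrace:
    """4 Hz train of NMDA-spike bursts; entries of ``suprathreshold`` set to
    False produce sub-threshold EPSP-like events instead of spikes."""
    if n_bursts < 1:
        raise ValueError("n_bursts must be >= 1")
    rng = _as_rng(rng)
    if suprathreshold is None:
        suprathreshold = [True] * n_bursts
    if len(suprathreshold) != n_bursts:
        raise ValueError("suprathreshold mask length must equal n_bursts")
    interval_ms = 1000.0 / burst_rate_hz
    onset0 = 50.0
    duration_ms = onset0 + n_bursts * interval_ms + 200.0
    n = int(round(duration_ms / 1000.0 * sampling_rate))
    t = np.arange(n) / sampling_rate * 1000.0
    v = np.zeros(n)
    events = []
    plateau_area_cap = nmda.amplitude_mean * (interval_ms * 0.6)
    for b, supra in enumerate(suprathreshold):
        onset = onset0 + b * interval_ms
        events.append(onset)
        if supra:
            amp, area = nmda.draw_spike(rng)
            area = min(area, plateau_area_cap)  # keep bursts non-overlapping
            v += _plateau_waveform(t, onset, amp, area, nmda.ramp_ms)
        else:
            k = EPSPKernel(amplitude=0.6 * nmda.voltage_threshold, onset=onset)
            v += k.waveform(t)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=n)
    return VoltageTrace(
        samples=v,
        sampling_rate=sampling_rate,
        annotations={"stimulus": events},
        meta={"kind": "nmda_train", "truth_spike_count": int(sum(suprathreshold))},
    )


# ---------------------------------------------------------------------------
# protocols and experiment specs


@dataclass(frozen=True)
class ProtocolSpec:
    """Machine-readable induction protocol and test-pulse schedule.

    STDP: one EPSP followed (``epsp_bap_delay`` ms) by a burst of
    ``baps_per_burst`` BAPs at ``bap_rate`` Hz; triplets of this pairing at
    ``triplet_rate`` Hz, the sweep repeated ``n_sweeps`` times at
    ``sweep_rate`` Hz (0.2 Hz = one sweep per 5 s).  NMDA train:
    ``pulses_per_burst`` stimuli at ``pulse_rate`` Hz per spike,
    ``n_bursts`` spikes at ``burst_rate`` Hz (sniff frequency).  Test pulses
    at ``test_pulse_rate`` Hz for ``pre_minutes``/``post_minutes``.
    """

    kind: str = "nmda_train"  # stdp | nmda_train | test_only
    epsp_bap_delay: float = 8.0
    baps_per_burst: int = 3
    bap_rate: float = 150.0
    triplets_per_sweep: int = 3
    triplet_rate: float = 20.0
    n_sweeps: int = 40
    sweep_rate: float = 0.2
    pulses_per_burst: int = 3
    pulse_rate: float = 50.0
    n_bursts: int = 5
    burst_rate: float = 4.0
    n_bursts_range: tuple[int, int] = (2, 23)
    test_pulse_rate: float = 0.033
    pre_minutes: float = 12.0
    post_minutes: float = 12.0

    def __post_init__(self) -> None:
        if self.kind not in ("stdp", "nmda_train", "test_only"):
            raise ValueError("kind must be stdp, nmda_train or test_only")
        for name in ("bap_rate", "triplet_rate", "sweep_rate", "pulse_rate",
                     "burst_rate", "test_pulse_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.n_bursts_range
        if self.kind == "nmda_train" and not (lo <= self.n_bursts <= hi):
            raise ValueError(f"n_bursts {self.n_bursts} outside admissible range {lo}-{hi}")
        if self.pre_minutes <= 0 or self.post_minutes <= 0:
            raise ValueError("recording phases must have positive duration")

    @property
    def sweep_interval_s(self) -> float:
        return 1.0 / self.sweep_rate

    @property
    def n_test_pulses_pre(self) -> int:
        return max(int(round(self.pre_minutes * 60 * self.test_pulse_rate)), 1)

    @property
    def n_test_pulses_post(self) -> int:
        return max(int(round(self.post_minutes * 60 * self.test_pulse_rate)), 1)


STDP_PROTOCOL = ProtocolSpec(kind="stdp")
NMDA_PROTOCOL = ProtocolSpec(kind="nmda_train")


@dataclass(frozen=True)
class ConditionPreset:
    """Published per-condition point estimates used as generator defaults."""

    factor: float
    n_cells: int
    sem_percent: float
    protocol_kind: str
    n_bursts_default: int = 5


# percent-of-control point estimates, cohort sizes and printed SEMs per
# condition; factors are percent/100.
CONDITION_PRESETS: dict[str, ConditionPreset] = {
    "LOT_Ia_stdp": ConditionPreset(1.0306, 11, 2.81, "stdp"),
    "LOT_Ia_nmda": ConditionPreset(2.1398, 26, 10.81, "nmda_train", 5),
    "IC_Ib_stdp": ConditionPreset(1.6893, 6, 6.54, "stdp"),
    "IC_Ib_nmda": ConditionPreset(1.4848, 9, 4.1, "nmda_train", 7),
    "basal_stdp": ConditionPreset(1.3712, 8, 6.11, "stdp"),
    "basal_nmda": ConditionPreset(1.4064, 6, 4.5, "nmda_train", 5),
    "apv": ConditionPreset(0.9506, 5, 4.69, "nmda_train", 5),
    "sub_nmda": ConditionPreset(1.0679, 5, 5.69, "nmda_train", 5),
    "baclofen_nmda": ConditionPreset(2.3657, 5, 17.51, "nmda_train", 5),
    "opto_nmda": ConditionPreset(2.3245, 11, 16.55, "nmda_train", 3),
    "pairing_4Hz": ConditionPreset(0.9731, 4, 3.64, "nmda_train", 5),
}

CONDITION_ORDER = list(CONDITION_PRESETS)


@dataclass(frozen=True)
class ExperimentSpec:
    """Generator parameters for one synthetic LTP cohort."""

    condition: str
    true_potentiation_factor: float
    n_cells: int
    within_cell_cv: float = 0.15
    between_cell_sd: float = 0.1
    rmp_drift_mV: float = 0.0
    baseline_mean_mV: float = 1.88
    baseline_cv: float = 0.35
    n_pre: int = 24
    n_post: int = 24
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITION_PRESETS:
            raise ValueError(
                f"unknown condition {self.condition!r}; known: {CONDITION_ORDER}"
            )
        if self.true_potentiation_factor <= 0:
            raise ValueError("true_potentiation_factor must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("within_cell_cv", "between_cell_sd", "baseline_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_pre < 1 or self.n_post < 1:
            raise ValueError("need at least one test pulse per phase")


def calibrated_between_cell_sd(
    factor: float,
    sem_percent: float,
    n_cells: int,
    within_cell_cv: float = 0.15,
    n_pre: int = 24,
    n_post: int = 24,
) -> float:
    """Between-cell sd of the potentiation factor that reproduces a target
    cohort SEM.

    The per-cell post/pre ratio has variance (between-cell factor variance)
    plus an analytic trial-noise term factor² · cv² · (1/n_pre + 1/n_post);
    the between-cell sd is set so the total matches (sem/100)²·n.
    """
    target_var = (sem_percent / 100.0) ** 2 * n_cells
    trial_var = factor**2 * within_cell_cv**2 * (1.0 / n_pre + 1.0 / n_post)
    return math.sqrt(max(target_var - trial_var, 1e-8))


def spec_for_condition(condition: str, seed: Optional[int] = None, **overrides) -> ExperimentSpec:
    """Build an :class:`ExperimentSpec` from a condition preset."""
    preset = CONDITION_PRESETS.get(condition)
    if preset is None:
        raise ValueError(f"unknown condition {condition!r}; known: {CONDITION_ORDER}")
    kwargs = dict(
        condition=condition,
        true_potentiation_factor=preset.factor,
        n_cells=preset.n_cells,
        seed=seed,
    )
    kwargs.update(overrides)
    cv = kwargs.get("within_cell_cv", 0.15)
    n_pre = kwargs.get("n_pre", 24)
    n_post = kwargs.get("n_post", 24)
    kwargs.setdefault(
        "between_cell_sd",
        calibrated_between_cell_sd(
            kwargs["true_potentiation_factor"], preset.sem_percent,
            kwargs["n_cells"], cv, n_pre, n_post,
        ),
    )
    return ExperimentSpec(**kwargs)


def protocol_for_condition(condition: str) -> ProtocolSpec:
    preset = CONDITION_PRESETS[condition]
    if preset.protocol_kind == "stdp":
        return STDP_PROTOCOL
    return replace(NMDA_PROTOCOL, n_bursts=preset.n_bursts_default)


def simulate_ltp_experiment(
    spec: ExperimentSpec,
    protocol: Optional[ProtocolSpec] = None,
    rng=None,
) -> list[ExperimentRecord]:
    """Simulate one cohort of LTP experiments.

    Per cell: a lognormal baseline EPSP amplitude; ``n_pre`` pre-induction
    test-pulse amplitudes (lognormal trial noise, CV ``within_cell_cv``); a
    cell-specific potentiation factor drawn around the condition's true
    factor (normal, truncated > 0); ``n_post`` post-induction amplitudes
    around baseline × factor (the step persists to the end of the series);
    a resting-potential series with optional linear drift.  All ground truth
    is stored on the record.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    rng = _as_rng(rng)
    if protocol is not None and protocol.kind != "test_only":
        n_pre, n_post = protocol.n_test_pulses_pre, protocol.n_test_pulses_post
    else:
        n_pre, n_post = spec.n_pre, spec.n_post
    records = []
    for i in range(spec.n_cells):
        baseline = float(_lognormal_mean_cv(rng, spec.baseline_mean_mV, spec.baseline_cv))
        factor = rng.normal(spec.true_potentiation_factor, spec.between_cell_sd)
        while factor <= 0:
            factor = rng.normal(spec.true_potentiation_factor, spec.between_cell_sd)
        pre = _lognormal_mean_cv(rng, baseline, spec.within_cell_cv, size=n_pre)
        post = _lognormal_mean_cv(rng, baseline * factor, spec.within_cell_cv, size=n_post)
        n_rmp = n_pre + n_post
        rmp = -70.0 + spec.rmp_drift_mV * np.linspace(0.0, 1.0, n_rmp)
        records.append(
            ExperimentRecord(
                cell_id=f"{spec.condition}_{i:03d}",
                condition=spec.condition,
                pre_amplitudes=pre,
                post_amplitudes=post,
                rmp_series=rmp,
                truth={
                    "baseline_mV": baseline,
                    "cell_factor": float(factor),
                    "condition_factor": spec.true_potentiation_factor,
                },
            )
        )
    return records


# ---------------------------------------------------------------------------
# line scans


def make_linescan(
    dff_peak_spine: float,
    dff_peak_shaft: float,
    f0: float = 100.0,
    noise_cv: float = 0.0,
    rng=0,
    rate: float = 500.0,
    baseline_ms: float = 100.0,
    duration_ms: float = 600.0,
    decay_tau_ms: float = 150.0,
) -> LineScan:
    """Synthesise a two-channel line scan with a calcium transient.

    Fluorescence sits at ``f0`` during the baseline, jumps to
    ``f0 * (1 + dff_peak)`` at transient onset and decays exponentially.
    Multiplicative noise with the given CV is applied per sample.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    if dff_peak_spine < 0 or dff_peak_shaft < 0:
        raise ValueError("only positive transients are simulated; dff peaks must be >= 0")
    rng = _as_rng(rng)
    n = int(round(duration_ms / 1000.0 * rate))
    i_on = int(round(baseline_ms / 1000.0 * rate))
    if not (0 < i_on < n):
        raise ValueError("baseline must be non-empty and shorter than the scan")
    t_ms = np.arange(n) / rate * 1000.0

    def channel(dff_peak: float) -> np.ndarray:
        f = np.full(n, f0)
        post = t_ms >= baseline_ms
        f[post] = f0 * (1.0 + dff_peak * np.exp(-(t_ms[post] - baseline_ms) / decay_tau_ms))
        if noise_cv > 0:
            f = f * np.maximum(rng.normal(1.0, noise_cv, size=n), 1e-6)
        return f

    return LineScan(
        spine_f=channel(dff_peak_spine),
        shaft_f=channel(dff_peak_shaft),
        rate=rate,
        baseline_window=(0, i_on),
        ground_truth={
            "dff_peak_spine": dff_peak_spine,
            "dff_peak_shaft": dff_peak_shaft,
            "f0": f0,
            "onset_index": i_on,
        },
    )
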