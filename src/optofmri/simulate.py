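"""Synthetic data generation with ground truth.

Everything the analysis stages consume can be simulated here: 4D BOLD runs
with block-locked positive and negative responders, trial-structured field
potentials carrying amplitude-modulated spindle-like oscillations (SLOs),
frequency-modulated Poisson spike trains with optional pulse-locked spiking,
and stereotyped EEG states.  Each generator takes an explicit seed and is
bit-reproducible; ground-truth labels/events are returned alongside the data
so detector performance can be scored exactly.

The BOLD model is deliberately minimal: an active voxel is a baseline level
modulated multiplicatively by the stimulation boxcar convolved with a smooth
causal hemodynamic kernel (gamma variate), plus additive linear drift and
white Gaussian noise.  No MR physics or neurovascular coupling beyond this
linear convolution is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocol import StimulusProtocol

__all__ = [
    "HrfParams",
    "RoiSpec",
    "GroundTruthScene",
    "BoldDataset",
    "SloSpec",
    "SloEvent",
    "LfpRecording",
    "SpikeTrain",
    "PulseLockedSpec",
    "ConditionProfile",
    "gamma_variate_hrf",
    "gen_bold_dataset",
    "gen_lfp",
    "gen_spike_trains",
    "gen_eeg",
]


# ---------------------------------------------------------------------------
# hemodynamics

@dataclass(frozen=True)
class HrfParams:
    """Gamma-variate hemodynamic kernel: peak time and full width at half max."""

    peak_s: float = 3.0
    fwhm_s: float = 3.0

    def __post_init__(self):
        if self.peak_s <= 0 or self.fwhm_s <= 0:
            raise ValueError("peak_s and fwhm_s must be positive")


def gamma_variate_hrf(t: np.ndarray, params: HrfParams = HrfParams()) -> np.ndarray:
    """Gamma-variate kernel h(t) = (t/tp)^a exp(a(1 - t/tp)), peak-normalized to 1.

    The shape exponent ``a`` is set from the requested FWHM through the
    Gaussian approximation FWHM ≈ 2.355·tp/sqrt(a).  Causal: h(t<=0) = 0.
    """
    t = np.asarray(t, dtype=float)
    tp = params.peak_s
    a = (2.355 * tp / params.fwhm_s) ** 2
    h = np.zeros_like(t)
    pos = t > 0
    h[pos] = (t[pos] / tp) ** a * np.exp(a * (1.0 - t[pos] / tp))
    return h


# ---------------------------------------------------------------------------
# BOLD scenes

@dataclass(frozen=True)
class RoiSpec:
    """An axis-aligned box of voxels sharing one response.

    ``amplitude_percent`` is the peak percent modulation; negative values
    produce suppressed (negative-going) responses.
    """

    name: str
    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # half-open per axis
    amplitude_percent: float
    onset_delay_s: float = 0.0
    hrf: HrfParams = field(default_factory=HrfParams)

    def __post_init__(self):
        if abs(self.amplitude_percent) > 100:
            raise ValueError(
                f"|amplitude| of {self.amplitude_percent}% exceeds 100% of baseline"
            )
        for lo, hi in self.box:
            if hi <= lo:
                raise ValueError(f"empty box extent ({lo}, {hi}) in ROI {self.name!r}")

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        (x0, x1), (y0, y1), (z0, z1) = self.box
        m[x0:x1, y0:y1, z0:z1] = True
        return m


@dataclass(frozen=True)
class GroundTruthScene:
    """Layout and noise model of a simulated BOLD run."""

    shape: tuple[int, int, int] = (32, 32, 8)
    rois: tuple[RoiSpec, ...] = ()
    noise_sd_percent: float = 0.5
    drift_slope_percent_per_min: float = 0.3
    baseline_level: float = 1000.0

    def __post_init__(self):
        # active voxels must belong to exactly one ROI
        total = np.zeros(self.shape, dtype=int)
        for roi in self.rois:
            total += roi.mask(self.shape)
        if (total > 1).any():
            raise ValueError("ROIs overlap: every active voxel must belong to exactly one ROI")
        if self.noise_sd_percent < 0:
            raise ValueError("noise_sd_percent must be >= 0")

    def truth_labels(self) -> np.ndarray:
        """Per-voxel truth: +1 positive responder, -1 negative, 0 inactive."""
        labels = np.zeros(self.shape, dtype=np.int8)
        for roi in self.rois:
            labels[roi.mask(self.shape)] = 1 if roi.amplitude_percent > 0 else -1
        return labels


@dataclass
class BoldDataset:
    """A 4D BOLD run (x, y, z, t) in arbitrary scanner units."""

    data: np.ndarray
    tr_s: float
    voxel_size_mm: tuple[float, float, float]
    protocol: StimulusProtocol
    n_baseline_frames: int = 0

    def __post_init__(self):
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        expected = int(round(self.protocol.n_cycles * self.protocol.cycle_period_s / self.tr_s))
        if self.data.shape[-1] != expected + self.n_baseline_frames:
            raise ValueError(
                f"time dimension {self.data.shape[-1]} != "
                f"{expected} cycle frames + {self.n_baseline_frames} baseline frames"
            )

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def frames_per_cycle(self) -> int:
        return int(round(self.protocol.cycle_period_s / self.tr_s))

    def stimulus_frames(self) -> np.ndarray:
        """The cycle-locked portion of the series (baseline frames stripped)."""
        return self.data[..., self.n_baseline_frames:]


def gen_bold_dataset(
    scene: GroundTruthScene,
    protocol: StimulusProtocol,
    tr_s: float = 0.75,
    voxel_size_mm: tuple[float, float, float] = (0.5, 0.5, 0.5),
    baseline_as_extra_frames: bool = True,
    seed: int | None = 0,
) -> tuple[BoldDataset, np.ndarray]:
    """Simulate a block-design BOLD run; returns (dataset, truth label volume).

    Active voxels follow baseline × (1 + amp/100 · (boxcar ⊛ HRF)); all
    voxels receive additive linear drift and white Gaussian noise, expressed
    as percent of the baseline level.  With ``baseline_as_extra_frames`` the
    protocol's rest baseline is prepended as extra frames; otherwise the run
    starts directly at cycle 1 and the first frames of cycle 1 serve as the
    percent-modulation reference downstream.
    """
    rng = np.random.default_rng(seed)
    n_cycle_frames = int(round(protocol.n_cycles * protocol.cycle_period_s / tr_s))
    n_base = int(round(protocol.baseline_s / tr_s)) if baseline_as_extra_frames else 0
    n_t = n_base + n_cycle_frames
    t = np.arange(n_t) * tr_s

    box = np.zeros(n_t)
    onsets = protocol.train_onsets_s(include_baseline=False) + n_base * tr_s
    for t0 in onsets:
        box[(t >= t0) & (t < t0 + protocol.train_duration_s)] = 1.0

    data = np.full(scene.shape + (n_t,), scene.baseline_level, dtype=float)

    for roi in scene.rois:
        kernel_t = np.arange(0, roi.hrf.peak_s + 6 * roi.hrf.fwhm_s, tr_s)
        kernel = gamma_variate_hrf(kernel_t, roi.hrf)
        delay_frames = int(round(roi.onset_delay_s / tr_s))
        shifted = np.roll(box, delay_frames)
        if delay_frames > 0:
            shifted[:delay_frames] = 0.0
        resp = np.convolve(shifted, kernel)[:n_t]
        resp /= max(resp.max(), 1e-12)  # unit peak => amplitude is the peak % modulation
        series = scene.baseline_level * (1.0 + roi.amplitude_percent / 100.0 * resp)
        data[roi.mask(scene.shape)] = series

    drift = scene.baseline_level * scene.drift_slope_percent_per_min / 100.0 * (t / 60.0)
    data += drift
    if scene.noise_sd_percent > 0:
        data += rng.normal(
            0.0,
            scene.baseline_level * scene.noise_sd_percent / 100.0,
            size=data.shape,
        )

    ds = BoldDataset(
        data=data,
        tr_s=tr_s,
        voxel_size_mm=voxel_size_mm,
        protocol=protocol,
        n_baseline_frames=n_base,
    )
    return ds, scene.truth_labels()


# ---------------------------------------------------------------------------
# field potentials with spindle-like oscillations

@dataclass(frozen=True)
class SloSpec:
    """Parameters of injected spindle-like oscillations.

    ``n_per_train`` events are placed in each trial's stimulation window with
    successive onsets separated by ``spacing_s`` ± ``spacing_jitter_s``
    (truncated below at ``min_gap_s``).  ``amplitude_sd`` scales the carrier
    peak in units of the background-noise standard deviation.
    """

    n_per_train: int = 3
    carrier_hz: float = 10.0
    envelope_s: float = 0.75
    amplitude_sd: float = 10.0
    spacing_s: float = 6.6
    spacing_jitter_s: float = 0.5
    min_gap_s: float = 1.5
    first_onset_s: float = 0.5  # after stim onset

    def __post_init__(self):
        if self.n_per_train < 0:
            raise ValueError("n_per_train must be >= 0")
        if self.min_gap_s <= self.envelope_s:
            raise ValueError("min_gap_s must exceed the envelope duration")


@dataclass(frozen=True)
class SloEvent:
    """One spindle-like oscillation: channel, trial and onset within the trial."""

    channel: int
    trial: int
    onset_s: float


@dataclass
class LfpRecording:
    """Trial-structured field potentials: (channels, trials, samples) in µV."""

    fs_hz: float
    traces: np.ndarray
    stim_window_s: tuple[float, float]

    def __post_init__(self):
        if self.traces.ndim != 3:
            raise ValueError("traces must be (channels, trials, samples)")
        start, stop = self.stim_window_s
        if not 0 <= start < stop <= self.traces.shape[-1] / self.fs_hz:
            raise ValueError("stim window must lie inside the trial")

    @property
    def n_channels(self) -> int:
        return self.traces.shape[0]

    @property
    def n_trials(self) -> int:
        return self.traces.shape[1]

    @property
    def trial_duration_s(self) -> float:
        return self.traces.shape[-1] / self.fs_hz


def gen_lfp(
    n_channels: int = 12,
    n_trials: int = 20,
    slo_spec: SloSpec = SloSpec(),
    noise_sd_uv: float = 50.0,
    fs_hz: float = 1000.0,
    trial_layout_s: tuple[float, float, float] = (20.0, 20.0, 20.0),
    seed: int | None = 0,
) -> tuple[LfpRecording, list[SloEvent]]:
    """Simulate trial-structured LFP with injected SLOs; returns (recording, truth).

    Each trial is ``pre + stim + post`` seconds of white Gaussian background
    at ``noise_sd_uv``; each injected SLO is a ``carrier_hz`` sinusoid under a
    Hann envelope of ``envelope_s`` seconds, peak amplitude
    ``amplitude_sd × noise_sd_uv``, with all onsets inside the stimulation
    window.
    """
    pre_s, stim_s, post_s = trial_layout_s
    if slo_spec.envelope_s > stim_s:
        raise ValueError(
            f"envelope ({slo_spec.envelope_s} s) longer than stimulation window ({stim_s} s)"
        )
    rng = np.random.default_rng(seed)
    n_samples = int(round((pre_s + stim_s + post_s) * fs_hz))
    traces = rng.normal(0.0, noise_sd_uv, size=(n_channels, n_trials, n_samples))

    n_env = int(round(slo_spec.envelope_s * fs_hz))
    env = np.hanning(n_env)
    tt = np.arange(n_env) / fs_hz
    amp = slo_spec.amplitude_sd * noise_sd_uv

    events: list[SloEvent] = []
    for ch in range(n_channels):
        for tr in range(n_trials):
            onset = pre_s + slo_spec.first_onset_s
            for _ in range(slo_spec.n_per_train):
                if onset + slo_spec.envelope_s > pre_s + stim_s:
                    raise ValueError(
                        f"{slo_spec.n_per_train} events at spacing {slo_spec.spacing_s} s "
                        f"do not fit inside the {stim_s} s stimulation window"
                    )
                i0 = int(round(onset * fs_hz))
                phase = rng.uniform(0, 2 * np.pi)
                burst = amp * env * np.sin(2 * np.pi * slo_spec.carrier_hz * tt + phase)
                traces[ch, tr, i0:i0 + n_env] += burst
                events.append(SloEvent(channel=ch, trial=tr, onset_s=onset))
                gap = slo_spec.spacing_s
                if slo_spec.spacing_jitter_s > 0:
                    gap += rng.normal(0.0, slo_spec.spacing_jitter_s)
                onset += max(gap, slo_spec.min_gap_s)

    rec = LfpRecording(fs_hz=fs_hz, traces=traces, stim_window_s=(pre_s, pre_s + stim_s))
    return rec, events


# ---------------------------------------------------------------------------
# spike trains

@dataclass(frozen=True)
class PulseLockedSpec:
    """Deterministic pulse-following component of a unit's response."""

    fidelity: float = 1.0      # probability a pulse evokes a spike
    latency_ms: float = 8.0
    jitter_ms: float = 0.0

    def __post_init__(self):
        if not 0 <= self.fidelity <= 1:
            raise ValueError("fidelity must be in [0, 1]")


@dataclass(frozen=True)
class ConditionProfile:
    """Firing-rate profile of one unit under one stimulation condition.

    ``stim_gains`` multiply the baseline rate within consecutive equal bins
    of the stimulation window (the convention is four 5 s bins of a 20 s
    train).  An optional pulse-locked component adds a spike after each light
    pulse with the given fidelity and latency jitter.
    """

    condition: str
    baseline_rate_hz: float
    stim_gains: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    pulse_locked: PulseLockedSpec | None = None
    trial_layout_s: tuple[float, float, float] = (20.0, 20.0, 20.0)

    def __post_init__(self):
        if self.baseline_rate_hz < 0:
            raise ValueError("baseline_rate_hz must be >= 0")
        if any(g < 0 for g in self.stim_gains):
            raise ValueError("negative instantaneous rate requested (gain < 0)")


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one unit on one trial, relative to trial start."""

    unit_id: int
    trial_id: int
    condition: str
    spike_times_s: np.ndarray
    trial_layout_s: tuple[float, float, float] = (20.0, 20.0, 20.0)

    def __post_init__(self):
        t = np.asarray(self.spike_times_s, dtype=float)
        if t.size and not (np.diff(t) > 0).all():
            raise ValueError("spike times must be strictly increasing")
        if t.size and (t[0] < 0 or t[-1] > sum(self.trial_layout_s)):
            raise ValueError("spike times must lie within the trial")


def _poisson_times(rng, rate_hz: float, t0: float, t1: float) -> np.ndarray:
    if rate_hz <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate_hz * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def gen_spike_trains(
    profile: ConditionProfile,
    n_trials: int = 17,
    unit_id: int = 0,
    protocol: StimulusProtocol | None = None,
    seed: int | None = 0,
) -> list[SpikeTrain]:
    """Simulate trial-aligned spike trains as an inhomogeneous Poisson process.

    Pre- and post-stimulation segments fire at the baseline rate; the
    stimulation window is split into ``len(stim_gains)`` equal bins with the
    baseline rate scaled per bin.  If the profile has a pulse-locked
    component, a ``protocol`` is required to derive pulse onset times, and a
    spike is appended after each pulse with the given fidelity and jittered
    latency.
    """
    pre_s, stim_s, post_s = profile.trial_layout_s
    rng = np.random.default_rng(seed)
    n_bins = len(profile.stim_gains)
    bin_s = stim_s / n_bins

    if profile.pulse_locked is not None and protocol is None:
        raise ValueError("a protocol is required for pulse-locked spiking")

    trains = []
    for trial in range(n_trials):
        parts = [_poisson_times(rng, profile.baseline_rate_hz, 0.0, pre_s)]
        for b, gain in enumerate(profile.stim_gains):
            t0 = pre_s + b * bin_s
            parts.append(_poisson_times(rng, profile.baseline_rate_hz * gain, t0, t0 + bin_s))
        parts.append(
            _poisson_times(rng, profile.baseline_rate_hz, pre_s + stim_s, pre_s + stim_s + post_s)
        )
        if profile.pulse_locked is not None:
            pl = profile.pulse_locked
            pulses = pre_s + protocol.pulse_onsets_s(cycle=0, include_baseline=False)
            evoked = pulses[rng.random(pulses.size) < pl.fidelity] + pl.latency_ms / 1000.0
            if pl.jitter_ms > 0:
                evoked = evoked + rng.normal(0.0, pl.jitter_ms / 1000.0, size=evoked.size)
            parts.append(np.clip(evoked, 0.0, pre_s + stim_s + post_s))
        times = np.sort(np.concatenate(parts))
        # enforce strict monotonicity (coincident samples are one spike)
        if times.size:
            times = times[np.concatenate([[True], np.diff(times) > 0])]
        trains.append(
            SpikeTrain(
                unit_id=unit_id,
                trial_id=trial,
                condition=profile.condition,
                spike_times_s=times,
                trial_layout_s=profile.trial_layout_s,
            )
        )
    return trains


# ---------------------------------------------------------------------------
# EEG states

def gen_eeg(
    state: str,
    duration_s: float = 20.0,
    fs_hz: float = 1000.0,
    seed: int | None = 0,
) -> np.ndarray:
    """Simulate a stereotyped EEG trace in µV.

    ``state='spike_wave'``: high-amplitude rhythmic discharge — a strong
    10 Hz fundamental with weaker harmonics (the sharpened, nonsinusoidal
    waveform of a spike-and-wave complex) over low background noise.
    ``state='low_voltage_fast'``: desynchronized low-amplitude broadband
    noise.
    """
    if fs_hz < 200:
        raise ValueError("fs_hz must be >= 200 Hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    if state == "spike_wave":
        trace = (
            300.0 * np.sin(2 * np.pi * 10.0 * t)
            + 90.0 * np.sin(2 * np.pi * 20.0 * t + 0.7)
            + 45.0 * np.sin(2 * np.pi * 30.0 * t + 1.1)
            + rng.normal(0.0, 15.0, size=n)
        )
    elif state == "low_voltage_fast":
        trace = rng.normal(0.0, 20.0, size=n)
    else:
        raise ValueError(f"unknown EEG state {state!r}; use 'spike_wave' or 'low_voltage_fast'")
    return trace
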