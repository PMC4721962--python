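"""Field-potential, spike-train and EEG analysis.

Covers preprocessing of raw extracellular recordings (4-pole Bessel
anti-alias low-pass and decimation to 1 kHz; 2 Hz high-pass against
respiratory artifacts), detection of spindle-like oscillations (SLOs) by an
amplitude-threshold rule, inter-event statistics, peristimulus time
histograms aligned to light pulses or trains, per-bin firing-rate change
tests, and EEG band-power fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as spsig

from .protocol import StimulusProtocol
from .simulate import LfpRecording, SloEvent, SpikeTrain
from .stats import TestResult, rank_sum_test, signed_rank_test

__all__ = [
    "preprocess_lfp",
    "detect_slos",
    "detect_slos_recording",
    "IntervalStats",
    "slo_interval_stats",
    "compare_slo_counts",
    "Psth",
    "psth",
    "BinRateTest",
    "firing_rate_change_test",
    "BandPower",
    "eeg_band_power",
    "DEFAULT_BANDS",
]


# ---------------------------------------------------------------------------
# preprocessing

def preprocess_lfp(
    raw: np.ndarray,
    fs_in_hz: float,
    mode: str = "acquire",
    lowpass_hz: float = 200.0,
    target_fs_hz: float = 1000.0,
    highpass_hz: float = 2.0,
    order: int = 4,
    axis: int = -1,
) -> tuple[np.ndarray, float]:
    """Condition a field-potential trace; returns (filtered, fs_out).

    ``mode='acquire'`` mimics the acquisition chain: a causal 4-pole Bessel
    low-pass at ``lowpass_hz`` followed by decimation to ``target_fs_hz``.
    ``mode='slo'`` applies a zero-phase 4-pole Butterworth high-pass at
    ``highpass_hz`` (respiration removal) at the input rate.
    """
    raw = np.asarray(raw, dtype=float)
    nyq = fs_in_hz / 2.0
    if mode == "acquire":
        if lowpass_hz >= nyq:
            raise ValueError(f"low-pass cutoff {lowpass_hz} Hz >= Nyquist {nyq} Hz")
        sos = spsig.bessel(order, lowpass_hz, btype="low", fs=fs_in_hz, output="sos", norm="mag")
        filt = spsig.sosfilt(sos, raw, axis=axis)
        factor = fs_in_hz / target_fs_hz
        if abs(factor - round(factor)) > 1e-9 or factor < 1:
            raise ValueError(
                f"fs {fs_in_hz} Hz is not an integer multiple of target {target_fs_hz} Hz"
            )
        step = int(round(factor))
        sl = [slice(None)] * filt.ndim
        sl[axis] = slice(None, None, step)
        return filt[tuple(sl)], target_fs_hz
    elif mode == "slo":
        if highpass_hz >= nyq:
            raise ValueError(f"high-pass cutoff {highpass_hz} Hz >= Nyquist {nyq} Hz")
        sos = spsig.butter(order, highpass_hz, btype="high", fs=fs_in_hz, output="sos")
        return spsig.sosfiltfilt(sos, raw, axis=axis), fs_in_hz
    raise ValueError(f"unknown mode {mode!r}; use 'acquire' or 'slo'")


# ---------------------------------------------------------------------------
# spindle-like oscillation detection

def detect_slos(
    trace: np.ndarray,
    fs_hz: float,
    k: float = 6.0,
    quiet_window_s: float = 0.5,
    active_window_s: float = 0.5,
    active_fraction: float = 0.02,
    analysis_window_s: tuple[float, float] | None = None,
    threshold_window_s: tuple[float, float] | None = None,
    sd_of: str = "abs",
) -> np.ndarray:
    """Detect SLO onsets (seconds) in a single high-pass-filtered trace.

    The detection threshold is T = mean(|x|) + k·SD, estimated over the full
    trace by default (or over ``threshold_window_s``); ``sd_of`` selects
    whether SD is that of the rectified signal ``'abs'`` (default — same
    units as the mean-absolute baseline) or of the raw signal ``'raw'``.
    An onset is counted at sample i when |x(i)| ≥ T, no sample in the
    preceding ``quiet_window_s`` reached T, and at least ``active_fraction``
    of the samples in the following ``active_window_s`` reach T.  Candidate
    onsets are restricted to ``analysis_window_s`` (default: whole trace);
    the quiet/occupancy windows may extend outside it.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1:
        raise ValueError("detect_slos expects a single 1-D trace")
    n = x.size
    q = int(round(quiet_window_s * fs_hz))
    w = int(round(active_window_s * fs_hz))
    if q > n or w > n:
        raise ValueError("quiet/active window longer than the trace")

    absx = np.abs(x)
    if threshold_window_s is None:
        seg = absx
        seg_raw = x
    else:
        i0, i1 = (int(round(s * fs_hz)) for s in threshold_window_s)
        if not 0 <= i0 < i1 <= n:
            raise ValueError("threshold window outside the trace")
        seg = absx[i0:i1]
        seg_raw = x[i0:i1]
    sd = seg.std() if sd_of == "abs" else seg_raw.std()
    if sd_of not in ("abs", "raw"):
        raise ValueError("sd_of must be 'abs' or 'raw'")
    threshold = seg.mean() + k * sd
    if threshold <= 0:
        return np.empty(0)  # degenerate constant/zero trace

    exceed = absx >= threshold
    if not exceed.any():
        return np.empty(0)
    csum = np.concatenate([[0], np.cumsum(exceed)])

    candidates = np.flatnonzero(exceed)
    if analysis_window_s is not None:
        a0, a1 = (int(round(s * fs_hz)) for s in analysis_window_s)
        candidates = candidates[(candidates >= a0) & (candidates < a1)]

    onsets = []
    for i in candidates:
        lo = max(i - q, 0)
        if csum[i] - csum[lo] > 0:  # exceedance in the preceding quiet window
            continue
        hi = min(i + w, n)
        occupancy = (csum[hi] - csum[i]) / (hi - i)
        if occupancy >= active_fraction:
            onsets.append(i)
    return np.asarray(onsets, dtype=float) / fs_hz


def detect_slos_recording(
    lfp: LfpRecording,
    restrict_to_stim: bool = True,
    **kwargs,
) -> list[SloEvent]:
    """Run :func:`detect_slos` on every channel/trial of a recording.

    The threshold is estimated per channel and trial; by default candidate
    onsets are restricted to the stimulation window.
    """
    window = lfp.stim_window_s if restrict_to_stim else None
    events: list[SloEvent] = []
    for ch in range(lfp.n_channels):
        for tr in range(lfp.n_trials):
            onsets = detect_slos(
                lfp.traces[ch, tr], lfp.fs_hz, analysis_window_s=window, **kwargs
            )
            events.extend(SloEvent(channel=ch, trial=tr, onset_s=float(t)) for t in onsets)
    return events


@dataclass(frozen=True)
class IntervalStats:
    """Pooled inter-event interval statistics across trials."""

    mean_s: float
    sem_s: float
    n_intervals: int
    intervals_s: np.ndarray


def slo_interval_stats(events: Sequence[SloEvent]) -> IntervalStats:
    """Mean ± s.e.m. of consecutive inter-event intervals, pooled over trials.

    Only channel/trial combinations with at least two events contribute; if
    none do, a flagged empty result (NaN mean) is returned with a warning.
    """
    groups: dict[tuple[int, int], list[float]] = {}
    for ev in events:
        groups.setdefault((ev.channel, ev.trial), []).append(ev.onset_s)
    intervals = []
    for onsets in groups.values():
        if len(onsets) >= 2:
            intervals.extend(np.diff(np.sort(onsets)))
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size == 0:
        warnings.warn("no channel/trial with >= 2 events; interval statistics undefined")
        return IntervalStats(np.nan, np.nan, 0, intervals)
    sem = intervals.std(ddof=1) / np.sqrt(intervals.size) if intervals.size > 1 else np.nan
    return IntervalStats(float(intervals.mean()), float(sem), int(intervals.size), intervals)


def compare_slo_counts(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    alternative: str = "greater",
) -> list[TestResult]:
    """Per-channel one-sided rank-sum test of SLO counts between conditions.

    ``counts_a`` and ``counts_b`` are (channels, trials) arrays of per-trial
    event counts; ``alternative='greater'`` asks whether condition A evokes
    more events than condition B on each channel.
    """
    a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    if a.shape[0] != b.shape[0]:
        raise ValueError("conditions must cover the same channels")
    return [rank_sum_test(a[ch], b[ch], alternative=alternative) for ch in range(a.shape[0])]


# ---------------------------------------------------------------------------
# peristimulus time histograms and rate tests

@dataclass(frozen=True)
class Psth:
    """Peristimulus time histogram.

    ``values`` are spike counts per bin summed over alignment events and
    averaged across trials; when normalized, counts are divided by the count
    expected from the pre-stimulation baseline rate (so 1 means "at
    baseline").
    """

    bin_edges_s: np.ndarray
    values: np.ndarray
    alignment: str
    normalized: bool

    @property
    def bin_s(self) -> float:
        return float(self.bin_edges_s[1] - self.bin_edges_s[0])

    @property
    def peak_latency_bin_s(self) -> tuple[float, float]:
        """Edges of the bin holding the histogram maximum."""
        i = int(np.argmax(self.values))
        return float(self.bin_edges_s[i]), float(self.bin_edges_s[i + 1])


def psth(
    spike_trains: Sequence[SpikeTrain],
    protocol: StimulusProtocol,
    alignment: str = "pulse",
    bin_s: float = 0.005,
    window_s: float | None = None,
    baseline_normalize: bool = False,
) -> Psth:
    """Histogram of spike times aligned to light pulses or to train onset.

    With ``alignment='pulse'`` spikes are binned relative to every pulse
    onset in the stimulation window and summed over pulses (window default:
    one pulse period); with ``'train'`` they are binned over the whole train
    (window default: the train duration).  Counts are averaged across trials.
    Normalization divides each bin by the expected count from the
    pre-stimulation firing rate: rate × bin width × number of alignment
    events.
    """
    if not spike_trains:
        raise ValueError("no spike trains given")
    pre_s, stim_s, _ = spike_trains[0].trial_layout_s
    if alignment == "pulse":
        onsets = pre_s + protocol.pulse_onsets_s(cycle=0, include_baseline=False)
        if window_s is None:
            window_s = protocol.pulse_period_s
    elif alignment == "train":
        onsets = np.array([pre_s])
        if window_s is None:
            window_s = stim_s
    else:
        raise ValueError(f"unknown alignment {alignment!r}")

    n_bins_f = window_s / bin_s
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9 or n_bins < 1:
        raise ValueError(f"bin width {bin_s} s does not divide the {window_s} s window")
    edges = np.arange(n_bins + 1) * bin_s

    counts = np.zeros(n_bins)
    pre_spikes = 0
    for train in spike_trains:
        t = np.asarray(train.spike_times_s)
        pre_spikes += int(np.count_nonzero(t < pre_s))
        for t0 in onsets:
            rel = t - t0
            sel = rel[(rel >= 0) & (rel < window_s)]
            if sel.size:
                counts += np.histogram(sel, bins=edges)[0]
    values = counts / len(spike_trains)

    if baseline_normalize:
        pre_rate = pre_spikes / (len(spike_trains) * pre_s)
        expected = pre_rate * bin_s * len(onsets)
        if expected <= 0:
            raise ValueError("cannot normalize: no baseline spikes")
        values = values / expected
    return Psth(bin_edges_s=edges, values=values, alignment=alignment,
                normalized=baseline_normalize)


@dataclass(frozen=True)
class BinRateTest:
    """Signed-rank comparison of one stimulation bin against the baseline rate."""

    bin_index: int
    bin_start_s: float
    bin_stop_s: float
    rate_pre_hz: float
    rate_bin_hz: float
    direction: str  # 'increase' | 'decrease' | 'none'
    pvalue: float
    significant: bool


def firing_rate_change_test(
    spike_trains: Sequence[SpikeTrain],
    bin_s: float = 5.0,
    alternative: str = "two-sided",
    alpha: float = 0.05,
) -> list[BinRateTest]:
    """Per-bin firing-rate change during stimulation versus baseline.

    Splits each trial's stimulation window into consecutive ``bin_s`` bins
    (the convention is four 5 s bins of a 20 s train) and compares the
    per-trial firing rate in each bin against the per-trial pre-stimulation
    rate with a Wilcoxon signed-rank test, uncorrected across bins.
    ``alternative`` may be ``'two-sided'`` (cortical preset), ``'greater'``
    (one-sided increase: thalamic/incertal preset) or ``'less'``.
    """
    if not spike_trains:
        raise ValueError("no spike trains given")
    pre_s, stim_s, _ = spike_trains[0].trial_layout_s
    n_bins_f = stim_s / bin_s
    n_bins = int(round(n_bins_f))
    if abs(n_bins_f - n_bins) > 1e-9 or n_bins < 1:
        raise ValueError(f"bin width {bin_s} s does not divide the {stim_s} s stimulation window")
    if len(spike_trains) < 6:
        warnings.warn(
            f"only {len(spike_trains)} trials: the exact signed-rank test has little "
            "power below 6 pairs"
        )

    pre_rates = np.array([
        np.count_nonzero(np.asarray(tr.spike_times_s) < pre_s) / pre_s for tr in spike_trains
    ])
    results = []
    for b in range(n_bins):
        t0, t1 = pre_s + b * bin_s, pre_s + (b + 1) * bin_s
        bin_rates = np.array([
            np.count_nonzero(
                (np.asarray(tr.spike_times_s) >= t0) & (np.asarray(tr.spike_times_s) < t1)
            ) / bin_s
            for tr in spike_trains
        ])
        diffs = bin_rates - pre_rates
        if np.all(diffs == 0):
            res = TestResult(0.0, 1.0, 0, "degenerate", alternative)
        else:
            res = signed_rank_test(bin_rates, pre_rates, alternative=alternative)
        sig = res.pvalue < alpha
        med = np.median(diffs)
        direction = "none" if not sig or med == 0 else ("increase" if med > 0 else "decrease")
        results.append(
            BinRateTest(
                bin_index=b,
                bin_start_s=t0 - pre_s,
                bin_stop_s=t1 - pre_s,
                rate_pre_hz=float(pre_rates.mean()),
                rate_bin_hz=float(bin_rates.mean()),
                direction=direction,
                pvalue=res.pvalue,
                significant=bool(sig),
            )
        )
    return results


# ---------------------------------------------------------------------------
# EEG band power

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}


@dataclass(frozen=True)
class BandPower:
    """Band-power fractions of total power on [0, fs/2]."""

    fractions: dict
    total_power: float

    def __getitem__(self, band: str) -> float:
        return self.fractions[band]


def eeg_band_power(
    trace: np.ndarray,
    fs_hz: float,
    bands: dict[str, tuple[float, float]] | None = None,
) -> BandPower:
    """Periodogram band power, each band normalized by total power on [0, fs/2].

    Bands are half-open ``[lo, hi)`` except that a band reaching the Nyquist
    frequency includes it, so a partition of [0, fs/2] has fractions summing
    to 1.
    """
    if bands is None:
        bands = DEFAULT_BANDS
    trace = np.asarray(trace, dtype=float)
    nyq = fs_hz / 2.0
    for name, (lo, hi) in bands.items():
        if not 0 <= lo < hi <= nyq:
            raise ValueError(f"band {name!r} = ({lo}, {hi}) must lie within [0, {nyq}] Hz")
    freqs, psd = spsig.periodogram(trace, fs=fs_hz, window="boxcar", detrend=False)
    total = psd.sum()
    if total <= 0:
        raise ValueError("trace has no power")
    fractions = {}
    for name, (lo, hi) in bands.items():
        mask = (freqs >= lo) & ((freqs < hi) | ((hi == nyq) & (freqs == nyq)))
        fractions[name] = float(psd[mask].sum() / total)
    return BandPower(fractions=fractions, total_power=float(total))
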