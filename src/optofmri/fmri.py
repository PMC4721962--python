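"""Per-voxel coherence/phase analysis of block-design BOLD runs.

The detection statistic is the coherence of a voxel time series with the
block repetition frequency f0 (1/60 Hz for 60 s cycles): the DFT amplitude
at f0 divided by the root-sum-of-squares of all positive-frequency
amplitudes (DC excluded).  The phase of the f0 component classifies
significant voxels as positive or negative responders; positive responses —
those rising with train onset after the hemodynamic lag — fall in
[0, π/2] ∪ [3π/2, 2π).  Activation volume in a region of interest is the
count of significant voxels of a given polarity times the voxel volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .protocol import StimulusProtocol
from .stats import TestResult, correct_pvalues, signed_rank_test

__all__ = [
    "percent_modulation",
    "boxcar_detrend",
    "coherence_phase",
    "classify_voxels",
    "ActivationSummary",
    "activation_volume",
    "extract_hrf",
    "coherence_p_value",
    "bonferroni",
    "average_sessions_then_subjects",
    "VolumeComparison",
    "compare_activation_volumes",
    "analyze_bold",
]

POSITIVE, NEGATIVE, INACTIVE = 1, -1, 0

#: default coherence significance threshold
COHERENCE_THRESHOLD = 0.35


def percent_modulation(
    data: np.ndarray,
    n_baseline_frames: int,
    axis: int = -1,
    rel_tol: float = 1e-6,
) -> np.ndarray:
    """Convert a series to percent modulation about its baseline mean.

    The baseline is the mean of the first ``n_baseline_frames`` samples along
    ``axis``.  Voxels whose baseline mean is zero (relative to the grand
    scale of the data) cannot be expressed as percent change and are returned
    as NaN so that downstream classification marks them inactive.
    """
    data = np.asarray(data, dtype=float)
    if n_baseline_frames < 1:
        raise ValueError("baseline window must contain at least one frame")
    data = np.moveaxis(data, axis, -1)
    base = data[..., :n_baseline_frames].mean(axis=-1, keepdims=True)
    scale = np.abs(data).max()
    bad = np.abs(base) <= rel_tol * max(scale, 1.0)
    safe = np.where(bad, 1.0, base)
    out = 100.0 * (data - base) / safe
    out = np.where(bad, np.nan, out)
    return np.moveaxis(out, -1, axis)


def boxcar_detrend(
    data: np.ndarray,
    window_s: float = 60.0,
    tr_s: float = 0.75,
    axis: int = -1,
) -> np.ndarray:
    """Remove slow drift by subtracting a centered moving average.

    The window is ``window_s / tr_s`` frames; near the edges it shrinks to
    the samples available.  A window spanning an integer number of block
    periods passes the block-frequency component essentially untouched while
    removing linear drift in the interior.
    """
    data = np.asarray(data, dtype=float)
    data = np.moveaxis(data, axis, -1)
    n = data.shape[-1]
    w = int(round(window_s / tr_s))
    if w < 2:
        raise ValueError(f"window of {w} frames is too short (need >= 2)")
    if w > n:
        raise ValueError(f"window ({w} frames) exceeds series length ({n})")
    half = w // 2
    csum = np.cumsum(np.concatenate([np.zeros(data.shape[:-1] + (1,)), data], axis=-1), axis=-1)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + (w - half), n)  # half-open upper edge
    mean = (csum[..., hi] - csum[..., lo]) / (hi - lo)
    return np.moveaxis(data - mean, -1, axis)


def coherence_phase(
    data: np.ndarray,
    tr_s: float = 0.75,
    f0_hz: float = 1.0 / 60.0,
    axis: int = -1,
    n_exclude_low: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Coherence and phase of a series at the block frequency.

    Coherence C = |X(f0)| / sqrt(Σ_{f>0} |X(f)|²), with the DC term always
    excluded and optionally the ``n_exclude_low`` lowest positive-frequency
    bins below f0 excluded as well (residual drift).  Phase is the negated
    argument of X(f0) mapped to [0, 2π), so a response that rises at train
    onset has a small positive phase and a suppressed (sign-flipped) response
    sits half a turn away.

    The series length must place f0 exactly on the DFT grid (an integer
    number of block periods); otherwise the statistic is ill-defined and a
    ValueError is raised.
    """
    data = np.asarray(data, dtype=float)
    data = np.moveaxis(data, axis, -1)
    n = data.shape[-1]
    k0_f = n * tr_s * f0_hz
    k0 = int(round(k0_f))
    if abs(k0_f - k0) > 1e-6 or k0 < 1:
        raise ValueError(
            f"f0 = {f0_hz} Hz does not fall on the DFT grid of a {n}-frame series "
            f"at TR {tr_s} s (bin index {k0_f}); use an integer number of block periods"
        )
    if n_exclude_low >= k0:
        raise ValueError("cannot exclude the analysis bin itself")
    spec = np.fft.rfft(np.nan_to_num(data), axis=-1)
    amp2 = np.abs(spec) ** 2
    denom2 = amp2[..., 1 + n_exclude_low:].sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.sqrt(amp2[..., k0] / denom2)
    nan_in = np.isnan(data).any(axis=-1)
    coh = np.where(nan_in | (denom2 == 0), np.nan, coh)
    phase = (-np.angle(spec[..., k0])) % (2 * np.pi)
    return coh, phase


def classify_voxels(
    coherence: np.ndarray,
    phase: np.ndarray,
    threshold: float = COHERENCE_THRESHOLD,
) -> np.ndarray:
    """Label voxels +1 (positive), -1 (negative) or 0 (inactive).

    A voxel is significant when its coherence exceeds ``threshold``;
    significant voxels with phase in [0, π/2] ∪ [3π/2, 2π) are positive
    responders, the rest negative.  NaN coherence (flagged voxels) is
    inactive.
    """
    coherence = np.asarray(coherence, dtype=float)
    phase = np.asarray(phase, dtype=float)
    sig = np.nan_to_num(coherence, nan=-np.inf) > threshold
    pos = (phase <= np.pi / 2) | (phase >= 3 * np.pi / 2)
    labels = np.zeros(coherence.shape, dtype=np.int8)
    labels[sig & pos] = POSITIVE
    labels[sig & ~pos] = NEGATIVE
    return labels


@dataclass(frozen=True)
class ActivationSummary:
    """Significant-voxel count and volume of one polarity inside one ROI."""

    roi: str
    polarity: int
    n_voxels: int
    volume_mm3: float


def activation_volume(
    labels: np.ndarray,
    roi_mask: np.ndarray,
    polarity: int,
    voxel_size_mm: tuple[float, float, float] = (0.5, 0.5, 0.5),
    roi_name: str = "roi",
) -> ActivationSummary:
    """Volume of significant voxels of one polarity within an ROI mask."""
    labels = np.asarray(labels)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if labels.shape != roi_mask.shape:
        raise ValueError(
            f"label grid {labels.shape} does not match mask grid {roi_mask.shape}"
        )
    if polarity not in (POSITIVE, NEGATIVE):
        raise ValueError("polarity must be +1 or -1")
    n = int(np.count_nonzero(labels[roi_mask] == polarity))
    vol = float(np.prod(voxel_size_mm))
    return ActivationSummary(roi=roi_name, polarity=polarity, n_voxels=n, volume_mm3=n * vol)


def extract_hrf(
    series: np.ndarray,
    protocol: StimulusProtocol,
    tr_s: float = 0.75,
    zero_reference: bool = False,
    axis: int = -1,
) -> np.ndarray:
    """Average single-cycle response (empirical HRF) of a series.

    Folds the cycle-locked series into ``n_cycles`` segments of one cycle
    period and averages frame-wise.  With ``zero_reference`` the first
    frame's value is subtracted so the response is expressed relative to
    train onset.
    """
    series = np.asarray(series, dtype=float)
    series = np.moveaxis(series, axis, -1)
    fpc = int(round(protocol.cycle_period_s / tr_s))
    n = series.shape[-1]
    if n != protocol.n_cycles * fpc:
        raise ValueError(
            f"series length {n} != n_cycles ({protocol.n_cycles}) × frames per cycle ({fpc}); "
            "strip baseline frames first"
        )
    hrf = series.reshape(series.shape[:-1] + (protocol.n_cycles, fpc)).mean(axis=-2)
    if zero_reference:
        hrf = hrf - hrf[..., :1]
    return np.moveaxis(hrf, -1, axis)


def coherence_p_value(
    coherence,
    df: float = 470.0,
    method: str = "t",
    n_freq_bins: int | None = None,
) -> np.ndarray:
    """One-sided p-value for observing a coherence this large under Gaussian noise.

    ``method='t'`` (default) uses the correlation-statistic transform
    t = C·sqrt(df)/sqrt(1−C²) referred to a t distribution with ``df``
    degrees of freedom — the convention under which a 480-frame series has
    ~470 degrees of freedom.  ``method='white-noise-exact'`` uses the exact
    null of the coherence of white noise, C² ~ Beta(1, K−1) for K
    positive-frequency bins (pass ``n_freq_bins``); this is the distribution
    the Monte-Carlo calibration of the detector follows.

    C = 1 maps to p = 0 (with a warning: the statistic is saturated).
    """
    c = np.asarray(coherence, dtype=float)
    if (np.nan_to_num(c) < 0).any() or (np.nan_to_num(c) > 1).any():
        raise ValueError("coherence must lie in [0, 1]")
    if (c == 1).any():
        warnings.warn("coherence of exactly 1: p = 0 returned (saturated statistic)")
    if method == "t":
        if df <= 2:
            raise ValueError("df must exceed 2")
        with np.errstate(divide="ignore", invalid="ignore"):
            t = c * np.sqrt(df) / np.sqrt(1.0 - c**2)
        p = sps.t.sf(t, df)
        p = np.where(c == 1, 0.0, p)
    elif method == "white-noise-exact":
        if n_freq_bins is None or n_freq_bins < 2:
            raise ValueError("white-noise-exact requires n_freq_bins >= 2")
        # C^2 ~ Beta(1, K-1): P(C >= c) = (1 - c^2)^(K-1)
        p = (1.0 - c**2) ** (n_freq_bins - 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    return p if np.ndim(coherence) else float(p)


def bonferroni(p, n_tests: int):
    """Bonferroni family-wise correction: min(1, p × n)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return np.minimum(1.0, np.asarray(p, dtype=float) * n_tests) if np.ndim(p) else min(
        1.0, float(p) * n_tests
    )


def average_sessions_then_subjects(sessions_by_animal: dict) -> np.ndarray:
    """Two-level group average: mean within each animal, then across animals.

    Every animal contributes equally regardless of how many sessions it has;
    all arrays must share one grid.
    """
    if not sessions_by_animal:
        raise ValueError("no animals provided")
    animal_means = []
    shape = None
    for animal, sessions in sessions_by_animal.items():
        arrays = [np.asarray(s, dtype=float) for s in sessions]
        if not arrays:
            raise ValueError(f"animal {animal!r} has no sessions")
        for a in arrays:
            if shape is None:
                shape = a.shape
            elif a.shape != shape:
                raise ValueError(
                    f"grid mismatch: {a.shape} vs {shape} (register sessions first)"
                )
        animal_means.append(np.mean(arrays, axis=0))
    return np.mean(animal_means, axis=0)


@dataclass(frozen=True)
class VolumeComparison:
    """Paired volume comparison between two stimulation conditions."""

    statistic: float
    pvalue: float
    pvalue_corrected: float
    n_pairs: int
    alternative: str
    correction: str


def compare_activation_volumes(
    volumes_a,
    volumes_b,
    alternative: str = "greater",
    n_comparisons: int = 1,
    correction: str = "bonferroni",
) -> VolumeComparison:
    """One-sided paired signed-rank test of activation volume between conditions.

    ``alternative='greater'`` asks whether volumes in condition A exceed
    those in B animal-by-animal.  The family-wise correction multiplies the
    p-value by ``n_comparisons`` (Bonferroni) — pass the size of the
    ROI × frequency-pair family — or use :func:`optofmri.stats.correct_pvalues`
    with ``'holm'`` across the whole family.
    """
    a = np.asarray(volumes_a, dtype=float)
    b = np.asarray(volumes_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    res: TestResult = signed_rank_test(a, b, alternative=alternative)
    if correction == "bonferroni":
        p_corr = min(1.0, res.pvalue * n_comparisons)
    elif correction == "holm":
        # degenerate single-test holm == bonferroni; full-family holm is applied
        # by the caller across all p-values
        p_corr = float(correct_pvalues([res.pvalue] * 1, method="holm")[0] * n_comparisons)
        p_corr = min(1.0, p_corr)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return VolumeComparison(
        statistic=res.statistic,
        pvalue=res.pvalue,
        pvalue_corrected=p_corr,
        n_pairs=res.n,
        alternative=alternative,
        correction=correction,
    )


def analyze_bold(
    dataset,
    threshold: float = COHERENCE_THRESHOLD,
    detrend_window_s: float = 60.0,
    n_exclude_low: int = 0,
):
    """Full per-voxel pipeline: percent modulation → detrend → coherence/phase → labels.

    ``dataset`` is a :class:`optofmri.simulate.BoldDataset` (or any object
    with ``data``, ``tr_s``, ``protocol`` and ``n_baseline_frames``).
    Returns ``(coherence, phase, labels)`` volumes.  Percent modulation is
    referenced to the leading baseline frames when present, otherwise to the
    pre-train frames of the first cycle.
    """
    n_base = dataset.n_baseline_frames
    if n_base == 0:
        # fall back to the rest frames before anything happens in cycle 1
        n_ref = max(int(round(1.0 / dataset.tr_s)), 1)
    else:
        n_ref = n_base
    pct = percent_modulation(dataset.data, n_ref)
    pct = boxcar_detrend(pct, window_s=detrend_window_s, tr_s=dataset.tr_s)
    cycles = pct[..., n_base:]
    f0 = 1.0 / dataset.protocol.cycle_period_s
    coh, phase = coherence_phase(
        cycles, tr_s=dataset.tr_s, f0_hz=f0, n_exclude_low=n_exclude_low
    )
    labels = classify_voxels(coh, phase, threshold=threshold)
    return coh, phase, labels
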