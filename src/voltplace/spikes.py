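"""Spike detection, removal, spike-height normalization, and spike statistics.

Optical action potentials are fast (~ms) positive fluorescence transients.
Detection is a threshold-and-maximum procedure on a high-passed copy of the
trace: noise sigma is estimated robustly (1.4826 x median absolute
deviation, insensitive to the spikes themselves), threshold crossings at
``threshold_multiplier x sigma`` (default 4) are grouped and the local
maximum of each excursion is the spike sample.  Spike height is the median
peak amplitude above the local baseline and defines the cell's amplitude
unit; SNR = spike height / noise sigma.

The analytic detection-error model treats baseline noise as Gaussian: the
expected false-positive count is the upper tail beyond the threshold times
the number of samples, and the per-spike false-negative probability is the
Gaussian tail more than (snr - threshold) sigma below the spike peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .core import Trace
from .errors import AnalysisError, InvalidConfigError
from .filters import fir_zero_phase, highpass_zero_phase, moving_average, ramp_lowpass_taps


@dataclass
class SpikeTrain:
    indices: np.ndarray               # strictly increasing spike sample indices
    sample_rate: float
    spike_height: float = np.nan      # fluorescence units (per-cell scalar)
    noise_sigma: float = np.nan       # fluorescence units
    threshold_multiplier: float = 4.0
    cell_id: str = "cell0"

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)

    def __len__(self) -> int:
        return self.indices.size

    @property
    def snr(self) -> float:
        return self.spike_height / self.noise_sigma

    @property
    def times_s(self) -> np.ndarray:
        return self.indices / self.sample_rate


@dataclass
class STAWaveform:
    lags_ms: np.ndarray
    mean: np.ndarray
    n_events: int
    n_excluded: int = 0


@dataclass
class ThresholdResult:
    value: float
    defined: bool
    index: int = -1


@dataclass
class DetectionErrorModel:
    p4: float                   # Gaussian mass within +/- threshold sigma
    fp_expected_count: float    # expected false positives per record
    fn_probability: float       # per-spike miss probability
    snr: float
    threshold_multiplier: float
    duration_s: float
    sample_rate: float


def detect_spikes(
    trace: Trace,
    threshold_multiplier: float = 4.0,
    highpass_hz: float = 50.0,
    min_separation_ms: float = 1.0,
    noise_sigma: float | None = None,
) -> SpikeTrain:
    """Threshold-and-maximum spike detection on a high-passed trace.

    The default 4x-noise threshold can be overridden per cell via
    ``threshold_multiplier`` (the manual-adjustment hook); ``noise_sigma``
    replaces the robust estimate when the cell's noise level is already
    known (e.g. re-detection on a spike-removed residual).
    """
    data = trace.data
    if len(data) < trace.sample_rate:
        raise AnalysisError("record shorter than 1 s")
    if np.ptp(data) == 0:
        raise AnalysisError("zero-variance trace")
    fs = trace.sample_rate
    hp = highpass_zero_phase(data, highpass_hz, fs)
    sigma = noise_sigma if noise_sigma is not None \
        else 1.4826 * np.median(np.abs(hp - np.median(hp)))
    if sigma == 0:
        raise AnalysisError("zero noise estimate")

    above = hp > threshold_multiplier * sigma
    # group contiguous supra-threshold runs; one spike per run at its maximum
    bounds = np.flatnonzero(np.diff(np.r_[False, above, False].astype(np.int8)))
    peaks = np.asarray(
        [s + int(np.argmax(hp[s:e])) for s, e in zip(bounds[::2], bounds[1::2])],
        dtype=np.int64,
    )

    # enforce minimum separation, keeping the larger peak of close pairs
    min_sep = max(int(round(min_separation_ms * fs / 1000.0)), 1)
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < min_sep:
            if hp[p] > hp[kept[-1]]:
                kept[-1] = int(p)
        else:
            kept.append(int(p))
    peaks = np.asarray(kept, dtype=np.int64)

    if peaks.size == 0:
        return SpikeTrain(peaks, fs, np.nan, sigma, threshold_multiplier, trace.cell_id)

    heights = _peak_heights(data, peaks, fs)
    return SpikeTrain(peaks, fs, float(np.median(heights)), float(sigma),
                      threshold_multiplier, trace.cell_id)


def _peak_heights(data: np.ndarray, peaks: np.ndarray, fs: float) -> np.ndarray:
    """Peak amplitude above the local (median) baseline around each spike."""
    pre_a, pre_b = int(0.012 * fs), int(0.004 * fs)
    post_a, post_b = int(0.007 * fs), int(0.015 * fs)
    heights = np.empty(len(peaks))
    n = len(data)
    for i, p in enumerate(peaks):
        ctx = np.concatenate([
            data[max(p - pre_a, 0):max(p - pre_b, 0)],
            data[min(p + post_a, n):min(p + post_b, n)],
        ])
        base = np.median(ctx) if ctx.size else 0.0
        heights[i] = data[p] - base
    return heights


def measure_snr(trace: Trace, spike_indices, highpass_hz: float = 50.0) -> float:
    """SNR at known spike samples: median local peak height / robust noise sigma.

    Intended for generator validation, where the spike times are ground
    truth rather than detections (detection at threshold ~ SNR would bias
    the height estimate upward by selection).
    """
    idx = np.asarray(spike_indices, dtype=np.int64)
    if idx.size == 0:
        return np.nan
    fs = trace.sample_rate
    hp = highpass_zero_phase(trace.data, highpass_hz, fs)
    sigma = 1.4826 * np.median(np.abs(hp - np.median(hp)))
    heights = _peak_heights(trace.data, idx, fs)
    return float(np.median(heights) / sigma)


def spike_removal_intervals(indices: np.ndarray, n: int, fs: float,
                            pre_ms: float = 3.0, post_ms: float = 6.0) -> list:
    """Merged [peak - pre, peak + post] windows, clipped to the record."""
    pre = int(round(pre_ms * fs / 1000.0))
    post = int(round(post_ms * fs / 1000.0))
    merged: list[list[int]] = []
    for p in np.sort(indices):
        a, b = max(int(p) - pre, 0), min(int(p) + post, n - 1)
        if merged and a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged]


def remove_spikes(trace: Trace, spikes: SpikeTrain,
                  pre_ms: float = 3.0, post_ms: float = 6.0) -> Trace:
    """Replace each spike window with linear interpolation of its boundary samples."""
    data = trace.data.copy()
    n = len(data)
    for a, b in spike_removal_intervals(spikes.indices, n, trace.sample_rate, pre_ms, post_ms):
        lo = data[a - 1] if a > 0 else data[b + 1] if b + 1 < n else data[a]
        hi = data[b + 1] if b + 1 < n else lo
        data[a:b + 1] = np.linspace(lo, hi, b - a + 3)[1:-1]
    return trace.with_data(data)


def normalize_and_dvm(trace: Trace, spikes: SpikeTrain,
                      lowpass_taps: np.ndarray | None = None) -> Trace:
    """Subthreshold membrane-potential proxy in spike-height units.

    dVm(t) = (low-passed spike-removed F(t) - whole-record mean of the
    spike-removed F) / spike height.  The whole-record mean includes the
    inter-trial intervals, anchoring dVm ~ 0 at the resting baseline.
    """
    if not np.isfinite(spikes.spike_height):
        raise AnalysisError("spike height undefined (no detected spikes)")
    removed = remove_spikes(trace, spikes)
    taps = ramp_lowpass_taps(trace.sample_rate) if lowpass_taps is None else lowpass_taps
    low = fir_zero_phase(taps, removed.data)
    dvm = (low - removed.data.mean()) / spikes.spike_height
    return trace.with_data(dvm, normalization="spike_height")


def spike_triggered_average(trace: Trace, events, window_ms=(100.0, 100.0)) -> STAWaveform:
    """Mean of trace segments aligned to events (spikes or stimulus onsets).

    Events whose window is truncated by the record edges are excluded and
    counted in ``n_excluded``.
    """
    idx = events.indices if isinstance(events, SpikeTrain) else np.asarray(events, dtype=np.int64)
    fs = trace.sample_rate
    pre = int(round(window_ms[0] * fs / 1000.0))
    post = int(round(window_ms[1] * fs / 1000.0))
    n = len(trace.data)
    ok = (idx - pre >= 0) & (idx + post < n)
    used = idx[ok]
    if used.size == 0:
        raise AnalysisError("no events with a full window inside the record")
    segs = np.stack([trace.data[p - pre:p + post + 1] for p in used])
    lags = (np.arange(-pre, post + 1) / fs) * 1000.0
    return STAWaveform(lags, segs.mean(axis=0), int(used.size), int((~ok).sum()))


def sta_spike_threshold(sta: STAWaveform, criterion: float = 0.1,
                        smooth_ms: float = 2.0) -> ThresholdResult:
    """Baseline-to-spike-initiation threshold from the STA derivative.

    Returns the STA amplitude at the first pre-peak sample from which
    dSTA/dt exceeds and stays above ``criterion`` (spike height per second,
    default 0.1) through the peak.  Flagged undefined when no sustained
    crossing exists.
    """
    if sta.lags_ms[0] > -50.0:
        raise AnalysisError("STA must cover at least 50 ms pre-peak")
    dt_s = (sta.lags_ms[1] - sta.lags_ms[0]) / 1000.0
    sm = moving_average(sta.mean, max(int(round(smooth_ms / 1000.0 / dt_s)), 1))
    deriv = np.gradient(sm, dt_s)
    peak = int(np.argmax(sta.mean))
    pre = deriv[:peak]
    if pre.size == 0:
        return ThresholdResult(np.nan, False)
    above = pre >= criterion
    if not above.any():
        return ThresholdResult(np.nan, False)
    # earliest index whose suffix (through the peak) stays above criterion
    below = np.flatnonzero(~above)
    start = 0 if below.size == 0 else int(below[-1]) + 1
    if start >= peak:
        return ThresholdResult(np.nan, False)
    return ThresholdResult(float(sta.mean[start]), True, start)


def detection_error_rates(
    snr: float,
    threshold_multiplier: float = 4.0,
    duration_s: float = 30.0,
    sample_rate: float = 1000.0,
) -> DetectionErrorModel:
    """Analytic false-positive and false-negative rates for Gaussian noise.

    ``p4`` is the Gaussian mass within +/- threshold sigma; the expected
    false-positive count is (1 - p4)/2 x sample_rate x duration; the
    per-spike false-negative probability is the upper Gaussian tail beyond
    (snr - threshold) sigma.
    """
    if snr <= 0 or threshold_multiplier <= 0 or duration_s <= 0 or sample_rate <= 0:
        raise InvalidConfigError("all inputs must be positive")
    p = float(special.erf(threshold_multiplier / np.sqrt(2.0)))
    fp = (1.0 - p) / 2.0 * sample_rate * duration_s
    fn = float(stats.norm.sf(snr - threshold_multiplier))
    if snr <= threshold_multiplier:
        warnings.warn("snr <= threshold: false-negative probability >= 0.5")
    return DetectionErrorModel(p, fp, fn, snr, threshold_multiplier, duration_s, sample_rate)


def spike_autocorrelogram(spikes: SpikeTrain, bin_ms: float = 1.0,
                          max_lag_ms: float = 50.0):
    """Normalized spike-pair lag histogram (probability per spike), zero lag excluded.

    Returns ``(lag_centers_ms, probability)`` over symmetric lags.
    """
    if len(spikes) < 2:
        raise AnalysisError("need at least 2 spikes")
    t_ms = spikes.indices / spikes.sample_rate * 1000.0
    max_lag = max_lag_ms
    # bins centered on multiples of bin_ms so the histogram is lag-symmetric
    edges = np.arange(-max_lag - bin_ms / 2, max_lag + bin_ms, bin_ms)
    counts = np.zeros(len(edges) - 1)
    for i, ti in enumerate(t_ms):
        lo = np.searchsorted(t_ms, ti - max_lag)
        hi = np.searchsorted(t_ms, ti + max_lag, side="right")
        lags = t_ms[lo:hi] - ti
        lags = lags[lags != 0.0]
        counts += np.histogram(lags, bins=edges)[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / len(spikes)
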