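"""Epoch-structured protocol analyses.

Three protocols share this module:

* **Plasticity** — closed-loop place-field induction.  Trials are labeled
  Pre/Stim/Post (optionally PostI/PostII/Day2); maps are computed per epoch,
  and plasticity is quantified as the anticipatory firing rate in the
  10-30 cm window before the stimulated location, plus the backward shift of
  the induced field peak relative to the stimulation location (negative =
  earlier on the track).
* **Excitability (F-I)** — mean firing rate within 500 ms stimulus windows
  as a function of optogenetic intensity; the slope over a declared
  intensity range is the excitability metric, and the post/pre slope ratio
  compares paired sessions.
* **Synaptic test pulses** — spikes within 26 ms of a presynaptic stimulus
  onset are "evoked"; cells are classified excitatory/inhibitory from the
  evoked-spike count and the signed area (AUC) of the baseline-subtracted,
  spike-removed stimulus-locked response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import BehaviorTrack, Trace
from .errors import AnalysisError
from .spatial import RateMap, SignalMap, make_rate_map, make_signal_map
from .spikes import STAWaveform, SpikeTrain, remove_spikes

EPOCH_ORDER = ("Pre", "Stim", "PostI", "PostII", "Post", "Day2")


@dataclass
class EpochedSession:
    epoch_of_trial: list                 # label per trial
    stim_location_cm: float | None = None
    stim_events: list = field(default_factory=list)   # StimEvent-like records
    sample_rate: float = 1000.0

    def trials_in(self, label: str) -> np.ndarray:
        return np.flatnonzero([e == label for e in self.epoch_of_trial])

    @property
    def labels(self) -> list:
        seen = []
        for e in self.epoch_of_trial:
            if e not in seen:
                seen.append(e)
        return seen


@dataclass
class PlasticityResult:
    anticipatory_rate_hz: dict           # epoch -> Hz in the 10-30 cm pre-stim window
    backward_shift_cm: float             # Post map peak minus stimulation location
    in_field_rate_hz: dict
    out_field_rate_hz: dict
    dvm_window: dict                     # epoch -> mean dVm in the pre-stim window
    theta_window: dict
    stim_location_cm: float


@dataclass
class FICurve:
    intensities: np.ndarray              # mW/mm^2, strictly increasing
    rates_hz: np.ndarray
    spontaneous_rate_hz: float
    slope: float                         # Hz per mW/mm^2 over slope_range
    slope_range: tuple


@dataclass
class EvokedSpikes:
    per_trial: np.ndarray                # bool, evoked spike in the window
    latencies_ms: np.ndarray             # first evoked-spike latency per spiking trial
    evoked_spike_indices: np.ndarray     # all spike samples flagged evoked
    window_ms: float


@dataclass
class SynapticClassification:
    label: str                           # "excitatory" | "inhibitory"
    auc: float                           # spike-height * ms, signed
    n_evoked_trials: int
    n_trials: int
    evoked: EvokedSpikes
    suppression_stat: float              # paired-t on 25-85 ms vs. baseline rates
    suppression_p: float


# --------------------------------------------------------------------------
# epoch maps and plasticity metrics
# --------------------------------------------------------------------------

def epoch_maps(
    session: EpochedSession,
    spikes: SpikeTrain,
    behavior: BehaviorTrack,
    dvm: Trace | None = None,
    theta: Trace | None = None,
    **map_kwargs,
) -> dict:
    """Independent rate (and optional signal) maps per epoch.

    Returns ``{epoch: {"rate": RateMap, "dvm": SignalMap, "theta": SignalMap}}``;
    an epoch whose samples are all removed is flagged ``{"missing": True}``.
    """
    out = {}
    for label in session.labels:
        mask = behavior.trial_mask(session.trials_in(label))
        entry = {}
        try:
            entry["rate"] = make_rate_map(spikes, behavior, sample_mask=mask, **map_kwargs)
        except AnalysisError:
            out[label] = {"missing": True}
            continue
        if dvm is not None:
            entry["dvm"] = make_signal_map(dvm, behavior, sample_mask=mask, **map_kwargs)
        if theta is not None:
            entry["theta"] = make_signal_map(theta, behavior, sample_mask=mask, **map_kwargs)
        out[label] = entry
    return out


def _window_bins(rate_map, lo_cm: float, hi_cm: float) -> np.ndarray:
    """Bins overlapping [lo_cm, hi_cm]."""
    edges = rate_map.bin_edges
    return np.flatnonzero((edges[:-1] < hi_cm) & (edges[1:] > lo_cm))


def anticipatory_rate(rate_map: RateMap, stim_location_cm: float,
                      window_cm=(30.0, 10.0)) -> float:
    """Occupancy-weighted mean rate 10-30 cm before the stimulated location."""
    lo, hi = stim_location_cm - window_cm[0], stim_location_cm - window_cm[1]
    if lo < 0 or hi > rate_map.track_length:
        raise AnalysisError("anticipatory window extends outside the track")
    bins = _window_bins(rate_map, lo, hi)
    occ = rate_map.occupancy_s[bins]
    rate = np.nan_to_num(rate_map.rate[bins])
    if occ.sum() == 0:
        return 0.0
    return float(np.sum(rate * occ) / occ.sum())


def window_signal_mean(signal_map: SignalMap, stim_location_cm: float,
                       window_cm=(30.0, 10.0)) -> float:
    """Occupancy-weighted mean of a signal map in the pre-stimulus window."""
    lo, hi = stim_location_cm - window_cm[0], stim_location_cm - window_cm[1]
    bins = _window_bins(signal_map, lo, hi)
    occ = signal_map.occupancy_s[bins]
    vals = signal_map.values[bins]
    good = np.isfinite(vals) & (occ > 0)
    if not good.any():
        return np.nan
    return float(np.sum(vals[good] * occ[good]) / occ[good].sum())


def backward_shift(rate_map: RateMap, stim_location_cm: float) -> float:
    """Signed displacement of the map peak from the stimulated location (cm).

    Negative values mean the peak precedes the stimulus location on the
    track.  NaN when the map is empty (all-zero or unvisited).
    """
    rate = np.nan_to_num(rate_map.rate, nan=-np.inf)
    if not np.isfinite(rate).any() or np.nanmax(rate_map.rate) <= 0:
        return np.nan
    peak = int(np.argmax(rate))  # ties break to the lowest bin index
    return float(rate_map.bin_centers[peak] - stim_location_cm)


def pairwise_map_correlation(maps: list) -> list:
    """Pearson r of rates over jointly visited bins, for every map pair.

    Returns ``[(i, j, r), ...]`` with ``r = nan`` flagged for constant maps.
    """
    out = []
    for i in range(len(maps)):
        for j in range(i + 1, len(maps)):
            a, b = maps[i].rate, maps[j].rate
            good = np.isfinite(a) & np.isfinite(b)
            x, y = a[good], b[good]
            if x.size < 2 or x.std() == 0 or y.std() == 0:
                out.append((i, j, np.nan))
            else:
                out.append((i, j, float(np.corrcoef(x, y)[0, 1])))
    return out


def plasticity_metrics(
    session: EpochedSession,
    spikes: SpikeTrain,
    behavior: BehaviorTrack,
    dvm: Trace | None = None,
    theta: Trace | None = None,
    post_label: str = "Post",
    **map_kwargs,
) -> PlasticityResult:
    """Anticipatory rates, backward shift, and in/out-field statistics per epoch."""
    from .spatial import identify_place_fields, in_out_field_rates

    maps = epoch_maps(session, spikes, behavior, dvm=dvm, theta=theta, **map_kwargs)
    stim = session.stim_location_cm
    anticipatory, in_rate, out_rate, dvm_w, theta_w = {}, {}, {}, {}, {}
    shift = np.nan
    for label, entry in maps.items():
        if entry.get("missing"):
            continue
        rm = entry["rate"]
        anticipatory[label] = anticipatory_rate(rm, stim)
        fields = identify_place_fields(rm) if rm.smoothed else []
        in_rate[label], out_rate[label] = in_out_field_rates(rm, fields)
        if "dvm" in entry:
            dvm_w[label] = window_signal_mean(entry["dvm"], stim)
        if "theta" in entry:
            theta_w[label] = window_signal_mean(entry["theta"], stim)
        if label == post_label:
            shift = backward_shift(rm, stim)
    return PlasticityResult(anticipatory, shift, in_rate, out_rate, dvm_w, theta_w, stim)


# --------------------------------------------------------------------------
# excitability (F-I)
# --------------------------------------------------------------------------

def fi_analysis(
    spikes: SpikeTrain,
    schedule,
    stim_duration_ms: float = 500.0,
    slope_range=(0.0, 17.0),
    record_samples: int | None = None,
) -> FICurve:
    """F-I curve from a stepped-stimulus schedule ``[(onset_sample, intensity), ...]``.

    Rate per intensity is total spikes in that intensity's stimulus windows
    divided by total window time; the spontaneous rate comes from all
    samples outside every window and enters the fit as the I = 0 point.
    The slope is ordinary least squares over intensities in ``slope_range``.
    """
    fs = spikes.sample_rate
    win = int(round(stim_duration_ms * fs / 1000.0))
    schedule = [(int(s), float(i)) for s, i in schedule]
    intensities = np.unique([i for _, i in schedule])
    if len(intensities) < 2:
        raise AnalysisError("need at least 2 stimulus intensities for a slope")

    t = spikes.indices
    rates = []
    for inten in intensities:
        onsets = [s for s, i in schedule if i == inten]
        count = sum(int(np.count_nonzero((t >= s) & (t < s + win))) for s in onsets)
        rates.append(count / (len(onsets) * win / fs))
    rates = np.asarray(rates)

    n_total = record_samples if record_samples is not None else (int(t.max()) + int(fs) if t.size else int(fs))
    in_window = np.zeros(n_total, bool)
    for s, _ in schedule:
        in_window[s:s + win] = True
    spont_time = (n_total - in_window.sum()) / fs
    spont_count = int(np.count_nonzero(~in_window[np.clip(t, 0, n_total - 1)]))
    spont = spont_count / spont_time if spont_time > 0 else np.nan

    xs = np.r_[0.0, intensities]
    ys = np.r_[spont, rates]
    sel = (xs >= slope_range[0]) & (xs <= slope_range[1])
    if sel.sum() < 2:
        slope = np.nan
    else:
        slope = float(np.polyfit(xs[sel], ys[sel], 1)[0])
    return FICurve(intensities, rates, float(spont), slope, tuple(slope_range))


def fi_slope_ratio(pre: FICurve, post: FICurve) -> float:
    """Excitability change across paired sessions: slope_post / slope_pre."""
    return post.slope / pre.slope


# --------------------------------------------------------------------------
# synaptic test pulses
# --------------------------------------------------------------------------

def classify_evoked_spikes(spikes: SpikeTrain, stim_onsets, window_ms: float = 26.0) -> EvokedSpikes:
    """Spikes within (0, window_ms] of a stimulus onset are evoked.

    All spikes in a window are flagged; the first defines that trial's
    latency.
    """
    fs = spikes.sample_rate
    onsets = np.asarray(stim_onsets, dtype=np.int64)
    win = window_ms * fs / 1000.0
    flags = np.zeros(len(onsets), bool)
    latencies = []
    evoked_idx = []
    for k, s in enumerate(onsets):
        d = spikes.indices - s
        hit = spikes.indices[(d > 0) & (d <= win)]
        if hit.size:
            flags[k] = True
            latencies.append((hit[0] - s) / fs * 1000.0)
            evoked_idx.extend(hit.tolist())
    return EvokedSpikes(flags, np.asarray(latencies), np.asarray(evoked_idx, np.int64), window_ms)


def classify_synaptic_response(
    trace: Trace,
    spikes: SpikeTrain,
    stim_onsets,
    auc_window_ms: float = 100.0,
    baseline_ms: float = 200.0,
    evoked_window_ms: float = 26.0,
    suppression_window_ms=(25.0, 85.0),
) -> SynapticClassification:
    """Excitatory/inhibitory classification of the stimulus-locked response.

    AUC is the signed area (0 to ``auc_window_ms`` post-onset) of the
    spike-removed, per-trial baseline-subtracted response, averaged across
    trials.  Cells with more than one evoked spike, or AUC > 0, are
    excitatory; cells with no more than one evoked spike and AUC < 0 are
    inhibitory.  The suppression contrast compares spike rates in the
    25-85 ms post-onset window against the 200 ms pre-onset baseline.
    """
    onsets = np.asarray(stim_onsets, dtype=np.int64)
    if onsets.size == 0:
        raise AnalysisError("no stimulation trials")
    if onsets.size < 12:
        warnings.warn("fewer than 12 stimulation trials; classification is underpowered")
    fs = trace.sample_rate
    removed = remove_spikes(trace, spikes)
    if np.isfinite(spikes.spike_height) and trace.normalization != "spike_height":
        data = (removed.data - removed.data.mean()) / spikes.spike_height
    else:
        data = removed.data

    pre = int(round(baseline_ms * fs / 1000.0))
    post = int(round(auc_window_ms * fs / 1000.0))
    dt_ms = 1000.0 / fs
    aucs = []
    for s in onsets:
        if s - pre < 0 or s + post > len(data):
            continue
        seg = data[s:s + post] - data[s - pre:s].mean()
        aucs.append(seg.sum() * dt_ms)
    if not aucs:
        raise AnalysisError("no trial with a full AUC window")
    auc = float(np.mean(aucs))

    evoked = classify_evoked_spikes(spikes, onsets, evoked_window_ms)
    n_evoked = int(evoked.per_trial.sum())
    label = "excitatory" if (n_evoked > 1 or auc > 0) else "inhibitory"

    lo = int(round(suppression_window_ms[0] * fs / 1000.0))
    hi = int(round(suppression_window_ms[1] * fs / 1000.0))
    t = spikes.indices
    win_rates, base_rates = [], []
    for s in onsets:
        win_rates.append(np.count_nonzero((t >= s + lo) & (t < s + hi)) / ((hi - lo) / fs))
        base_rates.append(np.count_nonzero((t >= s - pre) & (t < s)) / (pre / fs))
    diffs = np.asarray(win_rates) - np.asarray(base_rates)
    if np.allclose(diffs, diffs[0]):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.ttest_rel(win_rates, base_rates)
    return SynapticClassification(label, auc, n_evoked, len(onsets), evoked,
                                  float(stat), float(p))


def stimulus_triggered_average_split(
    trace: Trace,
    spikes: SpikeTrain,
    stim_onsets,
    window_ms=(200.0, 300.0),
    baseline_ms: float = 200.0,
    evoked_window_ms: float = 26.0,
    spike_removed: bool = False,
):
    """Stimulus-triggered averages split by evoked-spike outcome.

    Trials are partitioned by whether the stimulus evoked a spike; each
    trial is baseline-subtracted (mean of the 200 ms pre-onset window)
    before averaging.  With ``spike_removed=True`` the averages are taken on
    the spike-interpolated trace, which isolates the underlying PSP from
    spontaneous spike transients (useful when few trials are available).
    Returns ``(sta_spiking, sta_nonspiking)``; a split with no trials is
    ``None``.
    """
    onsets = np.asarray(stim_onsets, dtype=np.int64)
    evoked = classify_evoked_spikes(spikes, onsets, evoked_window_ms)
    fs = trace.sample_rate
    pre = int(round(window_ms[0] * fs / 1000.0))
    post = int(round(window_ms[1] * fs / 1000.0))
    base = int(round(baseline_ms * fs / 1000.0))
    src = remove_spikes(trace, spikes) if spike_removed else trace
    if np.isfinite(spikes.spike_height) and trace.normalization != "spike_height":
        data = (src.data - src.data.mean()) / spikes.spike_height
    else:
        data = src.data

    def _sta(sel_onsets):
        segs = []
        for s in sel_onsets:
            if s - pre < 0 or s + post >= len(data):
                continue
            seg = data[s - pre:s + post + 1] - data[s - base:s].mean()
            segs.append(seg)
        if not segs:
            return None
        lags = np.arange(-pre, post + 1) / fs * 1000.0
        return STAWaveform(lags, np.mean(segs, axis=0), len(segs))

    return _sta(onsets[evoked.per_trial]), _sta(onsets[~evoked.per_trial])
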