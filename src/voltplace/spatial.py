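"""Track maps, spatial information, the place-cell shuffle test, and fields.

The virtual track is divided into ``nbin`` equal bins (default 80 bins of
2.25 cm on a 180 cm track; bin i covers [i*w, (i+1)*w), the final bin closed
at the track end).  Samples where the animal runs slower than 5 cm/s are
removed from both occupancy and event counting.  Rate maps are optionally
smoothed with a 5-point Gaussian window (sigma = 1 bin), with kernel weights
renormalized over visited bins so unvisited bins stay missing rather than
zero.

Spatial information (bits/spike):

    SI = sum_i p_i (lambda_i / lambda) log2(lambda_i / lambda)

with p_i the fractional occupancy of bin i, lambda_i its mean rate and
lambda = sum_i p_i lambda_i the overall mean rate.  Significance is a
within-trial circular-permutation test: each shuffle applies an independent
uniform circular shift to each trial's firing-rate time series relative to
the position trace, the map and SI are recomputed, and a cell is a place
cell when its observed SI exceeds the 95th percentile of 1000 shuffles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d
from scipy.signal.windows import gaussian as gaussian_window

from .core import BehaviorTrack, Trace
from .errors import AnalysisError
from .spikes import SpikeTrain

DEFAULT_NBIN = 80
DEFAULT_SPEED_MIN = 5.0  # cm/s

#: 5-point Gaussian smoothing kernel, sigma = 1 bin.
SMOOTH_KERNEL = gaussian_window(5, std=1.0)
SMOOTH_KERNEL = SMOOTH_KERNEL / SMOOTH_KERNEL.sum()


@dataclass
class RateMap:
    bin_edges: np.ndarray       # cm, length nbin + 1
    occupancy_s: np.ndarray     # s per bin
    counts: np.ndarray          # events per bin
    rate: np.ndarray            # Hz per bin (smoothed when ``smoothed``); NaN = unvisited
    smoothed: bool
    track_length: float

    @property
    def nbin(self) -> int:
        return len(self.occupancy_s)

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def visited(self) -> np.ndarray:
        return self.occupancy_s > 0

    @property
    def occupancy_p(self) -> np.ndarray:
        """Fractional occupancy p_i (sums to 1 over visited bins)."""
        total = self.occupancy_s.sum()
        return self.occupancy_s / total if total > 0 else self.occupancy_s

    @property
    def rate_unsmoothed(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.visited, self.counts / self.occupancy_s, np.nan)

    @property
    def mean_rate(self) -> float:
        """Overall mean rate lambda = sum p_i lambda_i."""
        lam = np.where(self.visited, self.rate, 0.0)
        return float(np.sum(self.occupancy_p * np.nan_to_num(lam)))


@dataclass
class SignalMap:
    bin_edges: np.ndarray
    occupancy_s: np.ndarray
    values: np.ndarray          # per-bin mean of the signal; NaN = unvisited
    smoothed: bool
    track_length: float

    bin_centers = RateMap.bin_centers
    visited = RateMap.visited
    nbin = RateMap.nbin


@dataclass
class PlaceField:
    start_bin: int
    end_bin: int                # inclusive
    peak_bin: int
    in_rate: float              # mean in-field rate, Hz
    out_rate: float             # mean rate outside the field, Hz

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1


@dataclass
class PlaceCellResult:
    si: float
    shuffle_si: np.ndarray
    percentile: float           # rank of the observed SI in the null, 0-100
    is_place_cell: bool
    fields: list = field(default_factory=list)
    rate_map: RateMap | None = None


@dataclass
class QCStatus:
    n_trials: int
    mean_rate_hz: float
    included: bool
    reasons: list = field(default_factory=list)


def smooth_with_missing(values: np.ndarray, kernel: np.ndarray = SMOOTH_KERNEL) -> np.ndarray:
    """Convolve, renormalizing kernel weights over non-missing bins."""
    valid = np.isfinite(values)
    num = convolve1d(np.where(valid, values, 0.0), kernel, mode="constant")
    den = convolve1d(valid.astype(float), kernel, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~valid] = np.nan
    return out


def _bin_index(position: np.ndarray, track_length: float, nbin: int) -> np.ndarray:
    idx = np.floor(position / track_length * nbin).astype(np.int64)
    return np.clip(idx, 0, nbin - 1)  # closes the final bin at the track end


def _retained(behavior: BehaviorTrack, speed_min: float, sample_mask=None) -> np.ndarray:
    keep = behavior.velocity >= speed_min
    if sample_mask is not None:
        keep &= sample_mask
    return keep


def make_rate_map(
    event_samples,
    behavior: BehaviorTrack,
    nbin: int = DEFAULT_NBIN,
    speed_min: float = DEFAULT_SPEED_MIN,
    smooth: bool = True,
    sample_mask=None,
) -> RateMap:
    """Occupancy-normalized event-rate map from point events (spike samples)."""
    idx = event_samples.indices if isinstance(event_samples, SpikeTrain) \
        else np.asarray(event_samples, dtype=np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= len(behavior)):
        raise AnalysisError("events outside the behavior time span")
    keep = _retained(behavior, speed_min, sample_mask)
    if not keep.any():
        raise AnalysisError("all samples removed by the speed filter")

    bins = _bin_index(behavior.position, behavior.track_length, nbin)
    occupancy = np.bincount(bins[keep], minlength=nbin) * behavior.dt
    kept_events = idx[keep[idx]] if idx.size else idx
    counts = np.bincount(bins[kept_events], minlength=nbin).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occupancy > 0, counts / occupancy, np.nan)
    if smooth:
        rate = smooth_with_missing(rate)
    edges = np.linspace(0.0, behavior.track_length, nbin + 1)
    return RateMap(edges, occupancy, counts, rate, smooth, behavior.track_length)


def make_signal_map(
    signal: Trace,
    behavior: BehaviorTrack,
    nbin: int = DEFAULT_NBIN,
    speed_min: float = DEFAULT_SPEED_MIN,
    smooth: bool = True,
    sample_mask=None,
) -> SignalMap:
    """Per-bin mean of a continuous signal (e.g. dVm or theta amplitude)."""
    data = signal.data if isinstance(signal, Trace) else np.asarray(signal, float)
    if len(data) != len(behavior):
        raise AnalysisError("signal and behavior length mismatch")
    keep = _retained(behavior, speed_min, sample_mask)
    if not keep.any():
        raise AnalysisError("all samples removed by the speed filter")
    bins = _bin_index(behavior.position, behavior.track_length, nbin)
    occ_counts = np.bincount(bins[keep], minlength=nbin)
    sums = np.bincount(bins[keep], weights=data[keep], minlength=nbin)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(occ_counts > 0, sums / occ_counts, np.nan)
    if smooth:
        values = smooth_with_missing(values)
    edges = np.linspace(0.0, behavior.track_length, nbin + 1)
    return SignalMap(edges, occ_counts * behavior.dt, values, smooth, behavior.track_length)


def spatial_information(rate_map: RateMap, use_smoothed: bool = True) -> float:
    """Spatial information in bits/spike from a rate map."""
    rates = rate_map.rate if use_smoothed else rate_map.rate_unsmoothed
    return spatial_information_from_arrays(rate_map.occupancy_p, rates)


def spatial_information_from_arrays(p: np.ndarray, rates: np.ndarray) -> float:
    """SI = sum_i p_i (lambda_i/lambda) log2(lambda_i/lambda); zero-rate bins contribute 0."""
    p = np.asarray(p, float)
    rates = np.asarray(rates, float)
    valid = np.isfinite(rates) & (p > 0)
    p, rates = p[valid], rates[valid]
    lam = float(np.sum(p * rates))
    if lam <= 0:
        raise AnalysisError("overall mean rate is zero; SI undefined")
    pos = rates > 0
    ratio = rates[pos] / lam
    return float(np.sum(p[pos] * ratio * np.log2(ratio)))


# --------------------------------------------------------------------------
# place-cell shuffle test
# --------------------------------------------------------------------------

def binned_rate_series(
    spikes,
    behavior: BehaviorTrack,
    window_ms: float = 100.0,
    nbin: int = DEFAULT_NBIN,
    speed_min: float = DEFAULT_SPEED_MIN,
    sample_mask=None,
):
    """Per-trial firing-rate time series for the circular-permutation test.

    Spike counts in ``window_ms`` windows define the rate series; each
    window carries the mean position (as a bin index) and a retained flag
    (mean speed >= speed_min).  Returns a list of per-trial dicts with keys
    ``rate``, ``bin``, ``keep`` and the window duration ``dt``.
    """
    idx = spikes.indices if isinstance(spikes, SpikeTrain) else np.asarray(spikes, np.int64)
    win = max(int(round(window_ms * behavior.sample_rate / 1000.0)), 1)
    dt = win / behavior.sample_rate
    spike_mark = np.zeros(len(behavior))
    spike_mark[idx] = 1.0
    extra_keep = np.ones(len(behavior), bool) if sample_mask is None else sample_mask

    trials = []
    for k in range(behavior.n_trials):
        sel = np.flatnonzero(behavior.trial_index == k)
        if sel.size < win:
            continue
        nwin = sel.size // win
        cut = sel[: nwin * win]
        counts = spike_mark[cut].reshape(nwin, win).sum(axis=1)
        pos = behavior.position[cut].reshape(nwin, win).mean(axis=1)
        speed = behavior.velocity[cut].reshape(nwin, win).mean(axis=1)
        keep = (speed >= speed_min) & extra_keep[cut].reshape(nwin, win).all(axis=1)
        trials.append({
            "rate": counts / dt,
            "bin": _bin_index(pos, behavior.track_length, nbin),
            "keep": keep,
            "dt": dt,
        })
    return trials


def _map_from_series(trials, nbin):
    occ = np.zeros(nbin)
    num = np.zeros(nbin)
    for tr in trials:
        b, k, r, dt = tr["bin"], tr["keep"], tr["rate"], tr["dt"]
        occ += np.bincount(b[k], minlength=nbin) * dt
        num += np.bincount(b[k], weights=r[k] * dt, minlength=nbin)
    return occ, num


def place_cell_test(
    trials,
    n_shuffles: int = 1000,
    seed: int | None = None,
    nbin: int = DEFAULT_NBIN,
    use_smoothed: bool = True,
    rate_map: RateMap | None = None,
) -> PlaceCellResult:
    """Circular-permutation significance test for spatial tuning.

    ``trials`` is the output of :func:`binned_rate_series`.  Each of the
    ``n_shuffles`` permutations applies an independent uniform circular
    shift to each trial's rate series (relative to its position series),
    rebuilds the occupancy-weighted map, and recomputes SI.
    """
    if n_shuffles < 100:
        warnings.warn("n_shuffles < 100 gives a coarse null distribution")
    if not trials:
        raise AnalysisError("no usable trials")
    rng = np.random.default_rng(seed)

    occ, num = _map_from_series(trials, nbin)
    visited = occ > 0
    if visited.sum() < 2:
        raise AnalysisError("degenerate session: fewer than two visited bins")
    p = occ / occ.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        obs_rates = np.where(visited, num / occ, np.nan)
    if use_smoothed:
        obs_rates = smooth_with_missing(obs_rates)
    si_obs = spatial_information_from_arrays(p, obs_rates)

    shuf_num = np.zeros((n_shuffles, nbin))
    for tr in trials:
        r, b, k, dt = tr["rate"], tr["bin"], tr["keep"], tr["dt"]
        L = len(r)
        shifts = rng.integers(0, L, size=n_shuffles)
        cols = (np.arange(L)[None, :] - shifts[:, None]) % L
        shifted = r[cols][:, k]                      # (n_shuffles, n_kept)
        w = np.zeros((k.sum(), nbin))
        w[np.arange(k.sum()), b[k]] = dt
        shuf_num += shifted @ w

    with np.errstate(invalid="ignore", divide="ignore"):
        shuf_rates = np.where(visited[None, :], shuf_num / occ[None, :], np.nan)
    if use_smoothed:
        valid = visited.astype(float)
        den = convolve1d(valid, SMOOTH_KERNEL, mode="constant")
        smoothed = convolve1d(np.nan_to_num(shuf_rates), SMOOTH_KERNEL, axis=1, mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            shuf_rates = np.where(visited[None, :], smoothed / den[None, :], np.nan)

    pv = p[visited]
    rv = np.nan_to_num(shuf_rates[:, visited])
    lam = rv @ pv
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = rv / lam[:, None]
        terms = np.where(rv > 0, pv[None, :] * ratio * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    shuffle_si = terms.sum(axis=1)

    percentile = 100.0 * np.mean(shuffle_si < si_obs)
    is_pc = bool(si_obs > np.percentile(shuffle_si, 95.0))
    fields = identify_place_fields(rate_map) if rate_map is not None else []
    return PlaceCellResult(float(si_obs), shuffle_si, float(percentile), is_pc,
                           fields, rate_map)


# --------------------------------------------------------------------------
# place fields and QC
# --------------------------------------------------------------------------

def identify_place_fields(
    rate_map: RateMap,
    peak_fraction: float = 0.25,
    min_bins: int = 4,
    min_in_rate: float = 1.5,
    min_ratio: float = 2.5,
) -> list:
    """Contiguous-bin place fields from a smoothed rate map.

    A candidate is the maximal run of contiguous bins around the (remaining)
    peak with rate > peak_fraction x peak rate; it is accepted when longer
    than ``min_bins`` bins, with mean in-field rate > ``min_in_rate`` Hz and
    > ``min_ratio`` x the mean rate outside the field.  The search repeats on
    remaining bins for secondary fields.  Peak ties break to the lowest bin.
    """
    if not rate_map.smoothed:
        raise AnalysisError("place fields are defined on smoothed maps")
    rate = rate_map.rate.copy()
    available = np.isfinite(rate)
    fields: list[PlaceField] = []
    while available.any():
        masked = np.where(available, rate, -np.inf)
        peak = int(np.argmax(masked))        # argmax returns the lowest index on ties
        peak_rate = masked[peak]
        if peak_rate < min_in_rate:          # no further candidate can pass
            break
        thr = peak_fraction * peak_rate
        run_ok = available & (rate > thr)
        lo = peak
        while lo - 1 >= 0 and run_ok[lo - 1]:
            lo -= 1
        hi = peak
        while hi + 1 < len(rate) and run_ok[hi + 1]:
            hi += 1
        in_bins = np.arange(lo, hi + 1)
        out_mask = np.isfinite(rate_map.rate)
        out_mask[in_bins] = False
        in_rate = float(np.nanmean(rate_map.rate[in_bins]))
        out_rate = float(np.nanmean(rate_map.rate[out_mask])) if out_mask.any() else np.nan
        if (len(in_bins) > min_bins and in_rate > min_in_rate
                and np.isfinite(out_rate) and in_rate > min_ratio * out_rate):
            fields.append(PlaceField(int(lo), int(hi), peak, in_rate, out_rate))
        available[in_bins] = False
    return fields


def in_out_field_rates(rate_map: RateMap, fields) -> tuple[float, float]:
    """Mean rate over the union of fields vs. its complement (visited bins)."""
    in_mask = np.zeros(rate_map.nbin, bool)
    for f in fields:
        in_mask[f.start_bin:f.end_bin + 1] = True
    visited = np.isfinite(rate_map.rate)
    inside = rate_map.rate[in_mask & visited]
    outside = rate_map.rate[~in_mask & visited]
    return (float(inside.mean()) if inside.size else np.nan,
            float(outside.mean()) if outside.size else np.nan)


def qc_status(n_trials: int, mean_rate_hz: float,
              min_trials: int = 5, min_rate_hz: float = 0.1) -> QCStatus:
    """Inclusion flags for place-cell analysis."""
    reasons = []
    if n_trials < min_trials:
        reasons.append(f"trials<{min_trials}")
    if mean_rate_hz < min_rate_hz:
        reasons.append(f"rate<{min_rate_hz}Hz")
    return QCStatus(n_trials, mean_rate_hz, not reasons, reasons)


def qc_filter_cells(cells) -> list:
    """Apply :func:`qc_status` to a list of (n_trials, mean_rate_hz) records."""
    return [qc_status(n, r) for n, r in cells]
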