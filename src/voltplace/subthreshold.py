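"""Subthreshold dynamics: ramp, theta amplitude, and plateau-driven complex spikes.

All operations act on the spike-removed trace in spike-height units.  The
ramp is the <3 Hz component (zero-phase 201-tap Hamming FIR); theta is the
6-10 Hz band-passed component whose instantaneous amplitude is the analytic
signal magnitude (Hilbert transform).  Plateau-driven complex spikes are
long (>10 ms) depolarizations exceeding 40% of spike height on the 20 ms
boxcar-smoothed trace and carrying a burst of riding spikes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert, welch

from .core import Trace
from .filters import fir_zero_phase, moving_average, ramp_lowpass_taps, theta_bandpass_taps
from .spatial import RateMap, make_rate_map
from .spikes import SpikeTrain


@dataclass
class SubthresholdTrace:
    ramp: Trace                 # <3 Hz dVm, spike-height units
    theta_amplitude: Trace      # 6-10 Hz envelope, spike-height units
    spikes: SpikeTrain | None = None


@dataclass
class ComplexSpikeEvent:
    onset: int                  # sample, half-amplitude crossing
    offset: int                 # sample
    duration_ms: float
    amplitude: float            # smoothed-peak height, fraction of spike height
    n_riding_spikes: int


def extract_ramp(spike_removed: Trace) -> Trace:
    """Low-pass (<3 Hz) the spike-removed trace; unit passband gain at DC."""
    taps = ramp_lowpass_taps(spike_removed.sample_rate)
    return spike_removed.with_data(fir_zero_phase(taps, spike_removed.data))


def extract_theta(spike_removed: Trace, band=(6.0, 10.0)) -> Trace:
    """Theta-band amplitude: |analytic signal| of the 6-10 Hz band-passed trace."""
    taps = theta_bandpass_taps(spike_removed.sample_rate, band)
    filtered = fir_zero_phase(taps, spike_removed.data)
    return spike_removed.with_data(np.abs(hilbert(filtered)))


def extract_subthreshold(spike_removed: Trace, spikes: SpikeTrain | None = None) -> SubthresholdTrace:
    return SubthresholdTrace(extract_ramp(spike_removed), extract_theta(spike_removed), spikes)


def detect_complex_spikes(
    spike_removed: Trace,
    spikes: SpikeTrain,
    threshold: float = 0.4,
    min_duration_ms: float = 10.0,
    min_riding_spikes: int = 2,
    smooth_ms: float = 20.0,
) -> list:
    """Plateau-driven complex spikes from the smoothed spike-removed trace.

    Candidate events are excursions of the 20 ms boxcar-smoothed trace above
    ``threshold`` (fraction of spike height).  Event boundaries are refined
    at half of the excursion's smoothed peak — for a boxcar-smoothed
    rectangular depolarization the half-amplitude width equals the true
    duration — and an event is kept when it lasts longer than
    ``min_duration_ms`` and contains at least ``min_riding_spikes`` detected
    spikes ("atop spiking bursts").
    """
    fs = spike_removed.sample_rate
    if spike_removed.normalization == "spike_height":
        u = spike_removed.data
    else:
        if not np.isfinite(spikes.spike_height):
            raise ValueError("spike height undefined; cannot normalize")
        u = (spike_removed.data - spike_removed.data.mean()) / spikes.spike_height
    sm = moving_average(u, max(int(round(smooth_ms * fs / 1000.0)), 1))

    above = sm > threshold
    bounds = np.flatnonzero(np.diff(np.r_[False, above, False].astype(np.int8)))
    events: list[ComplexSpikeEvent] = []
    n = len(sm)
    for s, e in zip(bounds[::2], bounds[1::2]):
        peak = float(sm[s:e].max())
        half = 0.5 * peak
        a = int(s)
        while a - 1 >= 0 and sm[a - 1] >= half:
            a -= 1
        b = int(e) - 1
        while b + 1 < n and sm[b + 1] >= half:
            b += 1
        if events and a <= events[-1].offset:   # merge overlapping half-amplitude spans
            prev = events.pop()
            a = prev.onset
            peak = max(peak, prev.amplitude)
        duration_ms = (b - a + 1) / fs * 1000.0
        n_spk = int(np.count_nonzero((spikes.indices >= a) & (spikes.indices <= b)))
        if duration_ms > min_duration_ms and n_spk >= min_riding_spikes:
            events.append(ComplexSpikeEvent(a, b, duration_ms, peak, n_spk))
    return events


def complex_spike_rate_map(events, behavior, **map_kwargs) -> RateMap:
    """Occupancy-normalized complex-spike rate map from event onsets."""
    onsets = np.asarray([ev.onset for ev in events], dtype=np.int64)
    return make_rate_map(onsets, behavior, **map_kwargs)


def power_spectrum(trace: Trace, nperseg: int = 4096):
    """Welch power spectral density of a trace; returns (freqs_hz, psd)."""
    return welch(trace.data, fs=trace.sample_rate, nperseg=min(nperseg, len(trace.data)))
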