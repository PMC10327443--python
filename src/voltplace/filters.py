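"""Shared filter designs.

All subthreshold filters follow the same recipe: linear-phase FIR kernels
designed with a 200 ms Hamming window (201 taps at 1 kHz) and applied
forward-backward, so binned spatial maps carry no filter lag.  Spike-band
filters are zero-phase Butterworth high-passes.

Design notes
------------
* The "<3 Hz" ramp low-pass places its -6 dB edge at 2.5 Hz.  A 201-tap
  Hamming kernel has a transition width of ~16 Hz, so the edge placement is
  what decides how much theta (6-10 Hz) leaks into the ramp estimate: with
  the edge at 2.5 Hz the forward-backward amplitude ratio at 7 Hz is 0.043,
  i.e. theta is excluded from the ramp at the few-percent level.
* The theta band-pass uses the canonical [6, 10] Hz edges.  The same
  transition width means content a few Hz below the band is attenuated but
  not annihilated (amplitude ratio ~0.1 at 2 Hz after forward-backward
  filtering); this is a property of any 200 ms Hamming design.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

#: FIR kernel duration in seconds (201 taps at 1 kHz).
FIR_WINDOW_S = 0.2
#: -6 dB pass edge of the "<3 Hz" ramp low-pass, Hz.
RAMP_EDGE_HZ = 2.5
#: Theta band edges, Hz.
THETA_BAND_HZ = (6.0, 10.0)


def _fir_ntaps(sample_rate: float) -> int:
    n = int(round(FIR_WINDOW_S * sample_rate)) + 1
    return n if n % 2 == 1 else n + 1  # odd length -> symmetric, integer delay


def ramp_lowpass_taps(sample_rate: float = 1000.0) -> np.ndarray:
    """201-tap Hamming FIR low-pass for the <3 Hz subthreshold ramp."""
    return signal.firwin(_fir_ntaps(sample_rate), RAMP_EDGE_HZ, fs=sample_rate, window="hamming")


def theta_bandpass_taps(sample_rate: float = 1000.0, band=THETA_BAND_HZ) -> np.ndarray:
    """201-tap Hamming FIR band-pass for the 6-10 Hz theta rhythm."""
    return signal.firwin(
        _fir_ntaps(sample_rate), list(band), fs=sample_rate, window="hamming", pass_zero=False
    )


def fir_zero_phase(taps: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Apply an FIR kernel forward-backward (zero phase, |H|^2 magnitude)."""
    padlen = 3 * (len(taps) - 1)
    if len(x) <= padlen:
        raise ValueError(f"record too short for filter: {len(x)} samples <= padlen {padlen}")
    return signal.filtfilt(taps, [1.0], x)


def butter_highpass_sos(cutoff_hz: float, sample_rate: float, order: int = 4) -> np.ndarray:
    return signal.butter(order, cutoff_hz, btype="highpass", fs=sample_rate, output="sos")


def highpass_zero_phase(x: np.ndarray, cutoff_hz: float, sample_rate: float,
                        order: int = 4, axis: int = -1) -> np.ndarray:
    sos = butter_highpass_sos(cutoff_hz, sample_rate, order)
    return signal.sosfiltfilt(sos, x, axis=axis)


def moving_average(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered boxcar smoothing with edge replication."""
    from scipy.ndimage import uniform_filter1d

    return uniform_filter1d(np.asarray(x, float), size=int(window_samples), mode="nearest")
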