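"""Photobleach correction.

Fluorophores bleach under continuous illumination, producing a slow
multiplicative decay of the whole recording.  Correction divides the movie
(or trace) by a single-exponential-plus-offset fit to the frame-mean
fluorescence, leaving a record with global mean ~1.  Motion correction is
assumed to have been applied upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import Trace
from .errors import AnalysisError

log = logging.getLogger(__name__)


@dataclass
class BleachModel:
    amplitude: float       # fluorescence units
    tau_s: float           # decay constant, > 0
    offset: float          # fluorescence units
    fallback: bool = False # True when constant normalization was used

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        if self.fallback:
            return np.full_like(np.asarray(t, float), self.amplitude + self.offset)
        return self.amplitude * np.exp(-np.asarray(t, float) / self.tau_s) + self.offset


def _initial_guess(t: np.ndarray, y: np.ndarray):
    """Log-linear initialization for a * exp(-t/tau) + c."""
    n = len(y)
    head = y[: max(n // 10, 1)].mean()
    tail = y[-max(n // 10, 1):].mean()
    c0 = tail - 0.05 * (head - tail)
    resid = y - c0
    pos = resid > 0.01 * max(abs(head - c0), 1e-12)
    if pos.sum() > 10 and head != tail:
        slope = np.polyfit(t[pos], np.log(resid[pos]), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else t[-1]
    else:
        tau0 = t[-1]
    return head - c0, float(np.clip(tau0, 1e-3, 100 * t[-1])), c0


def _fit_exponential(t: np.ndarray, y: np.ndarray) -> BleachModel:
    a0, tau0, c0 = _initial_guess(t, y)
    if abs(a0) < 1e-12 * max(abs(y.mean()), 1e-300):
        a0 = 0.01 * abs(y.mean()) + 1e-12
    try:
        popt, _ = curve_fit(
            lambda tt, a, tau, c: a * np.exp(-tt / tau) + c,
            t, y, p0=(a0, tau0, c0), maxfev=10000,
            bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
        )
        model = BleachModel(*popt)
    except RuntimeError:
        return BleachModel(amplitude=float(y.mean()), tau_s=np.inf, offset=0.0, fallback=True)
    # diverging fit: curve essentially flat over the record -> constant normalization
    curve = model.evaluate(t)
    mean_curve = curve.mean()
    if mean_curve <= 0 or np.ptp(curve) / abs(mean_curve) < 1e-4:
        log.warning("bleach fit degenerate (tau=%.3g s); using constant normalization", model.tau_s)
        return BleachModel(amplitude=float(y.mean()), tau_s=np.inf, offset=0.0, fallback=True)
    return model


def correct_photobleach(record, sample_rate: float | None = None):
    """Divide a movie (T, H, W array) or :class:`Trace` by its fitted bleach curve.

    Returns ``(corrected, BleachModel)``.  The fit is least squares on the
    frame-mean time series (the trace itself for 1-D input).
    """
    if isinstance(record, Trace):
        fs = record.sample_rate
        y = record.data
        is_trace = True
    else:
        arr = np.asarray(record, dtype=float)
        if sample_rate is None:
            raise ValueError("sample_rate required for array input")
        fs = sample_rate
        y = arr.mean(axis=tuple(range(1, arr.ndim)))
        is_trace = False

    if len(y) < fs:  # need >= 1 s to constrain a decay
        raise AnalysisError("record shorter than 1 s")
    if y.mean() <= 0:
        raise AnalysisError("mean fluorescence must be positive")

    t = np.arange(len(y)) / fs
    model = _fit_exponential(t, y)
    curve = model.evaluate(t)
    if np.any(curve <= 0):
        raise AnalysisError("fitted bleach curve is not strictly positive")

    if is_trace:
        return record.with_data(record.data / curve, normalization="bleach_corrected"), model
    shape = (len(y),) + (1,) * (arr.ndim - 1)
    return arr / curve.reshape(shape), model
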