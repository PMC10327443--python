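"""Activity-based segmentation of voltage-imaging movies (PCA/ICA).

Spiking is assumed uncorrelated with out-of-focus background while sharing a
spatial footprint with the cell's subthreshold signal, so masks are derived
from the movie after a 100 Hz high-pass (spike band only): per cell window,
pixels are reduced with PCA, unmixed with temporal ICA, and each component's
spatial loading map is thresholded into a mask.  Components are ranked and
accepted by the temporal skewness of their source (spikes are rare, large,
positive deflections; noise components have skewness ~ sqrt(6/T)).  Masks
are then applied to the *unfiltered* movie to extract traces, preserving
subthreshold content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA, FastICA

from .core import Trace
from .errors import AnalysisError, InvalidConfigError
from .filters import highpass_zero_phase

#: Acceptance threshold on temporal skewness.  The sampling SD of skewness on
#: Gaussian noise is ~sqrt(6/T) (~0.045 at T=3000 frames), so 0.5 rejects
#: noise components by a wide margin while spiking components score >1.
DEFAULT_SKEW_THRESHOLD = 0.5


@dataclass
class SpatialMask:
    weights: np.ndarray         # (h, w) pixel weights within the window, 0 outside support
    window: tuple               # (r0, r1, c0, c1) in frame coordinates
    frame_shape: tuple
    skewness: float = np.nan
    accepted: bool = True
    time_course: np.ndarray | None = None

    def full_frame_weights(self) -> np.ndarray:
        out = np.zeros(self.frame_shape)
        r0, r1, c0, c1 = self.window
        out[r0:r1, c0:c1] = self.weights
        return out


def segment_movie(
    movie: np.ndarray,
    sample_rate: float,
    n_components: int = 5,
    windows=None,
    highpass_hz: float = 100.0,
    skew_threshold: float = DEFAULT_SKEW_THRESHOLD,
    mask_sd: float = 3.0,
    seed: int = 0,
    max_retries: int = 3,
) -> list:
    """PCA/ICA segmentation of a (T, H, W) movie into per-cell spatial masks.

    ``windows`` is a list of (r0, r1, c0, c1) single-cell sub-movie rectangles
    (whole frame when omitted).  Masks are ranked by temporal skewness;
    ``accepted`` marks components above ``skew_threshold``.
    """
    movie = np.asarray(movie, dtype=float)
    n_frames, h, w = movie.shape
    if sample_rate < 2 * highpass_hz:
        raise InvalidConfigError("frame rate too low for the spike-band high-pass")
    if windows is None:
        windows = [(0, h, 0, w)]

    masks: list[SpatialMask] = []
    for win in windows:
        r0, r1, c0, c1 = win
        sub = movie[:, r0:r1, c0:c1].reshape(n_frames, -1)
        npix = sub.shape[1]
        if n_components > min(n_frames, npix):
            raise InvalidConfigError("n_components exceeds frames or pixels")
        hp = highpass_zero_phase(sub - sub.mean(axis=0), highpass_hz, sample_rate,
                                 order=4, axis=0)

        pca = PCA(n_components=n_components, random_state=seed)
        scores = pca.fit_transform(hp)
        sources = _run_ica(scores, seed, max_retries)

        for k in range(sources.shape[1]):
            s = sources[:, k]
            sk = stats.skew(s)
            if sk < 0:  # orient so spikes deflect positive
                s, sk = -s, -sk
            # spatial loading: regression of high-passed pixels on the source
            wmap = hp.T @ s / len(s)
            # robust SD so the footprint's own pixels do not inflate the threshold
            scale = 1.4826 * np.median(np.abs(wmap - np.median(wmap)))
            support = wmap > mask_sd * (scale if scale > 0 else wmap.std())
            weights = np.where(support, wmap, 0.0).reshape(r1 - r0, c1 - c0)
            accepted = bool(sk > skew_threshold) and bool((weights > 0).any())
            masks.append(SpatialMask(weights, win, (h, w), float(sk), accepted, s))

    masks.sort(key=lambda m: m.skewness, reverse=True)
    return masks


def _run_ica(scores: np.ndarray, seed: int, max_retries: int) -> np.ndarray:
    import warnings as _warnings
    from sklearn.exceptions import ConvergenceWarning

    last_err = None
    for attempt in range(max_retries):
        ica = FastICA(n_components=scores.shape[1], random_state=seed + attempt,
                      max_iter=2000, tol=1e-3, whiten="unit-variance")
        with _warnings.catch_warnings():
            _warnings.simplefilter("error", ConvergenceWarning)
            try:
                return ica.fit_transform(scores)
            except ConvergenceWarning as err:  # retry with a fresh seed
                last_err = err
    raise AnalysisError(f"ICA failed to converge after {max_retries} seeds: {last_err}")


def extract_traces(movie: np.ndarray, masks: list, sample_rate: float = 1000.0) -> list:
    """Weighted pixel averages of the *unfiltered* movie under each mask."""
    movie = np.asarray(movie, dtype=float)
    traces = []
    for i, mask in enumerate(masks):
        if movie.shape[1:] != mask.frame_shape:
            raise AnalysisError("movie and mask geometry mismatch")
        r0, r1, c0, c1 = mask.window
        wts = mask.weights
        total = wts.sum()
        if total <= 0:
            raise AnalysisError("mask has no positive weights")
        sub = movie[:, r0:r1, c0:c1].reshape(movie.shape[0], -1)
        data = sub @ wts.ravel() / total
        traces.append(Trace(data, sample_rate=sample_rate, cell_id=f"cell{i}"))
    return traces
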