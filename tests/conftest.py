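import numpy as np
import pytest
from hypothesis import settings

import voltplace as vp

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def place_session():
    """One moderate place-cell session with ground truth, shared across tests."""
    cfg = vp.SynthConfig(n_trials=10, rng_seed=42)
    behavior = vp.simulate_behavior(cfg)
    trace, gt = vp.simulate_voltage_trace(cfg, behavior)
    corrected, bleach = vp.correct_photobleach(trace)
    spikes = vp.detect_spikes(corrected)
    return {
        "config": cfg,
        "behavior": behavior,
        "trace": trace,
        "ground_truth": gt,
        "corrected": corrected,
        "bleach": bleach,
        "spikes": spikes,
    }


@pytest.fixture(scope="session")
def dvm_session(place_session):
    """Spike-removed and normalized signals derived from the shared session."""
    corrected = place_session["corrected"]
    spikes = place_session["spikes"]
    removed = vp.remove_spikes(corrected, spikes)
    removed_u = removed.with_data(
        (removed.data - removed.data.mean()) / spikes.spike_height,
        normalization="spike_height",
    )
    return {
        **place_session,
        "removed": removed,
        "removed_u": removed_u,
        "dvm": vp.normalize_and_dvm(corrected, spikes),
    }


def match_events(detected, truth, tol_samples=1):
    """Greedy one-to-one matching; returns (n_matched, recall, precision)."""
    truth = np.sort(np.asarray(truth))
    used = np.zeros(len(truth), bool)
    matched = 0
    for d in np.sort(np.asarray(detected)):
        j = np.searchsorted(truth, d)
        for k in (j - 1, j, j + 1):
            if 0 <= k < len(truth) and not used[k] and abs(truth[k] - d) <= tol_samples:
                used[k] = True
                matched += 1
                break
    recall = matched / len(truth) if len(truth) else np.nan
    precision = matched / len(detected) if len(detected) else np.nan
    return matched, recall, precision
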