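"""Top-level pipeline runner: configuration -> synthetic session -> report.

The runner wires the stages together for a whole session: simulate (or
load), bleach-correct, detect spikes, derive the subthreshold signals,
build epoch maps, run the place-cell test, and quantify the protocol
(plasticity metrics, F-I curve, or synaptic classification).  All
randomness flows from a single top-level seed through named substreams, so
a rerun with the same config is bit-identical (modulo the timestamp field).
"""

from __future__ import annotations

import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import yaml

from . import io as vio
from .errors import InvalidConfigError
from .preprocess import correct_photobleach
from .protocols import EpochedSession, classify_synaptic_response, fi_analysis, plasticity_metrics
from .spatial import binned_rate_series, place_cell_test, make_rate_map, qc_status
from .spikes import detect_spikes, normalize_and_dvm, remove_spikes
from .subthreshold import detect_complex_spikes, extract_theta
from .synthetic import SynthConfig, simulate_session

log = logging.getLogger("voltplace")

DEFAULT_CONFIG = {
    "seed": 0,
    "mode": "plasticity",
    "simulate": {},
    "synth": {},
    "placecells": {"n_shuffles": 1000, "window_ms": 100.0},
    "spikes": {"threshold_multiplier": 4.0},
}


def load_config(source) -> dict:
    if isinstance(source, (str, Path)):
        source = yaml.safe_load(Path(source).read_text())
    cfg = {**DEFAULT_CONFIG, **(source or {})}
    for key in ("simulate", "synth", "placecells", "spikes"):
        cfg[key] = {**DEFAULT_CONFIG.get(key, {}), **(cfg.get(key) or {})}
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: dict) -> None:
    if cfg["mode"] not in ("plasticity", "fi", "synaptic"):
        raise InvalidConfigError(f"unknown pipeline mode {cfg['mode']!r}")
    if cfg["placecells"]["n_shuffles"] < 1:
        raise InvalidConfigError("n_shuffles must be >= 1")
    if cfg["spikes"]["threshold_multiplier"] <= 0:
        raise InvalidConfigError("threshold_multiplier must be > 0")


def run_pipeline(config, out_dir=None) -> dict:
    """Execute the configured session end-to-end and return the report dict."""
    cfg = load_config(config)
    seed = int(cfg["seed"])
    ss = np.random.SeedSequence(seed)
    sim_rng, shuffle_seed = np.random.default_rng(ss.spawn(1)[0]), seed + 1

    synth = replace(SynthConfig(**cfg["synth"]), rng_seed=seed)
    session = simulate_session(cfg["mode"], synth, rng=sim_rng, **cfg["simulate"])

    report: dict = {
        "version": 1,
        "parameters": {"seed": seed, "mode": cfg["mode"], "synth": vars(synth),
                       "simulate": cfg["simulate"], "placecells": cfg["placecells"],
                       "spikes": cfg["spikes"]},
        "generated_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "cells": {},
    }

    for trace in session.traces:
        corrected, bleach = correct_photobleach(trace)
        spikes = detect_spikes(corrected, **cfg["spikes"])
        cell: dict = {
            "bleach": {"tau_s": bleach.tau_s, "fallback": bleach.fallback},
            "n_spikes": len(spikes),
            "snr": spikes.snr,
            "spike_height": spikes.spike_height,
        }
        if len(spikes) == 0:
            cell["flag"] = "no spikes detected"
            report["cells"][trace.cell_id] = cell
            continue
        dvm = normalize_and_dvm(corrected, spikes)
        removed = remove_spikes(corrected, spikes)
        removed_u = removed.with_data(
            (removed.data - removed.data.mean()) / spikes.spike_height,
            normalization="spike_height",
        )
        events = detect_complex_spikes(removed_u, spikes)
        cell["complex_spikes"] = {
            "n_events": len(events),
            "mean_duration_ms": float(np.mean([e.duration_ms for e in events])) if events else None,
            "mean_amplitude": float(np.mean([e.amplitude for e in events])) if events else None,
        }

        if cfg["mode"] == "plasticity":
            behavior = session.behavior
            theta = extract_theta(removed_u)
            epoched = EpochedSession(session.epoch_of_trial, session.stim_location_cm,
                                     session.stim_events, synth.sample_rate)
            metrics = plasticity_metrics(epoched, spikes, behavior, dvm=dvm, theta=theta)
            cell["plasticity"] = {
                "anticipatory_rate_hz": metrics.anticipatory_rate_hz,
                "backward_shift_cm": metrics.backward_shift_cm,
                "in_field_rate_hz": metrics.in_field_rate_hz,
                "out_field_rate_hz": metrics.out_field_rate_hz,
                "dvm_window": metrics.dvm_window,
                "theta_window": metrics.theta_window,
            }
            post_trials = epoched.trials_in("Post")
            mask = behavior.trial_mask(post_trials)
            qc = qc_status(len(post_trials),
                           len(spikes) / (len(behavior) / synth.sample_rate))
            cell["qc"] = {"included": qc.included, "reasons": qc.reasons}
            if qc.included:
                trials = binned_rate_series(spikes, behavior,
                                            window_ms=cfg["placecells"]["window_ms"],
                                            sample_mask=mask)
                post_map = make_rate_map(spikes, behavior, sample_mask=mask)
                pc = place_cell_test(trials, n_shuffles=cfg["placecells"]["n_shuffles"],
                                     seed=shuffle_seed, rate_map=post_map)
                cell["place_cell"] = {
                    "si_bits_per_spike": pc.si,
                    "percentile": pc.percentile,
                    "is_place_cell": pc.is_place_cell,
                    "n_fields": len(pc.fields),
                }
        elif cfg["mode"] == "fi":
            gt = session.ground_truth
            curve = fi_analysis(spikes, gt.extra["schedule"],
                                stim_duration_ms=gt.extra["stim_duration_ms"],
                                record_samples=len(trace))
            cell["fi"] = {
                "intensities": curve.intensities,
                "rates_hz": curve.rates_hz,
                "spontaneous_rate_hz": curve.spontaneous_rate_hz,
                "slope": curve.slope,
            }
        elif cfg["mode"] == "synaptic":
            onsets = [ev.onset_sample for ev in session.stim_events]
            cls = classify_synaptic_response(corrected, spikes, onsets)
            cell["synaptic"] = {
                "label": cls.label,
                "auc": cls.auc,
                "n_evoked_trials": cls.n_evoked_trials,
                "latencies_ms": cls.evoked.latencies_ms,
            }
        report["cells"][trace.cell_id] = cell
        log.info("cell %s: %d spikes, snr %.2f", trace.cell_id, len(spikes), spikes.snr)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        vio.write_json(report, out / "report.json")
        if session.behavior is not None:
            vio.behavior_to_csv(session.behavior, out / "behavior.csv")
        vio.traces_to_csv(session.traces, out / "traces.csv")
        vio.ground_truth_to_json(session.ground_truth, out / "ground_truth.json")
    return report
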