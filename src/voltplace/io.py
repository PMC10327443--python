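"""Readers and writers for the pipeline's plain formats.

Traces and behavior travel as CSV, movies as multi-page TIFF or HDF5, masks
as HDF5, ground truth and reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .core import BehaviorTrack, Trace
from .segmentation import SpatialMask
from .spikes import SpikeTrain


def traces_to_csv(traces: list, path) -> None:
    n = len(traces[0])
    cols = {"time_s": np.arange(n) / traces[0].sample_rate}
    for tr in traces:
        cols[tr.cell_id] = tr.data
    pd.DataFrame(cols).to_csv(path, index=False)


def traces_from_csv(path, sample_rate: float | None = None) -> list:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = sample_rate or float(round(1.0 / np.median(np.diff(t))))
    return [Trace(df[c].to_numpy(float), sample_rate=fs, cell_id=c)
            for c in df.columns if c != "time_s"]


def behavior_to_csv(behavior: BehaviorTrack, path) -> None:
    behavior.to_dataframe().to_csv(path, index=False)


def behavior_from_csv(path, track_length: float = 180.0) -> BehaviorTrack:
    return BehaviorTrack.from_dataframe(pd.read_csv(path), track_length=track_length)


def spikes_to_csv(spike_trains: list, path) -> None:
    rows = []
    for st in spike_trains:
        for s in st.indices:
            rows.append({"cell_id": st.cell_id, "sample_index": int(s),
                         "time_s": s / st.sample_rate})
    pd.DataFrame(rows, columns=["cell_id", "sample_index", "time_s"]).to_csv(path, index=False)


def spikes_summary_json(spike_trains: list, path) -> None:
    payload = {
        st.cell_id: {
            "n_spikes": int(len(st)),
            "spike_height": None if not np.isfinite(st.spike_height) else float(st.spike_height),
            "noise_sigma": float(st.noise_sigma),
            "snr": None if not np.isfinite(st.snr) else float(st.snr),
            "threshold_multiplier": float(st.threshold_multiplier),
        }
        for st in spike_trains
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def movie_to_tiff(movie: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(movie, np.float32))


def movie_from_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), float)


def movie_to_hdf5(movie: np.ndarray, path, dataset: str = "movie") -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset(dataset, data=np.asarray(movie, np.float32), compression="gzip")


def movie_from_hdf5(path, dataset: str = "movie") -> np.ndarray:
    with h5py.File(path, "r") as f:
        return np.asarray(f[dataset], float)


def masks_to_hdf5(masks: list, path) -> None:
    with h5py.File(path, "w") as f:
        for k, m in enumerate(masks):
            g = f.create_group(f"mask{k}")
            g.create_dataset("weights", data=m.weights)
            g.attrs["window"] = m.window
            g.attrs["frame_shape"] = m.frame_shape
            g.attrs["skewness"] = m.skewness
            g.attrs["accepted"] = m.accepted


def masks_from_hdf5(path) -> list:
    masks = []
    with h5py.File(path, "r") as f:
        for k in sorted(f.keys(), key=lambda s: int(s[4:])):
            g = f[k]
            masks.append(SpatialMask(
                weights=np.asarray(g["weights"]),
                window=tuple(int(x) for x in g.attrs["window"]),
                frame_shape=tuple(int(x) for x in g.attrs["frame_shape"]),
                skewness=float(g.attrs["skewness"]),
                accepted=bool(g.attrs["accepted"]),
            ))
    return masks


def rate_map_to_csv(rate_map, path) -> None:
    pd.DataFrame({
        "bin_start_cm": rate_map.bin_edges[:-1],
        "occupancy_s": rate_map.occupancy_s,
        "count": rate_map.counts,
        "rate_hz": rate_map.rate,
    }).to_csv(path, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return None if not np.isfinite(obj) else float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, np.bool_):
            return bool(obj)
        return super().default(obj)


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder) + "\n")


def ground_truth_to_json(gt, path) -> None:
    write_json({
        "true_spike_times": gt.true_spike_times,
        "true_plateau_intervals": gt.true_plateau_intervals,
        "field_center": gt.field_center,
        "field_width": gt.field_width,
        "psp_events": [vars(e) for e in gt.psp_events],
        "bleach_tau": None if not np.isfinite(gt.bleach_tau) else gt.bleach_tau,
        "epoch_labels": gt.epoch_labels,
        "extra": {k: v for k, v in gt.extra.items() if not isinstance(v, (list, np.ndarray)) or np.size(v) < 10000},
    }, path)
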