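"""File contracts shared across the pipeline.

WAV audio (float32 or PCM16) with a JSON sidecar carrying the full scene
spec and event times; CSV block manifests; HDF5 epoch containers laid out
as ``/subject_XX/{scene,appearance}/{condition}/data`` with rate/window
attributes; behavioural tables as long-format CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .scenes import SceneSpec, SourceSpec, Waveform
from .simulate import TrialTensor

__all__ = [
    "write_wav",
    "read_wav",
    "scene_to_dict",
    "scene_from_dict",
    "write_scene_json",
    "read_scene_json",
    "save_dataset",
    "load_dataset",
    "behavior_to_csv",
    "behavior_from_csv",
]


def write_wav(path, w: Waveform, pcm16: bool = False) -> None:
    x = np.asarray(w.samples)
    if pcm16:
        wavfile.write(path, int(w.rate_hz), np.round(x * 32767).astype(np.int16))
    else:
        wavfile.write(path, int(w.rate_hz), x.astype(np.float32))


def read_wav(path) -> Waveform:
    rate, x = wavfile.read(path)
    if x.dtype == np.int16:
        x = x.astype(float) / 32767.0
    return Waveform(np.asarray(x, dtype=float), int(rate))


def scene_to_dict(spec: SceneSpec) -> dict:
    return dataclasses.asdict(spec)


def scene_from_dict(d: dict) -> SceneSpec:
    def _src(s):
        if s is None:
            return None
        s = dict(s)
        if s.get("gap_range_ms") is not None:
            s["gap_range_ms"] = tuple(s["gap_range_ms"])
        s["gap_sequence_ms"] = tuple(s.get("gap_sequence_ms") or ())
        return SourceSpec(**s)

    d = dict(d)
    d["sources"] = tuple(_src(s) for s in d["sources"])
    d["appearing_source"] = _src(d.get("appearing_source"))
    return SceneSpec(**d)


def write_scene_json(path, spec: SceneSpec, events: dict | None = None) -> None:
    payload = {"scene": scene_to_dict(spec)}
    if events:
        payload["events"] = events
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_scene_json(path) -> SceneSpec:
    payload = json.loads(Path(path).read_text())
    return scene_from_dict(payload["scene"])


def _json_safe_labels(labels: dict) -> str:
    return json.dumps(labels, default=lambda o: list(o) if hasattr(o, "__iter__") else str(o))


def save_dataset(path, dataset: dict) -> None:
    """Write a simulated dataset (see :func:`scenemeg.simulate.simulate_dataset`)."""
    with h5py.File(path, "w") as f:
        f.attrs["rate_hz"] = dataset["rate_hz"]
        for subj in dataset["subjects"]:
            g = f.create_group(f"subject_{subj['id']:02d}")
            g.attrs["group"] = subj["group"]
            g.attrs["gain"] = subj["gain"]
            g.attrs["latency_shift_ms"] = subj["latency_shift_ms"]
            for lock in ("scene", "appearance"):
                gl = g.create_group(lock)
                for cond, tt in subj[lock].items():
                    gc = gl.create_group(cond)
                    gc.create_dataset("data", data=tt.data, compression="gzip")
                    gc.attrs["rate_hz"] = tt.rate_hz
                    gc.attrs["t0_ms"] = tt.t0_ms
                    gc.attrs["lock"] = tt.lock
                    gc.attrs["labels"] = _json_safe_labels(tt.labels)


def load_dataset(path) -> dict:
    subjects = []
    with h5py.File(path, "r") as f:
        rate = float(f.attrs["rate_hz"])
        for name in sorted(k for k in f.keys() if k.startswith("subject_")):
            g = f[name]
            subj = dict(
                id=int(name.split("_")[1]),
                group=str(g.attrs["group"]),
                gain=float(g.attrs["gain"]),
                latency_shift_ms=float(g.attrs["latency_shift_ms"]),
                scene={},
                appearance={},
            )
            for lock in ("scene", "appearance"):
                for cond in g[lock]:
                    gc = g[lock][cond]
                    subj[lock][cond] = TrialTensor(
                        np.asarray(gc["data"]),
                        float(gc.attrs["rate_hz"]),
                        float(gc.attrs["t0_ms"]),
                        str(gc.attrs["lock"]),
                        json.loads(gc.attrs["labels"]),
                    )
            subjects.append(subj)
    return dict(rate_hz=rate, subjects=subjects, sensors=None)


def behavior_to_csv(path, table: pd.DataFrame) -> None:
    t = table.copy()
    t["detection_times_ms"] = t["detection_times_ms"].apply(json.dumps)
    t.to_csv(path, index=False)


def behavior_from_csv(path) -> pd.DataFrame:
    t = pd.read_csv(path)
    t["detection_times_ms"] = t["detection_times_ms"].apply(json.loads)
    return t
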