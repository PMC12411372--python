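"""HDF5 / CSV / JSON serialization for recordings and results."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .synthetic_data import RecordingSet


def save_recording(path, rec: RecordingSet) -> None:
    """Write a RecordingSet to HDF5 (datasets /waveforms, /labels/*, /time;
    attrs: sample_rate, provenance JSON)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("waveforms", data=rec.waveforms, compression="gzip")
        lab = f.create_group("labels")
        lab.create_dataset("rate", data=rec.rate)
        lab.create_dataset("polarity", data=rec.polarity)
        f.create_dataset("time", data=rec.time)
        on = f.create_group("onsets")
        for rate, idx in rec.onsets.items():
            on.create_dataset(f"{rate:.6f}", data=idx)
        f.attrs["sample_rate"] = rec.sample_rate
        f.attrs["provenance"] = json.dumps(rec.provenance)


def load_recording(path) -> RecordingSet:
    with h5py.File(path, "r") as f:
        return RecordingSet(
            waveforms=f["waveforms"][()],
            rate=f["labels/rate"][()],
            polarity=f["labels/polarity"][()],
            time=f["time"][()],
            sample_rate=float(f.attrs["sample_rate"]),
            onsets={float(k): v[()] for k, v in f["onsets"].items()},
            provenance=json.loads(f.attrs["provenance"]),
        )


def load_config(path) -> dict:
    """Read a YAML or JSON pipeline configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def dump_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default, allow_nan=True))
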