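"""HDF5 container I/O for recordings and epoch sets.

The canonical on-disk format is a documented HDF5 layout (see
docs/methods.md): ``/signal`` (channels x samples, uV), ``/markers``
(N x 2 int: sample index, trial index), JSON-encoded trial labels and
provenance in attributes.  A JSON ground-truth sidecar can be written
next to a recording for interchange with other tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .preprocess import DEFAULT_CHANNELS, EpochSet, RawRecording

__all__ = [
    "save_recording",
    "load_recording",
    "read_recording",
    "save_epochs",
    "load_epochs",
]


def save_recording(
    path, rec: RawRecording, sidecar: bool = False, provenance: dict | None = None
) -> None:
    """Write a recording to the HDF5 container (optionally + JSON sidecar)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal)
        f.create_dataset(
            "markers", data=np.array(rec.markers, dtype=np.int64).reshape(-1, 2)
        )
        f.attrs["kind"] = "recording"
        f.attrs["sample_rate"] = rec.sample_rate
        f.attrs["channel_names"] = list(rec.channel_names)
        f.attrs["trial_info"] = json.dumps({str(k): v for k, v in rec.trial_info.items()})
        f.attrs["metadata"] = json.dumps(rec.metadata, default=str)
        if provenance is not None:
            f.attrs["provenance"] = json.dumps(provenance, sort_keys=True)
    if sidecar:
        side = path.with_suffix(path.suffix + ".truth.json")
        with open(side, "w") as fh:
            json.dump({str(k): v for k, v in rec.trial_info.items()}, fh, indent=1)


def load_recording(path, required_channels=None) -> RawRecording:
    """Read a recording container; verify required channels are present."""
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "recording":
            raise ValueError(f"{path} is not a recording container")
        channel_names = tuple(str(c) for c in f.attrs["channel_names"])
        if required_channels:
            missing = [c for c in required_channels if c not in channel_names]
            if missing:
                raise ValueError(
                    f"recording is missing required channels: {', '.join(missing)}"
                )
        markers = [(int(s), int(t)) for s, t in f["markers"][()]]
        trial_info = {
            int(k): v for k, v in json.loads(f.attrs["trial_info"]).items()
        }
        return RawRecording(
            signal=f["signal"][()],
            sample_rate=float(f.attrs["sample_rate"]),
            channel_names=channel_names,
            markers=markers,
            trial_info=trial_info,
            metadata=json.loads(f.attrs["metadata"]),
        )


def read_recording(path, required_channels=DEFAULT_CHANNELS) -> RawRecording:
    """Read a recording from a supported on-disk format.

    Currently the package container (``.h5``/``.hdf5``).  Channels are
    checked against the canonical montage; missing ones are named in the
    error.
    """
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return load_recording(path, required_channels=required_channels)
    raise ValueError(
        f"unsupported recording format {suffix!r}; use the HDF5 container"
    )


def save_epochs(path, epochs: EpochSet, provenance: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("kept_mask", data=epochs.kept_mask)
        f.attrs["kind"] = "epochs"
        f.attrs["sample_rate"] = epochs.sample_rate
        f.attrs["window"] = list(epochs.window)
        f.attrs["channel_names"] = list(epochs.channel_names)
        f.attrs["labels"] = json.dumps(epochs.labels)
        if epochs.rejection_report is not None:
            f.attrs["rejection_report"] = json.dumps(epochs.rejection_report)
        if provenance is not None:
            f.attrs["provenance"] = json.dumps(provenance, sort_keys=True)


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "epochs":
            raise ValueError(f"{path} is not an epochs container")
        report = f.attrs.get("rejection_report")
        return EpochSet(
            data=f["data"][()],
            sample_rate=float(f.attrs["sample_rate"]),
            window=tuple(f.attrs["window"]),
            labels=json.loads(f.attrs["labels"]),
            channel_names=tuple(str(c) for c in f.attrs["channel_names"]),
            kept_mask=f["kept_mask"][()],
            rejection_report=json.loads(report) if report else None,
        )
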