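"""HDF5/CSV containers for epochs, spectrogram frames and subject metadata."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .ersp import FrameSet
from .synth import EpochSet, SubjectRecord

__all__ = [
    "write_epochs", "read_epochs",
    "write_subjects", "read_subjects",
    "write_frames", "read_frames",
]


def write_epochs(path: str | Path, epochs: Mapping[str, EpochSet]) -> None:
    """Per-subject epoch arrays under /subjects/<id>/epochs, with the shared
    time axis and channel order at the file root."""
    with h5py.File(path, "w") as f:
        first = next(iter(epochs.values()))
        f.create_dataset("time_ms", data=first.time_ms)
        f.create_dataset("channels",
                         data=np.array(first.channel_names, dtype="S8"))
        f.attrs["sfreq"] = first.sfreq
        grp = f.create_group("subjects")
        for sid in sorted(epochs):
            es = epochs[sid]
            grp.create_dataset(f"{sid}/epochs", data=es.data)


def read_epochs(path: str | Path) -> dict[str, EpochSet]:
    with h5py.File(path, "r") as f:
        time_ms = f["time_ms"][:]
        channels = tuple(c.decode() for c in f["channels"][:])
        sfreq = float(f.attrs["sfreq"])
        out = {}
        for sid in f["subjects"]:
            out[sid] = EpochSet(
                data=f[f"subjects/{sid}/epochs"][:],
                time_ms=time_ms, channel_names=channels,
                sfreq=sfreq, subject_id=sid)
    return out


def write_subjects(path: str | Path, subjects: Sequence[SubjectRecord]) -> None:
    pd.DataFrame([{
        "subject_id": s.subject_id,
        "group": s.group,
        "age": s.age,
        "alpha_offset_z": s.alpha_offset_z,
        "theta_offset_z": s.theta_offset_z,
        "seed": s.seed,
    } for s in subjects]).to_csv(path, index=False)


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    return [SubjectRecord(
        subject_id=str(r.subject_id), group=str(r.group), age=float(r.age),
        alpha_offset_z=float(getattr(r, "alpha_offset_z", 0.0)),
        theta_offset_z=float(getattr(r, "theta_offset_z", 0.0)),
        seed=int(getattr(r, "seed", 0)),
    ) for r in df.itertuples(index=False)]


def write_frames(path: str | Path, frames: FrameSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=frames.frames)
        f.create_dataset("labels", data=np.array(frames.labels, dtype="S8"))
        f.create_dataset("subject_ids",
                         data=np.array(frames.subject_ids, dtype="S16"))
        f.create_dataset("freqs_hz", data=frames.freqs)
        f.create_dataset("time_ms", data=frames.time_centres)
        f.create_dataset("channels",
                         data=np.array(frames.channel_names, dtype="S8"))


def read_frames(path: str | Path) -> FrameSet:
    with h5py.File(path, "r") as f:
        return FrameSet(
            frames=f["frames"][:],
            labels=np.array([b.decode() for b in f["labels"][:]]),
            subject_ids=np.array([b.decode() for b in f["subject_ids"][:]]),
            freqs=f["freqs_hz"][:],
            time_centres=f["time_ms"][:],
            channel_names=tuple(c.decode() for c in f["channels"][:]),
        )
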