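"""Session and embedding file formats.

One HDF5 file per session: a units table (metadata plus ragged spike
times), the four-paw velocity table at 10 ms, the 500 ms label table, and
header attributes (duration, schema version, provenance). Spike times are
stored in seconds at source resolution; binning always happens downstream.
A CSV export mode writes the same tables as plain text for
interoperability. Embeddings are stored as HDF5 tables (coords,
eigenvalues, kept_time_index, params).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .manifold import Embedding
from .session import Session, make_units_table

SCHEMA_VERSION = 1
_STR = h5py.string_dtype(encoding="utf-8")


def write_session(session: Session, path: str | Path) -> None:
    """Write a session to one HDF5 file (lossless round-trip)."""
    session.validate()
    spikes = np.concatenate(session.spike_times) if session.n_units else np.array([])
    offsets = np.cumsum([0] + [len(s) for s in session.spike_times])
    meta = {
        k: v for k, v in session.meta.items() if k not in ("tuning", "rates")
    }
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["duration_s"] = session.duration_s
        f.attrs["meta_json"] = json.dumps(meta, default=str)
        g = f.create_group("units")
        g.create_dataset("spike_times", data=spikes, track_times=False)
        g.create_dataset("spike_offsets", data=offsets, track_times=False)
        for col in session.units.columns:
            data = session.units[col].to_numpy()
            if data.dtype.kind in ("O", "U", "S"):
                g.create_dataset(
                    col,
                    data=np.array([str(x) for x in data], dtype=object),
                    dtype=_STR,
                    track_times=False,
                )
            else:
                g.create_dataset(col, data=data, track_times=False)
        f.create_dataset("paw_velocity", data=session.paw_velocity,
                         track_times=False)
        f.create_dataset(
            "labels",
            data=np.array([str(x) for x in session.labels], dtype=object),
            dtype=_STR,
            track_times=False,
        )


def read_session(path: str | Path) -> Session:
    """Read and validate a session file.

    A missing somatotopic-region column degrades gracefully: units get
    region ``"unknown"`` (the somatotopy shuffle test will refuse them
    later).
    """
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema_version {version} in {path}"
            )
        duration = float(f.attrs["duration_s"])
        meta = json.loads(f.attrs.get("meta_json", "{}"))
        g = f["units"]
        spikes = g["spike_times"][()]
        offsets = g["spike_offsets"][()]
        cols = {}
        for col in ("unit_id", "area", "hemisphere", "region", "snr",
                    "single_unit"):
            if col in g:
                data = g[col][()]
                if data.dtype.kind in ("S", "O"):
                    data = np.array([d.decode() for d in data])
                cols[col] = data
        velocity = f["paw_velocity"][()]
        labels = np.array([s.decode() for s in f["labels"][()]])
    spike_times = [
        spikes[offsets[i] : offsets[i + 1]] for i in range(len(offsets) - 1)
    ]
    units = make_units_table(pd.DataFrame(cols).to_dict("records"))
    session = Session(
        spike_times=spike_times,
        units=units,
        paw_velocity=velocity,
        labels=labels,
        duration_s=duration,
        meta=meta,
    )
    session.validate()
    return session


def export_session_csv(session: Session, directory: str | Path) -> None:
    """Plain-text export: units.csv, spikes.csv, velocity.csv, labels.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    session.units.to_csv(directory / "units.csv", index=False)
    rows = [
        {"unit_id": session.units.iloc[i]["unit_id"], "time_s": t}
        for i in range(session.n_units)
        for t in session.spike_times[i]
    ]
    pd.DataFrame(rows).to_csv(directory / "spikes.csv", index=False)
    pd.DataFrame(
        session.paw_velocity,
        columns=["front_left", "front_right", "hind_left", "hind_right"],
    ).to_csv(directory / "velocity.csv", index=False)
    pd.DataFrame({"label": session.labels}).to_csv(
        directory / "labels.csv", index=False
    )
    header = {
        "schema_version": SCHEMA_VERSION,
        "duration_s": session.duration_s,
        "meta": {
            k: str(v)
            for k, v in session.meta.items()
            if k not in ("tuning", "rates")
        },
    }
    (directory / "header.json").write_text(json.dumps(header, indent=2))


def write_embedding(embedding: Embedding, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=embedding.coords, track_times=False)
        f.create_dataset("eigenvalues", data=embedding.eigenvalues,
                         track_times=False)
        f.create_dataset("kept_time_index", data=embedding.kept_time_index,
                         track_times=False)
        f.attrs["method"] = embedding.method
        f.attrs["params_json"] = json.dumps(embedding.params, default=str)


def read_embedding(path: str | Path) -> Embedding:
    with h5py.File(path, "r") as f:
        return Embedding(
            coords=f["coords"][()],
            eigenvalues=f["eigenvalues"][()],
            kept_time_index=f["kept_time_index"][()],
            method=str(f.attrs["method"]),
            params=json.loads(f.attrs.get("params_json", "{}")),
        )
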