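"""Session container read/write.

Two dialects are supported:

* **CSV bundle** — a directory of tidy tables with a JSON manifest.
  Dependency-free, diff-able and the canonical fixture format for tests.
  Floats are written with Python's shortest round-trippable repr, so a
  write -> read cycle reproduces every value bit-exactly.
* **HDF5 container** — a single ``.h5`` file whose layout follows the
  Neurodata Without Borders convention of separate ``acquisition`` and
  ``processing`` groups (raw acceleration series under ``/acquisition``,
  derived tables under ``/processing``, subject metadata under
  ``/general``). It mimics that structure rather than implementing a
  certified schema.

All timestamps are stored in seconds relative to the injection event.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .exceptions import ParseError
from .types import Session, TriaxSegment

__all__ = ["SessionContainer", "write_session", "read_session"]

_MANIFEST = "manifest.json"
_FORMAT_NAME = "tremorkit-csv-bundle"


@dataclass
class SessionContainer:
    """A session plus any processed products (tables keyed by name)."""

    session: Session
    processed: dict[str, pd.DataFrame] = field(default_factory=dict)


def _acquisition_frame(session: Session) -> pd.DataFrame:
    rows = []
    for seg in session.segments:
        rows.append(pd.DataFrame({
            "segment_id": seg.segment_id,
            "sample": np.arange(seg.n_samples),
            "ax": seg.channels[0],
            "ay": seg.channels[1],
            "az": seg.channels[2],
        }))
    return pd.concat(rows, ignore_index=True)


def _segment_index(session: Session) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.segment_id, s.start_time, s.sampling_rate, s.n_samples)
         for s in session.segments],
        columns=["segment_id", "start_time", "sampling_rate", "n_samples"],
    )


def write_session(
    container: SessionContainer | Session,
    path,
    format: str = "csv-bundle",
) -> Path:
    """Write a session container; returns the path written.

    ``format`` is ``"csv-bundle"`` (directory of tables) or ``"hdf5"``.
    """
    if isinstance(container, Session):
        container = SessionContainer(session=container)
    path = Path(path)
    if format == "csv-bundle":
        return _write_csv_bundle(container, path)
    if format == "hdf5":
        return _write_hdf5(container, path)
    raise ParseError(f"unknown container format {format!r}")


def _write_csv_bundle(container: SessionContainer, path: Path) -> Path:
    session = container.session
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "session.json", "w") as fh:
        json.dump({"subject_id": session.subject_id,
                   "dose_mg_per_kg": session.dose_mg_per_kg}, fh, indent=1)
    _segment_index(session).to_csv(path / "segments.csv", index=False)
    _acquisition_frame(session).to_csv(path / "acquisition.csv", index=False)
    tables = ["segments", "acquisition"]
    for name, df in container.processed.items():
        df.to_csv(path / f"{name}.csv", index=False)
        tables.append(name)
    with open(path / _MANIFEST, "w") as fh:
        json.dump({"format": _FORMAT_NAME, "version": 1, "tables": tables},
                  fh, indent=1)
    return path


def _write_hdf5(container: SessionContainer, path: Path) -> Path:
    session = container.session
    with h5py.File(path, "w") as f:
        gen = f.create_group("general")
        gen.attrs["subject_id"] = session.subject_id
        gen.attrs["dose_mg_per_kg"] = session.dose_mg_per_kg
        acq = f.create_group("acquisition")
        for seg in session.segments:
            g = acq.create_group(seg.segment_id)
            g.create_dataset("data", data=seg.channels)
            g.attrs["sampling_rate"] = seg.sampling_rate
            g.attrs["start_time"] = seg.start_time
        proc = f.create_group("processing")
        for name, df in container.processed.items():
            g = proc.create_group(name)
            g.attrs["columns"] = list(df.columns)
            for col in df.columns:
                vals = df[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype(str)
                    g.create_dataset(
                        col, data=vals.astype(h5py.string_dtype()))
                else:
                    g.create_dataset(col, data=vals)
    return path


def read_session(path) -> SessionContainer:
    """Read a container written by :func:`write_session`.

    Directories are parsed as CSV bundles, files as HDF5 containers.
    Segments are returned time-sorted regardless of on-disk order.
    """
    path = Path(path)
    if path.is_dir():
        return _read_csv_bundle(path)
    if path.is_file():
        return _read_hdf5(path)
    raise ParseError(f"no session container at {path}")


def _read_csv_bundle(path: Path) -> SessionContainer:
    manifest_path = path / _MANIFEST
    if not manifest_path.exists():
        raise ParseError(f"missing {_MANIFEST} in {path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if manifest.get("format") != _FORMAT_NAME:
        raise ParseError(
            f"unknown bundle format {manifest.get('format')!r}")
    for name in manifest["tables"]:
        if not (path / f"{name}.csv").exists():
            raise ParseError(
                f"manifest lists table {name!r} but {name}.csv is missing")
    with open(path / "session.json") as fh:
        meta = json.load(fh)
    seg_index = pd.read_csv(path / "segments.csv",
                            float_precision="round_trip")
    acq = pd.read_csv(path / "acquisition.csv", float_precision="round_trip")
    for col in ("ax", "ay", "az"):
        if col not in acq.columns:
            raise ParseError(
                "expected 3 acceleration channels (columns ax, ay, az); "
                f"column {col!r} missing from acquisition.csv")
    segments = []
    for row in seg_index.itertuples():
        block = acq[acq["segment_id"] == row.segment_id]
        if len(block) != row.n_samples:
            raise ParseError(
                f"segment {row.segment_id!r}: segments.csv declares "
                f"{row.n_samples} samples but acquisition.csv has "
                f"{len(block)}")
        block = block.sort_values("sample")
        segments.append(TriaxSegment(
            channels=np.vstack([block["ax"], block["ay"], block["az"]]),
            sampling_rate=float(row.sampling_rate),
            start_time=float(row.start_time),
            subject_id=str(meta["subject_id"]),
            segment_id=str(row.segment_id),
        ))
    session = Session(subject_id=str(meta["subject_id"]),
                      dose_mg_per_kg=float(meta["dose_mg_per_kg"]),
                      segments=segments)
    processed = {
        name: pd.read_csv(path / f"{name}.csv",
                          float_precision="round_trip")
        for name in manifest["tables"]
        if name not in ("segments", "acquisition")
    }
    return SessionContainer(session=session, processed=processed)


def _read_hdf5(path: Path) -> SessionContainer:
    with h5py.File(path, "r") as f:
        if "acquisition" not in f:
            raise ParseError(f"{path} has no acquisition group")
        gen = f["general"].attrs if "general" in f else {}
        segments = []
        for sid, g in f["acquisition"].items():
            data = np.asarray(g["data"])
            if data.ndim != 2 or data.shape[0] != 3:
                raise ParseError(
                    f"segment {sid!r}: expected 3 acceleration channels, "
                    f"got data of shape {data.shape}")
            segments.append(TriaxSegment(
                channels=data,
                sampling_rate=float(g.attrs["sampling_rate"]),
                start_time=float(g.attrs["start_time"]),
                subject_id=str(gen.get("subject_id", "")),
                segment_id=str(sid),
            ))
        processed = {}
        if "processing" in f:
            for name, g in f["processing"].items():
                cols = list(g.attrs["columns"])
                data = {}
                for col in cols:
                    vals = np.asarray(g[col])
                    if vals.dtype.kind in ("S", "O"):
                        vals = vals.astype(str)
                    data[col] = vals
                processed[name] = pd.DataFrame(data)
        session = Session(
            subject_id=str(gen.get("subject_id", "")),
            dose_mg_per_kg=float(gen.get("dose_mg_per_kg", 0.0)),
            segments=segments,
        )
    return SessionContainer(session=session, processed=processed)
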