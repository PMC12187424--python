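"""Readers and writers for cubes, trajectories and signals.

Data cubes live in self-describing HDF5 files (``/cube`` dataset plus a
``config`` group carrying the radar configuration as attributes, and an
optional ``/trajectory``); 1-D signals are also exportable as two-column
CSV for desk-scale inspection.
"""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import numpy as np
import yaml

from .core import DisplacementSignal, DisplacementTrajectory, IQSeries, RadarConfig, RadarDataCube
from .errors import ConfigurationError, FormatError

__all__ = [
    "write_cube",
    "read_cube",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_signal_csv",
    "write_iq",
    "read_iq",
    "load_yaml_spec",
]

_CONFIG_FIELDS = list(RadarConfig().to_dict().keys())


def write_cube(path, cube: RadarDataCube,
               trajectory: DisplacementTrajectory | None = None) -> None:
    """Write a data cube (and optionally the driving trajectory) to HDF5."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("cube", data=cube.values)
        ds.attrs["axes"] = "frame,antenna,chirp,sample"
        grp = f.create_group("config")
        for k, v in cube.config.to_dict().items():
            grp.attrs[k] = v
        if trajectory is not None:
            tds = f.create_dataset("trajectory", data=trajectory.values)
            tds.attrs["sample_rate"] = trajectory.sample_rate
            tds.attrs["description"] = trajectory.description


def read_cube(path) -> RadarDataCube:
    """Read a cube written by :func:`write_cube`, validating the layout."""
    with h5py.File(path, "r") as f:
        if "cube" not in f:
            raise FormatError(f"{path}: missing dataset '/cube'")
        if "config" not in f:
            raise FormatError(f"{path}: missing group '/config'")
        attrs = dict(f["config"].attrs)
        missing = [k for k in _CONFIG_FIELDS if k not in attrs]
        if missing:
            raise FormatError(f"{path}: /config missing attributes {missing}")
        cfg = RadarConfig(**{k: attrs[k].item() if hasattr(attrs[k], "item") else attrs[k]
                             for k in _CONFIG_FIELDS})
        values = np.asarray(f["cube"])
    return RadarDataCube(values, cfg)


def write_trajectory_csv(path, trajectory: DisplacementTrajectory) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "value_m"])
        for t, v in zip(trajectory.times, trajectory.values):
            w.writerow([f"{t:.9g}", f"{v:.12g}"])


def read_trajectory_csv(path, description: str = "") -> DisplacementTrajectory:
    """Read a two-column (time_s, value_m) CSV; malformed rows report their
    line number."""
    times, values = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if lineno == 1 and row and row[0].strip().lower() == "time_s":
                continue
            if not row:
                continue
            if len(row) < 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns, got {len(row)}")
            try:
                times.append(float(row[0]))
                values.append(float(row[1]))
            except ValueError as e:
                raise FormatError(f"{path}: line {lineno}: non-numeric value {row!r}") from e
    if len(values) < 2:
        raise FormatError(f"{path}: fewer than 2 data rows")
    dt = np.diff(times)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
        raise FormatError(f"{path}: time column is not uniformly increasing")
    return DisplacementTrajectory(1.0 / dt[0], np.asarray(values), description)


def write_signal_csv(path, signal: DisplacementSignal) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "displacement_m"])
        for t, v in zip(signal.times, signal.values):
            w.writerow([f"{t:.9g}", f"{v:.12g}"])


def write_iq(path, iq: IQSeries) -> None:
    """Write an I/Q series to HDF5 (/iq/real, /iq/imag)."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("iq")
        grp.create_dataset("real", data=iq.values.real)
        grp.create_dataset("imag", data=iq.values.imag)
        grp.attrs["sample_rate"] = iq.sample_rate
        grp.attrs["source_bin"] = iq.source_bin


def read_iq(path) -> IQSeries:
    with h5py.File(path, "r") as f:
        if "iq" not in f or "real" not in f["iq"] or "imag" not in f["iq"]:
            raise FormatError(f"{path}: missing /iq/real or /iq/imag datasets")
        grp = f["iq"]
        values = np.asarray(grp["real"]) + 1j * np.asarray(grp["imag"])
        return IQSeries(values, float(grp.attrs["sample_rate"]), int(grp.attrs["source_bin"]))


def load_yaml_spec(path, allowed_keys) -> dict:
    """Load a YAML mapping, rejecting unknown keys rather than silently
    substituting defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a YAML mapping")
    unknown = sorted(set(data) - set(allowed_keys))
    if unknown:
        raise ConfigurationError(f"{path}: unknown keys {unknown}")
    return data
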