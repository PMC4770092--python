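"""Readers and writers for traces, dwell tables, FEC sweeps and PMF grids.

All formats are plain text for inspectability:

* ``*.trace.tsv`` — columns ``time_s``, ``signal_nm`` and optionally
  ``force_pN``; numbers at full double precision.  A sidecar
  ``*.trace.meta`` holds ``key = value`` metadata including an
  append-only processing history.
* ``*.fec.tsv`` — ``trap_distance_nm``, ``force_pN`` with sweep
  metadata in ``#`` header comments.
* ``*.pmf2d.dat`` — three whitespace-separated columns (AMP-lid
  coordinate Å, ATP-lid coordinate Å, free energy) on a rectangular
  grid; the energy unit is declared in a ``# unit:`` header and
  converted to kBT on read.  Missing rows mark masked (unsampled)
  cells.

An HDF5 container for long traces is provided behind the same
interface.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import Constants, DEFAULT_CONSTANTS
from .dwells import DwellSet
from .pmf import PMFGrid
from .synthetic import ForceExtensionCurve
from .trace import REQUIRED_META_KEYS, Trace

_FMT = "%.17g"


class TraceSchemaError(ValueError):
    """Mandatory trace metadata is missing."""


def _meta_path(path: Path) -> Path:
    name = path.name
    if name.endswith(".trace.tsv"):
        return path.with_name(name[: -len(".tsv")] + ".meta")
    return path.with_suffix(path.suffix + ".meta")


def _serialise_meta_value(value) -> str:
    if isinstance(value, (list, tuple, dict)):
        return json.dumps(value)
    return str(value)


def _parse_meta_value(raw: str):
    raw = raw.strip()
    try:
        return json.loads(raw)
    except (json.JSONDecodeError, ValueError):
        return raw


def write_trace(trace: Trace, path) -> Path:
    """Write a trace as TSV + sidecar metadata; returns the data path."""
    path = Path(path)
    missing = [k for k in REQUIRED_META_KEYS if k not in trace.meta]
    if missing:
        raise TraceSchemaError(f"trace metadata missing mandatory keys: {missing}")
    cols = ["time_s", "signal_nm"]
    arrays = [trace.time, trace.signal]
    if trace.force is not None:
        cols.append("force_pN")
        arrays.append(trace.force)
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        np.savetxt(fh, np.column_stack(arrays), fmt=_FMT, delimiter="\t")
    meta_path = _meta_path(path)
    with open(meta_path, "w") as fh:
        for key in sorted(trace.meta):
            fh.write(f"{key} = {_serialise_meta_value(trace.meta[key])}\n")
    return path


def read_trace(path) -> Trace:
    path = Path(path)
    meta_path = _meta_path(path)
    if not meta_path.exists():
        raise TraceSchemaError(f"missing sidecar metadata file {meta_path}")
    meta: dict = {}
    for line in meta_path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        meta[key.strip()] = _parse_meta_value(value)
    missing = [k for k in REQUIRED_META_KEYS if k not in meta]
    if missing:
        raise TraceSchemaError(f"trace metadata missing mandatory keys: {missing}")
    if not isinstance(meta.get("history", []), list):
        meta["history"] = [meta["history"]]

    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    col = {name: i for i, name in enumerate(header)}
    time = data[:, col["time_s"]]
    dt = np.diff(time)
    if dt.size and not np.all(dt > 0):
        bad = int(np.argmax(dt <= 0)) + 3  # sample index +1, header line, 1-based
        raise ValueError(f"{path}: time not strictly increasing at line {bad}")
    force = data[:, col["force_pN"]] if "force_pN" in col else None
    return Trace(time=time, signal=data[:, col["signal_nm"]], force=force, meta=meta)


def write_trace_hdf5(trace: Trace, path) -> Path:
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("time_s", data=trace.time)
        fh.create_dataset("signal_nm", data=trace.signal)
        if trace.force is not None:
            fh.create_dataset("force_pN", data=trace.force)
        fh.attrs["meta_json"] = json.dumps(trace.meta)
    return path


def read_trace_hdf5(path) -> Trace:
    import h5py

    with h5py.File(path, "r") as fh:
        time = fh["time_s"][:]
        signal = fh["signal_nm"][:]
        force = fh["force_pN"][:] if "force_pN" in fh else None
        meta = json.loads(fh.attrs["meta_json"])
    return Trace(time=time, signal=signal, force=force, meta=meta)


def write_dwells(dwells: DwellSet, path) -> Path:
    path = Path(path)
    df = dwells.to_frame()
    with open(path, "w") as fh:
        for key in sorted(dwells.meta):
            if key == "true_forces":
                continue
            fh.write(f"# {key} = {_serialise_meta_value(dwells.meta[key])}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    return path


def read_dwells(path) -> DwellSet:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = _parse_meta_value(value)
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t",
                     float_precision="round_trip")
    return DwellSet.from_frame(df, meta=meta)


def write_fec(fec: ForceExtensionCurve, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# pulling_velocity_nm_per_s = {_FMT % fec.pulling_velocity}\n")
        fh.write(f"# direction = {fec.direction}\n")
        for key in sorted(fec.meta):
            fh.write(f"# {key} = {_serialise_meta_value(fec.meta[key])}\n")
        fh.write("trap_distance_nm\tforce_pN\n")
        np.savetxt(fh, np.column_stack([fec.trap_distance, fec.force]),
                   fmt=_FMT, delimiter="\t")
    return path


def read_fec(path) -> ForceExtensionCurve:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = _parse_meta_value(value)
        else:
            body.append(line)
    data = np.loadtxt(body[1:], delimiter="\t", ndmin=2)
    velocity = float(meta.pop("pulling_velocity_nm_per_s", 1.0))
    direction = str(meta.pop("direction", "stretch"))
    return ForceExtensionCurve(
        trap_distance=data[:, 0], force=data[:, 1],
        pulling_velocity=velocity, direction=direction, meta=meta,
    )


_PMF_UNITS = {"kbt", "kcal/mol"}


def read_pmf_grid(path, constants: Constants = DEFAULT_CONSTANTS) -> PMFGrid:
    """Parse a whitespace three-column 2D free-energy grid.

    The header must declare the energy unit (``# unit: kcal/mol`` or
    ``# unit: kBT``); energies are converted to kBT.  Combinations of
    axis values absent from the file become masked cells; duplicated
    cells are an error.
    """
    path = Path(path)
    unit = None
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            content = stripped[1:].strip()
            if content.lower().startswith("unit:"):
                unit = content[len("unit:"):].strip()
            continue
        parts = stripped.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
        rows.append([float(p) for p in parts])
    if unit is None:
        raise ValueError(f"{path}: missing '# unit:' header")
    if unit.lower() not in _PMF_UNITS:
        raise ValueError(f"{path}: unknown energy unit {unit!r}")
    if not rows:
        raise ValueError(f"{path}: empty grid")
    arr = np.asarray(rows)
    a_axis = np.unique(arr[:, 0])
    b_axis = np.unique(arr[:, 1])
    energy = np.full((a_axis.size, b_axis.size), np.nan)
    seen = np.zeros(energy.shape, dtype=bool)
    ia = np.searchsorted(a_axis, arr[:, 0])
    ib = np.searchsorted(b_axis, arr[:, 1])
    for i, j, g in zip(ia, ib, arr[:, 2]):
        if seen[i, j]:
            raise ValueError(f"{path}: duplicate grid cell ({a_axis[i]}, {b_axis[j]})")
        seen[i, j] = True
        energy[i, j] = g
    if unit.lower() == "kcal/mol":
        energy = constants.kcal_per_mol_to_kBT(1.0) * energy
    return PMFGrid(d_amp_axis=a_axis, d_atp_axis=b_axis, free_energy=energy)


def write_pmf_grid(grid: PMFGrid, path, unit: str = "kBT",
                   constants: Constants = DEFAULT_CONSTANTS) -> Path:
    if unit.lower() not in _PMF_UNITS:
        raise ValueError(f"unknown energy unit {unit!r}")
    factor = 1.0
    if unit.lower() == "kcal/mol":
        factor = constants.kBT_to_kcal_per_mol(1.0)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# unit: {unit}\n")
        fh.write("# columns: d_AMP_lid_A d_ATP_lid_A free_energy\n")
        for i, a in enumerate(grid.d_amp_axis):
            for j, b in enumerate(grid.d_atp_axis):
                g = grid.free_energy[i, j]
                if np.isnan(g):
                    continue
                fh.write(f"{_FMT % a} {_FMT % b} {_FMT % (g * factor)}\n")
    return path
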