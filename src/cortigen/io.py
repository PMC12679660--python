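"""Record containers (HDF5), CSV exports and JSON reports.

All writes go through a temp-file-and-rename so a failed run never leaves
a partial output behind.  The record container layout is versioned; a
reader refuses a container written under a different layout version.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import CorruptRecordError, FormatVersionError
from .field import (
    ActivationFunction,
    DendriticKernel,
    FieldConfig,
    FieldGeometry,
    GainState,
    PlasticityConfig,
    SimulationRecord,
)
from .morphogenesis import CellLayout, ConnectionGraph

__all__ = [
    "FORMAT_VERSION",
    "export_layout_csv",
    "export_opmap",
    "read_record",
    "record_summary",
    "write_json_report",
    "write_record",
]

FORMAT_VERSION = "cortigen-record-1"


def _atomic(path: Path, write_fn) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=path.suffix + ".tmp")
    os.close(fd)
    try:
        write_fn(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _config_json(config: FieldConfig) -> str:
    d = dataclasses.asdict(config)
    if d.get("positions") is not None:
        d["positions"] = np.asarray(d["positions"]).tolist()
    return json.dumps(d, sort_keys=True)


def _config_from_json(text: str) -> FieldConfig:
    d = json.loads(text)
    d["kernel"] = DendriticKernel(**d["kernel"])
    if d.get("kernel_inh") is not None:
        d["kernel_inh"] = DendriticKernel(**d["kernel_inh"])
    d["activation"] = ActivationFunction(**d["activation"])
    d["plasticity"] = PlasticityConfig(**d["plasticity"])
    if d.get("positions") is not None:
        d["positions"] = np.asarray(d["positions"], dtype=float)
    return FieldConfig(**d)


def write_record(record: SimulationRecord, path: str | Path) -> None:
    """Write a simulation record to an HDF5 container (lossless)."""

    def _write(tmp):
        with h5py.File(tmp, "w") as h5:
            h5.attrs["format_version"] = FORMAT_VERSION
            h5.attrs["seed"] = record.seed
            h5.attrs["burn_in"] = record.burn_in
            h5.attrs["config_json"] = _config_json(record.config)
            for name in ("Q", "V", "drive", "exc_flux", "inh_flux",
                         "norm_steps", "balance_residuals"):
                h5.create_dataset(name, data=getattr(record, name))
            if record.phi is not None:
                h5.create_dataset("phi", data=record.phi)
            geo = h5.create_group("geometry")
            geo.create_dataset("positions", data=record.geometry.positions)
            geo.create_dataset("ei_label", data=record.geometry.ei_label)
            geo.create_dataset("delay_matrix", data=record.geometry.delay_matrix)
            geo.attrs["v"] = record.geometry.v
            geo.attrs["dt"] = record.geometry.dt
            geo.attrs["single_population"] = record.geometry.single_population
            gg = h5.create_group("gains")
            for name in ("eps", "g", "rho", "sign", "mask"):
                gg.create_dataset(name, data=getattr(record.gains_final, name))
            for name in ("row_cap_e", "row_cap_i"):
                val = getattr(record.gains_final, name)
                if val is not None:
                    gg.create_dataset(name, data=val)

    _atomic(Path(path), _write)


def read_record(path: str | Path) -> SimulationRecord:
    """Read a record container; refuses foreign versions and truncations."""
    path = Path(path)
    try:
        with h5py.File(path, "r") as h5:
            version = h5.attrs.get("format_version")
            if version != FORMAT_VERSION:
                raise FormatVersionError(
                    f"container version {version!r} != {FORMAT_VERSION!r}"
                )
            geo = h5["geometry"]
            geometry = FieldGeometry(
                positions=geo["positions"][()],
                ei_label=geo["ei_label"][()],
                v=float(geo.attrs["v"]), dt=float(geo.attrs["dt"]),
                delay_matrix=geo["delay_matrix"][()],
                single_population=bool(geo.attrs["single_population"]),
            )
            gg = h5["gains"]
            gains = GainState(
                eps=gg["eps"][()], g=gg["g"][()], rho=gg["rho"][()],
                sign=gg["sign"][()], mask=gg["mask"][()].astype(bool),
                row_cap_e=gg["row_cap_e"][()] if "row_cap_e" in gg else None,
                row_cap_i=gg["row_cap_i"][()] if "row_cap_i" in gg else None,
            )
            return SimulationRecord(
                Q=h5["Q"][()], V=h5["V"][()], drive=h5["drive"][()],
                exc_flux=h5["exc_flux"][()], inh_flux=h5["inh_flux"][()],
                phi=h5["phi"][()] if "phi" in h5 else None,
                geometry=geometry, gains_final=gains,
                config=_config_from_json(h5.attrs["config_json"]),
                burn_in=int(h5.attrs["burn_in"]), seed=int(h5.attrs["seed"]),
                norm_steps=h5["norm_steps"][()],
                balance_residuals=h5["balance_residuals"][()],
            )
    except (OSError, KeyError) as exc:
        raise CorruptRecordError(f"unreadable record container {path}: {exc}") from exc


def record_summary(record: SimulationRecord) -> pd.DataFrame:
    """Per-step summary (burn-in excluded; one row per retained step)."""
    sl = slice(record.burn_in, record.steps)
    steps = np.arange(record.burn_in, record.steps)
    return pd.DataFrame({
        "step": steps,
        "mean_Q": record.Q[sl].mean(axis=1),
        "std_Q": record.Q[sl].std(axis=1),
        "mean_V": record.V[sl].mean(axis=1),
        "sum_phi_e": record.exc_flux[sl].sum(axis=1),
        "sum_phi_i": record.inh_flux[sl].sum(axis=1),
        "drive_rms": np.sqrt((record.drive[sl] ** 2).mean(axis=1)),
    })


def export_layout_csv(layout: CellLayout, cells_path: str | Path,
                      graph: ConnectionGraph | None = None,
                      edges_path: str | Path | None = None) -> None:
    """Export a layout (and optionally its graph) as CSV tables."""
    cells = pd.DataFrame({
        "id": np.arange(layout.n),
        "x": layout.positions[:, 0],
        "y": layout.positions[:, 1],
        "population": layout.population,
    })
    if layout.chirality is not None:
        cells["chirality"] = layout.chirality
    _atomic(Path(cells_path), lambda tmp: cells.to_csv(tmp, index=False))
    if graph is not None and edges_path is not None:
        edges = pd.DataFrame({
            "i": graph.edges[:, 0] if len(graph.edges) else [],
            "j": graph.edges[:, 1] if len(graph.edges) else [],
            "weight": graph.weights,
            "symmetric": graph.symmetric,
        })
        _atomic(Path(edges_path), lambda tmp: edges.to_csv(tmp, index=False))


def export_opmap(opmap, csv_path: str | Path,
                 pgm_path: str | Path | None = None) -> None:
    """Export an OP raster as a CSV grid and an 8-bit grayscale PGM."""
    df = pd.DataFrame(opmap.raster, index=opmap.ys, columns=opmap.xs)
    _atomic(Path(csv_path), lambda tmp: df.to_csv(tmp))
    if pgm_path is not None:
        gray = np.clip(opmap.raster / 180.0 * 255.0, 0, 255).astype(np.uint8)

        def _write(tmp):
            with open(tmp, "wb") as fh:
                fh.write(f"P5\n{gray.shape[1]} {gray.shape[0]}\n255\n".encode())
                fh.write(gray.tobytes())

        _atomic(Path(pgm_path), _write)


def write_json_report(data: dict, path: str | Path) -> None:
    """Deterministic (sorted-key) JSON report."""

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    text = json.dumps(data, sort_keys=True, indent=2, default=_default) + "\n"
    _atomic(Path(path), lambda tmp: Path(tmp).write_text(text))
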