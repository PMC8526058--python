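"""Plain-text dataset and result I/O.

A dataset is a directory of desk-scale, diff-able text files:

* ``dataset.json`` — manifest: schema version, mode, cell ids, generator
  config (if synthetic).
* ``<cell_id>.traces.csv`` — long-format traces, columns
  ``sweep_id, sample_index, current_pA``.
* ``<cell_id>.meta.json`` — per-cell metadata sidecar (dt, stim onset,
  grid geometry, soma position, genotype, pair id, LED power, mode) and
  one metadata record per sweep.
* ``ground_truth.json`` — generator ground truth, when present.

Writing then reading reproduces all numeric fields exactly (floats are
serialised with ``repr`` round-trip precision) and metadata verbatim.
An NWB adapter would slot in behind :func:`read_dataset`; it is a
documented extension point, not a dependency.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import CellRecording, GridGeometry, SweepRecord
from .exceptions import SchemaError
from .synthgen import GroundTruth

__all__ = ["write_dataset", "read_dataset", "SCHEMA_VERSION"]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


def _cell_meta(cell: CellRecording) -> dict:
    meta = {
        "cell_id": cell.cell_id,
        "genotype": cell.genotype,
        "pair_id": cell.pair_id,
        "mode": cell.mode,
        "dt": cell.dt,
        "stim_onset": cell.stim_onset,
        "soma_pos": list(cell.soma_pos),
        "led_power": cell.led_power,
        "grid": None if cell.grid is None else {
            "rows": cell.grid.rows, "cols": cell.grid.cols,
            "x_spacing": cell.grid.x_spacing, "y_spacing": cell.grid.y_spacing,
        },
        "metadata": cell.metadata,
        "sweeps": [
            {
                "sweep_id": s.sweep_id,
                "stim_kind": s.stim_kind,
                "grid_index": None if s.grid_index is None else list(s.grid_index),
                "power": s.power,
                "holding": s.holding,
                "stim_onset": s.stim_onset,
                "n_samples": s.n_samples,
            }
            for s in cell.sweeps
        ],
    }
    return meta


def write_dataset(cells: list, path, ground_truth: Optional[GroundTruth] = None,
                  mode: Optional[str] = None, config: Optional[dict] = None) -> Path:
    """Write a dataset directory; returns its path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "mode": mode or (cells[0].mode if cells else None),
        "cells": [c.cell_id for c in cells],
        "config": config,
    }
    (path / "dataset.json").write_text(json.dumps(manifest, indent=1))
    for cell in cells:
        (path / f"{cell.cell_id}.meta.json").write_text(
            json.dumps(_cell_meta(cell), indent=1))
        frames = []
        for s in cell.sweeps:
            frames.append(pd.DataFrame({
                "sweep_id": s.sweep_id,
                "sample_index": np.arange(s.n_samples),
                "current_pA": s.samples,
            }))
        df = pd.concat(frames, ignore_index=True) if frames else \
            pd.DataFrame(columns=["sweep_id", "sample_index", "current_pA"])
        df.to_csv(path / f"{cell.cell_id}.traces.csv", index=False)
    if ground_truth is not None:
        gt = {
            "ko_scale": ground_truth.ko_scale,
            "config": ground_truth.config,
            "cells": ground_truth.cells,
            "sweeps": ground_truth.sweeps,
            "sr_events": ground_truth.sr_events,
        }
        (path / "ground_truth.json").write_text(json.dumps(gt))
    log.info("wrote dataset with %d cell(s) to %s", len(cells), path)
    return path


def _require(d: dict, key: str, where: str):
    if key not in d:
        raise SchemaError(f"{where}: missing required field {key!r}")
    return d[key]


def _read_cell(path: Path, cell_id: str) -> CellRecording:
    meta_file = path / f"{cell_id}.meta.json"
    trace_file = path / f"{cell_id}.traces.csv"
    if not meta_file.exists():
        raise SchemaError(f"{meta_file}: sidecar missing")
    if not trace_file.exists():
        raise SchemaError(f"{trace_file}: trace file missing")
    try:
        meta = json.loads(meta_file.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{meta_file}: invalid JSON ({exc})") from exc
    for key in ("cell_id", "genotype", "pair_id", "mode", "dt",
                "stim_onset", "soma_pos", "sweeps"):
        _require(meta, key, str(meta_file))
    try:
        # round_trip parser: exact float64 recovery of the written repr
        df = pd.read_csv(trace_file, dtype={"sweep_id": str},
                         float_precision="round_trip")
    except Exception as exc:
        raise SchemaError(f"{trace_file}: unreadable ({exc})") from exc
    for col in ("sweep_id", "sample_index", "current_pA"):
        if col not in df.columns:
            raise SchemaError(f"{trace_file}: missing column {col!r}")
    cur = pd.to_numeric(df["current_pA"], errors="coerce")
    bad = np.nonzero(~np.isfinite(cur.to_numpy()))[0]
    if bad.size:
        i = int(bad[0])
        raise SchemaError(
            f"{trace_file}: corrupted value at line {i + 2} "
            f"(sweep_id={df['sweep_id'].iloc[i]!r})")
    df["current_pA"] = cur
    grid = None
    if meta.get("grid"):
        g = meta["grid"]
        grid = GridGeometry(g["rows"], g["cols"], g["x_spacing"], g["y_spacing"])
    cell = CellRecording(
        cell_id=meta["cell_id"], genotype=meta["genotype"],
        pair_id=meta["pair_id"], mode=meta["mode"], dt=meta["dt"],
        stim_onset=meta["stim_onset"], soma_pos=tuple(meta["soma_pos"]),
        grid=grid, led_power=meta.get("led_power"),
        metadata=meta.get("metadata", {}))
    grouped = {k: v for k, v in df.groupby("sweep_id", sort=False)}
    for srec in meta["sweeps"]:
        sid = _require(srec, "sweep_id", str(meta_file))
        if sid not in grouped:
            raise SchemaError(f"{trace_file}: no trace rows for sweep_id={sid!r}")
        sub = grouped[sid].sort_values("sample_index")
        n = int(srec.get("n_samples", len(sub)))
        if len(sub) != n:
            raise SchemaError(
                f"{trace_file}: sweep_id={sid!r} has {len(sub)} samples, "
                f"sidecar says {n}")
        idx = sub["sample_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(sub))):
            raise SchemaError(
                f"{trace_file}: sweep_id={sid!r} sample_index not contiguous")
        gi = srec.get("grid_index")
        cell.sweeps.append(SweepRecord(
            samples=sub["current_pA"].to_numpy(),
            dt=meta["dt"],
            stim_onset=srec.get("stim_onset", meta["stim_onset"]),
            stim_kind=srec.get("stim_kind", "none"),
            grid_index=None if gi is None else tuple(gi),
            power=srec.get("power"),
            holding=srec.get("holding", -70.0),
            sweep_id=sid))
    return cell


def read_dataset(path) -> tuple:
    """Read a dataset directory; returns ``(cells, ground_truth_or_None)``."""
    path = Path(path)
    manifest_file = path / "dataset.json"
    if not manifest_file.exists():
        raise SchemaError(f"{manifest_file}: dataset manifest missing")
    try:
        manifest = json.loads(manifest_file.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{manifest_file}: invalid JSON ({exc})") from exc
    version = _require(manifest, "schema_version", str(manifest_file))
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"{manifest_file}: unknown schema version {version!r} "
            f"(supported: {SCHEMA_VERSION})")
    cells = [_read_cell(path, cid) for cid in _require(manifest, "cells",
                                                       str(manifest_file))]
    gt = None
    gt_file = path / "ground_truth.json"
    if gt_file.exists():
        raw = json.loads(gt_file.read_text())
        gt = GroundTruth(ko_scale=raw["ko_scale"], config=raw.get("config", {}),
                         cells=raw.get("cells", {}), sweeps=raw.get("sweeps", {}),
                         sr_events=raw.get("sr_events", {}))
    log.info("read dataset with %d cell(s) from %s", len(cells), path)
    return cells, gt
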