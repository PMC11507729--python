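"""Tabular readers/writers and run configuration.

All tabular input is CSV with fixed schemas per modality; results are
written as deterministic JSON (sorted keys, full float precision) with
the package version and a hash of the configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .types import FilamentTrace, GelLane, Linescan, MotionTrace, PolymerizationTrace
from .sarcomere_morphometry import CellMorphometry

__all__ = ["SchemaError", "read_trace_table", "write_results", "load_config"]

_SCHEMAS: dict[str, list[str]] = {
    "pyrene": ["condition", "time_s", "value"],
    "tirf": ["filament_id", "time_s", "length_subunits"],
    "motion": ["roi_id", "time_s", "speed_um_s"],
    "linescan": ["cell_id", "myofibril_id", "position_um", "intensity"],
    "lanes": ["construct", "conc_nm", "supernatant", "pellet", "replicate"],
    "cells": ["cell_id", "ha_au_per_um2", "nuclei"],
}


class SchemaError(ValueError):
    """Raised when an input table does not match the expected schema."""


def _check_schema(df: pd.DataFrame, kind: str, path: str) -> None:
    missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} for kind '{kind}'")


def _check_monotone_time(sub: pd.DataFrame, col: str, key: str, path: str) -> None:
    t = sub[col].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        row = int(sub.index[bad[0] + 1])
        raise SchemaError(f"{path}: non-increasing {col} at row {row} (group {key})")


def read_trace_table(path: str | Path, kind: str) -> list[Any]:
    """Read one CSV table into typed domain objects.

    ``kind`` selects the schema: pyrene -> PolymerizationTrace list
    (grouped by condition), tirf -> FilamentTrace list, motion ->
    MotionTrace list, linescan -> Linescan list, lanes -> GelLane list,
    cells -> CellMorphometry list.
    """
    path = Path(path)
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path)
    _check_schema(df, kind, str(path))

    if kind == "pyrene":
        out: list[Any] = []
        for cond, sub in df.groupby("condition", sort=False):
            _check_monotone_time(sub, "time_s", str(cond), str(path))
            from .types import AssayCondition

            out.append(
                PolymerizationTrace(
                    time_s=sub["time_s"].to_numpy(float),
                    value=sub["value"].to_numpy(float),
                    condition=AssayCondition(construct_id=str(cond)),
                )
            )
        return out
    if kind == "tirf":
        out = []
        for fid, sub in df.groupby("filament_id", sort=False):
            _check_monotone_time(sub, "time_s", str(fid), str(path))
            out.append(
                FilamentTrace(
                    time_s=sub["time_s"].to_numpy(float),
                    length_su=sub["length_subunits"].to_numpy(float),
                    filament_id=str(fid),
                )
            )
        return out
    if kind == "motion":
        out = []
        for rid, sub in df.groupby("roi_id", sort=False):
            _check_monotone_time(sub, "time_s", str(rid), str(path))
            out.append(
                MotionTrace(
                    time_s=sub["time_s"].to_numpy(float),
                    speed_um_s=sub["speed_um_s"].to_numpy(float),
                    roi_id=str(rid),
                )
            )
        return out
    if kind == "linescan":
        out = []
        for (cid, mid), sub in df.groupby(["cell_id", "myofibril_id"], sort=False):
            pos = sub["position_um"].to_numpy(float)
            _check_monotone_time(sub, "position_um", f"{cid}/{mid}", str(path))
            pixel = float(np.median(np.diff(pos))) if pos.size >= 2 else 0.1
            out.append(
                Linescan(position_um=pos, intensity=sub["intensity"].to_numpy(float), pixel_um=pixel)
            )
        return out
    if kind == "lanes":
        return [
            GelLane(
                formin_conc_nm=float(r.conc_nm),
                supernatant_intensity=float(r.supernatant),
                pellet_intensity=float(r.pellet),
                construct_id=str(r.construct),
                replicate=int(r.replicate),
            )
            for r in df.itertuples()
        ]
    # cells
    return [
        CellMorphometry(
            cell_id=str(r.cell_id),
            ha_intensity_per_um2=float(r.ha_au_per_um2),
            nuclei_count=int(r.nuclei),
        )
        for r in df.itertuples()
    ]


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_results(
    results: Any,
    path: str | Path,
    fmt: str = "json",
    config: dict | None = None,
) -> None:
    """Write results deterministically (sorted keys, full precision)."""
    path = Path(path)
    payload = _jsonable(results)
    meta = {"fhodquant_version": __version__}
    if config is not None:
        cfg_bytes = json.dumps(_jsonable(config), sort_keys=True).encode()
        meta["config_sha256"] = hashlib.sha256(cfg_bytes).hexdigest()
    if fmt == "json":
        doc = {"meta": meta, "results": payload}
        path.write_text(json.dumps(doc, sort_keys=True, indent=2) + "\n")
    elif fmt == "csv":
        df = pd.DataFrame(payload)
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_config(path: str | Path, known_keys: set[str] | None = None) -> dict:
    """Load a YAML/JSON run configuration; unknown top-level keys are rejected."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise SchemaError("config must be a mapping")
    if known_keys is not None:
        unknown = set(cfg) - known_keys
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
    return cfg
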