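"""CSV/JSON input and output dialects, and the packaged example tables.

Survivor curves
    columns ``temperature_C,time_min,conc`` or
    ``temperature_C,time_min,log10_conc``; an optional ``curve_id`` column
    separates replicate curves at the same temperature; one file may hold
    several temperatures.

D tables
    columns ``temperature_C,D_min,CI95_half_min``; one row per temperature.

Two example D tables ship with the package (l-carnitine thermal
inactivation at eight temperatures): ``table1_original`` with the narrow
regression CIs and ``table1_expanded`` with deliberately widened CIs.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from importlib import resources
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, ParseError
from .kinetics import DTEstimate, DTTable, IsothermalDataset, SecondaryFit

__all__ = [
    "read_curves",
    "write_curves",
    "read_dt_table",
    "write_dt_table",
    "load_example_table",
    "write_results",
    "read_results",
]

PathLike = Union[str, Path]


def load_example_table(which: str = "original") -> DTTable:
    """Load a packaged D table: ``"original"`` (narrow CIs) or ``"expanded"``."""
    if which not in ("original", "expanded"):
        raise InvalidInputError("which must be 'original' or 'expanded'")
    ref = resources.files("thermoprop.data") / f"table1_{which}.csv"
    with resources.as_file(ref) as path:
        return read_dt_table(path)


def read_dt_table(path: PathLike) -> DTTable:
    """Read a D table CSV with per-row validation.

    Raises :class:`ParseError` naming the offending line for missing
    columns, non-numeric cells, duplicate temperatures or non-positive D.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: not a readable CSV ({exc})") from exc
    required = ["temperature_C", "D_min", "CI95_half_min"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
    entries = []
    seen = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        vals = {}
        for col in required:
            try:
                vals[col] = float(row[col])
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"{path}, line {line}: non-numeric value {row[col]!r} in {col}"
                ) from exc
            if not np.isfinite(vals[col]):
                raise ParseError(f"{path}, line {line}: non-finite value in {col}")
        temp = vals["temperature_C"]
        if temp in seen:
            raise ParseError(
                f"{path}, line {line}: duplicate temperature {temp} "
                f"(first at line {seen[temp]})"
            )
        seen[temp] = line
        if vals["D_min"] <= 0:
            raise ParseError(f"{path}, line {line}: D_min must be positive")
        if vals["CI95_half_min"] < 0:
            raise ParseError(f"{path}, line {line}: CI95_half_min must be >= 0")
        entries.append(
            DTEstimate(
                temperature=temp,
                d_value=vals["D_min"],
                ci95_half=vals["CI95_half_min"],
            )
        )
    if len(entries) < 3:
        raise ParseError(f"{path}: a D table needs at least 3 rows, found {len(entries)}")
    return DTTable(entries)


def write_dt_table(table: DTTable, path: PathLike) -> None:
    """Write a D table in the ``temperature_C,D_min,CI95_half_min`` dialect."""
    pd.DataFrame(
        {
            "temperature_C": table.temperatures,
            "D_min": table.d_values,
            "CI95_half_min": table.ci95_halves,
        }
    ).to_csv(path, index=False)


def read_curves(path: PathLike) -> List[IsothermalDataset]:
    """Read survivor curves, one dataset per (temperature, curve_id) group."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: not a readable CSV ({exc})") from exc
    if "temperature_C" not in df.columns or "time_min" not in df.columns:
        raise ParseError(f"{path}: need columns temperature_C and time_min")
    if "log10_conc" in df.columns:
        ycol, raw = "log10_conc", False
    elif "conc" in df.columns:
        ycol, raw = "conc", True
    else:
        raise ParseError(f"{path}: need a conc or log10_conc column")
    keys = ["temperature_C"] + (["curve_id"] if "curve_id" in df.columns else [])
    datasets = []
    for key, grp in df.groupby(keys, sort=True):
        temp = key[0] if isinstance(key, tuple) else key
        label = "" if len(keys) == 1 else f"curve {key[1]}"
        times = grp["time_min"].to_numpy(dtype=float)
        yvals = grp[ycol].to_numpy(dtype=float)
        if raw:
            datasets.append(
                IsothermalDataset.from_concentrations(float(temp), times, yvals, label)
            )
        else:
            datasets.append(IsothermalDataset(float(temp), times, yvals, label))
    return datasets


def write_curves(datasets: List[IsothermalDataset], path: PathLike) -> None:
    """Write survivor curves in the log10_conc dialect with curve ids."""
    frames = []
    for i, ds in enumerate(datasets):
        frames.append(
            pd.DataFrame(
                {
                    "temperature_C": ds.temperature,
                    "curve_id": i,
                    "time_min": ds.times,
                    "log10_conc": ds.log_conc,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, SecondaryFit):
        d = asdict(obj)
        return {k: _jsonable(v) for k, v in d.items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(bundle: Dict, path: PathLike, format: str = "json") -> None:
    """Write a result bundle (estimates, CIs, config echo, seed) to disk.

    JSON keeps the full nested structure; CSV flattens to one row per
    (section, field) pair with a numeric value column.
    """
    bundle = _jsonable(bundle)
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n")
    elif format == "csv":
        rows = []

        def walk(prefix, node):
            if isinstance(node, dict):
                for k, v in node.items():
                    walk(f"{prefix}.{k}" if prefix else str(k), v)
            elif isinstance(node, list):
                for i, v in enumerate(node):
                    walk(f"{prefix}[{i}]", v)
            else:
                rows.append({"field": prefix, "value": node})

        walk("", bundle)
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise InvalidInputError("format must be 'json' or 'csv'")


def read_results(path: PathLike) -> Dict:
    """Read back a JSON result bundle written by :func:`write_results`."""
    return json.loads(Path(path).read_text())
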