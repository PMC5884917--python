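"""File formats: TSV signal tables, ground-truth JSON, report writing.

TSV is the canonical signal format: a first comment line carrying the
sampling rate and units, then a header row and tab-separated values.
Floats are written with 17 significant digits so a write/read round trip
is bit-identical.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signals import COPTrajectory, FEET, MARKER_NAMES, MarkerTrajectories

__all__ = [
    "FormatError",
    "marker_columns",
    "write_marker_table",
    "read_marker_table",
    "write_cop_table",
    "read_cop_table",
    "write_report",
]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"
_AXES = ("x", "y", "z")  # x = AP, y = ML (positive left), z = vertical


class FormatError(ValueError):
    """Malformed signal table."""


def marker_columns() -> list[str]:
    return [
        f"{foot}_{marker}_{ax}"
        for foot in FEET
        for marker in MARKER_NAMES
        for ax in _AXES
    ]


def _write_tsv(path, df: pd.DataFrame, rate: float) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz={rate:g} units=m,s\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def _read_tsv(path) -> tuple[pd.DataFrame, float]:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# sampling_rate_hz="):
            raise FormatError(f"{path}: missing sampling-rate header line")
        rate = float(first.split("=", 2)[1].split()[0])
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    return df, rate


def write_marker_table(path, markers: MarkerTrajectories) -> None:
    data = {"time": markers.time}
    for foot in FEET:
        for marker in MARKER_NAMES:
            arr = markers.positions[foot][marker]
            for a, ax in enumerate(_AXES):
                data[f"{foot}_{marker}_{ax}"] = arr[:, a]
    _write_tsv(path, pd.DataFrame(data), markers.rate)


def read_marker_table(path) -> MarkerTrajectories:
    """Read a marker TSV; validates channel count and monotone time."""
    df, rate = _read_tsv(path)
    expected = ["time"] + marker_columns()
    if list(df.columns) != expected:
        missing = set(expected) - set(df.columns)
        extra = set(df.columns) - set(expected)
        raise FormatError(
            f"expected {len(expected)} columns; "
            f"missing={sorted(missing)} unexpected={sorted(extra)}"
        )
    time = df["time"].to_numpy(float)
    if np.any(np.diff(time) <= 0):
        raise FormatError("column 'time' is not strictly increasing")
    positions = {
        foot: {
            marker: np.column_stack(
                [df[f"{foot}_{marker}_{ax}"].to_numpy(float) for ax in _AXES]
            )
            for marker in MARKER_NAMES
        }
        for foot in FEET
    }
    return MarkerTrajectories(time=time, positions=positions, rate=rate)


def write_cop_table(path, cop: COPTrajectory) -> None:
    _write_tsv(
        path,
        pd.DataFrame({"time": cop.time, "cop_ap": cop.ap, "cop_ml": cop.ml}),
        cop.rate,
    )


def read_cop_table(path) -> COPTrajectory:
    df, rate = _read_tsv(path)
    expected = ["time", "cop_ap", "cop_ml"]
    if list(df.columns) != expected:
        raise FormatError(f"expected columns {expected}, got {list(df.columns)}")
    time = df["time"].to_numpy(float)
    if np.any(np.diff(time) <= 0):
        raise FormatError("column 'time' is not strictly increasing")
    return COPTrajectory(
        time=time,
        ap=df["cop_ap"].to_numpy(float),
        ml=df["cop_ml"].to_numpy(float),
        rate=rate,
    )


def _versions() -> dict[str, str]:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "precistep": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }


def write_report(
    outdir,
    cohort: pd.DataFrame | None,
    stats: Mapping | None,
    seeds: Mapping[str, int] | None = None,
    config: Mapping | None = None,
) -> dict[str, Path]:
    """Write cohort CSV, a JSON stats summary, and a provenance log.

    Deterministic output: identical inputs produce identical files.  Empty
    inputs yield valid empty tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    cohort = pd.DataFrame() if cohort is None else cohort
    paths["cohort"] = outdir / "cohort.csv"
    cohort.to_csv(paths["cohort"], index=False, float_format=_FLOAT_FMT)

    paths["stats"] = outdir / "stats.json"
    with open(paths["stats"], "w") as fh:
        json.dump(stats or {}, fh, indent=1, sort_keys=True, default=_jsonable)

    paths["log"] = outdir / "report.log"
    with open(paths["log"], "w") as fh:
        fh.write("precistep analysis report\n")
        for name, ver in _versions().items():
            fh.write(f"version {name}={ver}\n")
        for name, value in (seeds or {}).items():
            fh.write(f"seed {name}={value}\n")
        if config is not None:
            fh.write("config " + json.dumps(config, sort_keys=True, default=_jsonable) + "\n")
    return paths


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
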