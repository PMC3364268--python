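"""CSV reading/writing with provenance headers.

Every table written by the pipeline starts with comment lines of the form
``# key=value`` recording the tool version, the configuration hash and the
seed, so any output file is traceable to the run that produced it. Readers
skip those lines transparently and can recover the metadata.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .hydrology import WaterLevelSeries

__all__ = [
    "config_hash",
    "write_table",
    "read_table",
    "read_header",
    "write_water_levels",
    "read_water_levels",
]


def config_hash(config: Mapping) -> str:
    """Short stable hash of a configuration mapping."""
    canon = yaml.safe_dump(config, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: Path | str,
                meta: Optional[Mapping[str, object]] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# marshpulse={__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}={v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)


def read_header(path: Path | str) -> Dict[str, str]:
    meta: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def read_table(path: Path | str,
               parse_dates: Sequence[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in parse_dates:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col])
    return df


def write_water_levels(series: Sequence[WaterLevelSeries], path: Path | str,
                       meta: Optional[Mapping[str, object]] = None) -> None:
    """Write stacked long-format series; marsh elevations go in the header."""
    meta = dict(meta or {})
    for s in series:
        meta[f"marsh_elevation.{s.area_id}"] = s.marsh_elevation
    df = pd.concat([s.to_frame() for s in series], ignore_index=True)
    write_table(df, path, meta)


def read_water_levels(
    path: Path | str,
    datum_offsets: Optional[Mapping[str, float]] = None,
) -> Dict[str, WaterLevelSeries]:
    """Read series per area; ``datum_offsets`` (mm) are added to stage on read.

    Marsh elevations are recovered from the ``marsh_elevation.<area>``
    header entries.
    """
    meta = read_header(path)
    df = read_table(path, parse_dates=["timestamp"])
    out: Dict[str, WaterLevelSeries] = {}
    for area, grp in df.groupby("area", sort=False):
        key = f"marsh_elevation.{area}"
        if key not in meta:
            raise ValueError(f"{path}: missing header entry {key}")
        offset = (datum_offsets or {}).get(str(area), 0.0)
        out[str(area)] = WaterLevelSeries(
            str(area), float(meta[key]),
            pd.DatetimeIndex(grp["timestamp"]),
            grp["stage_mm"].to_numpy(dtype=float) + offset)
    return out
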