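"""Readers and writers for the package's plain-text interchange formats.

* turf-map CSV (long format): turf_id, year, taxon, row, col, cover_cm2
  [, cover_class] — absent rows mean zero cover;
* demography CSV: as produced by :mod:`turflag.tracking`;
* climate CSV: scenario_id, year, T_summer_C, moisture;
* parameter JSON: {taxon: {survival: {...}, growth: {...}, recruitment: {...}}};
* run config YAML: grid/kernel geometry and scenario blocks.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .climate import ClimateSeries
from .grid import DEFAULT_SCALE, GridSpec, KernelSpec, OrdinalScale, TurfMap, make_grid
from .vital_rates import TaxonParams

__all__ = [
    "read_maps",
    "write_maps",
    "read_climate",
    "write_climate",
    "read_params",
    "write_params",
    "read_config",
    "write_config",
]

MAP_COLUMNS = ["turf_id", "year", "taxon", "row", "col", "cover_cm2"]


def write_maps(
    maps: Mapping[str, Sequence[TurfMap]],
    path: str | Path,
    scale: Optional[OrdinalScale] = None,
) -> None:
    """Write turf maps to long-format CSV; optionally add ordinal classes."""
    rows = []
    for turf_id in sorted(maps):
        for tm in sorted(maps[turf_id], key=lambda m: m.year):
            area = tm.grid.quadrant_area_cm2
            for (taxon, r, c), cover in sorted(tm.cover.items()):
                row = {
                    "turf_id": turf_id,
                    "year": tm.year,
                    "taxon": taxon,
                    "row": r,
                    "col": c,
                    "cover_cm2": cover,
                }
                if scale is not None:
                    row["cover_class"] = scale.encode(cover, area)
                rows.append(row)
    cols = MAP_COLUMNS + (["cover_class"] if scale is not None else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_maps(
    path: str | Path,
    grid: GridSpec,
    scale: Optional[OrdinalScale] = None,
    use_classes: bool = False,
) -> Dict[str, List[TurfMap]]:
    """Read turf maps from CSV into per-turf, year-ordered lists.

    With ``use_classes`` the ordinal cover_class column is decoded to class
    midpoints instead of using the raw cover_cm2 column.
    """
    df = pd.read_csv(path)
    missing = set(MAP_COLUMNS) - {"cover_cm2"} - set(df.columns)
    if missing:
        raise ValueError(f"map CSV missing columns: {sorted(missing)}")
    if use_classes:
        scale = scale or DEFAULT_SCALE
        if "cover_class" not in df.columns:
            raise ValueError("use_classes requested but no cover_class column")
        df = df.assign(cover_cm2=[scale.decode(int(c)) for c in df["cover_class"]])
    elif "cover_cm2" not in df.columns:
        raise ValueError("map CSV missing cover_cm2 column")
    out: Dict[str, List[TurfMap]] = {}
    for (turf_id, year), group in df.groupby(["turf_id", "year"], sort=True):
        cover = {
            (str(t), int(r), int(c)): float(v)
            for t, r, c, v in zip(group["taxon"], group["row"], group["col"], group["cover_cm2"])
            if v > 0
        }
        tm = TurfMap(turf_id=str(turf_id), year=int(year), grid=grid, cover=cover)
        tm.validate()
        out.setdefault(str(turf_id), []).append(tm)
    for series in out.values():
        series.sort(key=lambda m: m.year)
    return out


def write_climate(series: Mapping[str, ClimateSeries] | Sequence[ClimateSeries], path: str | Path) -> None:
    if isinstance(series, Mapping):
        items = list(series.values())
    else:
        items = list(series)
    rows = []
    for s in items:
        for y, t, m in zip(s.years, s.t_summer, s.moisture):
            rows.append(
                {"scenario_id": s.series_id, "year": int(y), "T_summer_C": float(t), "moisture": float(m)}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_climate(path: str | Path) -> Dict[str, ClimateSeries]:
    df = pd.read_csv(path)
    required = {"scenario_id", "year", "T_summer_C"}
    if not required <= set(df.columns):
        raise ValueError(f"climate CSV needs columns {sorted(required)}")
    out: Dict[str, ClimateSeries] = {}
    for sid, group in df.groupby("scenario_id", sort=True):
        group = group.sort_values("year")
        moisture = group["moisture"].to_numpy() if "moisture" in group else None
        out[str(sid)] = ClimateSeries(
            str(sid), group["year"].to_numpy(), group["T_summer_C"].to_numpy(), moisture
        )
    return out


def write_params(params: Mapping[str, TaxonParams], path: str | Path) -> None:
    payload = {taxon: p.to_dict() for taxon, p in sorted(params.items())}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_params(path: str | Path) -> Dict[str, TaxonParams]:
    payload = json.loads(Path(path).read_text())
    return {taxon: TaxonParams.from_dict(taxon, spec) for taxon, spec in payload.items()}


def write_config(grid: GridSpec, kernel: KernelSpec, path: str | Path, extra: Optional[dict] = None) -> None:
    cfg = {
        "turf_side_m": grid.turf_side_m,
        "quadrant_side_m": grid.quadrant_side_m,
        "buffer_m": grid.buffer_m,
        "kernel_sigma_m": kernel.sigma_m,
        "kernel_truncation_m": kernel.truncation_m,
    }
    if extra:
        cfg.update(extra)
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def read_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    cfg["grid"] = make_grid(cfg["turf_side_m"], cfg["quadrant_side_m"], cfg["buffer_m"])
    cfg["kernel"] = KernelSpec(cfg["kernel_sigma_m"], cfg["kernel_truncation_m"])
    return cfg
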