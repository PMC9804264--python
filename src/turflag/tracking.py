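"""Link demographic units between consecutive annual turf maps.

Units of a taxon in year t are matched to units of the same taxon in year
t+1 by a deterministic greedy two-pass scheme: first same-quadrant matches,
then remaining units by smallest quadrant-centre distance within a maximum
displacement radius (ties by smallest size change, then row-major order).
Unmatched year-t units are deaths; unmatched year-t+1 units are recruits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .grid import Crowding, KernelSpec, TurfMap, crowding_fields

__all__ = ["DemographicRecord", "link_years", "build_demography_table", "records_to_frame"]

EVENTS = ("survival", "death", "recruit")


@dataclass
class DemographicRecord:
    """One unit-year transition: a survival (with growth), death, or recruit."""

    turf_id: str
    taxon: str
    year_from: int
    year_to: int
    event: str
    quadrant_from: Optional[Tuple[int, int]] = None  # absent for recruits
    quadrant_to: Optional[Tuple[int, int]] = None    # absent for deaths
    size_from: Optional[float] = None                # u_{t-1}, absent for recruits
    size_to: Optional[float] = None                  # u_t, absent for deaths
    w_con: Optional[float] = None
    w_het: Optional[float] = None

    def __post_init__(self) -> None:
        if self.event not in EVENTS:
            raise ValueError(f"unknown event {self.event!r}")
        if self.event == "survival" and not (
            self.size_from and self.size_to and self.size_from > 0 and self.size_to > 0
        ):
            raise ValueError("survival records need positive size_from and size_to")
        if self.event == "death" and (self.size_to is not None or not self.size_from):
            raise ValueError("death records need size_from only")
        if self.event == "recruit" and (self.size_from is not None or not self.size_to):
            raise ValueError("recruit records need size_to only")


def link_years(
    map_t: TurfMap, map_t1: TurfMap, max_displacement_quadrants: int = 1
) -> List[DemographicRecord]:
    """Match units between two consecutive years of the same turf.

    Eligible matches are same-taxon units whose quadrant-centre distance is
    at most ``max_displacement_quadrants`` quadrant side lengths (so with
    radius 1 a unit may shift to a rook-adjacent quadrant but not diagonally).
    """
    if map_t.turf_id != map_t1.turf_id:
        raise ValueError("maps belong to different turfs")
    if map_t.grid != map_t1.grid:
        raise ValueError("maps have different grids")
    if map_t1.year != map_t.year + 1:
        raise ValueError(
            f"years not consecutive: {map_t.year} -> {map_t1.year}"
        )

    records: List[DemographicRecord] = []
    taxa = sorted(set(map_t.taxa()) | set(map_t1.taxa()))
    for taxon in taxa:
        units_t = dict(sorted(map_t.units_of(taxon).items()))
        units_t1 = dict(sorted(map_t1.units_of(taxon).items()))
        links: Dict[Tuple[int, int], Tuple[int, int]] = {}

        # pass 1: in-place matches
        for q in list(units_t):
            if q in units_t1 and q not in links.values():
                links[q] = q
        taken = set(links.values())

        # pass 2: nearest free unit within the displacement radius
        for q, size_q in units_t.items():
            if q in links:
                continue
            best = None
            for q1, size_q1 in units_t1.items():
                if q1 in taken:
                    continue
                d = math.hypot(q1[0] - q[0], q1[1] - q[1])
                if d > max_displacement_quadrants + 1e-9:
                    continue
                key = (d, abs(size_q1 - size_q), q1)
                if best is None or key < best:
                    best = key
            if best is not None:
                links[q] = best[2]
                taken.add(best[2])

        for q, size_q in units_t.items():
            if q in links:
                q1 = links[q]
                records.append(
                    DemographicRecord(
                        turf_id=map_t.turf_id,
                        taxon=taxon,
                        year_from=map_t.year,
                        year_to=map_t1.year,
                        event="survival",
                        quadrant_from=q,
                        quadrant_to=q1,
                        size_from=size_q,
                        size_to=units_t1[q1],
                    )
                )
            else:
                records.append(
                    DemographicRecord(
                        turf_id=map_t.turf_id,
                        taxon=taxon,
                        year_from=map_t.year,
                        year_to=map_t1.year,
                        event="death",
                        quadrant_from=q,
                        size_from=size_q,
                    )
                )
        for q1, size_q1 in units_t1.items():
            if q1 not in taken:
                records.append(
                    DemographicRecord(
                        turf_id=map_t.turf_id,
                        taxon=taxon,
                        year_from=map_t.year,
                        year_to=map_t1.year,
                        event="recruit",
                        quadrant_to=q1,
                        size_to=size_q1,
                    )
                )
    return records


def _annotate_crowding(
    records: Sequence[DemographicRecord], map_t: TurfMap, kernel: KernelSpec
) -> None:
    """Fill w_con/w_het on records from the year_from map (in place).

    Survivals and deaths use the focal unit's year_from quadrant; recruits
    use the arrival quadrant (unoccupied by the taxon in year_from, so
    w_con there has no focal-self term to exclude).
    """
    taxa = map_t.taxa()
    arr = map_t.to_arrays(taxa)
    w_con_f, w_het_f = crowding_fields(arr, map_t.grid, kernel)
    idx = {t: k for k, t in enumerate(taxa)}
    for rec in records:
        q = rec.quadrant_from if rec.event in ("survival", "death") else rec.quadrant_to
        r, c = q
        if rec.taxon in idx:
            k = idx[rec.taxon]
            rec.w_con = float(w_con_f[k, r, c])
            rec.w_het = float(w_het_f[k, r, c])
        else:
            # taxon absent from the year_from map: all neighbours heterospecific
            from .grid import compute_crowding

            cr = compute_crowding(map_t, rec.taxon, q, kernel)
            rec.w_con, rec.w_het = cr.w_con, cr.w_het


def build_demography_table(
    maps: Mapping[str, Sequence[TurfMap]],
    kernel: KernelSpec = KernelSpec(),
    max_displacement: int = 1,
) -> pd.DataFrame:
    """Batch :func:`link_years` over turfs and years, attaching crowding.

    ``maps`` maps turf_id -> year-ordered TurfMaps.  Year gaps emit a warning
    and skip the transition.  Returns the long-format demography table.
    """
    all_records: List[DemographicRecord] = []
    for turf_id, turf_maps in maps.items():
        series = sorted(turf_maps, key=lambda m: m.year)
        if len(series) < 2:
            warnings.warn(f"turf {turf_id!r} has < 2 years; skipped")
            continue
        for m0, m1 in zip(series, series[1:]):
            if m1.year != m0.year + 1:
                warnings.warn(
                    f"turf {turf_id!r}: year gap {m0.year} -> {m1.year}; "
                    "transition skipped"
                )
                continue
            recs = link_years(m0, m1, max_displacement)
            _annotate_crowding(recs, m0, kernel)
            all_records.extend(recs)
    return records_to_frame(all_records)


def records_to_frame(records: Sequence[DemographicRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "turf_id": r.turf_id,
                "taxon": r.taxon,
                "year_from": r.year_from,
                "year_to": r.year_to,
                "event": r.event,
                "row_from": r.quadrant_from[0] if r.quadrant_from else pd.NA,
                "col_from": r.quadrant_from[1] if r.quadrant_from else pd.NA,
                "row_to": r.quadrant_to[0] if r.quadrant_to else pd.NA,
                "col_to": r.quadrant_to[1] if r.quadrant_to else pd.NA,
                "size_from_cm2": r.size_from,
                "size_to_cm2": r.size_to,
                "w_con": r.w_con,
                "w_het": r.w_het,
            }
        )
    columns = [
        "turf_id", "taxon", "year_from", "year_to", "event",
        "row_from", "col_from", "row_to", "col_to",
        "size_from_cm2", "size_to_cm2", "w_con", "w_het",
    ]
    return pd.DataFrame(rows, columns=columns)
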