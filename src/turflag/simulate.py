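"""Individual-based community simulator.

Annual synchronous update of a gridded turf: every unit survives with a
probability from the survival model, survivors draw a new size from the
growth model, and each (taxon, unoccupied quadrant) pair recruits with a
probability from the recruitment model.  All vital rates are evaluated on
the start-of-year map, so within-year update order cannot matter.

Only inner (surveyed) quadrants are updated demographically; buffer
quadrants keep their cover frozen but contribute to crowding.  There is no
immigration: once a taxon's cover hits zero it stays extinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import vital_rates as vr
from .climate import ClimateSeries
from .grid import GridSpec, KernelSpec, TurfMap, crowding_fields
from .summaries import shannon

__all__ = [
    "CommunityState",
    "EquilibriumCriterion",
    "EquilibrationError",
    "StepEvents",
    "Trajectory",
    "step_year",
    "equilibrate",
    "run_scenario",
    "run_no_lag",
    "run_stepwise",
]


@dataclass
class CommunityState:
    """Dense array view of one turf in one year.

    ``sizes`` is (n_taxa, n_side, n_side) cover in cm²; zero means absent.
    """

    turf_id: str
    year: int
    grid: GridSpec
    taxa: Tuple[str, ...]
    sizes: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        expected = (len(self.taxa), self.grid.n_side, self.grid.n_side)
        if self.sizes.shape != expected:
            raise ValueError(f"sizes shape {self.sizes.shape} != {expected}")

    @classmethod
    def from_turf_map(
        cls, turf_map: TurfMap, taxa: Optional[Sequence[str]] = None
    ) -> "CommunityState":
        taxa = tuple(taxa) if taxa is not None else tuple(turf_map.taxa())
        return cls(
            turf_id=turf_map.turf_id,
            year=turf_map.year,
            grid=turf_map.grid,
            taxa=taxa,
            sizes=turf_map.to_arrays(taxa),
        )

    def to_turf_map(self) -> TurfMap:
        return TurfMap.from_arrays(self.turf_id, self.year, self.grid, self.taxa, self.sizes)

    def copy(self) -> "CommunityState":
        return CommunityState(self.turf_id, self.year, self.grid, self.taxa, self.sizes.copy())

    def per_taxon_cover(self, inner_only: bool = True) -> np.ndarray:
        if inner_only:
            mask = self.grid.inner_mask()
            return self.sizes[:, mask].sum(axis=1)
        return self.sizes.reshape(len(self.taxa), -1).sum(axis=1)

    def total_cover(self, inner_only: bool = True) -> float:
        return float(self.per_taxon_cover(inner_only).sum())


@dataclass(frozen=True)
class EquilibriumCriterion:
    """Quasi-equilibrium halting rule on total cover between subsequent years.

    Halts when the total-cover growth rate |C'/C - 1| falls below
    ``growth_rate_threshold`` OR the absolute change |C' - C| falls below
    ``cover_change_frac`` of total turf area.
    """

    growth_rate_threshold: float = 0.05
    cover_change_frac: float = 0.005
    max_years: int = 500

    def __post_init__(self) -> None:
        if self.growth_rate_threshold <= 0 or self.cover_change_frac <= 0:
            raise ValueError("thresholds must be positive")
        if self.max_years < 1:
            raise ValueError("max_years must be >= 1")

    def satisfied(self, cover_before: float, cover_after: float, turf_area_cm2: float) -> bool:
        change = abs(cover_after - cover_before)
        if change < self.cover_change_frac * turf_area_cm2:
            return True
        if cover_before <= 0:
            return cover_after <= 0
        return abs(cover_after / cover_before - 1.0) < self.growth_rate_threshold


class EquilibrationError(RuntimeError):
    """Equilibration did not converge; carries the cover trajectory."""

    def __init__(self, message: str, trajectory: Optional[List[float]] = None, year: Optional[int] = None):
        super().__init__(message)
        self.trajectory = trajectory or []
        self.year = year


@dataclass
class StepEvents:
    """Ground-truth fates of one annual update (used by the data generator)."""

    survivals: List[Tuple[str, int, int, float, float]] = field(default_factory=list)
    deaths: List[Tuple[str, int, int, float]] = field(default_factory=list)
    recruits: List[Tuple[str, int, int, float]] = field(default_factory=list)


class _ParamTable:
    """Per-taxon parameter vectors for vectorised stepping."""

    def __init__(self, taxa: Sequence[str], params: Mapping[str, vr.TaxonParams]):
        missing = [t for t in taxa if t not in params]
        if missing:
            raise ValueError(f"missing parameters for taxa: {missing}")
        self.taxa = tuple(taxa)
        self.survival = [params[t].survival for t in taxa]
        self.growth = [params[t].growth for t in taxa]
        self.recruitment = [params[t].recruitment for t in taxa]
        self.u_init = np.array([params[t].recruitment.u_init for t in taxa])


def step_year(
    state: CommunityState,
    T_prev: float,
    moisture: float,
    params: Mapping[str, vr.TaxonParams],
    kernel: KernelSpec,
    rng: np.random.Generator,
    record_events: bool = False,
    u_min: float = vr.U_MIN,
    allow_immigration: bool = False,
) -> CommunityState | Tuple[CommunityState, StepEvents]:
    """One synchronous annual update of a turf.

    With ``allow_immigration=False`` (default) a taxon with zero cover in the
    whole turf cannot recruit, making extinction absorbing; set it to True to
    let the background recruitment rate operate even for absent taxa.
    """
    table = _ParamTable(state.taxa, params)
    grid = state.grid
    n_taxa = len(state.taxa)
    inner = grid.inner_mask()
    cap = grid.quadrant_area_cm2

    w_con, w_het = crowding_fields(state.sizes, grid, kernel)
    occupied = state.sizes > 0
    new_sizes = state.sizes.copy()
    events = StepEvents()

    u_surv = rng.random(state.sizes.shape)
    growth_noise = rng.normal(0.0, 1.0, size=state.sizes.shape)
    u_rec = rng.random(state.sizes.shape)

    for k in range(n_taxa):
        sp, gp, rp = table.survival[k], table.growth[k], table.recruitment[k]
        occ = occupied[k] & inner
        if occ.any():
            u_prev = state.sizes[k][occ]
            p_surv = vr.survival_prob(
                sp, T_prev, moisture, u_prev, w_con[k][occ], w_het[k][occ]
            )
            alive = u_surv[k][occ] < p_surv
            mean = vr.growth_mean(gp, T_prev, u_prev, w_con[k][occ], w_het[k][occ])
            grown = np.clip(mean + gp.sigma_eps * growth_noise[k][occ], u_min, cap)
            result = np.where(alive, grown, 0.0)
            new_sizes[k][occ] = result
            if record_events:
                rows, cols = np.nonzero(occ)
                for i, (r, c) in enumerate(zip(rows.tolist(), cols.tolist())):
                    if alive[i]:
                        events.survivals.append(
                            (state.taxa[k], r, c, float(u_prev[i]), float(result[i]))
                        )
                    else:
                        events.deaths.append((state.taxa[k], r, c, float(u_prev[i])))

        # recruitment into quadrants unoccupied by this taxon (inner only),
        # and only while the taxon is extant somewhere (no immigration)
        if allow_immigration or state.sizes[k].sum() > 0:
            empty = (~occupied[k]) & inner
            if empty.any():
                p_rec = vr.recruitment_prob(
                    rp, T_prev, w_con[k][empty], w_het[k][empty]
                )
                recruited = u_rec[k][empty] < p_rec
                vals = np.where(recruited, table.u_init[k], 0.0)
                new_sizes[k][empty] = vals
                if record_events:
                    rows, cols = np.nonzero(empty)
                    for i, (r, c) in enumerate(zip(rows.tolist(), cols.tolist())):
                        if recruited[i]:
                            events.recruits.append(
                                (state.taxa[k], r, c, float(table.u_init[k]))
                            )

    new_state = CommunityState(state.turf_id, state.year + 1, grid, state.taxa, new_sizes)
    if record_events:
        return new_state, events
    return new_state


def equilibrate(
    state: CommunityState,
    constant_T: float,
    moisture: float,
    params: Mapping[str, vr.TaxonParams],
    criterion: EquilibriumCriterion,
    kernel: KernelSpec,
    rng: np.random.Generator,
) -> CommunityState:
    """Iterate annual steps under constant climate until quasi-equilibrium.

    The criterion is applied to each taxon's summed cover separately; the
    loop halts at the first state where every taxon's between-year change
    satisfies it.  Raises :class:`EquilibrationError` after
    ``criterion.max_years`` steps.
    """
    area = state.grid.turf_area_cm2
    trajectory = [state.total_cover()]
    current = state
    for _ in range(criterion.max_years):
        nxt = step_year(current, constant_T, moisture, params, kernel, rng)
        c0, c1 = current.per_taxon_cover(), nxt.per_taxon_cover()
        trajectory.append(float(c1.sum()))
        if all(
            criterion.satisfied(float(a), float(b), area) for a, b in zip(c0, c1)
        ):
            return nxt
        current = nxt
    raise EquilibrationError(
        f"no quasi-equilibrium within {criterion.max_years} years "
        f"(T={constant_T:.2f})",
        trajectory=trajectory,
    )


@dataclass
class Trajectory:
    """Ensemble of per-year per-taxon total covers plus Shannon diversity.

    ``cover`` is (n_reps, n_years, n_taxa); ``shannon`` is (n_reps, n_years)
    with NaN where the community is empty.
    """

    scenario_id: str
    years: np.ndarray
    taxa: Tuple[str, ...]
    cover: np.ndarray
    shannon: np.ndarray

    @property
    def n_reps(self) -> int:
        return self.cover.shape[0]

    def summary(self) -> Dict[str, np.ndarray]:
        """Per-year median/q05/q95 of each taxon's cover and of diversity."""
        return {
            "cover_median": np.median(self.cover, axis=0),
            "cover_q05": np.quantile(self.cover, 0.05, axis=0),
            "cover_q95": np.quantile(self.cover, 0.95, axis=0),
            "shannon_median": np.nanmedian(self.shannon, axis=0),
            "shannon_q05": np.nanquantile(self.shannon, 0.05, axis=0),
            "shannon_q95": np.nanquantile(self.shannon, 0.95, axis=0),
        }

    def to_dataframe(self, include_summary: bool = True) -> pd.DataFrame:
        rows = []
        for r in range(self.n_reps):
            for i, year in enumerate(self.years):
                for k, taxon in enumerate(self.taxa):
                    rows.append(
                        {
                            "scenario_id": self.scenario_id,
                            "replicate": str(r),
                            "year": int(year),
                            "taxon": taxon,
                            "total_cover_cm2": float(self.cover[r, i, k]),
                        }
                    )
        if include_summary:
            s = self.summary()
            for label, arr in (
                ("median", s["cover_median"]),
                ("q05", s["cover_q05"]),
                ("q95", s["cover_q95"]),
            ):
                for i, year in enumerate(self.years):
                    for k, taxon in enumerate(self.taxa):
                        rows.append(
                            {
                                "scenario_id": self.scenario_id,
                                "replicate": label,
                                "year": int(year),
                                "taxon": taxon,
                                "total_cover_cm2": float(arr[i, k]),
                            }
                        )
        return pd.DataFrame(rows)

    def diversity_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in range(self.n_reps):
            for i, year in enumerate(self.years):
                rows.append(
                    {
                        "scenario_id": self.scenario_id,
                        "replicate": str(r),
                        "year": int(year),
                        "shannon": float(self.shannon[r, i]),
                    }
                )
        return pd.DataFrame(rows)


def _record(cover_arr, shannon_arr, r, i, state: CommunityState) -> None:
    per_taxon = state.per_taxon_cover()
    cover_arr[r, i] = per_taxon
    shannon_arr[r, i] = shannon(per_taxon) if per_taxon.sum() > 0 else np.nan


def run_scenario(
    initial: CommunityState,
    climate: ClimateSeries,
    params: Mapping[str, vr.TaxonParams],
    kernel: KernelSpec = KernelSpec(),
    n_reps: int = 20,
    seed: Optional[int] = None,
) -> Trajectory:
    """Project ``n_reps`` stochastic replicates over a climate series.

    Year i of the output is the state after stepping with the series'
    i-th temperature/moisture; replicate RNG streams are spawned from the
    seed, so results are bit-identical for identical (inputs, seed).
    """
    n_years = len(climate)
    n_taxa = len(initial.taxa)
    cover = np.zeros((n_reps, n_years, n_taxa))
    shan = np.zeros((n_reps, n_years))
    seeds = np.random.SeedSequence(seed).spawn(n_reps)
    for r in range(n_reps):
        rng = np.random.default_rng(seeds[r])
        state = initial.copy()
        for i in range(n_years):
            state = step_year(
                state, climate.t_summer[i], climate.moisture[i], params, kernel, rng
            )
            state.year = int(climate.years[i])
            _record(cover, shan, r, i, state)
    return Trajectory(climate.series_id, climate.years.copy(), tuple(initial.taxa), cover, shan)


def run_no_lag(
    initial: CommunityState,
    climate: ClimateSeries,
    params: Mapping[str, vr.TaxonParams],
    criterion: EquilibriumCriterion = EquilibriumCriterion(),
    kernel: KernelSpec = KernelSpec(),
    n_reps: int = 20,
    seed: Optional[int] = None,
) -> Trajectory:
    """Counterfactual projection with ecological lags removed.

    Each year the community is re-equilibrated to that year's climate before
    the year's state is recorded, so abundances always track the climate-
    driven quasi-equilibrium.
    """
    n_years = len(climate)
    n_taxa = len(initial.taxa)
    cover = np.zeros((n_reps, n_years, n_taxa))
    shan = np.zeros((n_reps, n_years))
    seeds = np.random.SeedSequence(seed).spawn(n_reps)
    for r in range(n_reps):
        rng = np.random.default_rng(seeds[r])
        state = initial.copy()
        for i in range(n_years):
            try:
                state = equilibrate(
                    state, climate.t_summer[i], climate.moisture[i], params,
                    criterion, kernel, rng,
                )
            except EquilibrationError as err:
                err.year = int(climate.years[i])
                raise
            state.year = int(climate.years[i])
            _record(cover, shan, r, i, state)
    return Trajectory(
        f"{climate.series_id}-nolag", climate.years.copy(), tuple(initial.taxa), cover, shan
    )


def run_stepwise(
    initial: CommunityState,
    source_climate: ClimateSeries,
    window: Tuple[int, int],
    n_years: int,
    params: Mapping[str, vr.TaxonParams],
    kernel: KernelSpec = KernelSpec(),
    n_reps: int = 20,
    seed: Optional[int] = None,
) -> Trajectory:
    """Project under an immediate jump to a climate window's statistics.

    Convenience wrapper building a stepwise series from ``source_climate``
    (sharing the seed between climate draws and dynamics) and running it.
    """
    from .climate import stepwise_scenario

    series = stepwise_scenario(
        source_climate, window[0], window[1], n_years, seed=seed,
        start_year=int(source_climate.years[0]),
    )
    return run_scenario(initial, series, params, kernel=kernel, n_reps=n_reps, seed=seed)
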