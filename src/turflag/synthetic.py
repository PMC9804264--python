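"""Synthetic study generator: parameter sets, turf-map time series produced
by the package's own vital-rate models, tracked-fate ground truth, and
climate series — everything needed to exercise tracking, inference,
validation and projection without any external data.

The default design mirrors a transplant layout: turfs from one home site are
"moved" to warmer sites offset by 0/2.2/3.3/5.5 K, surveyed annually on a
1 m grid of 5 cm quadrants with a 10 cm buffer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as tio
from . import vital_rates as vr
from .climate import ClimateSeries, constant_scenario
from .grid import GridSpec, KernelSpec, TurfMap, crowding_fields, make_grid
from .simulate import CommunityState, StepEvents, step_year

__all__ = [
    "SyntheticDesign",
    "SyntheticDataset",
    "sample_taxon_params",
    "generate_turf_series",
    "make_fixture_suite",
    "make_lag_fixture",
    "simulate_survival_data",
    "simulate_growth_data",
    "simulate_recruitment_data",
    "RECOVERY_SURVIVAL",
    "RECOVERY_GROWTH",
    "RECOVERY_RECRUITMENT",
    "RECOVERY_TEMPS",
]


@dataclass(frozen=True)
class SyntheticDesign:
    """Layout and sampling ranges of a synthetic transplant study."""

    n_taxa: int = 8
    n_turfs_per_site: int = 3
    site_offsets_k: Tuple[float, ...] = (0.0, 2.2, 3.3, 5.5)
    n_years: int = 4
    year0: int = 2017
    t_home: float = 12.3
    moisture: float = 0.5
    turf_side_m: float = 1.0
    quadrant_side_m: float = 0.05
    buffer_m: float = 0.10
    kernel_sigma_m: float = 0.05
    kernel_truncation_m: float = 0.15
    init_occupancy: float = 0.18
    burn_in_years: int = 25
    displacement_rate: float = 0.10
    populate_buffer: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_turfs_per_site < 1 or self.n_years < 1:
            raise ValueError("counts must be >= 1")
        if not all(np.isfinite(self.site_offsets_k)):
            raise ValueError("site offsets must be finite")

    @property
    def grid(self) -> GridSpec:
        return make_grid(self.turf_side_m, self.quadrant_side_m, self.buffer_m)

    @property
    def kernel(self) -> KernelSpec:
        return KernelSpec(self.kernel_sigma_m, self.kernel_truncation_m)

    @classmethod
    def full_scale(cls, **overrides) -> "SyntheticDesign":
        """Full-size layout: 10 turfs per site, 5 sites."""
        defaults = dict(
            n_turfs_per_site=10,
            site_offsets_k=(0.0, 1.0, 2.2, 3.3, 5.5),
            n_taxa=24,
        )
        defaults.update(overrides)
        return cls(**defaults)


def _uniform(rng, lo, hi):
    return float(rng.uniform(lo, hi))


def sample_taxon_params(
    design: SyntheticDesign, rng: np.random.Generator
) -> Dict[str, vr.TaxonParams]:
    """Draw per-taxon parameter sets with viable community dynamics.

    The first taxon gets a warm thermal optimum (peaks 2-4 K above the home
    temperature and recruits better when warm); the second a cold optimum
    (monotone decliner under warming); the rest are sampled around home
    conditions.
    """
    T0 = design.t_home
    params: Dict[str, vr.TaxonParams] = {}
    for i in range(design.n_taxa):
        name = f"t{i:02d}"
        if i == 0:  # warm-optimum taxon
            t_opt = T0 + _uniform(rng, 2.0, 4.0)
            r_ii1 = _uniform(rng, 0.08, 0.15)
            t_infl = t_opt + _uniform(rng, 2.0, 3.0)
        elif i == 1:  # cold-optimum taxon
            t_opt = T0 - _uniform(rng, 0.5, 2.0)
            r_ii1 = _uniform(rng, -0.08, -0.02)
            t_infl = T0 + _uniform(rng, 1.5, 3.0)
        else:
            t_opt = T0 + _uniform(rng, -1.0, 2.5)
            r_ii1 = _uniform(rng, -0.04, 0.08)
            t_infl = t_opt + _uniform(rng, 1.5, 3.5)

        a_ii1 = _uniform(rng, 0.0, 0.002)
        a_ij1 = _uniform(rng, 0.0, 0.002)
        survival = vr.SurvivalParams(
            lam_max=_uniform(rng, 3.5, 5.0),
            T_infl0=t_infl,
            m_moist=_uniform(rng, -0.5, 0.5),
            k_sig=_uniform(rng, 0.8, 1.5),
            b_S=_uniform(rng, 0.02, 0.08),
            a_ii0=_uniform(rng, 0.004, 0.015) - a_ii1 * T0,
            a_ii1=a_ii1,
            a_ij0=_uniform(rng, 0.004, 0.015) - a_ij1 * T0,
            a_ij1=a_ij1,
        )
        d_ii = _uniform(rng, 0.0, 0.05)
        d_ij = _uniform(rng, 0.0, 0.05)
        growth = vr.GrowthParams(
            g_max=_uniform(rng, 2.0, 3.5),
            T_opt=t_opt,
            sigma_T=_uniform(rng, 2.5, 4.0),
            b_G=_uniform(rng, 0.72, 0.82),
            c_ii=float(np.log(_uniform(rng, 0.004, 0.010))) - d_ii * T0,
            d_ii=d_ii,
            c_ij=float(np.log(_uniform(rng, 0.004, 0.012))) - d_ij * T0,
            d_ij=d_ij,
            sigma_eps=_uniform(rng, 0.5, 0.9),
        )
        r_ij1 = _uniform(rng, -0.02, 0.04)
        recruitment = vr.RecruitmentParams(
            r_ii0=float(np.log(_uniform(rng, 0.12, 0.25))) - r_ii1 * t_opt,
            r_ii1=r_ii1,
            r_ij0=float(np.log(_uniform(rng, 0.010, 0.030))) - r_ij1 * T0,
            r_ij1=r_ij1,
            theta_r=-5.0,
            u_init=0.25,
        )
        params[name] = vr.TaxonParams(name, survival, growth, recruitment)
    return params


# --- turf-series generation with ground truth --------------------------------

@dataclass
class SyntheticDataset:
    """A complete miniature study with known ground truth."""

    design: SyntheticDesign
    params: Dict[str, vr.TaxonParams]
    maps_observed: Dict[str, List[TurfMap]]
    maps_true: Dict[str, List[TurfMap]]
    truth_demography: pd.DataFrame
    recruit_trials: pd.DataFrame
    climate: Dict[str, ClimateSeries]
    site_of_turf: Dict[str, float] = field(default_factory=dict)


def _initial_state(
    design: SyntheticDesign, taxa: Sequence[str], rng: np.random.Generator, turf_id: str
) -> CommunityState:
    grid = design.grid
    n = grid.n_side
    sizes = np.zeros((len(taxa), n, n))
    region = grid.inner_mask() if not design.populate_buffer else np.ones((n, n), bool)
    occupy = rng.random((len(taxa), n, n)) < design.init_occupancy
    occupy &= region
    sizes[occupy] = rng.uniform(2.0, 10.0, size=int(occupy.sum()))
    return CommunityState(turf_id, design.year0 - 1, grid, tuple(taxa), sizes)


def _displace_survivors(
    events: StepEvents,
    new_state: CommunityState,
    design: SyntheticDesign,
    rng: np.random.Generator,
) -> Dict[Tuple[str, int, int], Tuple[int, int]]:
    """Assign observed positions to this year's units (true pos -> obs pos).

    Each survivor keeps its true quadrant except with probability
    ``displacement_rate``, when it is recorded one rook-step away — but only
    into an inner quadrant that is truly empty for that taxon and not already
    claimed, so observed maps keep one unit per taxon per quadrant.
    Recruits are never displaced.
    """
    grid = design.grid
    inner = grid.inner_range
    k_of = {t: k for k, t in enumerate(new_state.taxa)}
    new_obs: Dict[Tuple[str, int, int], Tuple[int, int]] = {}
    claimed: set = set()
    for taxon, r, c, _s0, _s1 in sorted(events.survivals):
        pos = (r, c)
        if rng.random() < design.displacement_rate:
            steps = [(0, 1), (0, -1), (1, 0), (-1, 0)]
            rng.shuffle(steps)
            for dr, dc in steps:
                cand = (r + dr, c + dc)
                if (
                    cand[0] in inner
                    and cand[1] in inner
                    and new_state.sizes[k_of[taxon], cand[0], cand[1]] <= 0
                    and (taxon, *cand) not in claimed
                ):
                    pos = cand
                    break
        claimed.add((taxon, *pos))
        new_obs[(taxon, r, c)] = pos
    for taxon, r, c, _s in sorted(events.recruits):
        new_obs[(taxon, r, c)] = (r, c)
    return new_obs


def generate_turf_series(
    design: SyntheticDesign,
    params: Dict[str, vr.TaxonParams],
    rng: Optional[np.random.Generator] = None,
) -> SyntheticDataset:
    """Forward-simulate every turf and record observed maps plus true fates.

    Each turf is burnt in at the home temperature, then stepped forward at
    its site temperature for ``n_years - 1`` transitions.  Observed maps may
    displace surviving units by one quadrant (observation noise); the truth
    table records each unit's true fate with observed from/to positions and
    crowding covariates from the true start-of-year map.
    """
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    taxa = tuple(sorted(params))
    grid = design.grid
    kernel = design.kernel

    maps_obs: Dict[str, List[TurfMap]] = {}
    maps_true: Dict[str, List[TurfMap]] = {}
    truth_rows: List[dict] = []
    trial_rows: List[dict] = []
    climate: Dict[str, ClimateSeries] = {}
    site_of_turf: Dict[str, float] = {}

    for s_idx, offset in enumerate(design.site_offsets_k):
        T_site = design.t_home + offset
        for j in range(design.n_turfs_per_site):
            turf_id = f"s{s_idx}_t{j}"
            site_of_turf[turf_id] = T_site
            climate[turf_id] = constant_scenario(
                T_site,
                design.n_years + 1,
                year0=design.year0 - 1,
                moisture=design.moisture,
                series_id=turf_id,
            )
            state = _initial_state(design, taxa, rng, turf_id)
            for _ in range(design.burn_in_years):
                state = step_year(state, design.t_home, design.moisture, params, kernel, rng)
            state.year = design.year0

            obs_pos = {
                (taxa[k], int(r), int(c)): (int(r), int(c))
                for k in range(len(taxa))
                for r, c in zip(*np.nonzero(state.sizes[k]))
            }
            maps_true[turf_id] = [state.copy().to_turf_map()]
            maps_obs[turf_id] = [_observed_map(state, obs_pos)]

            for step in range(design.n_years - 1):
                w_con, w_het = crowding_fields(state.sizes, grid, kernel)
                prev_state = state
                state, events = step_year(
                    state, T_site, design.moisture, params, kernel, rng, record_events=True
                )
                new_obs = _displace_survivors(events, state, design, rng)

                year_from, year_to = prev_state.year, state.year
                k_of = {t: k for k, t in enumerate(taxa)}
                for taxon, r, c, s0, s1 in events.survivals:
                    k = k_of[taxon]
                    fr = obs_pos[(taxon, r, c)]
                    to = new_obs[(taxon, r, c)]
                    truth_rows.append(dict(
                        turf_id=turf_id, taxon=taxon, year_from=year_from, year_to=year_to,
                        event="survival", row_from=fr[0], col_from=fr[1],
                        row_to=to[0], col_to=to[1], size_from_cm2=s0, size_to_cm2=s1,
                        w_con=float(w_con[k, r, c]), w_het=float(w_het[k, r, c]),
                        T_prev=T_site, moisture=design.moisture,
                    ))
                for taxon, r, c, s0 in events.deaths:
                    k = k_of[taxon]
                    fr = obs_pos[(taxon, r, c)]
                    truth_rows.append(dict(
                        turf_id=turf_id, taxon=taxon, year_from=year_from, year_to=year_to,
                        event="death", row_from=fr[0], col_from=fr[1],
                        row_to=None, col_to=None, size_from_cm2=s0, size_to_cm2=None,
                        w_con=float(w_con[k, r, c]), w_het=float(w_het[k, r, c]),
                        T_prev=T_site, moisture=design.moisture,
                    ))
                for taxon, r, c, s1 in events.recruits:
                    k = k_of[taxon]
                    truth_rows.append(dict(
                        turf_id=turf_id, taxon=taxon, year_from=year_from, year_to=year_to,
                        event="recruit", row_from=None, col_from=None,
                        row_to=r, col_to=c, size_from_cm2=None, size_to_cm2=s1,
                        w_con=float(w_con[k, r, c]), w_het=float(w_het[k, r, c]),
                        T_prev=T_site, moisture=design.moisture,
                    ))
                # recruitment trials: every (taxon, empty inner quadrant)
                inner = grid.inner_mask()
                recruited_at = {(t, r, c) for t, r, c, _ in events.recruits}
                for taxon in taxa:
                    k = k_of[taxon]
                    if prev_state.sizes[k].sum() <= 0:
                        continue
                    empty = (prev_state.sizes[k] <= 0) & inner
                    rows_, cols_ = np.nonzero(empty)
                    for r, c in zip(rows_.tolist(), cols_.tolist()):
                        trial_rows.append(dict(
                            turf_id=turf_id, taxon=taxon, year_from=year_from,
                            recruited=(taxon, r, c) in recruited_at,
                            w_con=float(w_con[k, r, c]), w_het=float(w_het[k, r, c]),
                            T_prev=T_site, moisture=design.moisture,
                        ))
                obs_pos = new_obs
                maps_true[turf_id].append(state.copy().to_turf_map())
                maps_obs[turf_id].append(_observed_map(state, obs_pos))

    return SyntheticDataset(
        design=design,
        params=params,
        maps_observed=maps_obs,
        maps_true=maps_true,
        truth_demography=pd.DataFrame(truth_rows),
        recruit_trials=pd.DataFrame(trial_rows),
        climate=climate,
        site_of_turf=site_of_turf,
    )


def _observed_map(state: CommunityState, obs_pos: Mapping[Tuple[str, int, int], Tuple[int, int]]) -> TurfMap:
    cover = {}
    k_of = {t: k for k, t in enumerate(state.taxa)}
    for (taxon, r, c), (ro, co) in obs_pos.items():
        size = state.sizes[k_of[taxon], r, c]
        if size > 0:
            cover[(taxon, ro, co)] = float(size)
    # buffer units (never displaced, not in obs_pos) pass through unchanged
    for k, taxon in enumerate(state.taxa):
        rows, cols = np.nonzero(state.sizes[k])
        for r, c in zip(rows.tolist(), cols.tolist()):
            if (taxon, int(r), int(c)) not in obs_pos and not state.grid.is_inner(r, c):
                cover[(taxon, int(r), int(c))] = float(state.sizes[k, r, c])
    return TurfMap(state.turf_id, state.year, state.grid, cover)


def make_fixture_suite(
    out_dir: str | Path, seed: int = 0, design: Optional[SyntheticDesign] = None
) -> SyntheticDataset:
    """Write a complete miniature study to ``out_dir``.

    Produces maps.csv (observed), maps_true.csv, climate.csv,
    true_params.json, true_demography.csv, recruit_trials.csv, config.yaml.
    Byte-identical for identical seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = design or SyntheticDesign(seed=seed)
    rng = np.random.default_rng(seed)
    params = sample_taxon_params(design, rng)
    data = generate_turf_series(design, params, rng)

    tio.write_maps(data.maps_observed, out / "maps.csv")
    tio.write_maps(data.maps_true, out / "maps_true.csv")
    tio.write_climate(data.climate, out / "climate.csv")
    tio.write_params(params, out / "true_params.json")
    data.truth_demography.to_csv(out / "true_demography.csv", index=False)
    data.recruit_trials.to_csv(out / "recruit_trials.csv", index=False)
    tio.write_config(
        design.grid, design.kernel, out / "config.yaml",
        extra={"seed": seed, "t_home": design.t_home, "moisture": design.moisture,
               "year0": design.year0, "n_years": design.n_years},
    )
    return data


# --- two-taxon ecological-lag demonstration fixture --------------------------

def make_lag_fixture(seed: int = 0):
    """Two-taxon community engineered to demonstrate ecological lags.

    The ``warm`` taxon has a thermal optimum ~3 K above the starting climate,
    a sharp size-dependent survival cliff, and conspecific-driven recruitment
    with a very low background rate: at the starting temperature its
    quasi-equilibrium is extinction, but its decline is slow enough for
    gradual warming to rescue it.  The ``cold`` taxon is a broadly tolerant
    slow expander whose transient keeps yearly re-equilibration running long.

    Returns ``(params, initial_state, climate, criterion)`` ready for
    lagged vs no-lag runs.
    """
    from .climate import gradual_scenario
    from .simulate import CommunityState, EquilibriumCriterion

    T0 = 12.3
    warm = vr.TaxonParams(
        "warm",
        vr.SurvivalParams(lam_max=0.2, T_infl0=T0 + 20, m_moist=0.0, k_sig=1.0,
                          b_S=2.5, a_ii0=0.0, a_ii1=0.0, a_ij0=0.2, a_ij1=0.0),
        vr.GrowthParams(g_max=3.5, T_opt=T0 + 3.0, sigma_T=1.2, b_G=0.8,
                        c_ii=-20.0, d_ii=0.0, c_ij=-20.0, d_ij=0.0, sigma_eps=0.4),
        vr.RecruitmentParams(r_ii0=float(np.log(0.6)) - 0.5 * (T0 + 3), r_ii1=0.5,
                             r_ij0=-20.0, r_ij1=0.0, theta_r=-12.0, u_init=0.25),
    )
    cold = vr.TaxonParams(
        "cold",
        vr.SurvivalParams(lam_max=4.0, T_infl0=T0 + 6, m_moist=0.0, k_sig=1.0,
                          b_S=0.05, a_ii0=0.01, a_ii1=0.0, a_ij0=0.005, a_ij1=0.0),
        vr.GrowthParams(g_max=2.4, T_opt=T0, sigma_T=5.0, b_G=0.8,
                        c_ii=-4.5, d_ii=0.0, c_ij=-5.0, d_ij=0.0, sigma_eps=0.6),
        vr.RecruitmentParams(r_ii0=float(np.log(0.2)), r_ii1=0.0, r_ij0=-5.0,
                             r_ij1=0.0, theta_r=-5.0, u_init=0.25),
    )
    params = {"warm": warm, "cold": cold}
    grid = make_grid(1.0, 0.05, 0.10)
    rng = np.random.default_rng(seed)
    n = grid.n_side
    sizes = np.zeros((2, n, n))  # taxa order: cold, warm
    inner = grid.inner_mask()
    occ_w = (rng.random((n, n)) < 0.30) & inner
    occ_c = (rng.random((n, n)) < 0.12) & inner & ~occ_w
    sizes[1][occ_w] = rng.uniform(4.0, 8.0, int(occ_w.sum()))
    sizes[0][occ_c] = rng.uniform(6.0, 12.0, int(occ_c.sum()))
    initial = CommunityState("lagfx", 2020, grid, ("cold", "warm"), sizes)
    climate = gradual_scenario(T0, 3.0, 2021, 2050, shape="linear",
                               interannual_sd=0.0, series_id="lagfx-gradual")
    criterion = EquilibriumCriterion(
        growth_rate_threshold=0.03, cover_change_frac=0.001, max_years=400
    )
    return params, initial, climate, criterion


# --- independent covariate draws for the parameter-recovery harness ----------

#: site temperatures used when simulating recovery data (4 sites over ~5 K)
RECOVERY_TEMPS = (12.3, 14.5, 15.6, 17.8)

RECOVERY_SURVIVAL = vr.SurvivalParams(
    lam_max=4.0, T_infl0=15.0, m_moist=2.0, k_sig=1.0, b_S=0.05,
    a_ii0=0.01, a_ii1=0.002, a_ij0=0.015, a_ij1=0.001,
)
RECOVERY_GROWTH = vr.GrowthParams(
    g_max=3.0, T_opt=14.5, sigma_T=2.0, b_G=0.8,
    c_ii=-4.0, d_ii=0.05, c_ij=-3.5, d_ij=0.02, sigma_eps=0.8,
)
RECOVERY_RECRUITMENT = vr.RecruitmentParams(
    r_ii0=-3.0, r_ii1=0.1, r_ij0=-4.0, r_ij1=0.05, theta_r=-5.0, u_init=0.25,
)


def _covariates(n: int, rng: np.random.Generator):
    T = rng.choice(RECOVERY_TEMPS, size=n)
    M = rng.uniform(0.0, 1.0, size=n)
    u = rng.uniform(0.5, 12.0, size=n)
    wc = rng.uniform(0.0, 30.0, size=n)
    wh = rng.uniform(0.0, 40.0, size=n)
    return T, M, u, wc, wh


def simulate_survival_data(
    n: int, rng: np.random.Generator, params: vr.SurvivalParams = RECOVERY_SURVIVAL
) -> pd.DataFrame:
    """Bernoulli survival outcomes drawn from the survival model itself."""
    T, M, u, wc, wh = _covariates(n, rng)
    p = vr.survival_prob(params, T, M, u, wc, wh)
    alive = rng.random(n) < p
    return pd.DataFrame({
        "event": np.where(alive, "survival", "death"),
        "T_prev": T, "moisture": M, "size_from_cm2": u, "w_con": wc, "w_het": wh,
    })


def simulate_growth_data(
    n: int, rng: np.random.Generator, params: vr.GrowthParams = RECOVERY_GROWTH
) -> pd.DataFrame:
    """Gaussian next-size outcomes from the growth model (no truncation, so
    the Gaussian likelihood used by the fitter is exact)."""
    T, M, u, wc, wh = _covariates(n, rng)
    mu = vr.growth_mean(params, T, u, wc, wh)
    u1 = mu + rng.normal(0.0, params.sigma_eps, size=n)
    return pd.DataFrame({
        "event": "survival", "T_prev": T, "moisture": M,
        "size_from_cm2": u, "size_to_cm2": u1, "w_con": wc, "w_het": wh,
    })


def simulate_recruitment_data(
    n: int, rng: np.random.Generator, params: vr.RecruitmentParams = RECOVERY_RECRUITMENT
) -> pd.DataFrame:
    """Bernoulli recruitment outcomes for unoccupied quadrant-years."""
    T = rng.choice(RECOVERY_TEMPS, size=n)
    # conspecific crowding: half the quadrants have no conspecifics nearby
    wc = np.where(rng.random(n) < 0.5, 0.0, rng.exponential(10.0, size=n))
    wh = rng.uniform(0.0, 60.0, size=n)
    p = vr.recruitment_prob(params, T, wc, wh)
    rec = rng.random(n) < p
    return pd.DataFrame({
        "recruited": rec, "T_prev": T, "moisture": 0.5, "w_con": wc, "w_het": wh,
    })
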