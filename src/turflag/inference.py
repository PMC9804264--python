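"""Fit vital-rate parameters to demography tables by regularised MAP
estimation, with curvature-based standard errors, plus the sum-of-squared-
residuals validation rule used to decide which taxa enter projections.

Parameters that must stay positive (``k_sig``, ``sigma_T``, ``sigma_eps``)
are optimised on the log scale; priors are Gaussian on the internal
(unconstrained) scale — SD 2 for intercept-like parameters, SD 1 for slopes
and log-scale parameters, and a wide prior centred on the observed mean
temperature for the temperature-location parameters.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from . import vital_rates as vr
from .climate import ClimateSeries
from .grid import KernelSpec, TurfMap
from .summaries import log_cover_ratio

__all__ = [
    "FitResult",
    "ValidationResult",
    "attach_climate",
    "fit_survival",
    "fit_growth",
    "fit_recruitment",
    "fit_all",
    "validate_taxon",
    "select_taxa",
    "survival_params_to_internal",
    "growth_params_to_internal",
    "recruitment_params_to_internal",
]


def attach_climate(records: pd.DataFrame, climate: Mapping[str, ClimateSeries]) -> pd.DataFrame:
    """Add T_prev and moisture columns, looked up per turf at year_from."""
    out = records.copy()
    t_prev = np.empty(len(out))
    moist = np.empty(len(out))
    for i, (turf, year) in enumerate(zip(out["turf_id"], out["year_from"])):
        series = climate[turf]
        idx = np.nonzero(series.years == year)[0]
        if not len(idx):
            raise ValueError(f"no climate for turf {turf!r} year {year}")
        t_prev[i] = series.t_summer[idx[0]]
        moist[i] = series.moisture[idx[0]]
    out["T_prev"] = t_prev
    out["moisture"] = moist
    return out


@dataclass
class FitResult:
    """MAP estimate of one vital-rate model for one taxon."""

    taxon: str
    model: str
    estimates: Dict[str, float]
    se: Dict[str, float]            # on the internal (unconstrained) scale
    x: np.ndarray                   # internal parameter vector at the optimum
    x_names: List[str]
    x_truth_scale: Dict[str, float] = field(default_factory=dict)
    log_posterior: float = float("nan")
    n_obs: int = 0
    converged: bool = False
    diagnostics: Dict[str, object] = field(default_factory=dict)

    def within(self, truth_internal: Mapping[str, float], n_se: float = 3.0) -> bool:
        """True if every internal parameter lies within n_se SEs of truth."""
        for name, true_val in truth_internal.items():
            i = self.x_names.index(name)
            se = self.se[name]
            if not math.isfinite(se) or abs(self.x[i] - true_val) > n_se * se:
                return False
        return True


def _hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian."""
    n = len(x)
    H = np.zeros((n, n))
    hs = eps * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = hs[i]
            ej = np.zeros(n); ej[j] = hs[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hs[i] * hs[j])
    return H


def _map_fit(
    nll_grad,
    names: Sequence[str],
    prior_mean: np.ndarray,
    prior_sd: np.ndarray,
    seed: int,
    n_starts: int = 3,
    tol: float = 1e-8,
):
    """Minimise nll + Gaussian prior penalty from several seeded starts.

    ``nll_grad(x)`` returns (value, gradient); the analytic gradient keeps
    desk-scale recovery studies fast.
    """

    def neg_log_post(x: np.ndarray):
        val, grad = nll_grad(x)
        dx = (x - prior_mean) / prior_sd
        val = val + 0.5 * float((dx**2).sum())
        grad = grad + dx / prior_sd
        if not np.isfinite(val):
            return 1e12, np.zeros_like(x)
        return val, grad

    rng = np.random.default_rng(seed)
    starts = [prior_mean.copy()]
    for _ in range(n_starts - 1):
        starts.append(prior_mean + rng.normal(0.0, 0.5, size=len(prior_mean)) * prior_sd)

    best = None
    for x0 in starts:
        res = optimize.minimize(neg_log_post, x0, method="L-BFGS-B", jac=True, tol=tol)
        if best is None or res.fun < best.fun:
            best = res

    H = _hessian(lambda x: neg_log_post(x)[0], best.x)
    diagnostics: Dict[str, object] = {"n_starts": n_starts, "optimizer_success": bool(best.success)}
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.any(diag <= 0):
            raise np.linalg.LinAlgError("non-positive curvature")
        se = np.sqrt(diag)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        se = np.sqrt(np.abs(np.diag(cov)))
        diagnostics["hessian_singular"] = True
    diagnostics["cov"] = cov
    return best.x, dict(zip(names, se)), -best.fun, bool(best.success), diagnostics


_SURV_NAMES = ["lam_max", "T_infl0", "m_moist", "log_k_sig", "b_S",
               "a_ii0", "a_ii1", "a_ij0", "a_ij1"]
_GROWTH_NAMES = ["g_max", "T_opt", "log_sigma_T", "b_G",
                 "c_ii", "d_ii", "c_ij", "d_ij", "log_sigma_eps"]
_REC_NAMES = ["r_ii0", "r_ii1", "r_ij0", "r_ij1"]


def survival_params_to_internal(p: vr.SurvivalParams) -> Dict[str, float]:
    return {
        "lam_max": p.lam_max, "T_infl0": p.T_infl0, "m_moist": p.m_moist,
        "log_k_sig": math.log(p.k_sig), "b_S": p.b_S,
        "a_ii0": p.a_ii0, "a_ii1": p.a_ii1, "a_ij0": p.a_ij0, "a_ij1": p.a_ij1,
    }


def growth_params_to_internal(p: vr.GrowthParams) -> Dict[str, float]:
    return {
        "g_max": p.g_max, "T_opt": p.T_opt, "log_sigma_T": math.log(p.sigma_T),
        "b_G": p.b_G, "c_ii": p.c_ii, "d_ii": p.d_ii, "c_ij": p.c_ij, "d_ij": p.d_ij,
        "log_sigma_eps": math.log(p.sigma_eps),
    }


def recruitment_params_to_internal(p: vr.RecruitmentParams) -> Dict[str, float]:
    return {"r_ii0": p.r_ii0, "r_ii1": p.r_ii1, "r_ij0": p.r_ij0, "r_ij1": p.r_ij1}


def _survival_from_x(x: np.ndarray) -> vr.SurvivalParams:
    return vr.SurvivalParams(
        lam_max=x[0], T_infl0=x[1], m_moist=x[2], k_sig=math.exp(x[3]), b_S=x[4],
        a_ii0=x[5], a_ii1=x[6], a_ij0=x[7], a_ij1=x[8],
    )


def _growth_from_x(x: np.ndarray) -> vr.GrowthParams:
    return vr.GrowthParams(
        g_max=x[0], T_opt=x[1], sigma_T=math.exp(x[2]), b_G=x[3],
        c_ii=x[4], d_ii=x[5], c_ij=x[6], d_ij=x[7], sigma_eps=math.exp(x[8]),
    )


def _recruitment_from_x(x: np.ndarray, theta_r: float, u_init: float) -> vr.RecruitmentParams:
    return vr.RecruitmentParams(
        r_ii0=x[0], r_ii1=x[1], r_ij0=x[2], r_ij1=x[3], theta_r=theta_r, u_init=u_init,
    )


def _default_priors(names: Sequence[str], T_centre: float) -> Tuple[np.ndarray, np.ndarray]:
    mean, sd = [], []
    for name in names:
        if name in ("T_infl0", "T_opt"):
            mean.append(T_centre); sd.append(5.0)
        elif name.startswith("log_"):
            mean.append(0.0); sd.append(1.0)
        elif name.endswith("1") or name in ("d_ii", "d_ij", "b_S", "b_G", "m_moist"):
            mean.append(0.0); sd.append(1.0)   # slope-like
        else:
            mean.append(0.0); sd.append(2.0)   # intercept-like
    return np.array(mean), np.array(sd)


def _bernoulli_nll(z: np.ndarray, y: np.ndarray) -> float:
    # -log p = softplus(-z) for y=1, softplus(z) for y=0
    return float(np.logaddexp(0.0, np.where(y, -z, z)).sum())


def _merge_climate(records, climate):
    if climate is not None and "T_prev" not in records.columns:
        return attach_climate(records, climate)
    if "T_prev" not in records.columns:
        raise ValueError("records need T_prev (pass a climate mapping or merge first)")
    return records


def fit_survival(
    records: pd.DataFrame,
    climate: Optional[Mapping[str, ClimateSeries]] = None,
    priors: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    seed: int = 0,
    taxon: str = "",
) -> FitResult:
    """MAP fit of the survival model to survival/death records.

    ``records`` must contain event in {survival, death}, size_from_cm2,
    w_con, w_het, and (after climate merge) T_prev and moisture.
    """
    df = _merge_climate(records, climate)
    df = df[df["event"].isin(["survival", "death"])]
    y = (df["event"] == "survival").to_numpy()
    if len(np.unique(y)) < 2:
        sep_flag = True
    else:
        sep_flag = False
    T = df["T_prev"].to_numpy(float)
    M = df["moisture"].to_numpy(float) if "moisture" in df else np.full(len(df), 0.5)
    u = df["size_from_cm2"].to_numpy(float)
    wc = df["w_con"].to_numpy(float)
    wh = df["w_het"].to_numpy(float)

    def nll_grad(x: np.ndarray):
        lam_max, T_infl0, m_moist, log_k, b_S, a_ii0, a_ii1, a_ij0, a_ij1 = x
        k = math.exp(min(max(log_k, -6.0), 6.0))
        infl = T_infl0 + m_moist * M
        sig = expit(-k * (T - infl))
        z = lam_max * sig + b_S * u - (a_ii0 + a_ii1 * T) * wc - (a_ij0 + a_ij1 * T) * wh
        p = expit(z)
        dz = p - y  # d(-loglik)/dz
        s1 = lam_max * sig * (1 - sig)
        grad = np.array([
            (dz * sig).sum(),
            (dz * s1 * k).sum(),
            (dz * s1 * k * M).sum(),
            (dz * s1 * (-(T - infl)) * k).sum(),
            (dz * u).sum(),
            -(dz * wc).sum(),
            -(dz * T * wc).sum(),
            -(dz * wh).sum(),
            -(dz * T * wh).sum(),
        ])
        return _bernoulli_nll(z, y), grad

    prior_mean, prior_sd = priors or _default_priors(_SURV_NAMES, float(T.mean()))
    x, se, logpost, ok, diag = _map_fit(nll_grad, _SURV_NAMES, prior_mean, prior_sd, seed)
    diag["separation"] = sep_flag
    p_hat = _survival_from_x(x)
    return FitResult(
        taxon=taxon, model="survival", estimates=p_hat.to_dict(), se=se,
        x=x, x_names=list(_SURV_NAMES), log_posterior=logpost,
        n_obs=len(df), converged=ok and not sep_flag, diagnostics=diag,
    )


def fit_growth(
    records: pd.DataFrame,
    climate: Optional[Mapping[str, ClimateSeries]] = None,
    priors: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    seed: int = 0,
    taxon: str = "",
) -> FitResult:
    """MAP fit of the growth model to survival (grower) records."""
    df = _merge_climate(records, climate)
    df = df[df["event"] == "survival"]
    T = df["T_prev"].to_numpy(float)
    u0 = df["size_from_cm2"].to_numpy(float)
    u1 = df["size_to_cm2"].to_numpy(float)
    wc = df["w_con"].to_numpy(float)
    wh = df["w_het"].to_numpy(float)

    def nll_grad(x: np.ndarray):
        g_max, T_opt, log_sT, b_G, c_ii, d_ii, c_ij, d_ij, log_se = x
        # clip transformed scales so line-search excursions cannot overflow
        sT = math.exp(min(max(log_sT, -6.0), 6.0))
        s = math.exp(min(max(log_se, -6.0), 6.0))
        dT = T - T_opt
        G = np.exp(-np.minimum((dT**2) / (2 * sT**2), 700.0))
        a_con = np.exp(np.minimum(c_ii + d_ii * T, 50.0))
        a_het = np.exp(np.minimum(c_ij + d_ij * T, 50.0))
        mu = g_max * G + b_G * u0 - a_con * wc - a_het * wh
        r = u1 - mu
        dmu = -r / s**2  # d(-loglik)/dmu
        grad = np.array([
            (dmu * G).sum(),
            (dmu * g_max * G * dT / sT**2).sum(),
            (dmu * g_max * G * dT**2 / sT**2).sum(),
            (dmu * u0).sum(),
            -(dmu * a_con * wc).sum(),
            -(dmu * T * a_con * wc).sum(),
            -(dmu * a_het * wh).sum(),
            -(dmu * T * a_het * wh).sum(),
            (1.0 - (r / s) ** 2).sum(),
        ])
        val = float((0.5 * (r / s) ** 2 + math.log(s)).sum())
        if not np.isfinite(val) or not np.all(np.isfinite(grad)):
            return 1e12, np.zeros_like(x)
        return val, grad

    prior_mean, prior_sd = priors or _default_priors(_GROWTH_NAMES, float(T.mean()))
    x, se, logpost, ok, diag = _map_fit(nll_grad, _GROWTH_NAMES, prior_mean, prior_sd, seed)
    if len(np.unique(np.round(T, 6))) < 2:
        diag["temperature_ridge"] = True  # T_opt/sigma_T unidentifiable
    p_hat = _growth_from_x(x)
    return FitResult(
        taxon=taxon, model="growth", estimates=p_hat.to_dict(), se=se,
        x=x, x_names=list(_GROWTH_NAMES), log_posterior=logpost,
        n_obs=len(df), converged=ok, diagnostics=diag,
    )


def fit_recruitment(
    records: pd.DataFrame,
    climate: Optional[Mapping[str, ClimateSeries]] = None,
    priors: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    seed: int = 0,
    taxon: str = "",
    theta_r: float = -5.0,
    u_init: float = 0.25,
) -> FitResult:
    """MAP fit of the recruitment model to empty->occupied quadrant outcomes.

    ``records`` holds one row per (quadrant-year) that was unoccupied by the
    taxon, with a boolean/0-1 ``recruited`` column plus T_prev, w_con, w_het.
    """
    df = _merge_climate(records, climate)
    y = df["recruited"].to_numpy(bool)
    T = df["T_prev"].to_numpy(float)
    wc = df["w_con"].to_numpy(float)
    wh = df["w_het"].to_numpy(float)

    def nll_grad(x: np.ndarray):
        r_ii0, r_ii1, r_ij0, r_ij1 = x
        A = np.exp(np.minimum(r_ii0 + r_ii1 * T, 50.0))
        B = np.exp(np.minimum(r_ij0 + r_ij1 * T, 50.0))
        z = A * wc - B * wh + theta_r
        dz = expit(z) - y
        grad = np.array([
            (dz * A * wc).sum(),
            (dz * T * A * wc).sum(),
            -(dz * B * wh).sum(),
            -(dz * T * B * wh).sum(),
        ])
        return _bernoulli_nll(z, y), grad

    prior_mean, prior_sd = priors or _default_priors(_REC_NAMES, float(T.mean()))
    x, se, logpost, ok, diag = _map_fit(nll_grad, _REC_NAMES, prior_mean, prior_sd, seed)
    p_hat = _recruitment_from_x(x, theta_r, u_init)
    return FitResult(
        taxon=taxon, model="recruitment", estimates=p_hat.to_dict(), se=se,
        x=x, x_names=list(_REC_NAMES), log_posterior=logpost,
        n_obs=len(df), converged=ok, diagnostics=diag,
    )


def fit_all(
    demog: pd.DataFrame,
    recruit_trials: pd.DataFrame,
    climate: Optional[Mapping[str, ClimateSeries]] = None,
    seed: int = 0,
    min_obs: int = 0,
) -> Dict[str, vr.TaxonParams]:
    """Fit all three models per taxon and bundle the point estimates."""
    taxa = select_taxa(demog, min_obs) if min_obs else sorted(demog["taxon"].unique())
    out: Dict[str, vr.TaxonParams] = {}
    for i, taxon in enumerate(taxa):
        sub = demog[demog["taxon"] == taxon]
        rec_sub = recruit_trials[recruit_trials["taxon"] == taxon]
        fs = fit_survival(sub, climate, seed=seed + 3 * i, taxon=taxon)
        fg = fit_growth(sub, climate, seed=seed + 3 * i + 1, taxon=taxon)
        fr = fit_recruitment(rec_sub, climate, seed=seed + 3 * i + 2, taxon=taxon)
        out[taxon] = vr.TaxonParams(
            taxon=taxon,
            survival=vr.SurvivalParams.from_dict(fs.estimates),
            growth=vr.GrowthParams.from_dict(fg.estimates),
            recruitment=vr.RecruitmentParams.from_dict(fr.estimates),
        )
    return out


@dataclass
class ValidationResult:
    """Outcome of the predicted-vs-observed log cover-ratio check."""

    taxon: str
    turf_ids: List[str]
    predicted: np.ndarray
    observed: np.ndarray
    ssr_model: float
    ssr_null: float
    ssr_ratio: float
    included: bool

    @classmethod
    def from_ratios(cls, taxon: str, turf_ids, predicted, observed, threshold: float = 0.80):
        predicted = np.asarray(predicted, dtype=float)
        observed = np.asarray(observed, dtype=float)
        ssr_model = float(((predicted - observed) ** 2).sum())
        ssr_null = float((observed**2).sum())
        ratio = ssr_model / ssr_null if ssr_null > 0 else (0.0 if ssr_model == 0 else float("inf"))
        return cls(
            taxon=taxon, turf_ids=list(turf_ids), predicted=predicted,
            observed=observed, ssr_model=ssr_model, ssr_null=ssr_null,
            ssr_ratio=ratio, included=bool(ratio <= threshold),
        )


def validate_taxon(
    taxon: str,
    params: Mapping[str, vr.TaxonParams],
    initial_maps: Sequence[TurfMap],
    observed_final: Sequence[TurfMap],
    climate: Mapping[str, ClimateSeries],
    kernel: KernelSpec = KernelSpec(),
    n_reps: int = 20,
    seed: int = 0,
    pseudo: float = 0.25,
    threshold: float = 0.80,
) -> ValidationResult:
    """Simulate forward from initial maps and compare per-turf predicted and
    observed log cover ratios of one taxon against a no-change null.

    ``included`` is True when the model's summed squared residuals are at
    most ``threshold`` (default 80%) of the null's.
    """
    from .simulate import CommunityState, step_year

    finals = {m.turf_id: m for m in observed_final}
    if not any(
        m.total_cover(taxon, inner_only=True) > 0
        for m in initial_maps
        if m.turf_id in finals
    ):
        raise ValueError(f"taxon {taxon!r} absent from every initial map")
    preds, obs, turfs = [], [], []
    for init in initial_maps:
        if init.turf_id not in finals:
            continue
        fin = finals[init.turf_id]
        h = fin.year - init.year
        if h < 1:
            raise ValueError(f"final year must exceed initial year on turf {init.turf_id!r}")
        init_cover = init.total_cover(taxon, inner_only=True)
        series = climate[init.turf_id]
        t_idx = {int(y): i for i, y in enumerate(series.years)}
        temps = [series.t_summer[t_idx[y]] for y in range(init.year, fin.year)]
        moists = [series.moisture[t_idx[y]] for y in range(init.year, fin.year)]

        taxa = tuple(sorted(set(init.taxa()) | {taxon}))
        base = CommunityState.from_turf_map(init, taxa)
        k = taxa.index(taxon)
        turf_key = zlib.crc32(init.turf_id.encode()) & 0xFFFF
        seeds = np.random.SeedSequence((seed, turf_key)).spawn(n_reps)
        ratios = np.empty(n_reps)
        for r in range(n_reps):
            rng = np.random.default_rng(seeds[r])
            state = base.copy()
            for T, M in zip(temps, moists):
                state = step_year(state, T, M, params, kernel, rng)
            final_cover = float(state.per_taxon_cover()[k])
            ratios[r] = log_cover_ratio(init_cover, final_cover, pseudo)
        preds.append(float(np.median(ratios)))
        obs.append(log_cover_ratio(init_cover, fin.total_cover(taxon, inner_only=True), pseudo))
        turfs.append(init.turf_id)
    return ValidationResult.from_ratios(taxon, turfs, preds, obs, threshold)


def select_taxa(records: pd.DataFrame, min_obs: int = 1000) -> List[str]:
    """Taxa with at least ``min_obs`` demographic records."""
    if records.empty:
        return []
    counts = records.groupby("taxon").size()
    return sorted(counts[counts >= min_obs].index.tolist())
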