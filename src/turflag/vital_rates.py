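"""Climate- and density-dependent vital-rate models.

Three per-taxon demographic models drive the simulator, all functions of the
previous summer's mean temperature ``T_prev``, the focal unit's size
``u_prev`` (cm²) and the conspecific / heterospecific crowding indices
``w_con`` / ``w_het``:

survival (logistic)::

    logit(s) = lam(T, M) + b_S*u - a_con(T)*w_con - a_het(T)*w_het
    lam(T, M) = lam_max / (1 + exp(k_sig*(T - (T_infl0 + m_moist*M))))
    a_con(T)  = a_ii0 + a_ii1*T      (linear in T, either sign)
    a_het(T)  = a_ij0 + a_ij1*T

growth (Gaussian mean on the cover scale)::

    E[u'] = g_max*exp(-(T - T_opt)²/(2*sigma_T²)) + b_G*u
            - exp(c_ii + d_ii*T)*w_con - exp(c_ij + d_ij*T)*w_het

    realisations add N(0, sigma_eps) noise, truncated to [u_min, cover cap];
    neighbour effects on growth are strictly negative by construction.

recruitment (logistic, unoccupied quadrants only)::

    logit(r) = exp(r_ii0 + r_ii1*T)*w_con - exp(r_ij0 + r_ij1*T)*w_het + theta_r

    conspecific neighbours act as propagule sources (positive), hetero-
    specifics compete (negative); theta_r is a fixed background log-odds,
    default -5.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any, Dict, Mapping

import numpy as np
from scipy.special import expit

__all__ = [
    "SurvivalParams",
    "GrowthParams",
    "RecruitmentParams",
    "TaxonParams",
    "survival_logit",
    "survival_prob",
    "growth_mean",
    "sample_growth",
    "recruitment_logit",
    "recruitment_prob",
    "inv_logit",
    "U_MIN",
]

#: lower size bound applied when truncating growth realisations (cm²).
#: A size at the bound does NOT imply death; mortality comes only from the
#: survival model.
U_MIN = 0.1

inv_logit = expit


def _check_finite(**kwargs: Any) -> None:
    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)):
            raise ValueError(f"{name} must be finite")


def _from_dict(cls, data: Mapping[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    missing = {
        f.name
        for f in dataclasses.fields(cls)
        if f.default is dataclasses.MISSING and f.name not in data
    }
    if missing:
        raise ValueError(f"missing {cls.__name__} fields: {sorted(missing)}")
    return cls(**{k: float(v) for k, v in data.items()})


@dataclass(frozen=True)
class SurvivalParams:
    """Parameters of the survival model (logit scale)."""

    lam_max: float = 4.0       # upper asymptote of the intrinsic survival logit
    T_infl0: float = 16.0      # sigmoid inflection temperature (°C) at moisture 0
    m_moist: float = 0.0       # shift of the inflection per moisture unit (°C)
    k_sig: float = 1.0         # sigmoid steepness (per °C), > 0
    b_S: float = 0.05          # size effect (per cm²)
    a_ii0: float = 0.01        # conspecific coefficient: intercept
    a_ii1: float = 0.0         # conspecific coefficient: slope (per °C)
    a_ij0: float = 0.01        # heterospecific coefficient: intercept
    a_ij1: float = 0.0         # heterospecific coefficient: slope (per °C)

    def __post_init__(self) -> None:
        _check_finite(**dataclasses.asdict(self))
        if self.k_sig <= 0:
            raise ValueError("k_sig must be positive")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SurvivalParams":
        return _from_dict(cls, data)

    def to_dict(self) -> Dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the growth model (cover scale, cm²)."""

    g_max: float = 3.0         # intrinsic growth height at the thermal optimum
    T_opt: float = 13.0        # optimal temperature (°C)
    sigma_T: float = 3.0       # Gaussian temperature width (°C), > 0
    b_G: float = 0.8           # size effect (per cm²)
    c_ii: float = -4.0         # log conspecific coefficient: intercept
    d_ii: float = 0.0          # log conspecific coefficient: slope (per °C)
    c_ij: float = -4.0         # log heterospecific coefficient: intercept
    d_ij: float = 0.0          # log heterospecific coefficient: slope (per °C)
    sigma_eps: float = 0.8     # residual SD of next size (cm²), > 0

    def __post_init__(self) -> None:
        _check_finite(**dataclasses.asdict(self))
        if self.sigma_T <= 0:
            raise ValueError("sigma_T must be positive")
        if self.sigma_eps <= 0:
            raise ValueError("sigma_eps must be positive")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "GrowthParams":
        return _from_dict(cls, data)

    def to_dict(self) -> Dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class RecruitmentParams:
    """Parameters of the recruitment model (logit scale)."""

    r_ii0: float = -1.5        # log conspecific (facilitative) coefficient: intercept
    r_ii1: float = 0.0         # slope (per °C)
    r_ij0: float = -4.0        # log heterospecific (competitive) coefficient: intercept
    r_ij1: float = 0.0         # slope (per °C)
    theta_r: float = -5.0      # background recruitment log-odds, fixed by default
    u_init: float = 0.25       # initial recruit size (cm²)

    def __post_init__(self) -> None:
        _check_finite(**dataclasses.asdict(self))
        if not 0.0 < self.u_init <= 25.0:
            raise ValueError("u_init must be in (0, 25]")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RecruitmentParams":
        return _from_dict(cls, data)

    def to_dict(self) -> Dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class TaxonParams:
    """Per-taxon bundle of the three vital-rate parameter sets."""

    taxon: str
    survival: SurvivalParams
    growth: GrowthParams
    recruitment: RecruitmentParams

    @classmethod
    def from_dict(cls, taxon: str, data: Mapping[str, Any]) -> "TaxonParams":
        unknown = set(data) - {"survival", "growth", "recruitment"}
        if unknown:
            raise ValueError(f"unknown TaxonParams sections: {sorted(unknown)}")
        return cls(
            taxon=taxon,
            survival=SurvivalParams.from_dict(data.get("survival", {})),
            growth=GrowthParams.from_dict(data.get("growth", {})),
            recruitment=RecruitmentParams.from_dict(data.get("recruitment", {})),
        )

    def to_dict(self) -> Dict[str, Dict[str, float]]:
        return {
            "survival": self.survival.to_dict(),
            "growth": self.growth.to_dict(),
            "recruitment": self.recruitment.to_dict(),
        }


# --- model functions (vectorised over numpy inputs) --------------------------

def survival_intrinsic(p: SurvivalParams, T_prev, moisture):
    """Sigmoidal intrinsic survival contribution lam(T, M) in (0, lam_max)."""
    infl = p.T_infl0 + p.m_moist * np.asarray(moisture, dtype=float)
    return p.lam_max * expit(-p.k_sig * (np.asarray(T_prev, dtype=float) - infl))


def survival_logit(p: SurvivalParams, T_prev, moisture, u_prev, w_con, w_het):
    """Log-odds of one-year survival of a unit of size ``u_prev``."""
    _check_finite(T_prev=T_prev, moisture=moisture, u_prev=u_prev, w_con=w_con, w_het=w_het)
    T = np.asarray(T_prev, dtype=float)
    a_con = p.a_ii0 + p.a_ii1 * T
    a_het = p.a_ij0 + p.a_ij1 * T
    return (
        survival_intrinsic(p, T, moisture)
        + p.b_S * np.asarray(u_prev, dtype=float)
        - a_con * np.asarray(w_con, dtype=float)
        - a_het * np.asarray(w_het, dtype=float)
    )


def survival_prob(p: SurvivalParams, T_prev, moisture, u_prev, w_con, w_het):
    return expit(survival_logit(p, T_prev, moisture, u_prev, w_con, w_het))


def growth_intrinsic(p: GrowthParams, T_prev):
    """Gaussian intrinsic growth term, peaking at T_opt with height g_max."""
    T = np.asarray(T_prev, dtype=float)
    return p.g_max * np.exp(-((T - p.T_opt) ** 2) / (2.0 * p.sigma_T**2))


def growth_mean(p: GrowthParams, T_prev, u_prev, w_con, w_het):
    """Expected next-year size (cm²) of a surviving unit."""
    _check_finite(T_prev=T_prev, u_prev=u_prev, w_con=w_con, w_het=w_het)
    T = np.asarray(T_prev, dtype=float)
    a_con = np.exp(p.c_ii + p.d_ii * T)
    a_het = np.exp(p.c_ij + p.d_ij * T)
    return (
        growth_intrinsic(p, T)
        + p.b_G * np.asarray(u_prev, dtype=float)
        - a_con * np.asarray(w_con, dtype=float)
        - a_het * np.asarray(w_het, dtype=float)
    )


def sample_growth(
    p: GrowthParams,
    T_prev,
    u_prev,
    w_con,
    w_het,
    rng: np.random.Generator,
    u_min: float = U_MIN,
    cover_cap: float = 25.0,
):
    """Stochastic next-year size: mean + Gaussian noise, truncated to
    [u_min, cover_cap]."""
    mean = growth_mean(p, T_prev, u_prev, w_con, w_het)
    draw = mean + rng.normal(0.0, p.sigma_eps, size=np.shape(mean))
    return np.clip(draw, u_min, cover_cap)


def recruitment_logit(p: RecruitmentParams, T_prev, w_con, w_het):
    """Log-odds that an unoccupied quadrant gains a recruit of this taxon."""
    _check_finite(T_prev=T_prev, w_con=w_con, w_het=w_het)
    T = np.asarray(T_prev, dtype=float)
    a_con = np.exp(p.r_ii0 + p.r_ii1 * T)
    a_het = np.exp(p.r_ij0 + p.r_ij1 * T)
    return (
        a_con * np.asarray(w_con, dtype=float)
        - a_het * np.asarray(w_het, dtype=float)
        + p.theta_r
    )


def recruitment_prob(p: RecruitmentParams, T_prev, w_con, w_het):
    return expit(recruitment_logit(p, T_prev, w_con, w_het))
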