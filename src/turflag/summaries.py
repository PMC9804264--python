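"""Community summaries: Shannon diversity, log cover ratios, principal
coordinates ordination on Euclidean distances, and trajectory comparisons."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "shannon",
    "log_cover_ratio",
    "pcoa",
    "OrdinationResult",
    "compare_trajectories",
]


def shannon(covers, base: Optional[float] = None) -> float:
    """Shannon diversity H = -sum p*log(p) over taxa with positive cover.

    Natural log by default; pass ``base`` for another logarithm base.
    All-zero input is undefined and raises ``ValueError``.
    """
    c = np.asarray(covers, dtype=float)
    if np.any(c < 0):
        raise ValueError("covers must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("Shannon diversity undefined for all-zero covers")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def log_cover_ratio(initial: float, final: float, pseudo: float = 0.25) -> float:
    """ln((final + c)/(initial + c)) with pseudo-count c to absorb zeros."""
    if pseudo <= 0:
        raise ValueError("pseudo-count must be positive")
    if initial < 0 or final < 0:
        raise ValueError("covers must be non-negative")
    return float(np.log((final + pseudo) / (initial + pseudo)))


@dataclass
class OrdinationResult:
    """Classical (metric) MDS of a community matrix.

    ``coordinates`` has one row per observation, columns are ordination axes
    ordered by decreasing eigenvalue; ``proportion`` is the fraction of total
    (positive) eigenvalue mass per axis.  ``taxon_vectors`` holds the
    correlation of each taxon's cover with axes 1-2, and ``taxon_r2`` the R²
    of each taxon's cover regressed on those two axes.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion: np.ndarray
    taxa: List[str]
    taxon_vectors: np.ndarray  # (n_taxa, 2) correlations with axes 1-2
    taxon_r2: np.ndarray       # (n_taxa,) variance explained by axes 1-2

    def high_fidelity_taxa(self, threshold: float = 0.90) -> List[str]:
        """Taxa whose cover variation is mostly captured by axes 1-2."""
        return [t for t, r2 in zip(self.taxa, self.taxon_r2) if r2 > threshold]


def pcoa(matrix, taxa: Optional[Sequence[str]] = None) -> OrdinationResult:
    """Principal coordinates analysis on Euclidean distances.

    ``matrix`` is observations x taxa (e.g. per-year total covers).  With
    Euclidean input this equals PCA scores up to axis sign; axes are oriented
    so the largest-magnitude taxon correlation on each axis is positive.
    """
    X = np.asarray(matrix, dtype=float)
    if isinstance(matrix, pd.DataFrame):
        taxa = list(matrix.columns)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-d matrix with >= 3 observations")
    if taxa is None:
        taxa = [f"taxon_{j}" for j in range(X.shape[1])]

    D = squareform(pdist(X, metric="euclidean"))
    if np.allclose(D, 0.0):
        raise ValueError("all observations identical; ordination degenerate")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10, 1e-9 * abs(eigval[0]))
    keep = eigval > tol
    eigval = eigval[keep]
    coords = eigvec[:, keep] * np.sqrt(eigval)
    proportion = eigval / eigval.sum()

    # correlations of taxon covers with axis scores
    Xc = X - X.mean(axis=0)
    n_axes = coords.shape[1]
    corr = np.zeros((X.shape[1], n_axes))
    for j in range(X.shape[1]):
        sx = Xc[:, j].std()
        if sx == 0:
            continue
        for a in range(n_axes):
            sa = coords[:, a].std()
            if sa > 0:
                corr[j, a] = np.corrcoef(X[:, j], coords[:, a])[0, 1]

    # orient each axis so its largest-|loading| taxon points positive
    for a in range(n_axes):
        j = int(np.argmax(np.abs(corr[:, a])))
        if corr[j, a] < 0:
            coords[:, a] *= -1
            corr[:, a] *= -1

    # R² of each taxon on axes 1-2
    k = min(2, n_axes)
    A = coords[:, :k] - coords[:, :k].mean(axis=0)
    r2 = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        y = Xc[:, j]
        ss_tot = float(y @ y)
        if ss_tot == 0:
            r2[j] = 0.0
            continue
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        r2[j] = 1.0 - float(resid @ resid) / ss_tot

    vectors = np.zeros((X.shape[1], 2))
    vectors[:, :k] = corr[:, :k]
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=eigval,
        proportion=proportion,
        taxa=list(taxa),
        taxon_vectors=vectors,
        taxon_r2=r2,
    )


def _median_cover(traj) -> np.ndarray:
    """(n_years, n_taxa) per-year median cover across replicates."""
    return np.median(traj.cover, axis=0)


def _extinction_years(traj) -> Dict[str, float]:
    """Per-taxon median (across replicates) first year of zero cover; NaN if
    the taxon persists in most replicates."""
    out: Dict[str, float] = {}
    n_reps, n_years, _ = traj.cover.shape
    for k, taxon in enumerate(traj.taxa):
        firsts = np.full(n_reps, np.nan)
        for r in range(n_reps):
            zero = np.nonzero(traj.cover[r, :, k] <= 0)[0]
            if len(zero):
                firsts[r] = traj.years[zero[0]]
        out[taxon] = float(np.nanmedian(firsts)) if np.isfinite(firsts).sum() > n_reps / 2 else float("nan")
    return out


def compare_trajectories(ensembles: Sequence) -> Dict[str, pd.DataFrame]:
    """Tabulate contrasts between scenario ensembles.

    Returns a report with per-taxon median first-extinction years, per-
    scenario diversity minima/final values, and per-year per-taxon median
    cover differences of every scenario against the first one.
    """
    if not ensembles:
        raise ValueError("no ensembles given")
    taxa = ensembles[0].taxa
    years = ensembles[0].years
    for e in ensembles[1:]:
        if list(e.taxa) != list(taxa) or not np.array_equal(e.years, years):
            raise ValueError("ensembles must share taxa and year ranges")

    ext_rows = []
    div_rows = []
    for e in ensembles:
        ext = _extinction_years(e)
        for taxon in taxa:
            ext_rows.append(
                {"scenario": e.scenario_id, "taxon": taxon, "extinction_year": ext[taxon]}
            )
        med_div = np.nanmedian(e.shannon, axis=0)
        div_rows.append(
            {
                "scenario": e.scenario_id,
                "diversity_min": float(np.nanmin(med_div)),
                "diversity_min_year": int(years[int(np.nanargmin(med_div))]),
                "diversity_final": float(med_div[-1]),
            }
        )

    ref = _median_cover(ensembles[0])
    diff_rows = []
    for e in ensembles[1:]:
        diff = _median_cover(e) - ref
        for i, year in enumerate(years):
            for k, taxon in enumerate(taxa):
                diff_rows.append(
                    {
                        "scenario": e.scenario_id,
                        "reference": ensembles[0].scenario_id,
                        "year": int(year),
                        "taxon": taxon,
                        "median_cover_diff": float(diff[i, k]),
                    }
                )
    return {
        "extinctions": pd.DataFrame(ext_rows),
        "diversity": pd.DataFrame(div_rows),
        "cover_differences": pd.DataFrame(diff_rows),
    }
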