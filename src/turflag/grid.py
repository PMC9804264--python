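"""Gridded turf data model: grid geometry, ordinal cover scale, Gaussian
crowding kernel, and per-quadrant crowding indices.

A *turf* is a square block of vegetation subdivided into square quadrants.
Cover of each taxon in each quadrant is recorded in cm²; all shoots of one
taxon rooted in one quadrant form a single demographic unit.  Crowding on a
focal unit is a kernel-weighted sum of neighbour cover, split into a
conspecific component ``w_con`` (other quadrants only) and a heterospecific
component ``w_het`` (all quadrants, including the focal one at distance 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "GridConfigError",
    "GridSpec",
    "KernelSpec",
    "OrdinalScale",
    "TurfMap",
    "Crowding",
    "make_grid",
    "kernel_weight",
    "kernel_matrix",
    "compute_crowding",
    "crowding_fields",
    "DEFAULT_SCALE",
]


class GridConfigError(ValueError):
    """Raised for inconsistent grid geometry."""


def _exact_multiple(total: float, unit: float) -> int:
    """Return total/unit as an int, or -1 if not a whole multiple."""
    n = total / unit
    if abs(n - round(n)) > 1e-9:
        return -1
    return int(round(n))


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a square turf divided into square quadrants.

    Quadrants are indexed 0-based ``(row, col)`` from the south-west corner.
    The outermost ``buffer_quadrants`` rings are an unsurveyed buffer: they
    may carry cover (contributing to crowding) but their units are not
    modelled demographically.
    """

    turf_side_m: float
    quadrant_side_m: float
    buffer_m: float
    n_side: int = field(init=False)
    buffer_quadrants: int = field(init=False)

    def __post_init__(self) -> None:
        if self.turf_side_m <= 0 or self.quadrant_side_m <= 0:
            raise GridConfigError("turf_side_m and quadrant_side_m must be positive")
        if self.buffer_m < 0:
            raise GridConfigError("buffer_m must be non-negative")
        n_side = _exact_multiple(self.turf_side_m, self.quadrant_side_m)
        if n_side < 0:
            raise GridConfigError(
                f"quadrant_side_m={self.quadrant_side_m} does not divide "
                f"turf_side_m={self.turf_side_m} exactly"
            )
        n_buf = _exact_multiple(self.buffer_m, self.quadrant_side_m)
        if n_buf < 0:
            raise GridConfigError(
                f"buffer_m={self.buffer_m} is not a whole multiple of "
                f"quadrant_side_m={self.quadrant_side_m}"
            )
        if 2 * n_buf >= n_side:
            raise GridConfigError("buffer covers the whole turf; no inner quadrants")
        object.__setattr__(self, "n_side", n_side)
        object.__setattr__(self, "buffer_quadrants", n_buf)

    @property
    def inner_range(self) -> range:
        return range(self.buffer_quadrants, self.n_side - self.buffer_quadrants)

    @property
    def n_inner_side(self) -> int:
        return self.n_side - 2 * self.buffer_quadrants

    @property
    def n_inner(self) -> int:
        return self.n_inner_side**2

    @property
    def quadrant_area_cm2(self) -> float:
        return (self.quadrant_side_m * 100.0) ** 2

    @property
    def turf_area_cm2(self) -> float:
        return (self.turf_side_m * 100.0) ** 2

    def is_inner(self, row: int, col: int) -> bool:
        r = self.inner_range
        return row in r and col in r

    def inner_indices(self) -> List[Tuple[int, int]]:
        r = self.inner_range
        return [(i, j) for i in r for j in r]

    def inner_mask(self) -> np.ndarray:
        mask = np.zeros((self.n_side, self.n_side), dtype=bool)
        b = self.buffer_quadrants
        mask[b : self.n_side - b, b : self.n_side - b] = True
        return mask

    def centre_m(self, row: int, col: int) -> Tuple[float, float]:
        """Physical centre of a quadrant, metres from the SW turf corner."""
        h = self.quadrant_side_m
        return ((col + 0.5) * h, (row + 0.5) * h)

    def contains(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_side and 0 <= col < self.n_side


def make_grid(turf_side_m: float, quadrant_side_m: float, buffer_m: float) -> GridSpec:
    """Build a :class:`GridSpec`, validating divisibility of all lengths."""
    return GridSpec(turf_side_m, quadrant_side_m, buffer_m)


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian interaction kernel, truncated at a finite radius.

    With the default ``sigma_m = 0.05`` about 95% of the kernel mass lies
    within a 0.10 m radius; weights are zero beyond ``truncation_m``.
    """

    sigma_m: float = 0.05
    truncation_m: float = 0.15

    def __post_init__(self) -> None:
        if self.sigma_m <= 0:
            raise ValueError("sigma_m must be positive")
        if self.truncation_m < self.sigma_m:
            raise ValueError("truncation_m must be >= sigma_m")


def kernel_weight(distance_m, kernel: KernelSpec):
    """Gaussian kernel weight exp(-d²/2σ²), zero beyond the truncation radius.

    Accepts scalars or arrays; negative distances raise ``ValueError``.
    """
    d = np.asarray(distance_m, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance_m must be non-negative")
    w = np.exp(-(d**2) / (2.0 * kernel.sigma_m**2))
    # small pad so quadrant-centre distances exactly at the radius are kept
    # regardless of floating-point rounding in the distance computation
    w = np.where(d <= kernel.truncation_m + 1e-9, w, 0.0)
    if np.isscalar(distance_m):
        return float(w)
    return w


def kernel_matrix(grid: GridSpec, kernel: KernelSpec) -> np.ndarray:
    """Discrete kernel over quadrant-centre offsets, for convolution.

    Square matrix of odd side 2R+1 where R is the truncation radius in
    quadrants; entry (R+dr, R+dc) is the weight at the centre-to-centre
    distance of offset (dr, dc).
    """
    h = grid.quadrant_side_m
    R = int(math.floor(kernel.truncation_m / h + 1e-9))
    off = np.arange(-R, R + 1)
    dr, dc = np.meshgrid(off, off, indexing="ij")
    dist = h * np.sqrt(dr.astype(float) ** 2 + dc.astype(float) ** 2)
    return kernel_weight(dist, kernel)


# --- ordinal cover scale -----------------------------------------------------

@dataclass(frozen=True)
class OrdinalScale:
    """Ordinal cover classes on the cover *fraction* of a quadrant.

    Class 0 is exact absence.  Class k (k >= 1) covers the fraction interval
    (upper_bounds[k-1], upper_bounds[k]] with upper_bounds[0] == 0 and the
    last bound == 1.  ``midpoints_cm2`` are the representative cover areas
    used when decoding, including 0 for the absence class.
    """

    upper_bounds: Tuple[float, ...] = (0.0, 0.02, 0.06, 0.14, 0.30, 0.60, 1.0)
    midpoints_cm2: Tuple[float, ...] = (0.0, 0.25, 1.0, 2.5, 5.5, 11.25, 20.0)

    def __post_init__(self) -> None:
        if len(self.upper_bounds) != len(self.midpoints_cm2):
            raise ValueError("bounds and midpoints must have equal length")
        if self.upper_bounds[0] != 0.0 or abs(self.upper_bounds[-1] - 1.0) > 1e-12:
            raise ValueError("bounds must start at 0 and end at 1")
        if any(b >= c for b, c in zip(self.upper_bounds, self.upper_bounds[1:])):
            raise ValueError("bounds must be strictly increasing")
        if any(m >= n for m, n in zip(self.midpoints_cm2, self.midpoints_cm2[1:])):
            raise ValueError("midpoints must be strictly increasing")

    @property
    def n_classes(self) -> int:
        return len(self.upper_bounds)

    def encode(self, cover_cm2: float, quadrant_area_cm2: float = 25.0) -> int:
        if not 0.0 <= cover_cm2 <= quadrant_area_cm2 + 1e-9:
            raise ValueError(
                f"cover {cover_cm2} outside [0, {quadrant_area_cm2}] cm²"
            )
        if cover_cm2 == 0.0:
            return 0
        frac = min(cover_cm2 / quadrant_area_cm2, 1.0)
        for k in range(1, self.n_classes):
            if frac <= self.upper_bounds[k] + 1e-12:
                return k
        return self.n_classes - 1

    def decode(self, code: int) -> float:
        if not 0 <= code < self.n_classes:
            raise ValueError(f"class code {code} out of range")
        return self.midpoints_cm2[code]


DEFAULT_SCALE = OrdinalScale()


# --- turf maps and crowding --------------------------------------------------

Quadrant = Tuple[int, int]
CoverKey = Tuple[str, int, int]  # (taxon, row, col)


@dataclass
class TurfMap:
    """Per-year snapshot of one turf: cover of each taxon in each quadrant.

    ``cover`` maps (taxon, row, col) -> cover area in cm²; absent keys mean
    zero cover.  One demographic unit per taxon per quadrant by construction.
    """

    turf_id: str
    year: int
    grid: GridSpec
    cover: Dict[CoverKey, float] = field(default_factory=dict)

    def validate(self) -> None:
        cap = self.grid.quadrant_area_cm2
        for (taxon, row, col), c in self.cover.items():
            if not self.grid.contains(row, col):
                raise ValueError(f"quadrant ({row},{col}) outside grid for {taxon!r}")
            if not 0.0 < c <= cap + 1e-9:
                raise ValueError(
                    f"cover {c} for {taxon!r}@({row},{col}) outside (0, {cap}]"
                )

    def taxa(self) -> List[str]:
        return sorted({t for (t, _, _) in self.cover})

    def units_of(self, taxon: str) -> Dict[Quadrant, float]:
        return {
            (r, c): v for (t, r, c), v in self.cover.items() if t == taxon
        }

    def total_cover(self, taxon: str | None = None, inner_only: bool = False) -> float:
        tot = 0.0
        for (t, r, c), v in self.cover.items():
            if taxon is not None and t != taxon:
                continue
            if inner_only and not self.grid.is_inner(r, c):
                continue
            tot += v
        return tot

    def to_arrays(self, taxa_order: Iterable[str]) -> np.ndarray:
        """Dense (n_taxa, n_side, n_side) cover array in the given taxa order."""
        taxa = list(taxa_order)
        idx = {t: k for k, t in enumerate(taxa)}
        arr = np.zeros((len(taxa), self.grid.n_side, self.grid.n_side))
        for (t, r, c), v in self.cover.items():
            if t in idx:
                arr[idx[t], r, c] = v
        return arr

    @classmethod
    def from_arrays(
        cls, turf_id: str, year: int, grid: GridSpec, taxa: Iterable[str], arr: np.ndarray
    ) -> "TurfMap":
        cover: Dict[CoverKey, float] = {}
        for k, taxon in enumerate(taxa):
            rows, cols = np.nonzero(arr[k])
            for r, c in zip(rows.tolist(), cols.tolist()):
                cover[(taxon, r, c)] = float(arr[k, r, c])
        return cls(turf_id=turf_id, year=year, grid=grid, cover=cover)


@dataclass(frozen=True)
class Crowding:
    """Kernel-weighted neighbour cover around one focal (taxon, quadrant).

    ``w_con`` sums conspecific units in *other* quadrants; ``w_het`` sums
    heterospecific units in *all* quadrants including the focal one.
    """

    w_con: float
    w_het: float


def crowding_fields(
    cover: np.ndarray, grid: GridSpec, kernel: KernelSpec
) -> Tuple[np.ndarray, np.ndarray]:
    """Crowding of every (taxon, quadrant) at once.

    ``cover`` is a dense (n_taxa, n, n) array.  Returns ``(w_con, w_het)``
    with the same shape.  Quadrants outside the turf contribute nothing
    (no wrap-around).
    """
    K = kernel_matrix(grid, kernel)
    conv = np.empty_like(cover)
    for k in range(cover.shape[0]):
        conv[k] = ndimage.convolve(cover[k], K, mode="constant", cval=0.0)
    total = conv.sum(axis=0)
    w_het = total - conv
    w_con = conv - cover  # subtract the focal quadrant's own (weight-1) cover
    np.clip(w_con, 0.0, None, out=w_con)
    np.clip(w_het, 0.0, None, out=w_het)
    return w_con, w_het


def compute_crowding(
    turf_map: TurfMap, taxon: str, quadrant: Quadrant, kernel: KernelSpec
) -> Crowding:
    """Crowding around one focal quadrant for one taxon.

    The focal taxon's own cover in the focal quadrant is excluded from
    ``w_con``; heterospecific cover in the focal quadrant enters ``w_het``
    at distance 0 (weight 1).
    """
    row, col = quadrant
    if not turf_map.grid.contains(row, col):
        raise ValueError(f"quadrant {quadrant} outside grid")
    taxa = turf_map.taxa()
    arr = turf_map.to_arrays(taxa)
    w_con_f, w_het_f = crowding_fields(arr, turf_map.grid, kernel)
    if taxon in taxa:
        k = taxa.index(taxon)
        return Crowding(float(w_con_f[k, row, col]), float(w_het_f[k, row, col]))
    # unknown focal taxon: everything present is heterospecific
    if not taxa:
        return Crowding(0.0, 0.0)
    tot = (w_het_f + w_con_f + arr)[0]  # total weighted cover incl. focal quadrant
    return Crowding(0.0, float(tot[row, col]))
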