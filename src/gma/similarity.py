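"""Node similarity functions and edge-weight functionals.

Every node (segment) carries a *similarity function* phi: a discretized,
non-negative density over the CIELAB a* axis with unit integral.  At the
pixel scale phi is a Gaussian parameterized by the local neighbourhood
mean/std; at coarser scales it is the renormalized sum (uniform mixture)
of the member functions.

The weight of an edge is a [0, 1] functional of the two incident
densities.  Three functionals are provided:

``overlap`` (default)
    ``integral of min(phi_i, phi_j)`` — the shared area under the two
    curves.  Equals 1 exactly when the densities coincide bin-wise.
``product``
    ``integral of phi_i * phi_j`` — the literal product integral.  For
    normalized densities this does *not* reach 1 for identical inputs
    (``integral of phi^2`` depends on the spread), so it violates the
    identity-of-indiscernibles property; it is kept for comparison only.
``bhattacharyya``
    ``integral of sqrt(phi_i * phi_j)`` — also 1 iff the densities are
    equal.

All functions in a run share a single :class:`Grid` so that Gaussians and
mixtures are handled uniformly by midpoint-rule quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.special import ndtr

from .errors import ContractError, ParameterError

#: default number of quadrature bins on the a* axis
DEFAULT_BINS = 256

#: default lower bound on any Gaussian sigma (a* units)
SIGMA_FLOOR = 1e-3

#: tolerance on the unit-integral contract
NORMALIZATION_TOL = 1e-6


class WeightFunctional(str, Enum):
    """Choice of edge-weight functional; ``OVERLAP`` is the default."""

    OVERLAP = "overlap"
    PRODUCT = "product"
    BHATTACHARYYA = "bhattacharyya"

    @classmethod
    def coerce(cls, value: "WeightFunctional | str") -> "WeightFunctional":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError as exc:
            raise ParameterError(f"unknown weight functional: {value!r}") from exc


@dataclass(frozen=True)
class Grid:
    """Uniform discretization of the a* axis: ``n_bins`` midpoint cells on
    ``[alpha_min, alpha_max]``."""

    alpha_min: float
    alpha_max: float
    n_bins: int = DEFAULT_BINS

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha_min) or not np.isfinite(self.alpha_max):
            raise ParameterError("grid bounds must be finite")
        if self.alpha_max <= self.alpha_min:
            raise ParameterError("alpha_max must exceed alpha_min")
        if self.n_bins < 2:
            raise ParameterError("grid needs at least 2 bins")

    @property
    def spacing(self) -> float:
        return (self.alpha_max - self.alpha_min) / self.n_bins

    @property
    def centers(self) -> np.ndarray:
        d = self.spacing
        return self.alpha_min + d * (np.arange(self.n_bins) + 0.5)

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.alpha_min, self.alpha_max, self.n_bins + 1)

    @classmethod
    def from_samples(
        cls,
        values: np.ndarray,
        n_bins: int = DEFAULT_BINS,
        pad_sigmas: float = 6.0,
        min_pad: float = 1.0,
    ) -> "Grid":
        """Grid spanning the observed value range padded by ``pad_sigmas``
        global standard deviations (at least ``min_pad`` a* units)."""
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ContractError("cannot build a grid from no samples")
        lo = float(values.min())
        hi = float(values.max())
        pad = max(pad_sigmas * float(values.std()), min_pad)
        return cls(lo - pad, hi + pad, n_bins)


@dataclass(frozen=True)
class SimilarityFunction:
    """Discretized non-negative density with unit midpoint-rule integral."""

    grid: Grid
    density: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        dens = np.asarray(self.density, dtype=float)
        if dens.shape != (self.grid.n_bins,):
            raise ContractError(
                f"density has shape {dens.shape}, grid expects ({self.grid.n_bins},)"
            )
        if np.any(dens < 0) or not np.all(np.isfinite(dens)):
            raise ContractError("density must be finite and non-negative")
        total = float(dens.sum() * self.grid.spacing)
        if abs(total - 1.0) > NORMALIZATION_TOL:
            raise ContractError(f"density integrates to {total}, expected 1")
        object.__setattr__(self, "density", dens)

    def integral(self) -> float:
        return float(self.density.sum() * self.grid.spacing)

    def mean(self) -> float:
        return float(np.sum(self.grid.centers * self.density) * self.grid.spacing)


def gaussian_density_rows(
    mus: np.ndarray, sigmas: np.ndarray, grid: Grid
) -> np.ndarray:
    """Rows of discretized normal densities, one per (mu, sigma) pair.

    Bin masses come from CDF differences (exact for arbitrarily small
    sigma), then each row is renormalized to unit midpoint integral.
    """
    mus = np.atleast_1d(np.asarray(mus, dtype=float))
    sigmas = np.atleast_1d(np.asarray(sigmas, dtype=float))
    if np.any(sigmas <= 0):
        raise ParameterError("sigma must be strictly positive")
    edges = grid.edges
    z = (edges[None, :] - mus[:, None]) / sigmas[:, None]
    masses = np.diff(ndtr(z), axis=1)
    totals = masses.sum(axis=1, keepdims=True)
    # a Gaussian far outside the grid leaves zero mass: park it on the
    # nearest bin so the density is still a proper distribution
    empty = totals[:, 0] <= 0
    if np.any(empty):
        idx = np.clip(
            np.searchsorted(grid.centers, mus[empty]), 0, grid.n_bins - 1
        )
        masses[empty] = 0.0
        masses[np.nonzero(empty)[0], idx] = 1.0
        totals = masses.sum(axis=1, keepdims=True)
    return masses / (totals * grid.spacing)


def gaussian_phi(mu: float, sigma: float, grid: Grid) -> SimilarityFunction:
    """Discretized normal density N(mu, sigma) renormalized on ``grid``."""
    row = gaussian_density_rows(np.array([mu]), np.array([sigma]), grid)[0]
    return SimilarityFunction(grid, row)


def _check_same_grid(phi_i: SimilarityFunction, phi_j: SimilarityFunction) -> None:
    if phi_i.grid != phi_j.grid:
        raise ContractError("similarity functions live on different grids")


def weight_rows(
    rows_i: np.ndarray,
    rows_j: np.ndarray,
    spacing: float,
    functional: WeightFunctional | str = WeightFunctional.OVERLAP,
) -> np.ndarray:
    """Vectorized edge weights for stacked density rows (same shape)."""
    functional = WeightFunctional.coerce(functional)
    if functional is WeightFunctional.OVERLAP:
        integrand = np.minimum(rows_i, rows_j)
    elif functional is WeightFunctional.PRODUCT:
        integrand = rows_i * rows_j
    else:
        integrand = np.sqrt(rows_i * rows_j)
    return integrand.sum(axis=-1) * spacing


def edge_weight(
    phi_i: SimilarityFunction,
    phi_j: SimilarityFunction,
    functional: WeightFunctional | str = WeightFunctional.OVERLAP,
) -> float:
    """Similarity weight in [0, 1] between two densities on a shared grid."""
    _check_same_grid(phi_i, phi_j)
    return float(
        weight_rows(phi_i.density, phi_j.density, phi_i.grid.spacing, functional)
    )


def pairwise_weights(
    density_rows: np.ndarray,
    edge_index: np.ndarray,
    spacing: float,
    functional: WeightFunctional | str = WeightFunctional.OVERLAP,
    chunk: int = 8192,
) -> np.ndarray:
    """Weights for an (E, 2) edge index over an (N, B) density matrix,
    computed in chunks to bound peak memory."""
    edge_index = np.asarray(edge_index)
    out = np.empty(len(edge_index), dtype=float)
    for start in range(0, len(edge_index), chunk):
        sel = edge_index[start : start + chunk]
        out[start : start + len(sel)] = weight_rows(
            density_rows[sel[:, 0]], density_rows[sel[:, 1]], spacing, functional
        )
    return out


def normalize_rows(rows: np.ndarray, spacing: float) -> np.ndarray:
    totals = rows.sum(axis=-1, keepdims=True) * spacing
    if np.any(totals <= 0):
        raise ContractError("cannot normalize an all-zero density")
    return rows / totals


def aggregate_phi(phis: Sequence[SimilarityFunction]) -> SimilarityFunction:
    """Pointwise sum of member densities renormalized to unit integral
    (the uniform mixture, for unit-mass inputs)."""
    if len(phis) == 0:
        raise ContractError("aggregate_phi needs at least one function")
    grid = phis[0].grid
    for p in phis[1:]:
        _check_same_grid(phis[0], p)
    total = np.sum([p.density for p in phis], axis=0)
    return SimilarityFunction(grid, normalize_rows(total, grid.spacing))


def aggregate_rows(
    density_rows: np.ndarray,
    labels: np.ndarray,
    n_groups: int,
    spacing: float,
) -> np.ndarray:
    """Group-wise aggregate_phi over an (N, B) matrix: rows with the same
    label are summed and renormalized.  Sparse matmul keeps this O(N*B)."""
    n, b = density_rows.shape
    assign = sparse.csr_matrix(
        (np.ones(n), (np.asarray(labels), np.arange(n))), shape=(n_groups, n)
    )
    summed = assign @ density_rows
    return normalize_rows(summed, spacing)
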