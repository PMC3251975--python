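"""Image-to-graph conversion and neighbourhood structure.

A segmentation run starts by projecting the RGB image onto the CIELAB a*
axis (the green-red opponent channel, effective for skin/background
contrast).  The pixel lattice becomes the scale-0 graph: one segment per
pixel, 4-neighbourhood edges, and a Gaussian similarity function per
node parameterized by the local neighbourhood mean/std.  Coarser scales
are scattered point sets (segment centroids), re-structured by Delaunay
triangulation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError
from skimage import color

from .errors import ContractError, FormatError
from . import similarity as sim
from .similarity import Grid, SimilarityFunction, WeightFunctional


@dataclass(frozen=True)
class APlaneImage:
    """Per-pixel CIELAB a* intensities for one image."""

    height: int
    width: int
    a_values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ContractError("image must have positive dimensions")
        vals = np.asarray(self.a_values, dtype=float)
        if vals.shape != (self.height, self.width):
            raise ContractError("a_values shape does not match height/width")
        if not np.all(np.isfinite(vals)):
            raise ContractError("a_values must be finite")
        object.__setattr__(self, "a_values", vals)

    @property
    def n_pixels(self) -> int:
        return self.height * self.width


@dataclass(frozen=True)
class Segment:
    """A node at some scale: member-pixel summary statistics, centroid
    position, dispersion and similarity function."""

    id: int
    scale: int
    pixel_stats: tuple[int, float, float]  # (count, sum of a, sum of a^2)
    centroid: tuple[float, float]  # (row, col), 0-based
    sigma: float
    phi: SimilarityFunction

    @property
    def count(self) -> int:
        return self.pixel_stats[0]

    def mean_a(self) -> float:
        n, s, _ = self.pixel_stats
        return s / n


class ScaleGraph:
    """Segments, edges and weights at one scale.

    Column-oriented: per-segment quantities are parallel numpy arrays and
    the similarity functions are the rows of ``phi_rows``.  ``segment(i)``
    and ``segments`` materialize :class:`Segment` views on demand.
    """

    def __init__(
        self,
        scale: int,
        grid: Grid,
        counts: np.ndarray,
        sum_a: np.ndarray,
        sum_sq: np.ndarray,
        centroids: np.ndarray,
        sigma: np.ndarray,
        phi_rows: np.ndarray,
        edges: np.ndarray,
        weights: np.ndarray,
        pos_sums: np.ndarray | None = None,
    ):
        self.scale = int(scale)
        self.grid = grid
        self.counts = np.asarray(counts, dtype=np.int64)
        self.sum_a = np.asarray(sum_a, dtype=float)
        self.sum_sq = np.asarray(sum_sq, dtype=float)
        self.centroids = np.asarray(centroids, dtype=float)
        self.sigma = np.asarray(sigma, dtype=float)
        self.phi_rows = np.asarray(phi_rows, dtype=float)
        self.edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        self.weights = np.asarray(weights, dtype=float)
        # per-segment sums of member-pixel (row, col); defaults to
        # centroid * count, which is exact whenever centroids are pixel means
        if pos_sums is None:
            pos_sums = self.centroids * self.counts[:, None]
        self.pos_sums = np.asarray(pos_sums, dtype=float)
        if len(self.weights) != len(self.edges):
            raise ContractError("weights must be defined exactly for the edge set")
        if len(self.edges) and np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ContractError("self-edges are not allowed")

    @property
    def n_segments(self) -> int:
        return len(self.counts)

    @property
    def edge_set(self) -> set[tuple[int, int]]:
        return {tuple(sorted(e)) for e in self.edges.tolist()}

    @property
    def weight_map(self) -> dict[tuple[int, int], float]:
        return {
            tuple(sorted(e)): w
            for e, w in zip(self.edges.tolist(), self.weights.tolist())
        }

    def segment(self, i: int) -> Segment:
        return Segment(
            id=int(i),
            scale=self.scale,
            pixel_stats=(
                int(self.counts[i]),
                float(self.sum_a[i]),
                float(self.sum_sq[i]),
            ),
            centroid=(float(self.centroids[i, 0]), float(self.centroids[i, 1])),
            sigma=float(self.sigma[i]),
            phi=SimilarityFunction(self.grid, self.phi_rows[i]),
        )

    @property
    def segments(self) -> list[Segment]:
        return [self.segment(i) for i in range(self.n_segments)]


def to_a_plane(rgb_image: np.ndarray) -> APlaneImage:
    """Project an RGB raster onto the CIELAB a* axis (sRGB, D65).

    Accepts 8-bit or float-in-[0,1] arrays of shape (H, W, 3).
    """
    arr = np.asarray(rgb_image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(
            f"expected an (H, W, 3) RGB image, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    else:
        arr = arr.astype(float)
        if arr.min() < -1e-9 or arr.max() > 1.0 + 1e-9:
            raise FormatError("float RGB input must lie in [0, 1]")
    lab = color.rgb2lab(arr)
    return APlaneImage(arr.shape[0], arr.shape[1], lab[..., 1])


def _neighbourhood_moments(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and population std of {pixel + in-bounds 4-neighbours}."""
    h, w = a.shape
    s = a.copy()
    s2 = a**2
    cnt = np.ones_like(a)
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        shifted = np.roll(a, shift, axis=axis)
        mask = np.ones_like(a)
        if axis == 0:
            (shifted[0, :] if shift == 1 else shifted[-1, :])[:] = 0.0
            (mask[0, :] if shift == 1 else mask[-1, :])[:] = 0.0
        else:
            (shifted[:, 0] if shift == 1 else shifted[:, -1])[:] = 0.0
            (mask[:, 0] if shift == 1 else mask[:, -1])[:] = 0.0
        s += shifted
        s2 += shifted**2
        cnt += mask
    mu = s / cnt
    var = np.maximum(s2 / cnt - mu**2, 0.0)
    return mu, np.sqrt(var)


def lattice_edges(height: int, width: int) -> np.ndarray:
    """4-neighbourhood edge index for a row-major H x W lattice:
    H*(W-1) horizontal plus W*(H-1) vertical edges."""
    ids = np.arange(height * width).reshape(height, width)
    horiz = np.stack([ids[:, :-1].ravel(), ids[:, 1:].ravel()], axis=1)
    vert = np.stack([ids[:-1, :].ravel(), ids[1:, :].ravel()], axis=1)
    return np.concatenate([horiz, vert], axis=0)


def build_lattice_graph(
    a_plane: APlaneImage,
    neighborhood_sigma_floor: float = sim.SIGMA_FLOOR,
    grid: Grid | None = None,
    n_bins: int = sim.DEFAULT_BINS,
    functional: WeightFunctional | str = WeightFunctional.OVERLAP,
) -> ScaleGraph:
    """Scale-0 graph: one segment per pixel with 4-neighbourhood edges.

    Each node's phi is the Gaussian N(mu, sigma) of its neighbourhood
    (pixel plus in-bounds 4-neighbours); sigma is floored at
    ``neighborhood_sigma_floor`` so constant neighbourhoods still yield a
    proper density.  The node dispersion at scale 0 is set to that same
    neighbourhood sigma.
    """
    a = a_plane.a_values
    h, w = a_plane.height, a_plane.width
    if grid is None:
        grid = Grid.from_samples(a, n_bins=n_bins)
    mu, nsig = _neighbourhood_moments(a)
    nsig = np.maximum(nsig, neighborhood_sigma_floor)
    flat_a = a.ravel()
    rows, cols = np.divmod(np.arange(h * w), w)
    centroids = np.stack([rows, cols], axis=1).astype(float)
    phi_rows = sim.gaussian_density_rows(mu.ravel(), nsig.ravel(), grid)
    edges = lattice_edges(h, w)
    weights = sim.pairwise_weights(phi_rows, edges, grid.spacing, functional)
    return ScaleGraph(
        scale=0,
        grid=grid,
        counts=np.ones(h * w, dtype=np.int64),
        sum_a=flat_a,
        sum_sq=flat_a**2,
        centroids=centroids,
        sigma=nsig.ravel(),
        phi_rows=phi_rows,
        edges=edges,
        weights=weights,
    )


def _jitter_duplicates(points: np.ndarray) -> np.ndarray:
    """Deterministic epsilon perturbation of duplicated coordinates so
    Qhull keeps every input point as a vertex."""
    pts = points.copy()
    _, first, counts = np.unique(pts, axis=0, return_index=True, return_counts=True)
    if np.all(counts == 1):
        return pts
    span = max(float(np.ptp(pts)), 1.0)
    eps = 1e-7 * span
    seen: dict[tuple[float, float], int] = {}
    for i, (r, c) in enumerate(map(tuple, points)):
        reps = seen.get((r, c), 0)
        seen[(r, c)] = reps + 1
        if reps:
            pts[i, 0] += eps * reps
            pts[i, 1] += eps * ((reps % 7) + 1)
    return pts


def delaunay_edges(centroids: np.ndarray) -> np.ndarray:
    """Delaunay edges over (row, col) centroid coordinates.

    Fewer than 3 points or a degenerate (collinear) configuration fall
    back to the complete graph; duplicate centroids are epsilon-jittered
    before triangulation.
    """
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n == 0:
        raise ContractError("no centroids given")
    if n == 1:
        warnings.warn("single segment: empty edge set", stacklevel=2)
        return np.empty((0, 2), dtype=np.int64)
    if n == 2:
        return np.array([[0, 1]], dtype=np.int64)
    pts = _jitter_duplicates(pts)
    try:
        tri = Delaunay(pts)
    except QhullError:
        pairs = np.array(list(itertools.combinations(range(n), 2)), dtype=np.int64)
        return pairs
    simp = tri.simplices
    pairs = np.concatenate(
        [simp[:, [0, 1]], simp[:, [1, 2]], simp[:, [0, 2]]], axis=0
    )
    pairs = np.sort(pairs, axis=1)
    return np.unique(pairs, axis=0).astype(np.int64)


def build_delaunay_graph(
    segments: "Sequence[Segment] | np.ndarray",
) -> np.ndarray:
    """Delaunay edge set over segment centroids (accepts a Segment list or
    an (N, 2) centroid array)."""
    if isinstance(segments, np.ndarray):
        centroids = segments
    else:
        centroids = np.array([s.centroid for s in segments], dtype=float)
    return delaunay_edges(centroids)


def segment_centroid(member_positions: Iterable[tuple[float, float]]) -> tuple[float, float]:
    """Arithmetic mean of member (row, col) positions."""
    pos = np.asarray(list(member_positions), dtype=float)
    if pos.size == 0:
        raise ContractError("segment_centroid needs at least one position")
    mean = pos.reshape(-1, 2).mean(axis=0)
    return float(mean[0]), float(mean[1])
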