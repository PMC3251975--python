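"""The multiscale aggregation engine.

Each scale pass walks the graph edges in descending-weight order and
assigns the incident nodes to next-scale groups:

* neither endpoint assigned — one shared new group if the dispersion
  criterion fires, else two new singleton groups;
* exactly one assigned — the unassigned node joins that group if the
  criterion (evaluated between the group's pooled statistics and the
  node) fires, else it opens a singleton group;
* both assigned — no action.

The pass stops when every node is assigned or the edges are exhausted;
leftover isolated nodes become singletons, so every node is always
assigned.  The criterion bounds the pooled dispersion of the merge by
the geometric mean of the parts plus a relaxation ``k``; when a scale
pass produces no reduction in segment count, ``k`` is incremented and
the scale retried.  The loop runs until ``target_segments`` (two:
hand/background) remain.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .errors import ContractError
from . import similarity as sim
from .similarity import Grid, WeightFunctional
from .graph_core import (
    APlaneImage,
    ScaleGraph,
    Segment,
    build_lattice_graph,
    delaunay_edges,
    to_a_plane,
)

log = logging.getLogger(__name__)


@dataclass
class AggregationParams:
    """Knobs of the multiscale loop.

    ``k0`` is the initial relaxation at every scale; ``k_step`` is added
    each time a scale pass stalls (no reduction), up to
    ``max_stuck_retries`` retries, after which the current partition is
    accepted with a warning.
    """

    k0: float = 0.01
    k_step: float = 0.01
    max_stuck_retries: int = 400
    target_segments: int = 2
    functional: WeightFunctional | str = WeightFunctional.OVERLAP
    n_bins: int = sim.DEFAULT_BINS
    sigma_floor: float = sim.SIGMA_FLOOR
    seed: int = 0
    skin_a_reference: Optional[float] = None
    #: rescale the working a* axis to [0, 1] over the observed range, so
    #: the k relaxation (default 0.01) is 1% of the image's dynamic range
    #: rather than of the absolute a* scale
    normalize_a: bool = True
    #: a scale pass counts as stalled unless it divides the segment count
    #: by this factor (clamped so the target count is always acceptable);
    #: k is bumped by k_step and the scale retried until it does
    reduction_target: float = 2.0
    #: how the criterion is evaluated when exactly one edge node is
    #: already assigned: against the two edge nodes ("node"), against the
    #: existing group's pooled stats ("group"), or both must hold ("both")
    case_b_delta: str = "both"
    #: once the k ladder passes this value, any reduction is accepted
    #: (None disables the cap); bounds how far a hard scale can relax
    #: the criterion before settling for slower progress
    k_soft_cap: Optional[float] = 0.10

    def __post_init__(self) -> None:
        if self.k0 < 0:
            raise ContractError("k0 must be >= 0")
        if self.target_segments < 1:
            raise ContractError("target_segments must be >= 1")
        self.functional = WeightFunctional.coerce(self.functional)


@dataclass
class ScaleRecord:
    scale: int
    n_before: int
    n_after: int
    k_used: float
    edges_evaluated: int
    merges: int
    retries: int


@dataclass
class ScaleTrace:
    """Per-scale log of a multiscale run."""

    records: list[ScaleRecord] = field(default_factory=list)

    def segment_counts(self) -> list[int]:
        if not self.records:
            return []
        return [self.records[0].n_before] + [r.n_after for r in self.records]

    def reduction_factors(self) -> list[float]:
        return [r.n_before / r.n_after for r in self.records if r.n_after > 0]

    def to_dict(self) -> dict:
        return {"records": [asdict(r) for r in self.records]}


@dataclass
class AggregationPass:
    """Outcome of one scale pass: the partition of current segments into
    next-scale groups."""

    labels: np.ndarray  # group id per segment, 0..n_groups-1
    n_groups: int
    merges: int
    edges_evaluated: int


@dataclass
class SegmentationResult:
    mask: np.ndarray  # uint8, 1 = hand
    labels: np.ndarray  # final segment id per pixel
    trace: ScaleTrace
    n_segments: int
    degenerate: bool
    stuck: bool = False


def order_edges(graph: ScaleGraph) -> np.ndarray:
    """Edges sorted by descending weight; ties broken by ascending
    (min id, max id) pair — fully deterministic."""
    edges = np.sort(graph.edges, axis=1)
    order = np.lexsort((edges[:, 1], edges[:, 0], -graph.weights))
    return edges[order]


def _pooled_sigma(n1, s1, ss1, n2, s2, ss2) -> float:
    n = n1 + n2
    mean = (s1 + s2) / n
    var = (ss1 + ss2) / n - mean * mean
    return math.sqrt(var) if var > 0.0 else 0.0


def merged_sigma(seg_i: Segment, seg_j: Segment) -> float:
    """Population std of the union of member a-values, from the pooled
    (count, sum, sum of squares) in O(1)."""
    n1, s1, ss1 = seg_i.pixel_stats
    n2, s2, ss2 = seg_j.pixel_stats
    return _pooled_sigma(n1, s1, ss1, n2, s2, ss2)


#: lower bound on sigma inside the weighted-geometric-mean logarithm
_SIGMA_EPS = 1e-6


def _geo_mean(sigma_i: float, sigma_j: float, w_i: float, w_j: float) -> float:
    si = sigma_i if sigma_i > _SIGMA_EPS else _SIGMA_EPS
    sj = sigma_j if sigma_j > _SIGMA_EPS else _SIGMA_EPS
    n = w_i + w_j
    return math.exp((w_i * math.log(si) + w_j * math.log(sj)) / n)


def delta(
    sigma_ij: float,
    sigma_i: float,
    sigma_j: float,
    k: float,
    w_i: float = 1.0,
    w_j: float = 1.0,
) -> int:
    """1 iff the pooled dispersion does not exceed the geometric mean of
    the part dispersions plus the relaxation k (non-strict).

    With the default unit weights this is the plain geometric mean
    ``sqrt(sigma_i * sigma_j) + k``.  The multiscale engine weights the
    mean by member-pixel counts: for equally sized parts (in particular
    every pair at the pixel scale) the two forms coincide, but the plain
    form degenerates for very unequal sizes — a single-pixel segment has
    zero dispersion, zeroing the geometric mean and making its pooled
    dispersion (= the big neighbour's sigma) unreachable for any small
    k, so stragglers would poison the coarsening.
    """
    return 1 if sigma_ij <= _geo_mean(sigma_i, sigma_j, w_i, w_j) + k else 0


def aggregate_scale(
    graph: ScaleGraph, k: float, params: AggregationParams | None = None
) -> AggregationPass:
    """One weight-ordered assignment pass over ``graph`` with relaxation
    ``k``; returns the partition into next-scale groups."""
    case_b = params.case_b_delta if params is not None else "both"
    use_node = case_b in ("node", "both")
    use_group = case_b in ("group", "both")
    n_nodes = graph.n_segments
    ordered = order_edges(graph)
    # plain-python locals: the edge loop is the hot path
    counts = graph.counts.tolist()
    sums = graph.sum_a.tolist()
    sumsqs = graph.sum_sq.tolist()
    sigmas = graph.sigma.tolist()
    labels = [-1] * n_nodes
    g_n: list[float] = []
    g_s: list[float] = []
    g_ss: list[float] = []
    g_sigma: list[float] = []
    assigned = 0
    merges = 0
    evaluated = 0

    def new_group(i: int) -> int:
        # a singleton group inherits its node's dispersion attribute (at
        # scale 0 the neighbourhood sigma, not the degenerate 0 of a
        # one-pixel population); grown groups carry pooled stds
        gid = len(g_n)
        g_n.append(counts[i])
        g_s.append(sums[i])
        g_ss.append(sumsqs[i])
        g_sigma.append(sigmas[i])
        labels[i] = gid
        return gid

    for i, j in ordered.tolist():
        if assigned == n_nodes:
            break
        evaluated += 1
        li = labels[i]
        lj = labels[j]
        if li >= 0 and lj >= 0:
            continue  # both already assigned: no action
        if li < 0 and lj < 0:
            sij = _pooled_sigma(
                counts[i], sums[i], sumsqs[i], counts[j], sums[j], sumsqs[j]
            )
            if sij <= _geo_mean(sigmas[i], sigmas[j], counts[i], counts[j]) + k:
                gid = len(g_n)
                g_n.append(counts[i] + counts[j])
                g_s.append(sums[i] + sums[j])
                g_ss.append(sumsqs[i] + sumsqs[j])
                g_sigma.append(sij)
                labels[i] = gid
                labels[j] = gid
                merges += 1
            else:
                new_group(i)
                new_group(j)
            assigned += 2
        else:
            # exactly one assigned.  The case table is written over node
            # indices, so the node-node criterion is the letter of it;
            # the group-node variant (pooled stats of the group the node
            # would join) guards against single-linkage chaining.  The
            # default requires both.
            g, u = (li, j) if li >= 0 else (lj, i)
            a = i if li >= 0 else j
            ok = True
            if use_node:
                sij = _pooled_sigma(
                    counts[a], sums[a], sumsqs[a], counts[u], sums[u], sumsqs[u]
                )
                ok = (
                    sij
                    <= _geo_mean(sigmas[a], sigmas[u], counts[a], counts[u]) + k
                )
            if ok and use_group:
                sgu = _pooled_sigma(
                    g_n[g], g_s[g], g_ss[g], counts[u], sums[u], sumsqs[u]
                )
                ok = (
                    sgu
                    <= _geo_mean(g_sigma[g], sigmas[u], g_n[g], counts[u]) + k
                )
            if ok:
                g_n[g] += counts[u]
                g_s[g] += sums[u]
                g_ss[g] += sumsqs[u]
                g_sigma[g] = _pooled_sigma(g_n[g], g_s[g], g_ss[g], 0, 0.0, 0.0)
                labels[u] = g
                merges += 1
            else:
                new_group(u)
            assigned += 1

    for i in range(n_nodes):  # isolated / unreached nodes become singletons
        if labels[i] < 0:
            new_group(i)

    return AggregationPass(
        labels=np.asarray(labels, dtype=np.int64),
        n_groups=len(g_n),
        merges=merges,
        edges_evaluated=evaluated,
    )


def coarsen(
    graph: ScaleGraph,
    labels: np.ndarray,
    n_groups: int,
    build_edges: bool = True,
    functional: WeightFunctional | str = WeightFunctional.OVERLAP,
) -> ScaleGraph:
    """Next-scale graph: pooled pixel stats, pixel-mean centroids,
    aggregated phi, population-std dispersion, Delaunay edges + weights."""
    labels = np.asarray(labels)
    counts = np.bincount(labels, weights=graph.counts, minlength=n_groups)
    sum_a = np.bincount(labels, weights=graph.sum_a, minlength=n_groups)
    sum_sq = np.bincount(labels, weights=graph.sum_sq, minlength=n_groups)
    pos_r = np.bincount(labels, weights=graph.pos_sums[:, 0], minlength=n_groups)
    pos_c = np.bincount(labels, weights=graph.pos_sums[:, 1], minlength=n_groups)
    pos_sums = np.stack([pos_r, pos_c], axis=1)
    centroids = pos_sums / counts[:, None]
    mean = sum_a / counts
    sigma = np.sqrt(np.maximum(sum_sq / counts - mean**2, 0.0))
    # a group with a single member node carries that node's dispersion
    # forward instead of its pooled std: a lone surviving pixel has
    # pooled std 0, which would zero the geometric mean in the merge
    # criterion and make the straggler effectively unmergeable (the same
    # degeneracy the scale-0 neighbourhood sigma avoids)
    members = np.bincount(labels, minlength=n_groups)
    single = members == 1
    if np.any(single):
        member_of = np.empty(n_groups, dtype=np.int64)
        member_of[labels[::-1]] = np.arange(len(labels) - 1, -1, -1)
        sigma[single] = np.maximum(
            sigma[single], graph.sigma[member_of[single]]
        )
    phi_rows = sim.aggregate_rows(graph.phi_rows, labels, n_groups, graph.grid.spacing)
    if build_edges and n_groups >= 2:
        edges = delaunay_edges(centroids)
        weights = sim.pairwise_weights(phi_rows, edges, graph.grid.spacing, functional)
    else:
        edges = np.empty((0, 2), dtype=np.int64)
        weights = np.empty(0)
    return ScaleGraph(
        scale=graph.scale + 1,
        grid=graph.grid,
        counts=counts.astype(np.int64),
        sum_a=sum_a,
        sum_sq=sum_sq,
        centroids=centroids,
        sigma=sigma,
        phi_rows=phi_rows,
        edges=edges,
        weights=weights,
        pos_sums=pos_sums,
    )


def label_hand(
    labels_map: np.ndarray,
    a_plane: APlaneImage | None = None,
    skin_a_reference: float | None = None,
) -> np.ndarray:
    """Binary hand mask from a final per-pixel segment-label map.

    Default heuristic: the segment with the smallest fraction of its
    pixels on the image border is the hand; ties break by smaller area,
    then smaller id.  If ``skin_a_reference`` is given (and the a-plane
    is available), the segment whose mean a* is closest to the reference
    wins instead.
    """
    labels_map = np.asarray(labels_map)
    seg_ids = np.unique(labels_map)
    if len(seg_ids) < 2:
        warnings.warn("degenerate 1-segment partition: all-zero mask", stacklevel=2)
        return np.zeros(labels_map.shape, dtype=np.uint8)
    if skin_a_reference is not None and a_plane is not None:
        means = np.array(
            [a_plane.a_values[labels_map == s].mean() for s in seg_ids]
        )
        hand = seg_ids[int(np.argmin(np.abs(means - skin_a_reference)))]
    else:
        areas = np.array([(labels_map == s).sum() for s in seg_ids])
        border = np.zeros(labels_map.shape, dtype=bool)
        border[0, :] = border[-1, :] = True
        border[:, 0] = border[:, -1] = True
        border_counts = np.array(
            [(labels_map[border] == s).sum() for s in seg_ids]
        )
        fractions = border_counts / areas
        order = np.lexsort((seg_ids, areas, fractions))
        hand = seg_ids[order[0]]
    return (labels_map == hand).astype(np.uint8)


def _refine_overshoot(
    graph: ScaleGraph,
    k_lo: float,
    k_hi: float,
    agg_hi: AggregationPass,
    accept_at: int,
    params: AggregationParams,
    steps: int = 10,
) -> tuple[AggregationPass, float]:
    """Bisect k in (k_lo, k_hi] for a pass whose group count lands within
    [target_segments, accept_at]; fall back to the overshooting pass."""
    target = params.target_segments
    fallback: tuple[AggregationPass, float] | None = None
    for _ in range(steps):
        mid = 0.5 * (k_lo + k_hi)
        agg = aggregate_scale(graph, mid, params)
        if agg.n_groups < target:
            k_hi = mid
        elif agg.n_groups <= accept_at:
            return agg, mid
        else:
            # reduces, but not by enough: remember the best such pass in
            # case no k lands inside the acceptance window
            if agg.n_groups < graph.n_segments and (
                fallback is None or agg.n_groups < fallback[0].n_groups
            ):
                fallback = (agg, mid)
            k_lo = mid
    return fallback if fallback is not None else (agg_hi, k_hi)


def run_multiscale(
    image: np.ndarray, params: AggregationParams | None = None
) -> SegmentationResult:
    """Full segmentation: lattice graph, weight-ordered aggregation per
    scale with Delaunay restructuring, down to ``target_segments``."""
    if params is None:
        params = AggregationParams()
    a_plane = to_a_plane(image)
    if a_plane.n_pixels < 2:
        raise ContractError("image must have at least 2 pixels")
    if params.normalize_a:
        a = a_plane.a_values
        span = float(a.max() - a.min())
        if span > 0:
            a_plane = APlaneImage(
                a_plane.height, a_plane.width, (a - a.min()) / span
            )
    grid = Grid.from_samples(
        a_plane.a_values,
        n_bins=params.n_bins,
        min_pad=0.05 if params.normalize_a else 1.0,
    )
    graph = build_lattice_graph(
        a_plane,
        neighborhood_sigma_floor=params.sigma_floor,
        grid=grid,
        functional=params.functional,
    )
    comp = np.arange(graph.n_segments)
    trace = ScaleTrace()
    stuck = False
    while graph.n_segments > params.target_segments:
        n_before = graph.n_segments
        # a pass must reduce the count by the reduction target (but never
        # require undershooting the final target); otherwise bump k
        accept_at = max(
            params.target_segments, int(n_before / max(params.reduction_target, 1.0))
        )
        if accept_at >= n_before:
            accept_at = n_before - 1
        k = params.k0
        retries = 0
        best: AggregationPass | None = None
        while True:
            agg = aggregate_scale(graph, k, params)
            if best is None or agg.n_groups < best.n_groups:
                best = agg
            if (
                params.k_soft_cap is not None
                and k > params.k_soft_cap
                and best.n_groups < n_before
            ):
                # k budget spent: settle for the best (slower) reduction
                # instead of relaxing the criterion further
                agg = best
                break
            if agg.n_groups <= accept_at:
                if agg.n_groups < params.target_segments:
                    # the ladder overshot (everything chained into fewer
                    # groups than wanted): bisect k against the previous
                    # rung for a pass that lands in [target, accept_at]
                    agg, k = _refine_overshoot(
                        graph, k - params.k_step, k, agg, accept_at, params
                    )
                break
            if retries >= params.max_stuck_retries:
                agg = best
                if agg.n_groups >= n_before:
                    warnings.warn(
                        f"scale {graph.scale} stuck at {n_before} segments "
                        f"after {retries} retries; accepting current partition",
                        stacklevel=2,
                    )
                    stuck = True
                break
            retries += 1
            k += params.k_step
        trace.records.append(
            ScaleRecord(
                scale=graph.scale,
                n_before=n_before,
                n_after=agg.n_groups,
                k_used=k,
                edges_evaluated=agg.edges_evaluated,
                merges=agg.merges,
                retries=retries,
            )
        )
        log.info(
            "scale %d: %d -> %d segments (k=%.4g, retries=%d)",
            graph.scale, n_before, agg.n_groups, k, retries,
        )
        if agg.n_groups >= n_before:
            break
        comp = agg.labels[comp]
        graph = coarsen(
            graph,
            agg.labels,
            agg.n_groups,
            build_edges=agg.n_groups > params.target_segments,
            functional=params.functional,
        )
    labels_map = comp.reshape(a_plane.height, a_plane.width)
    n_final = graph.n_segments
    degenerate = n_final < 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mask = label_hand(
            labels_map,
            a_plane=a_plane,
            skin_a_reference=params.skin_a_reference,
        )
    return SegmentationResult(
        mask=mask,
        labels=labels_map,
        trace=trace,
        n_segments=n_final,
        degenerate=degenerate,
        stuck=stuck,
    )
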