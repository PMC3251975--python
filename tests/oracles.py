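"""Independent reference implementations used as test oracles.

Everything here is deliberately naive (explicit pixel lists, per-pixel
loops, dense quadrature) and shares no code path with the package
implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np

_EPS = 1e-6


def quad_overlap(mu1, s1, mu2, s2, lo, hi, n=200_001):
    """Dense-midpoint quadrature of min of two normal pdfs."""
    x = np.linspace(lo, hi, n)
    p1 = np.exp(-0.5 * ((x - mu1) / s1) ** 2) / (s1 * math.sqrt(2 * math.pi))
    p2 = np.exp(-0.5 * ((x - mu2) / s2) ** 2) / (s2 * math.sqrt(2 * math.pi))
    return float(np.trapezoid(np.minimum(p1, p2), x))


def pooled_std(values_a, values_b) -> float:
    """Population std of the concatenated value lists."""
    return float(np.std(np.concatenate([values_a, values_b])))


def confusion_loop(pred, truth):
    """Per-pixel loop confusion counts (hand positive)."""
    tp = fn = fp = tn = 0
    for p, t in zip(np.asarray(pred).ravel(), np.asarray(truth).ravel()):
        if p and t:
            tp += 1
        elif not p and t:
            fn += 1
        elif p and not t:
            fp += 1
        else:
            tn += 1
    return tp, fn, fp, tn


def _geo(sig_i, sig_j, w_i, w_j):
    si = max(sig_i, _EPS)
    sj = max(sig_j, _EPS)
    return math.exp((w_i * math.log(si) + w_j * math.log(sj)) / (w_i + w_j))


class CaseTableOracle:
    """Literal transcription of the pairwise assignment case table.

    Nodes carry explicit pixel-value lists and a dispersion attribute;
    groups are plain python lists.  Edges are processed in the given
    order; for each edge:

    * neither node assigned: one new shared group if the criterion
      holds, else two new singleton groups;
    * exactly one assigned: the unassigned node joins that group if the
      criterion holds both between the two edge nodes and between the
      group and the node, else it opens a singleton group;
    * both assigned: nothing.

    Afterwards unassigned nodes become singletons.  The criterion is
    ``pooled_std <= weighted_geometric_mean(sigmas) + k`` with member
    counts as weights.
    """

    def __init__(self, pixel_lists, sigmas, k):
        self.pixels = [np.asarray(p, dtype=float) for p in pixel_lists]
        self.sigmas = [float(s) for s in sigmas]
        self.k = float(k)
        self.assignment = [None] * len(pixel_lists)
        self.group_pixels: list[np.ndarray] = []
        self.group_sigmas: list[float] = []

    def _new_group(self, node):
        gid = len(self.group_pixels)
        self.group_pixels.append(self.pixels[node])
        self.group_sigmas.append(self.sigmas[node])
        self.assignment[node] = gid
        return gid

    def _crit(self, pix_a, sig_a, pix_b, sig_b):
        merged = pooled_std(pix_a, pix_b)
        return merged <= _geo(sig_a, sig_b, len(pix_a), len(pix_b)) + self.k

    def run(self, ordered_edges):
        n = len(self.pixels)
        for i, j in ordered_edges:
            if all(a is not None for a in self.assignment):
                break
            ai, aj = self.assignment[i], self.assignment[j]
            if ai is not None and aj is not None:
                continue
            if ai is None and aj is None:
                if self._crit(
                    self.pixels[i], self.sigmas[i], self.pixels[j], self.sigmas[j]
                ):
                    gid = len(self.group_pixels)
                    merged = np.concatenate([self.pixels[i], self.pixels[j]])
                    self.group_pixels.append(merged)
                    self.group_sigmas.append(float(np.std(merged)))
                    self.assignment[i] = gid
                    self.assignment[j] = gid
                else:
                    self._new_group(i)
                    self._new_group(j)
            else:
                g, u = (ai, j) if ai is not None else (aj, i)
                a = i if ai is not None else j
                ok = self._crit(
                    self.pixels[a], self.sigmas[a], self.pixels[u], self.sigmas[u]
                ) and self._crit(
                    self.group_pixels[g],
                    self.group_sigmas[g],
                    self.pixels[u],
                    self.sigmas[u],
                )
                if ok:
                    merged = np.concatenate(
                        [self.group_pixels[g], self.pixels[u]]
                    )
                    self.group_pixels[g] = merged
                    self.group_sigmas[g] = float(np.std(merged))
                    self.assignment[u] = g
                else:
                    self._new_group(u)
        for node in range(n):
            if self.assignment[node] is None:
                self._new_group(node)
        return list(self.assignment)


def canonical_partition(labels):
    """Partition as a frozenset of frozensets (relabeling-invariant)."""
    groups: dict[int, set[int]] = {}
    for node, lab in enumerate(labels):
        groups.setdefault(int(lab), set()).add(node)
    return frozenset(frozenset(g) for g in groups.values())
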