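"""Nei genetic distances and UPGMA tree construction with Newick export."""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log, sqrt
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "TreeNode",
    "nei_distance",
    "nei_distance_matrix",
    "upgma",
    "to_newick",
]

INF_CAP = 10.0  # sentinel for -ln(0) under the standard variant


def nei_distance(
    freqs_x: Mapping[str, Mapping[int, float]],
    freqs_y: Mapping[str, Mapping[int, float]],
    variant: str = "standard_1972",
    cap: float = INF_CAP,
) -> float:
    """Nei genetic distance between two frequency profiles.

    ``standard_1972``: D = -ln(Jxy / sqrt(Jx * Jy)) with the identity
    terms averaged over loci; Jxy = 0 is reported as ``cap``.
    ``da_1983``: D = 1 - (1/L) * sum over loci of sum_i sqrt(x_i * y_i).
    """
    loci = sorted(set(freqs_x) & set(freqs_y))
    if not loci:
        raise ValueError("no shared loci")
    if variant == "standard_1972":
        jxy = jx = jy = 0.0
        for locus in loci:
            fx, fy = freqs_x[locus], freqs_y[locus]
            alleles = set(fx) | set(fy)
            jxy += sum(fx.get(a, 0.0) * fy.get(a, 0.0) for a in alleles)
            jx += sum(p * p for p in fx.values())
            jy += sum(p * p for p in fy.values())
        L = len(loci)
        jxy, jx, jy = jxy / L, jx / L, jy / L
        if jxy <= 0.0:
            return cap
        return max(-log(jxy / sqrt(jx * jy)), 0.0)
    if variant == "da_1983":
        total = 0.0
        for locus in loci:
            fx, fy = freqs_x[locus], freqs_y[locus]
            alleles = set(fx) | set(fy)
            total += sum(sqrt(fx.get(a, 0.0) * fy.get(a, 0.0)) for a in alleles)
        return 1.0 - total / len(loci)
    raise ValueError(f"unknown variant {variant!r}")


def nei_distance_matrix(
    pop_freqs: Mapping[str, Mapping[str, Mapping[int, float]]],
    variant: str = "standard_1972",
) -> tuple[list[str], np.ndarray]:
    labels = list(pop_freqs)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = nei_distance(pop_freqs[labels[i]], pop_freqs[labels[j]], variant)
            D[i, j] = D[j, i] = d
    return labels, D


@dataclass
class TreeNode:
    """Ultrametric tree node; ``height`` is the merge height (leaves: 0)."""

    label: str | None = None
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_labels())
        return out


def upgma(labels: Sequence[str], D: np.ndarray) -> TreeNode:
    """Average-linkage agglomeration of a symmetric distance matrix.

    Merge height is half the current minimum distance; ties break by the
    lexicographically smallest pair of cluster labels (a cluster is
    labelled by its smallest leaf).  Deterministic for any input.
    """
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("labels / matrix mismatch")
    if n == 1:
        return TreeNode(label=labels[0])
    nodes: dict[int, TreeNode] = {
        i: TreeNode(label=labels[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    keys = {i: labels[i] for i in range(n)}  # smallest leaf label per cluster
    dist = {(i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(nodes) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted((keys[kv[0][0]], keys[kv[0][1]])))),
        )
        (i, j), dmin = best
        height = dmin / 2.0
        merged = TreeNode(height=height, children=sorted(
            [nodes[i], nodes[j]], key=lambda nd: min(nd.leaf_labels())
        ))
        ni, nj = sizes[i], sizes[j]
        new_dist = {}
        for k in nodes:
            if k in (i, j):
                continue
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            new_dist[k] = (ni * dik + nj * djk) / (ni + nj)
        for key in [k for k in dist if i in k or j in k]:
            del dist[key]
        del nodes[i], nodes[j], sizes[i], sizes[j], keys[i], keys[j]
        nodes[next_id] = merged
        sizes[next_id] = ni + nj
        keys[next_id] = min(merged.leaf_labels())
        for k, d in new_dist.items():
            dist[tuple(sorted((k, next_id)))] = d
        next_id += 1
    return next(iter(nodes.values()))


def to_newick(node: TreeNode, parent_height: float | None = None) -> str:
    """Newick string with branch lengths equal to height differences."""

    def _fmt(nd: TreeNode, parent: float | None) -> str:
        if nd.is_leaf:
            body = nd.label
        else:
            body = "(" + ",".join(_fmt(c, nd.height) for c in nd.children) + ")"
        if parent is None:
            return body
        return f"{body}:{parent - nd.height:.17g}"

    return _fmt(node, parent_height) + ";"
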