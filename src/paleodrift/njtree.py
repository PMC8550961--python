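"""Neighbour joining (BioNJ variance weighting) and tree goodness of fit.

The fit diagnostic averages, for each sample, the ratio of tree
(patristic) to raw pairwise distance over all partners; ratios of one
indicate perfect phylogenetic placement, systematic deviations flag
samples whose affinities a bifurcating tree cannot express (e.g. admixed
lineages).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import DistanceMatrix


@dataclass
class Tree:
    """Unrooted tree as an undirected weighted adjacency structure."""

    adj: dict = field(default_factory=dict)  # node id -> list[(node id, length)]
    leaf_of: dict = field(default_factory=dict)  # label -> node id
    root_id: int | None = None  # internal node used for newick serialization

    def add_node(self, node_id: int):
        self.adj.setdefault(node_id, [])

    def add_edge(self, u: int, v: int, length: float):
        self.add_node(u)
        self.add_node(v)
        self.adj[u].append((v, float(length)))
        self.adj[v].append((u, float(length)))

    @property
    def leaves(self) -> list[str]:
        return list(self.leaf_of)

    def scale(self, factor: float) -> "Tree":
        t = Tree(leaf_of=dict(self.leaf_of), root_id=self.root_id)
        for u, nbrs in self.adj.items():
            t.adj[u] = [(v, l * factor) for v, l in nbrs]
        return t

    def distances_from(self, label: str) -> dict[str, float]:
        """Patristic distance from one leaf to every leaf, by graph traversal."""
        start = self.leaf_of[label]
        dist = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, l in self.adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + l
                    stack.append(v)
        return {lab: dist[nid] for lab, nid in self.leaf_of.items()}

    def patristic_matrix(self, labels: list[str] | None = None) -> pd.DataFrame:
        labels = labels if labels is not None else self.leaves
        out = np.zeros((len(labels), len(labels)))
        for i, a in enumerate(labels):
            d = self.distances_from(a)
            for j, b in enumerate(labels):
                out[i, j] = d[b]
        return pd.DataFrame(out, index=labels, columns=labels)

    def to_newick(self) -> str:
        root = self.root_id if self.root_id is not None else max(self.adj)
        names = {nid: lab for lab, nid in self.leaf_of.items()}

        def fmt(u: int, parent: int | None) -> str:
            children = [(v, l) for v, l in self.adj[u] if v != parent]
            if not children:
                return names[u]
            inner = ",".join(f"{fmt(v, u)}:{l:.12g}" for v, l in children)
            return f"({inner})"

        return fmt(root, None) + ";"


def neighbor_joining(d: DistanceMatrix, variance_weighted: bool = True) -> Tree:
    """Neighbour joining; with ``variance_weighted`` the BioNJ reduction is
    used (distance updates weighted to minimize variance), otherwise the
    classic equal-weight (lambda = 1/2) update.

    On additive matrices both recover the generating topology and branch
    lengths exactly.  Ties in the Q criterion break to the lowest active
    index pair, making the output deterministic.
    """
    D0 = np.asarray(d.values, dtype=float)
    labels = d.labels
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if np.any(~np.isfinite(D0)):
        iu, ju = np.where(~np.isfinite(D0))
        pairs = [(labels[i], labels[j]) for i, j in zip(iu, ju) if i < j]
        raise ValueError(f"incomplete distance matrix; missing pairs {pairs[:5]}")

    tree = Tree()
    node_of = {}
    for i, lab in enumerate(labels):
        tree.add_node(i)
        tree.leaf_of[lab] = i
        node_of[i] = i
    next_id = n

    active = list(range(n))
    D = {(i, j): D0[i, j] for i in range(n) for j in range(n) if i < j}
    V = dict(D)

    def get(M, i, j):
        return M[(i, j) if i < j else (j, i)]

    def put(M, i, j, val):
        M[(i, j) if i < j else (j, i)] = val

    while len(active) > 3:
        r = len(active)
        R = {i: sum(get(D, i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * get(D, i, j) - R[i] - R[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        dij = get(D, i, j)
        bi = dij / 2.0 + (R[i] - R[j]) / (2.0 * (r - 2))
        bj = dij - bi
        u = next_id
        next_id += 1
        tree.add_edge(node_of[i], u, bi)
        tree.add_edge(node_of[j], u, bj)
        node_of[u] = u

        others = [k for k in active if k != i and k != j]
        vij = get(V, i, j)
        if variance_weighted and vij > 1e-12 and others:
            lam = 0.5 + sum(get(V, j, k) - get(V, i, k) for k in others) / (
                2.0 * (r - 2) * vij
            )
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        for k in others:
            duk = lam * (get(D, i, k) - bi) + (1.0 - lam) * (get(D, j, k) - bj)
            vuk = lam * get(V, i, k) + (1.0 - lam) * get(V, j, k) - lam * (1.0 - lam) * vij
            put(D, u, k, duk)
            put(V, u, k, vuk)
        active = [k for k in active if k != i and k != j] + [u]

    x, y, z = active
    dxy, dxz, dyz = get(D, x, y), get(D, x, z), get(D, y, z)
    u = next_id
    tree.add_edge(node_of[x], u, (dxy + dxz - dyz) / 2.0)
    tree.add_edge(node_of[y], u, (dxy + dyz - dxz) / 2.0)
    tree.add_edge(node_of[z], u, (dxz + dyz - dxy) / 2.0)
    tree.root_id = u
    return tree


@dataclass
class FitRatioResult:
    ratios: pd.Series  # per-sample mean patristic/raw ratio
    n_excluded_pairs: int  # pairs with zero raw distance


def phylo_fit_ratio(tree: Tree, d: DistanceMatrix) -> FitRatioResult:
    """Per-sample mean of patristic(i,j) / d(i,j) over partners j != i.

    Pairs with zero raw distance are excluded and counted.  A mean ratio
    of one indicates the tree reproduces the sample's raw distances.
    """
    missing = [l for l in tree.leaves if l not in d.labels]
    if missing:
        raise ValueError(f"tree leaves absent from distance matrix: {missing}")
    labels = tree.leaves
    pat = tree.patristic_matrix(labels)
    idx = [d.labels.index(l) for l in labels]
    raw = d.values[np.ix_(idx, idx)]
    n = len(labels)
    ratios = {}
    excluded = 0
    for i, lab in enumerate(labels):
        vals = []
        for j in range(n):
            if j == i:
                continue
            if raw[i, j] == 0.0:
                excluded += 1
                continue
            vals.append(pat.iloc[i, j] / raw[i, j])
        ratios[lab] = float(np.mean(vals)) if vals else np.nan
    return FitRatioResult(pd.Series(ratios), excluded // 2)
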