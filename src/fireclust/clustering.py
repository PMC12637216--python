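"""Hierarchical density-based clustering (HDBSCAN) over fire points.

Implemented from first principles on the great-circle metric, with a single
tuning parameter ``k`` (minPts) playing both the core-distance and the
minimum-cluster-size role:

1.  core distance of a point = distance to its k-th nearest neighbour,
    counting the point itself as the rank-1 neighbour (so k coincident
    points form a valid cluster);
2.  mutual reachability d_mr(a, b) = max(core(a), core(b), d(a, b));
3.  exact minimum spanning tree of the complete mutual-reachability graph
    (Prim, O(n^2)), deterministic tie-breaking by lowest index pair;
4.  single-linkage dendrogram reinterpreted top-down at density level
    lambda = 1/weight and condensed with minimum cluster size k: at each
    split, any side with fewer than k points "falls out" of the current
    node at that lambda, while every side with >= k points becomes a child
    node with that birth level;
5.  cluster extraction by excess of mass: a node is selected when its
    stability  sum_p (lambda_p - lambda_birth)  exceeds the propagated
    stability of its children; the root is never selected when it splits
    into two or more children, so a year can never collapse into one
    all-encompassing cluster.

Points whose fall-out node has a selected ancestor-or-self belong to that
cluster; everything else is noise. Membership probability of a member is
lambda_p / lambda_max over the cluster, so the point that persists to the
densest level scores exactly 1 and edge points score low; noise scores 0.

Note on step 4: a side with >= k points always opens a *new* node (with a
new birth level) even when its sibling is too small to survive. The more
common library convention instead lets the big side continue its parent
node. The convention used here makes points shed on the approach to a dense
core compete through the stability criterion, so isolated stragglers far
from any selected cluster are labelled noise rather than absorbed as
low-probability members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geodesy import GeoPoint, pairwise_distance_matrix

__all__ = [
    "NOISE",
    "LAMBDA_CAP",
    "CondensedTree",
    "YearClustering",
    "core_distance",
    "core_distances",
    "mutual_reachability",
    "mst",
    "condense",
    "extract_clusters",
    "membership_probability",
    "membership_probabilities",
    "hdbscan",
]

#: Label given to unclustered (noise) detections.
NOISE = -1

#: Density level assigned where the merge distance is zero (duplicate
#: points); 1e9 / km corresponds to micrometre separation, far denser than
#: any physically distinct detection pair.
LAMBDA_CAP = 1e9


# ---------------------------------------------------------------------------
# Steps 1-3: core distances, mutual reachability, MST


def core_distances(D: np.ndarray, k: int) -> np.ndarray:
    """Core distance of every point: distance to the k-th nearest neighbour,
    with the point itself counted as rank 1 (so ``k=1`` gives all zeros)."""
    n = D.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    if k == 1:
        return np.zeros(n)
    # self-distance 0 sits in the sorted row, providing the rank-1 slot
    return np.sort(D, axis=1)[:, k - 1]


def core_distance(D: np.ndarray, i: int, k: int) -> float:
    """Core distance of point ``i`` (see :func:`core_distances`)."""
    return float(core_distances(D, k)[i])


def mutual_reachability(D: np.ndarray, cores: np.ndarray) -> np.ndarray:
    """d_mr(a, b) = max(core(a), core(b), d(a, b)) off-diagonal; zero diagonal."""
    mr = np.maximum(D, np.maximum(cores[:, None], cores[None, :]))
    np.fill_diagonal(mr, 0.0)
    return mr


def mst(d_mr: np.ndarray) -> list[tuple[int, int, float]]:
    """Exact minimum spanning tree of the complete weighted graph.

    Prim's algorithm in O(n^2); ties are broken by the lowest vertex index,
    and each returned edge is (min(i, j), max(i, j), weight). ``n < 2``
    yields an empty edge list.
    """
    n = d_mr.shape[0]
    if n < 2:
        return []
    in_tree = np.zeros(n, dtype=bool)
    in_tree[0] = True
    best = d_mr[0].copy()
    best_from = np.zeros(n, dtype=int)
    edges: list[tuple[int, int, float]] = []
    for _ in range(n - 1):
        cand = np.where(in_tree, np.inf, best)
        j = int(np.argmin(cand))  # first minimum -> lowest-index tie-break
        i = int(best_from[j])
        edges.append((min(i, j), max(i, j), float(best[j])))
        in_tree[j] = True
        closer = d_mr[j] < best
        best_from[closer] = j
        best = np.where(closer, d_mr[j], best)
    return edges


# ---------------------------------------------------------------------------
# Step 4: condensed tree


@dataclass
class CondensedTree:
    """Condensed cluster hierarchy.

    Node 0 is the root (birth level 0). ``point_node[p]`` is the node from
    which point ``p`` fell out at density level ``point_lambda[p]``;
    ``node_size`` is the number of points a node held at birth. Stability
    of a node is the sum over its points of (fall-out level - birth level),
    where points passing into a child count as leaving at the child's birth.
    """

    n_points: int
    k: int
    node_birth: list[float]
    node_parent: list[int | None]
    node_children: dict[int, list[int]]
    node_size: list[int]
    point_lambda: np.ndarray
    point_node: np.ndarray
    stability: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.stability:
            self.stability = self._compute_stability()

    def _compute_stability(self) -> list[float]:
        stab = [0.0] * len(self.node_birth)
        for p in range(self.n_points):
            nd = int(self.point_node[p])
            stab[nd] += float(self.point_lambda[p]) - self.node_birth[nd]
        for nd, children in self.node_children.items():
            for ch in children:
                stab[nd] += self.node_size[ch] * (self.node_birth[ch] - self.node_birth[nd])
        return stab

    @property
    def leaves(self) -> list[int]:
        return [nd for nd in range(len(self.node_birth)) if not self.node_children.get(nd)]


def _single_linkage(
    edges: Sequence[tuple[int, int, float]], n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Union-find agglomeration of ascending-weight MST edges.

    Returns (left, right, weight, size) arrays for the n-1 internal
    dendrogram nodes, ids n..2n-2; ties in weight resolve by the (i, j)
    order of the sorted edge list, which is deterministic.
    """
    order = sorted(edges, key=lambda e: (e[2], e[0], e[1]))
    parent = np.arange(2 * n - 1)
    left = np.zeros(n - 1, dtype=int)
    right = np.zeros(n - 1, dtype=int)
    weight = np.zeros(n - 1)
    size = np.ones(2 * n - 1, dtype=int)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    nxt = n
    for i, j, w in order:
        ri, rj = find(i), find(j)
        left[nxt - n], right[nxt - n], weight[nxt - n] = ri, rj, w
        size[nxt] = size[ri] + size[rj]
        parent[ri] = parent[rj] = nxt
        nxt += 1
    return left, right, weight, size


def condense(edges: Sequence[tuple[int, int, float]], n: int, k: int) -> CondensedTree:
    """Build the condensed tree from MST edges with minimum cluster size k."""
    if n < 1:
        raise ValueError("need at least one point")
    point_lambda = np.zeros(n)
    point_node = np.zeros(n, dtype=int)
    if n == 1 or not edges:
        # degenerate: single point falls out of the root at the cap level
        point_lambda[:] = LAMBDA_CAP
        return CondensedTree(n, k, [0.0], [None], {}, [n], point_lambda, point_node)

    left, right, weight, size = _single_linkage(edges, n)
    dend_root = 2 * n - 2

    node_birth = [0.0]
    node_parent: list[int | None] = [None]
    node_children: dict[int, list[int]] = {}
    node_size = [n]

    def dend_leaves(d: int) -> list[int]:
        out: list[int] = []
        stack = [d]
        while stack:
            x = stack.pop()
            if x < n:
                out.append(x)
            else:
                stack.append(left[x - n])
                stack.append(right[x - n])
        return out

    # (dendrogram node, condensed node) work list; each condensed node walks
    # down its dendrogram subtree until it dies or spawns children
    work = [(dend_root, 0)]
    while work:
        d, node = work.pop()
        while True:
            if d < n:  # a lone point can only reach here when k == 1
                point_lambda[d] = LAMBDA_CAP
                point_node[d] = node
                break
            w = weight[d - n]
            lam = 1.0 / w if w > 0.0 else LAMBDA_CAP
            l, r = int(left[d - n]), int(right[d - n])
            sides = [(l, int(size[l])), (r, int(size[r]))]
            big = [c for c, s in sides if s >= k]
            for c, s in sides:
                if s < k:
                    for p in dend_leaves(c):
                        point_lambda[p] = lam
                        point_node[p] = node
            if not big:
                break  # node dies here; all members recorded at lam
            if len(big) == 2:
                for c in big:
                    nid = len(node_birth)
                    node_birth.append(lam)
                    node_parent.append(node)
                    node_size.append(int(size[c]))
                    node_children.setdefault(node, []).append(nid)
                    work.append((c, nid))
                break
            # exactly one side survives: it opens a new child node
            nid = len(node_birth)
            node_birth.append(lam)
            node_parent.append(node)
            node_size.append(int(size[big[0]]))
            node_children.setdefault(node, []).append(nid)
            d, node = big[0], nid

    return CondensedTree(n, k, node_birth, node_parent, node_children, node_size,
                         point_lambda, point_node)


# ---------------------------------------------------------------------------
# Step 5: excess-of-mass extraction and membership probabilities


def extract_clusters(tree: CondensedTree) -> set[int]:
    """Excess-of-mass selection of condensed-tree nodes.

    Bottom-up: a node is selected when its stability exceeds the summed
    propagated stability of its children (deselecting all descendants).
    The root is never selected when it has two or more children; a
    single-node tree selects its root.
    """
    n_nodes = len(tree.node_birth)
    selected: set[int] = set()
    propagated = [0.0] * n_nodes
    for nd in range(n_nodes - 1, -1, -1):  # children always have larger ids
        children = tree.node_children.get(nd, [])
        if not children:
            selected.add(nd)
            propagated[nd] = tree.stability[nd]
            continue
        child_sum = sum(propagated[c] for c in children)
        is_split_root = tree.node_parent[nd] is None and len(children) >= 2
        if tree.stability[nd] > child_sum and not is_split_root:
            stack = list(children)
            while stack:
                x = stack.pop()
                selected.discard(x)
                stack.extend(tree.node_children.get(x, []))
            selected.add(nd)
            propagated[nd] = tree.stability[nd]
        else:
            propagated[nd] = child_sum
    return selected


def _selected_ancestor(tree: CondensedTree, selected: set[int]) -> list[int | None]:
    """For each node, its selected ancestor-or-self (None if no selection above)."""
    anc: list[int | None] = [None] * len(tree.node_birth)
    for nd in range(len(tree.node_birth)):  # parents precede children
        if nd in selected:
            anc[nd] = nd
        else:
            par = tree.node_parent[nd]
            anc[nd] = anc[par] if par is not None else None
    return anc


def membership_probabilities(
    tree: CondensedTree, selected: set[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and membership probabilities for every point.

    A point belongs to the selected ancestor-or-self of its fall-out node;
    points falling out above every selected node are noise (label -1,
    probability exactly 0). Within a cluster the probability is
    lambda_p / lambda_max over the cluster's members, in (0, 1], with at
    least one member at exactly 1.
    """
    anc = _selected_ancestor(tree, selected)
    owner = np.array(
        [-1 if anc[int(nd)] is None else anc[int(nd)] for nd in tree.point_node], dtype=int
    )
    labels = np.full(tree.n_points, NOISE, dtype=int)
    probs = np.zeros(tree.n_points)
    relabel: dict[int, int] = {}
    for sel in sorted(set(owner[owner >= 0].tolist())):
        relabel[sel] = len(relabel)
    for sel, lab in relabel.items():
        mask = owner == sel
        lam = tree.point_lambda[mask]
        labels[mask] = lab
        probs[mask] = lam / lam.max()
    return labels, probs


def membership_probability(tree: CondensedTree, selected: set[int], point: int) -> float:
    """Membership probability of a single point (0 for noise)."""
    _, probs = membership_probabilities(tree, selected)
    return float(probs[point])


# ---------------------------------------------------------------------------
# Composition


@dataclass
class YearClustering:
    """Labelling of one year's detections into clusters and noise.

    ``labels[i]`` is the cluster id (0..n_clusters-1) or ``NOISE`` for the
    i-th point given to :func:`hdbscan`; ``indices`` (when set by the annual
    driver) maps those positions back into the full detection list.
    """

    year: int | None
    k: int
    labels: np.ndarray
    membership_prob: np.ndarray
    n_clusters: int
    noise_fraction: float
    degenerate: bool = False
    indices: np.ndarray | None = None
    sweep: list | None = None

    @property
    def n_points(self) -> int:
        return len(self.labels)

    def cluster_members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def hdbscan(
    points: Sequence[GeoPoint],
    k: int,
    *,
    D: np.ndarray | None = None,
    year: int | None = None,
) -> YearClustering:
    """Cluster points on the great-circle metric with minPts = k.

    Deterministic for a fixed input order; permuting the input permutes the
    labels consistently (same partition, same probabilities). ``n == 0``
    gives an empty result and ``n < k`` marks every point noise.
    """
    if k < 2:
        raise ValueError("k (minPts) must be >= 2")
    n = len(points)
    if n == 0:
        return YearClustering(year, k, np.empty(0, dtype=int), np.empty(0), 0, 0.0,
                              degenerate=True)
    if n < k:
        return YearClustering(
            year, k, np.full(n, NOISE, dtype=int), np.zeros(n), 0, 1.0, degenerate=True
        )
    if D is None:
        D = pairwise_distance_matrix(points)
    cores = core_distances(D, k)
    mr = mutual_reachability(D, cores)
    edges = mst(mr)
    tree = condense(edges, n, k)
    selected = extract_clusters(tree)
    labels, probs = membership_probabilities(tree, selected)
    n_clusters = int(labels.max()) + 1 if labels.size and labels.max() >= 0 else 0
    noise_fraction = float(np.mean(labels == NOISE)) if n else 0.0
    return YearClustering(year, k, labels, probs, n_clusters, noise_fraction)
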