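import itertools
import logging

import numpy as np
import pytest

from fireclust.clustering import (
    LAMBDA_CAP,
    NOISE,
    condense,
    core_distance,
    core_distances,
    extract_clusters,
    hdbscan,
    membership_probabilities,
    mst,
    mutual_reachability,
)
from fireclust.geodesy import GeoPoint, pairwise_distance_matrix

from conftest import tight_triplet

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# independent oracles


def kruskal_mst_weight(d: np.ndarray) -> float:
    """Independent MST oracle: Kruskal with explicit sorting and union-find."""
    n = d.shape[0]
    edges = sorted(
        ((d[i, j], i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda e: e[0],
    )
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    total, used = 0.0, 0
    for w, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            total += w
            used += 1
            if used == n - 1:
                break
    return total


def dbscan_star_components(D: np.ndarray, k: int, eps: float) -> list[set[int]]:
    """Brute-force DBSCAN*: union-find over mutual-reachability edges <= eps
    restricted to points whose core distance is <= eps."""
    n = D.shape[0]
    cores = np.sort(D, axis=1)[:, k - 1]
    alive = [i for i in range(n) if cores[i] <= eps]
    parent = {i: i for i in alive}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(alive, 2):
        if max(D[i, j], cores[i], cores[j]) <= eps:
            parent[find(i)] = find(j)
    comps: dict[int, set[int]] = {}
    for i in alive:
        comps.setdefault(find(i), set()).add(i)
    return sorted(comps.values(), key=lambda s: min(s))


def mst_cut_components(edges, n, D, k, eps) -> list[set[int]]:
    """Components of the hierarchy cut at lambda = 1/eps: MST edges <= eps,
    restricted to points with core distance <= eps."""
    cores = np.sort(D, axis=1)[:, k - 1]
    alive = {i for i in range(n) if cores[i] <= eps}
    parent = {i: i for i in alive}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j, w in edges:
        if w <= eps and i in alive and j in alive:
            parent[find(i)] = find(j)
    comps: dict[int, set[int]] = {}
    for i in alive:
        comps.setdefault(find(i), set()).add(i)
    return sorted(comps.values(), key=lambda s: min(s))


def equator_points(km_positions) -> list[GeoPoint]:
    """Collinear points along the equator at given km offsets."""
    from conftest import KM_PER_DEG

    return [GeoPoint(0.0, km / KM_PER_DEG) for km in km_positions]


# ---------------------------------------------------------------------------


class TestCoreDistance:
    def test_k1_is_zero_everywhere(self):
        D = pairwise_distance_matrix(equator_points([0, 1, 3]))
        assert core_distances(D, 1) == pytest.approx([0, 0, 0])

    def test_collinear_k3(self):
        # points at 0, 1, 3 km: the two neighbour distances of point 0 sort to (1, 3)
        D = pairwise_distance_matrix(equator_points([0, 1, 3]))
        assert core_distance(D, 0, 3) == pytest.approx(3.0, rel=1e-6)
        assert core_distance(D, 1, 3) == pytest.approx(2.0, rel=1e-6)

    def test_coincident_pair_k2(self):
        D = pairwise_distance_matrix([GeoPoint(5.0, 5.0)] * 2)
        assert core_distance(D, 0, 2) == 0.0

    def test_fewer_points_than_k_flagged(self):
        D = pairwise_distance_matrix(equator_points([0, 1]))
        with pytest.raises(ValueError):
            core_distances(D, 3)


class TestMutualReachability:
    def test_distance_dominates(self):
        D = np.array([[0.0, 10.0], [10.0, 0.0]])
        cores = np.array([2.0, 3.0])
        mr = mutual_reachability(D, cores)
        assert mr[0, 1] == 10.0

    def test_core_dominates(self):
        D = np.array([[0.0, 2.0], [2.0, 0.0]])
        cores = np.array([5.0, 1.0])
        mr = mutual_reachability(D, cores)
        assert mr[0, 1] == 5.0
        assert mr[1, 0] == 5.0

    def test_all_coincident(self):
        D = np.zeros((3, 3))
        mr = mutual_reachability(D, np.zeros(3))
        assert np.all(mr == 0.0)


class TestMST:
    def test_two_points_single_edge(self):
        D = pairwise_distance_matrix(equator_points([0, 7]))
        edges = mst(D)
        assert len(edges) == 1
        assert edges[0][:2] == (0, 1)

    def test_single_point_empty(self):
        assert mst(np.zeros((1, 1))) == []

    def test_chain_with_increasing_gaps_exhaustive(self):
        # 4-point chain, gaps 1 < 2 < 4 km: of the 16 labelled spanning trees
        # the consecutive-gap tree is the unique minimum (Cayley enumeration)
        D = pairwise_distance_matrix(equator_points([0, 1, 3, 7]))
        best_w, best_tree = np.inf, None
        for pruefer in itertools.product(range(4), repeat=2):
            degree = [1] * 4
            for v in pruefer:
                degree[v] += 1
            seq, tree = list(pruefer), []
            leaves = sorted(i for i in range(4) if degree[i] == 1)
            for v in seq:
                leaf = leaves.pop(0)
                tree.append((min(leaf, v), max(leaf, v)))
                degree[v] -= 1
                if degree[v] == 1:
                    import bisect

                    bisect.insort(leaves, v)
            tree.append((leaves[0], leaves[1]))
            w = sum(D[i, j] for i, j in tree)
            if w < best_w:
                best_w, best_tree = w, sorted(tree)
        assert best_tree == [(0, 1), (1, 2), (2, 3)]
        got = mst(D)
        assert sorted((i, j) for i, j, _ in got) == best_tree
        assert sum(w for _, _, w in got) == pytest.approx(best_w)

    def test_total_weight_matches_kruskal_oracle(self, rng):
        pts = [GeoPoint(float(la), float(lo))
               for la, lo in zip(rng.uniform(30, 35, 20), rng.uniform(40, 45, 20))]
        D = pairwise_distance_matrix(pts)
        got = sum(w for _, _, w in mst(D))
        assert got == pytest.approx(kruskal_mst_weight(D), rel=1e-12)


class TestCondense:
    def test_two_tight_triplets_gives_root_with_two_leaves(self):
        pts = tight_triplet(33.0, 44.0) + tight_triplet(33.0, 45.0)
        D = pairwise_distance_matrix(pts)
        mr = mutual_reachability(D, core_distances(D, 3))
        tree = condense(mst(mr), 6, 3)
        assert tree.node_children.get(0) is not None
        assert len(tree.node_children[0]) == 2
        assert all(not tree.node_children.get(c) for c in tree.node_children[0])

    def test_n_equals_k_single_root(self):
        pts = tight_triplet(10.0, 10.0)
        D = pairwise_distance_matrix(pts)
        mr = mutual_reachability(D, core_distances(D, 3))
        tree = condense(mst(mr), 3, 3)
        assert len(tree.node_birth) == 1
        assert tree.node_children == {}

    def test_duplicate_points_capped_lambda(self):
        pts = [GeoPoint(10.0, 10.0)] * 3 + tight_triplet(10.5, 10.5)
        D = pairwise_distance_matrix(pts)
        mr = mutual_reachability(D, core_distances(D, 3))
        tree = condense(mst(mr), 6, 3)
        assert np.isfinite(tree.point_lambda).all()
        assert tree.point_lambda.max() == LAMBDA_CAP

    def test_lambda_never_below_birth(self):
        pts = tight_triplet(33.0, 44.0) + tight_triplet(33.0, 45.0) + [GeoPoint(33.4, 44.5)]
        D = pairwise_distance_matrix(pts)
        mr = mutual_reachability(D, core_distances(D, 3))
        tree = condense(mst(mr), 7, 3)
        for p in range(7):
            assert tree.point_lambda[p] >= tree.node_birth[int(tree.point_node[p])] - 1e-12


class TestExtractAndMembership:
    def test_two_strong_leaves_selected_over_root(self):
        pts = tight_triplet(33.0, 44.0) + tight_triplet(33.0, 45.0)
        D = pairwise_distance_matrix(pts)
        mr = mutual_reachability(D, core_distances(D, 3))
        tree = condense(mst(mr), 6, 3)
        selected = extract_clusters(tree)
        assert selected == set(tree.node_children[0])

    def test_single_node_tree_selects_root_no_noise(self):
        pts = tight_triplet(10.0, 10.0)
        D = pairwise_distance_matrix(pts)
        mr = mutual_reachability(D, core_distances(D, 3))
        tree = condense(mst(mr), 3, 3)
        selected = extract_clusters(tree)
        assert selected == {0}
        labels, probs = membership_probabilities(tree, selected)
        assert (labels == 0).all()

    def test_symmetric_triplet_probabilities_all_one(self):
        yc = hdbscan(tight_triplet(33.0, 44.0), 3)
        assert yc.membership_prob == pytest.approx([1.0, 1.0, 1.0])

    def test_noise_gets_zero_probability(self):
        pts = tight_triplet(33.0, 44.0) + tight_triplet(33.0, 45.1) + [GeoPoint(33.45, 44.5)]
        yc = hdbscan(pts, 3)
        assert yc.labels[-1] == NOISE
        assert yc.membership_prob[-1] == 0.0
        assert (yc.membership_prob[yc.labels >= 0] > 0).all()


class TestHdbscan:
    def test_fewer_points_than_k_all_noise(self):
        yc = hdbscan(tight_triplet(33.0, 44.0)[:2], 3)
        assert (yc.labels == NOISE).all()
        assert yc.n_clusters == 0 and yc.degenerate

    def test_empty_input(self):
        yc = hdbscan([], 3)
        assert yc.n_clusters == 0 and len(yc.labels) == 0

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            hdbscan(tight_triplet(1.0, 1.0), 1)

    def test_two_triplets_two_clusters_no_noise(self):
        pts = tight_triplet(33.0, 44.0) + tight_triplet(33.0, 45.0)
        yc = hdbscan(pts, 3)
        assert yc.n_clusters == 2
        assert yc.noise_fraction == 0.0
        assert set(yc.labels[:3]) != set(yc.labels[3:])

    def test_isolated_point_is_noise(self):
        # two triplets ~100 km apart plus one point ~50 km from everything
        pts = tight_triplet(33.0, 44.0) + tight_triplet(33.0, 45.1) + [GeoPoint(33.45, 44.5)]
        yc = hdbscan(pts, 3)
        assert yc.n_clusters == 2
        assert list(yc.labels[:6]).count(NOISE) == 0
        assert yc.labels[6] == NOISE

    def test_every_cluster_has_at_least_k_members(self, rng):
        pts = [GeoPoint(float(la), float(lo))
               for la, lo in zip(rng.normal(33, 0.05, 120), rng.normal(44, 0.05, 120))]
        for k in (3, 5):
            yc = hdbscan(pts, k)
            for label in range(yc.n_clusters):
                assert (yc.labels == label).sum() >= k

    def test_each_cluster_has_a_full_probability_point(self, rng):
        pts = [GeoPoint(float(la), float(lo))
               for la, lo in zip(rng.normal(33, 0.02, 80), rng.normal(44, 0.02, 80))]
        yc = hdbscan(pts, 4)
        for label in range(yc.n_clusters):
            probs = yc.membership_prob[yc.labels == label]
            assert probs.max() == pytest.approx(1.0)
            assert np.all((probs > 0) & (probs <= 1.0))

    def test_permutation_invariance(self, rng):
        pts = [GeoPoint(float(la), float(lo))
               for la, lo in zip(rng.normal(33, 0.03, 60), rng.normal(44, 0.03, 60))]
        base = hdbscan(pts, 4)
        for _ in range(5):
            perm = rng.permutation(60)
            shuffled = [pts[i] for i in perm]
            got = hdbscan(shuffled, 4)
            # identical partition up to label renaming, identical probabilities
            mapping = {}
            for orig_label, new_label in zip(base.labels[perm], got.labels):
                assert (orig_label == NOISE) == (new_label == NOISE)
                if orig_label != NOISE:
                    assert mapping.setdefault(orig_label, new_label) == new_label
            assert got.membership_prob == pytest.approx(base.membership_prob[perm])


class TestLambdaCutEquivalence:
    """The hierarchy cut at lambda = 1/eps must equal brute-force DBSCAN*."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("k", [3, 5])
    def test_cut_matches_union_find_oracle(self, seed, k):
        rng = np.random.default_rng(seed)
        centers = [(33.0, 44.0), (33.2, 44.1), (33.1, 44.4)]
        pts = []
        for la, lo in centers:
            pts += [GeoPoint(float(a), float(b))
                    for a, b in zip(rng.normal(la, 0.02, 25), rng.normal(lo, 0.02, 25))]
        pts += [GeoPoint(float(a), float(b))
                for a, b in zip(rng.uniform(32.8, 33.4, 15), rng.uniform(43.8, 44.6, 15))]
        D = pairwise_distance_matrix(pts)
        mr = mutual_reachability(D, core_distances(D, k))
        edges = mst(mr)
        for eps in (0.5, 2.0, 5.0, 15.0):
            assert mst_cut_components(edges, len(pts), D, k, eps) == dbscan_star_components(
                D, k, eps
            )


class TestDifferentialSklearn:
    def test_label_agreement_with_reference_implementation(self, rng):
        """Non-binding comparison against the community implementation; tie
        handling and condensation conventions differ, so discrepancies are
        logged rather than asserted."""
        sklearn = pytest.importorskip("sklearn.cluster")
        from fireclust.synthetic import adjusted_rand_index

        centers = [(33.0, 44.0), (33.3, 44.2), (33.1, 44.5), (32.8, 44.3)]
        pts = []
        for la, lo in centers:
            pts += [GeoPoint(float(a), float(b))
                    for a, b in zip(rng.normal(la, 0.015, 115), rng.normal(lo, 0.015, 115))]
        pts += [GeoPoint(float(a), float(b))
                for a, b in zip(rng.uniform(32.6, 33.5, 40), rng.uniform(43.8, 44.7, 40))]
        k = 5
        ours = hdbscan(pts, k)
        xy = np.array([[p.lat * 111.195, p.lon * 111.195 * np.cos(np.radians(33))]
                       for p in pts])
        ref = sklearn.HDBSCAN(min_cluster_size=k, min_samples=k, copy=True).fit(xy)
        ari = adjusted_rand_index([int(l) for l in ours.labels], [int(l) for l in ref.labels_])
        log.info("adjusted Rand vs reference implementation: %.4f", ari)
        if ari < 0.95:
            log.warning("label agreement below 0.95 (ARI=%.4f); conventions differ", ari)
        assert ari > 0.0  # sanity: the partitions are related, not random
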