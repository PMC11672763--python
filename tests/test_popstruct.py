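import numpy as np
import pytest

from snpanel.genotypes import MISSING
from snpanel.popstruct import (
    DistanceMatrix,
    cluster_concordance,
    grm,
    ibs_distance,
    nj_tree,
    pca,
    population_distance,
)

from conftest import make_gm


def brute_force_grm(calls):
    """Independent double-loop evaluation of the standardized estimator."""
    calls = np.asarray(calls, dtype=float)
    n, s = calls.shape
    called = calls >= 0
    p = np.array(
        [
            calls[called[:, i], i].sum() / (2 * called[:, i].sum())
            for i in range(s)
        ]
    )
    usable = (p > 0) & (p < 1)
    a = np.zeros((n, n))
    m = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            tot = 0.0
            cnt = 0
            for i in range(s):
                if not usable[i] or not called[j, i] or not called[k, i]:
                    continue
                tot += (calls[j, i] - 2 * p[i]) * (calls[k, i] - 2 * p[i]) / (
                    2 * p[i] * (1 - p[i])
                )
                cnt += 1
            a[j, k] = tot / cnt
            m[j, k] = cnt
    return a, m


# ---------------------------------------------------------------------------
# random additive trees for NJ oracles
# ---------------------------------------------------------------------------


def random_additive_tree(rng, n_leaves):
    """Random unrooted binary tree; returns (leaf names, distance matrix).

    Built by splitting random edges; all branch lengths in [0.1, 1.0] so the
    metric determines the topology uniquely.
    """
    # adjacency: node -> {neighbor: branch length}; leaves are 0..n-1 and
    # internal node ids start at n, so they never collide
    hub = n_leaves
    adj = {i: {} for i in (0, 1, 2, hub)}
    for leaf in (0, 1, 2):
        w = float(rng.uniform(0.1, 1.0))
        adj[hub][leaf] = w
        adj[leaf][hub] = w
    edges = [(0, hub), (1, hub), (2, hub)]
    nxt = hub + 1
    for leaf in range(3, n_leaves):
        mid = nxt
        nxt += 1
        u, v = edges[int(rng.integers(0, len(edges)))]
        w_uv = adj[u].pop(v)
        adj[v].pop(u)
        cut = float(rng.uniform(0.25, 0.75)) * w_uv
        adj[mid] = {}
        adj[leaf] = {}
        adj[u][mid] = adj[mid][u] = cut
        adj[v][mid] = adj[mid][v] = w_uv - cut
        w_leaf = float(rng.uniform(0.1, 1.0))
        adj[leaf][mid] = adj[mid][leaf] = w_leaf
        edges.remove((u, v))
        edges += [(u, mid), (v, mid), (leaf, mid)]

    # all-pairs leaf distances by BFS/DFS accumulation
    leaves = list(range(n_leaves))
    dist = np.zeros((n_leaves, n_leaves))
    for src in leaves:
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        for dst in leaves:
            dist[src, dst] = seen[dst]
    names = [f"L{i}" for i in leaves]
    return names, dist


def patristic_from_newick(newick, names):
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(names)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[names[i]], taxa[names[j]])
    return out


class TestGrm:
    def test_single_site_closed_form(self):
        # two samples (2, 0): pooled p = 0.5; diagonal for x=2 is
        # (2 - 1)^2 / (2 * 0.5 * 0.5) = 2.0
        gm = make_gm([[2], [0]])
        a = grm(gm)
        assert a.matrix[0, 0] == pytest.approx(2.0)
        assert a.matrix[1, 1] == pytest.approx(2.0)
        assert a.matrix[0, 1] == pytest.approx(-2.0)

    def test_identical_samples_offdiag_equals_diag(self, rng):
        calls = rng.integers(0, 3, size=(1, 40))
        gm = make_gm(np.vstack([calls, calls, rng.integers(0, 3, size=(2, 40))]))
        a = grm(gm)
        assert a.matrix[0, 1] == pytest.approx(a.matrix[0, 0])

    def test_against_double_loop_oracle(self, rng):
        calls = rng.integers(-1, 3, size=(10, 20)).astype(np.int8)
        # ensure every pair shares markers
        calls[:, :5] = np.abs(calls[:, :5])
        gm = make_gm(calls)
        a = grm(gm)
        expected, m = brute_force_grm(calls)
        assert np.max(np.abs(a.matrix - expected)) < 1e-10
        assert np.array_equal(a.m_pairs, m.astype(np.int64))

    def test_permutation_invariance(self, rng):
        calls = rng.integers(0, 3, size=(8, 30)).astype(np.int8)
        gm = make_gm(calls)
        perm = rng.permutation(8).tolist()
        a = grm(gm).matrix
        b = grm(gm.take_samples(perm)).matrix
        assert np.allclose(b, a[np.ix_(perm, perm)])

    def test_mean_diagonal_near_one_under_hwe(self, rng):
        f = rng.uniform(0.1, 0.9, size=2000)
        calls = rng.binomial(2, f, size=(40, 2000)).astype(np.int8)
        a = grm(make_gm(calls))
        assert np.mean(np.diag(a.matrix)) == pytest.approx(1.0, abs=0.05)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            grm(make_gm([[1, 0]]))


class TestPca:
    def test_identity_grm_equal_eigenvalues(self):
        from snpanel.popstruct import GRM

        n = 8
        rel = GRM(np.eye(n), np.full((n, n), 10), [f"s{i}" for i in range(n)])
        res = pca(rel, k=3)
        assert np.allclose(res.eigenvalues, 1.0)

    def test_rank_one_grm(self, rng):
        from snpanel.popstruct import GRM

        v = rng.normal(size=12)
        v -= v.mean()  # centered so double-centering preserves it
        rel = GRM(np.outer(v, v), np.full((12, 12), 5), [f"s{i}" for i in range(12)])
        res = pca(rel, k=3)
        assert res.eigenvalues[0] == pytest.approx(v @ v)
        assert abs(res.eigenvalues[1]) < 1e-8

    def test_eigensum_equals_centered_trace(self, rng):
        calls = rng.integers(0, 3, size=(10, 60)).astype(np.int8)
        rel = grm(make_gm(calls))
        res = pca(rel, k=10)
        n = 10
        j = np.eye(n) - np.ones((n, n)) / n
        assert res.eigenvalues.sum() == pytest.approx(np.trace(j @ rel.matrix @ j), abs=1e-8)

    def test_orthonormal_coords(self, rng):
        calls = rng.integers(0, 3, size=(12, 80)).astype(np.int8)
        res = pca(grm(make_gm(calls)), k=3)
        assert np.allclose(res.coords.T @ res.coords, np.eye(3), atol=1e-8)

    def test_k_exceeds_n(self, rng):
        rel = grm(make_gm(rng.integers(0, 3, size=(4, 30)).astype(np.int8)))
        with pytest.raises(ValueError):
            pca(rel, k=5)

    def test_two_population_separation(self):
        from snpanel.synth import SimConfig, simulate_cohort

        cfg = SimConfig(
            seed=5,
            breeds=("P", "Q"),
            types_in={},
            samples_per_pop=25,
            n_sites=5000,
            chroms=(("1", 400_000),),
        )
        _, gm = simulate_cohort(cfg)
        res = pca(grm(gm), k=3)
        pc1 = res.coords[:, 0]
        a, b = pc1[:25], pc1[25:]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) or max(
            b.min(), a.min()
        ) > min(b.max(), a.max())
        # zero overlap between the two populations on PC1
        assert (a.max() < b.min()) or (b.max() < a.min())


class TestIbsDistance:
    def test_identical_zero(self, rng):
        row = rng.integers(0, 3, size=(1, 30))
        gm = make_gm(np.vstack([row, row]))
        d = ibs_distance(gm)
        assert d.matrix[0, 1] == pytest.approx(0.0)

    def test_opposite_homozygotes_one(self):
        gm = make_gm([[0] * 10, [2] * 10])
        assert ibs_distance(gm).matrix[0, 1] == pytest.approx(1.0)

    def test_four_sample_hand_case(self):
        calls = [
            [0, 1, 2, 0],
            [0, 1, 2, 2],  # differs at site 4 by 2 -> d = 2/8
            [1, 1, 1, 1],
            [2, MISSING, 0, 1],
        ]
        d = ibs_distance(make_gm(calls)).matrix
        assert d[0, 1] == pytest.approx(2 / 8)
        assert d[0, 2] == pytest.approx((1 + 0 + 1 + 1) / 8)
        # pair (0,3): co-called sites 1,3,4 -> |0-2| + |2-0| + |0-1| = 5 over 6
        assert d[0, 3] == pytest.approx(5 / 6)

    def test_bounds_symmetry_identity(self, rng):
        calls = rng.integers(-1, 3, size=(8, 50)).astype(np.int8)
        calls[:, 0] = 1  # guarantee a shared site for every pair
        d = ibs_distance(make_gm(calls)).matrix
        assert np.allclose(d, d.T)
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()
        assert np.allclose(np.diag(d), 0.0)

    def test_population_distance_averages(self, rng):
        calls = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        gm = make_gm(calls, pops=["A"] * 3 + ["B"] * 3)
        d = ibs_distance(gm)
        pd_ = population_distance(d, gm.populations)
        block = d.matrix[np.ix_(range(3), range(3, 6))]
        assert pd_.matrix[0, 1] == pytest.approx(block.mean())


class TestNjTree:
    def test_three_taxa_closed_form(self):
        ids = ["a", "b", "c"]
        m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(m, np.ones_like(m, dtype=np.int64), ids))
        pat = patristic_from_newick(tree.newick, ids)
        assert np.allclose(pat, m, atol=1e-9)

    def test_four_taxon_topology_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> additive distances
        ids = ["a", "b", "c", "d"]
        m = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 0, 0],
            ],
            dtype=float,
        )
        m[3, 2] = m[2, 3] = 7
        m[3, 3] = 0
        tree = nj_tree(DistanceMatrix(m, np.ones_like(m, dtype=np.int64), ids))
        pat = patristic_from_newick(tree.newick, ids)
        assert np.allclose(pat, m, atol=1e-9)
        # correct split: {a,b} vs {c,d}
        assert ("(a:" in tree.newick or "a:" in tree.newick)

    def test_eight_taxon_additivity(self, rng):
        names, m = random_additive_tree(rng, 8)
        tree = nj_tree(DistanceMatrix(m, np.ones_like(m, dtype=np.int64), names))
        pat = patristic_from_newick(tree.newick, names)
        assert np.max(np.abs(pat - m)) < 1e-9

    def test_random_additive_matrices_recovered(self, rng):
        for _ in range(10):  # larger sweep lives in the acceptance suite
            n = int(rng.integers(5, 11))
            names, m = random_additive_tree(rng, n)
            tree = nj_tree(DistanceMatrix(m, np.ones_like(m, dtype=np.int64), names))
            pat = patristic_from_newick(tree.newick, names)
            assert np.max(np.abs(pat - m)) < 1e-9

    def test_newick_round_trip(self, rng):
        import dendropy

        names, m = random_additive_tree(rng, 6)
        tree = nj_tree(DistanceMatrix(m, np.ones_like(m, dtype=np.int64), names))
        parsed = dendropy.Tree.get(data=tree.newick, schema="newick")
        assert sorted(t.label for t in parsed.taxon_namespace) == sorted(names)

    def test_asymmetric_rejected(self):
        m = np.array([[0, 1, 2], [3, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(m, np.ones_like(m, dtype=np.int64), list("abc")))

    def test_too_few_leaves(self):
        m = np.zeros((2, 2))
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(m, np.ones_like(m, dtype=np.int64), ["a", "b"]))


class TestClusterConcordance:
    def test_perfect_partition(self, rng):
        coords = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))])
        labels = ["A"] * 20 + ["B"] * 20
        ari, purity, _ = cluster_concordance(coords, labels, seed=0)
        assert ari == pytest.approx(1.0)
        assert purity == pytest.approx(1.0)

    def test_random_labels_near_zero(self, rng):
        coords = rng.normal(size=(200, 2))
        labels = [("A", "B")[i] for i in rng.integers(0, 2, size=200)]
        ari, _, _ = cluster_concordance(coords, labels, seed=0)
        assert abs(ari) < 0.05

    def test_fewer_samples_than_clusters(self, rng):
        with pytest.raises(ValueError):
            cluster_concordance(rng.normal(size=(2, 2)), ["A", "B", "C"][:2], n_clusters=3)
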