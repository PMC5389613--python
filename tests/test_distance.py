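import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import nnls
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from bulkpop import (
    FrequencyTable,
    PCoA,
    distance_extremes,
    distance_matrix,
    neighbor_joining,
    psa_distance,
    tree_path_lengths,
)


class TestPSADistance:
    def test_identical_profiles_distance_zero(self):
        p = {"a": {1: 0.3, 2: 0.7}, "b": {3: 1.0}}
        assert psa_distance(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_allele_sets_distance_one(self):
        assert psa_distance({"a": {1: 1.0}}, {"a": {2: 1.0}}) == pytest.approx(1.0)

    def test_single_locus_arithmetic(self):
        d = psa_distance({"a": {1: 0.3, 2: 0.7}}, {"a": {1: 0.6, 2: 0.4}})
        assert d == pytest.approx(0.3, abs=1e-12)

    def test_no_shared_loci_rejected(self):
        with pytest.raises(ValueError):
            psa_distance({"a": {1: 1.0}}, {"b": {1: 1.0}})

    @given(st.data())
    @settings(deadline=None, max_examples=50)
    def test_symmetric_bounded_semimetric(self, data):
        def profile():
            out = {}
            for locus in ("a", "b"):
                raw = data.draw(
                    st.lists(
                        st.floats(min_value=0.01, max_value=1.0), min_size=1, max_size=5
                    )
                )
                tot = sum(raw)
                out[locus] = {10 + 2 * i: x / tot for i, x in enumerate(raw)}
            return out

        p, q = profile(), profile()
        d = psa_distance(p, q)
        assert 0.0 - 1e-12 <= d <= 1.0 + 1e-12
        assert d == pytest.approx(psa_distance(q, p), abs=1e-12)
        assert psa_distance(p, p) == pytest.approx(0.0, abs=1e-12)


class TestDistanceMatrix:
    def test_identical_populations(self):
        base = {"a": {1: 0.5, 2: 0.5}}
        dm = distance_matrix(FrequencyTable({"p1": base, "p2": base}))
        assert dm["p1", "p2"] == pytest.approx(0.0, abs=1e-12)

    def test_population_order_permutes_consistently(self, study_scale_dataset):
        t = study_scale_dataset.bulk_freqs
        sub = t.subset(t.populations[:6])
        perm = list(reversed(sub.populations))
        dm1 = distance_matrix(sub)
        dm2 = distance_matrix(sub.subset(perm))
        for i, j in itertools.combinations(perm, 2):
            assert dm1[i, j] == pytest.approx(dm2[i, j], abs=1e-12)

    def test_extremes_report(self):
        t = FrequencyTable(
            {
                "p1": {"a": {1: 1.0}},
                "p2": {"a": {2: 1.0}},
                "p3": {"a": {1: 0.9, 2: 0.1}},
            }
        )
        ext = distance_extremes(distance_matrix(t))
        assert ext["max"] == pytest.approx(1.0)
        assert set(ext["max_pair"]) == {"p1", "p2"}
        assert ext["min"] == pytest.approx(0.1, abs=1e-12)


class TestGenotypePSADistance:
    def _geno(self, rows):
        import pandas as pd

        return pd.DataFrame(
            rows, columns=["population", "individual", "locus", "allele1", "allele2"]
        )

    def test_analytic_cases(self):
        from bulkpop import genotype_distance_matrix

        rows = []
        for i in range(1, 6):
            rows.append(("p1", i, "l", 100, 102))  # all A/B heterozygotes
            rows.append(("p2", i, "l", 100, 100))  # all A/A
            rows.append(("p3", i, "l", 104, 104))  # disjoint allele
        dm = genotype_distance_matrix(self._geno(rows))
        assert dm["p1", "p2"] == pytest.approx(0.5)  # shared = min(1,2)/2
        assert dm["p2", "p3"] == pytest.approx(1.0)
        assert dm["p1", "p1"] == 0.0

    def test_tracks_frequency_route_on_simulated_individuals(self, small_k2_dataset):
        from bulkpop import (
            SimulationParams,
            frequencies_from_genotypes,
            genotype_distance_matrix,
            simulate_individuals,
        )

        table = small_k2_dataset.bulk_freqs.subset(
            small_k2_dataset.bulk_freqs.populations[:5]
        )
        geno = simulate_individuals(table, SimulationParams(seed=0))
        dg = genotype_distance_matrix(geno)
        df = distance_matrix(frequencies_from_genotypes(geno))
        pairs = list(itertools.combinations(table.populations, 2))
        for i, j in pairs:
            # Jensen: pair-averaged min-overlap ≤ min of averaged profiles,
            # so the genotype-route distance dominates the profile route
            assert df[i, j] - 1e-9 <= dg[i, j] <= 1.0 + 1e-9
        # both routes rank the same pairs as closest
        top_g = sorted(pairs, key=lambda p: dg[p])[:3]
        top_f = sorted(pairs, key=lambda p: df[p])[:3]
        assert set(top_g) == set(top_f)
        assert np.allclose(dg.data, dg.data.T)


# -- neighbor joining ------------------------------------------------------


def _all_topologies(n_leaves):
    """Every unrooted binary topology on leaves 0..n-1, as edge lists."""
    trees = [[(0, "i0"), (1, "i0"), (2, "i0")]]
    for leaf in range(3, n_leaves):
        grown = []
        for edges in trees:
            for k, (u, v) in enumerate(edges):
                node = f"i{leaf - 2}_{k}"
                new = [e for i, e in enumerate(edges) if i != k]
                new += [(u, node), (v, node), (leaf, node)]
                grown.append(new)
        trees = grown
    return trees


def _ls_rss(edges, d):
    """Least-squares branch fit (non-negative) of a topology to distances."""
    import networkx as nx

    g = nx.Graph()
    g.add_edges_from(edges)
    leaves = sorted(x for x in g.nodes if isinstance(x, int))
    eidx = {frozenset(e): i for i, e in enumerate(edges)}
    rows, y = [], []
    for i, j in itertools.combinations(leaves, 2):
        path = nx.shortest_path(g, i, j)
        row = np.zeros(len(edges))
        for u, v in zip(path, path[1:]):
            row[eidx[frozenset((u, v))]] = 1.0
        rows.append(row)
        y.append(d[i, j])
    _, rss = nnls(np.array(rows), np.array(y))
    return rss**2


def _additive_matrix(edges, lengths, n_leaves):
    import networkx as nx

    g = nx.Graph()
    for e, w in zip(edges, lengths):
        g.add_edge(*e, weight=w)
    d = np.zeros((n_leaves, n_leaves))
    for i, j in itertools.combinations(range(n_leaves), 2):
        d[i, j] = d[j, i] = nx.shortest_path_length(g, i, j, weight="weight")
    return d


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            [[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]], ids=["a", "b", "c"]
        )
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2, abs=1e-12)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2, abs=1e-12)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2, abs=1e-12)

    @pytest.mark.parametrize("n_leaves,seed", [(4, 0), (4, 1), (5, 2), (5, 3)])
    def test_additive_matrix_recovered_exactly(self, n_leaves, seed):
        """Distances generated from a random tree come back with identical
        path lengths (and hence topology)."""
        rng = np.random.default_rng(seed)
        topos = _all_topologies(n_leaves)
        edges = topos[rng.integers(len(topos))]
        lengths = rng.uniform(0.05, 0.5, size=len(edges))
        d = _additive_matrix(edges, lengths, n_leaves)
        ids = [str(i) for i in range(n_leaves)]
        tree = neighbor_joining(DistanceMatrix(d, ids=ids))
        back = tree_path_lengths(tree, ids)
        assert np.allclose(back.data, d, atol=1e-9)

    def test_near_additive_output_minimizes_least_squares(self):
        """With σ = 0.01 noise on an additive 5-taxon matrix, the NJ tree's
        topology attains the best least-squares fit among all 15."""
        rng = np.random.default_rng(7)
        topos = _all_topologies(5)
        for trial in range(3):
            edges = topos[rng.integers(len(topos))]
            lengths = rng.uniform(0.1, 0.5, size=len(edges))
            d = _additive_matrix(edges, lengths, 5)
            noise = rng.normal(0.0, 0.01, size=d.shape)
            d_noisy = d + (noise + noise.T) / 2
            np.fill_diagonal(d_noisy, 0.0)
            d_noisy = np.clip(d_noisy, 0.0, None)
            ids = [str(i) for i in range(5)]
            tree = neighbor_joining(DistanceMatrix(d_noisy, ids=ids))
            nj_rss = _ls_rss_of_tree(tree, d_noisy)
            best = min(_ls_rss(e, d_noisy) for e in topos)
            assert nj_rss <= best + 1e-8, trial

    def test_matches_reference_nj_on_additive_input(self):
        rng = np.random.default_rng(11)
        topos = _all_topologies(5)
        edges = topos[rng.integers(len(topos))]
        lengths = rng.uniform(0.05, 0.5, size=len(edges))
        d = _additive_matrix(edges, lengths, 5)
        ids = [str(i) for i in range(5)]
        dm = DistanceMatrix(d, ids=ids)
        ours = tree_path_lengths(neighbor_joining(dm), ids)
        ref = skbio_nj(dm).tip_tip_distances().filter(ids)
        assert np.allclose(ours.data, ref.data, atol=1e-6)

    def test_leaf_set_preserved_and_branches_nonnegative(self, study_scale_dataset):
        t = study_scale_dataset.bulk_freqs
        sub = t.subset(t.populations[:12])
        tree = neighbor_joining(distance_matrix(sub))
        assert {tip.name for tip in tree.tips()} == set(sub.populations)
        for node in tree.traverse():
            if node.length is not None:
                assert node.length >= 0.0

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"]))


def _tree_edges(tree):
    """Edge list of a TreeNode with integer leaf labels (topology only)."""
    names = {}
    edges = []

    def key(node):
        if node not in names:
            names[node] = int(node.name) if node.is_tip() else f"n{len(names)}"
        return names[node]

    for node in tree.traverse(include_self=True):
        for child in node.children:
            edges.append((key(node), key(child)))
    return edges


def _ls_rss_of_tree(tree, d):
    """Least-squares RSS of the NJ *topology* (branch lengths refitted)."""
    return _ls_rss(_tree_edges(tree), d)


# -- PCoA ------------------------------------------------------------------


class TestPCoA:
    def test_planar_configuration_recovered(self):
        """Euclidean distances of 4 planted planar points reproduce the
        configuration up to rotation/reflection (Procrustes < 1e-8)."""
        from scipy.spatial import procrustes
        from scipy.spatial.distance import squareform, pdist

        pts = np.array([[0.0, 0.0], [1.0, 0.2], [0.3, 1.1], [-0.8, 0.5]])
        dm = DistanceMatrix(squareform(pdist(pts)), ids=list("abcd"))
        ord_ = PCoA(n_axes=2).fit(dm)
        _, _, disparity = procrustes(pts, ord_.coordinates_.to_numpy())
        assert disparity < 1e-8

    def test_equilateral_distances_give_equal_eigenvalues(self):
        d = np.full((4, 4), 0.6)
        np.fill_diagonal(d, 0.0)
        ord_ = PCoA().fit(DistanceMatrix(d, ids=list("abcd")))
        assert len(ord_.eigenvalues_) == 3
        assert np.allclose(ord_.eigenvalues_, ord_.eigenvalues_[0], atol=1e-9)

    def test_rank_at_most_n_minus_one(self, study_scale_dataset):
        t = study_scale_dataset.bulk_freqs
        dm = distance_matrix(t.subset(t.populations[:8]))
        ord_ = PCoA().fit(dm)
        assert len(ord_.eigenvalues_) <= 7
        coords = ord_.coordinates_.to_numpy()
        assert np.allclose(coords.mean(axis=0), 0.0, atol=1e-9)
        assert np.all(np.diff(ord_.eigenvalues_) <= 1e-12)

    def test_euclidean_distances_preserved_in_full_space(self):
        from scipy.spatial.distance import squareform, pdist

        rng = np.random.default_rng(3)
        pts = rng.random((6, 3))
        d = squareform(pdist(pts))
        ord_ = PCoA().fit(DistanceMatrix(d, ids=[str(i) for i in range(6)]))
        back = squareform(pdist(ord_.coordinates_.to_numpy()))
        assert np.allclose(back, d, atol=1e-8)

    def test_matches_reference_pcoa(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa
        from scipy.spatial.distance import squareform, pdist

        rng = np.random.default_rng(9)
        pts = rng.random((7, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(7)])
        ours = PCoA().fit(dm)
        ref = skbio_pcoa(dm, number_of_dimensions=3)
        assert np.allclose(
            ours.eigenvalues_[:3], ref.eigvals.to_numpy()[:3], atol=1e-8
        )
        assert np.allclose(
            np.abs(ours.coordinates_.to_numpy()[:, :3]),
            np.abs(ref.samples.to_numpy()[:, :3]),
            atol=1e-6,
        )

    def test_degenerate_input_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            PCoA().fit(DistanceMatrix(d, ids=list("abc")))
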