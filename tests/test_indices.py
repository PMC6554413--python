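import numpy as np
import pytest

from ndseq import (
    UndirectedGraph,
    compute_all,
    degree_class_index,
    fixtures,
    generate,
    hierarchical_complexity,
    hierarchical_complexity_corrected,
    neighbourhood_organisation,
    neighbourhood_similarity,
    node_heterogeneity,
    omega_p,
    relative_node_heterogeneity,
    sequence_table,
    symmetric_double,
    wl2_signature,
)

from oracles import (
    complexity_naive,
    node_heterogeneity_loop,
    omega_literal,
    random_simple_graph,
    similarity_pairwise,
)


class TestNodeHeterogeneity:
    @pytest.mark.parametrize("n", [3, 5, 10, 50])
    def test_star_is_zero(self, n):
        assert node_heterogeneity(fixtures("star", n=n)) == 0.0

    def test_regular_is_zero(self, c5):
        assert node_heterogeneity(c5) == 0.0

    def test_p4_population(self, p4):
        # two degree-2 nodes with s={1,2}, var=0.25 each; divided by n=4
        assert node_heterogeneity(p4, "population") == pytest.approx(0.125)

    def test_matches_loop_oracle(self, karate):
        for conv, ddof in (("population", 0), ("sample", 1)):
            assert node_heterogeneity(karate, conv) == pytest.approx(
                node_heterogeneity_loop(karate.nodes, karate.edges, ddof=ddof)
            )

    def test_mean_over_contributing(self, p4):
        assert node_heterogeneity(p4, mean_over="contributing") == pytest.approx(0.25)


class TestRelativeNodeHeterogeneity:
    def test_regular_undefined(self, c5):
        assert relative_node_heterogeneity(c5) is None

    def test_p4_population(self, p4):
        assert relative_node_heterogeneity(p4, "population") == pytest.approx(0.5)

    def test_karate_sample_convention(self, karate):
        # sample variance (for both local and global) reproduces the
        # published reference value 1.714 for this graph
        val = relative_node_heterogeneity(karate, "sample")
        assert round(val, 3) == 1.714


class TestNeighbourhoodSimilarity:
    def test_cycle_regular(self, c5):
        assert neighbourhood_similarity(c5) == 1.0

    def test_p3(self, p3):
        # end nodes share (2,); the centre's (1,1) is unmatched
        assert neighbourhood_similarity(p3) == pytest.approx(2 / 3)

    def test_karate(self, karate):
        assert round(neighbourhood_similarity(karate), 3) == 0.324

    def test_literal_self_match_variant_is_one(self, p3, karate):
        assert neighbourhood_similarity(p3, include_self_match=True) == 1.0
        assert neighbourhood_similarity(karate, include_self_match=True) == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_hash_grouping_equals_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nodes, edges = random_simple_graph(rng, n_max=200 if seed < 3 else 60)
        g = UndirectedGraph(nodes=nodes, edges=edges)
        assert neighbourhood_similarity(g) == pytest.approx(
            similarity_pairwise(nodes, edges), abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(50))
    def test_proposition_disjoint_double_always_one(self, seed):
        rng = np.random.default_rng(1000 + seed)
        nodes, edges = random_simple_graph(rng, n_max=20, p=0.3)
        g = UndirectedGraph(nodes=nodes, edges=edges)
        assert neighbourhood_similarity(symmetric_double(g)) == 1.0


class TestOmegaP:
    def test_all_identical_is_zero(self, c5):
        dci = degree_class_index(sequence_table(c5))
        assert omega_p(dci, 2) == 0.0

    def test_all_unique_is_one(self):
        # degree-2 class: mids of a planted graph with all-singleton groups
        g = fixtures("planted_multiorder", multiplicities=[1, 1, 1])
        dci = degree_class_index(sequence_table(g))
        assert omega_p(dci, 2) == pytest.approx(1.0)

    def test_worked_counts_1_1_3(self):
        g = fixtures("planted_multiorder", multiplicities=[1, 1, 3])
        dci = degree_class_index(sequence_table(g))
        assert dci.classes[2].q == 5
        assert dci.classes[2].n_unique == 3
        assert omega_p(dci, 2) == pytest.approx(0.3)

    def test_singleton_class_rejected(self):
        star5 = fixtures("star", n=5)
        dci = degree_class_index(sequence_table(star5))
        with pytest.raises(ValueError):
            omega_p(dci, 4)
        with pytest.raises(KeyError):
            omega_p(dci, 99)

    @pytest.mark.parametrize("seed", range(20))
    def test_literal_equals_closed_form(self, seed):
        rng = np.random.default_rng(2000 + seed)
        nodes, edges = random_simple_graph(rng, n_max=60)
        g = UndirectedGraph(nodes=nodes, edges=edges)
        dci = degree_class_index(sequence_table(g))
        for p in dci.d2:
            cls = dci.classes[p]
            closed = cls.n_unique * (cls.n_unique - 1) / (cls.q * (cls.q - 1))
            assert omega_p(dci, p) == pytest.approx(closed, abs=1e-9)
            assert omega_p(dci, p) == pytest.approx(
                omega_literal(list(cls.sequences)), abs=1e-9
            )


class TestNeighbourhoodOrganisation:
    def test_regular_is_one(self, c5):
        assert neighbourhood_organisation(c5) == 1.0

    def test_p5(self, p5):
        assert neighbourhood_organisation(p5) == pytest.approx(5 / 6)

    def test_karate(self, karate):
        assert round(neighbourhood_organisation(karate), 3) == 0.279

    def test_empty_d2_undefined(self):
        # pigeonhole: any graph with an edge repeats a degree among its
        # non-isolated nodes, so D_2 is empty exactly for edgeless graphs
        assert neighbourhood_organisation(UndirectedGraph(nodes=["a", "b", "c"])) is None
        assert neighbourhood_organisation(UndirectedGraph(edges=[("a", "b")])) is not None

    def test_er_low_lattice_high(self):
        lattice = generate("watts_strogatz", n=50, k=4, beta=0.0, seed=1)
        assert neighbourhood_organisation(lattice) == 1.0
        er = generate("erdos_renyi", n=200, p=0.1, seed=1)
        assert neighbourhood_organisation(er) < 0.5


class TestHierarchicalComplexity:
    def test_regular_zero(self, c5):
        assert hierarchical_complexity(c5) == 0.0
        assert hierarchical_complexity_corrected(c5) == 0.0

    def test_p5_values(self, p5):
        assert hierarchical_complexity(p5) == pytest.approx(1 / 12)
        assert hierarchical_complexity_corrected(p5) == pytest.approx(1 / 36)

    def test_karate_table_scale(self, karate):
        assert round(hierarchical_complexity(karate, per_node_normalised=True), 3) == 0.296
        assert (
            round(hierarchical_complexity_corrected(karate, per_node_normalised=True), 3)
            == 0.190
        )

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_triple_sum(self, seed):
        rng = np.random.default_rng(3000 + seed)
        nodes, edges = random_simple_graph(rng, n_max=60)
        g = UndirectedGraph(nodes=nodes, edges=edges)
        r = hierarchical_complexity(g)
        ro = hierarchical_complexity_corrected(g)
        expected_r = complexity_naive(nodes, edges, weighted=False)
        expected_ro = complexity_naive(nodes, edges, weighted=True)
        if expected_r is None:
            assert r is None and ro is None
        else:
            assert r == pytest.approx(expected_r, abs=1e-9)
            assert ro == pytest.approx(expected_ro, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_corrected_never_exceeds_r(self, seed):
        rng = np.random.default_rng(4000 + seed)
        nodes, edges = random_simple_graph(rng)
        g = UndirectedGraph(nodes=nodes, edges=edges)
        r = hierarchical_complexity(g)
        ro = hierarchical_complexity_corrected(g)
        if r is not None:
            assert ro <= r + 1e-12


class TestWl2Signature:
    def test_triangle_tokens_equal(self, triangle):
        tokens = {wl2_signature(triangle, i) for i in triangle.nodes}
        assert len(tokens) == 1

    def test_p3_ends_match_centre_differs(self, p3):
        assert wl2_signature(p3, "a") == wl2_signature(p3, "c")
        assert wl2_signature(p3, "a") != wl2_signature(p3, "b")

    def test_unknown_node(self, p3):
        with pytest.raises(KeyError):
            wl2_signature(p3, "zzz")

    @pytest.mark.parametrize("seed", range(5))
    def test_token_multiset_matches_sequence_table(self, seed):
        rng = np.random.default_rng(5000 + seed)
        nodes, edges = random_simple_graph(rng)
        g = UndirectedGraph(nodes=nodes, edges=edges)
        t = sequence_table(g)
        from collections import Counter

        expected = Counter((len(s), s) for s in t.sequences.values())
        got = Counter()
        for i in g.nodes:
            if g.degree(i) > 0:
                k = g.degree(i)
                s = tuple(sorted(g.degree(j) for j in g.neighbors(i)))
                assert wl2_signature(g, i) == f"{k}|{','.join(map(str, s))}"
                got[(k, s)] += 1
        assert got == expected

    @pytest.mark.parametrize("seed", range(5))
    def test_refines_degree_partition(self, seed):
        rng = np.random.default_rng(6000 + seed)
        nodes, edges = random_simple_graph(rng)
        g = UndirectedGraph(nodes=nodes, edges=edges)
        for i in g.nodes:
            for j in g.nodes:
                if wl2_signature(g, i) == wl2_signature(g, j):
                    assert g.degree(i) == g.degree(j)


class TestComputeAll:
    def test_c5_report(self, c5):
        rep = compute_all(c5)
        assert rep.S == 1.0
        assert rep.V_n == 0.0
        assert rep.Omega == 1.0
        assert rep.R == 0.0
        assert rep.R_Omega == 0.0
        assert rep.V_hat_n is None
        assert "V_hat_n" in rep.flags

    def test_p5_report(self, p5):
        rep = compute_all(p5)
        assert rep.Omega == pytest.approx(5 / 6)
        assert rep.R == pytest.approx(1 / 12)
        assert rep.R_Omega == pytest.approx(1 / 36)

    def test_karate_reference_row(self, karate):
        rep = compute_all(
            karate,
            variance_convention="sample",
            per_node_normalised_complexity=True,
        )
        assert round(rep.S, 3) == 0.324
        assert round(rep.V_hat_n, 3) == 1.714
        assert round(rep.Omega, 3) == 0.279
        assert round(rep.R, 3) == 0.296
        assert round(rep.R_Omega, 3) == 0.190
        assert rep.flags == {}

    def test_per_degree_table(self, p5):
        rep = compute_all(p5)
        rows = {row.p: row for row in rep.per_degree}
        assert rows[1].q_p == 2 and rows[1].omega_p == 0.0
        assert rows[2].q_p == 3 and rows[2].omega_p == pytest.approx(1 / 3)

    def test_undefined_never_silently_zeroed(self):
        rep = compute_all(UndirectedGraph(nodes=["a", "b", "c"]))
        assert rep.Omega is None and "Omega" in rep.flags
        assert rep.R is None and rep.R_Omega is None

    def test_consistency_with_individual_ops(self, karate):
        rep = compute_all(karate)
        assert rep.S == neighbourhood_similarity(karate)
        assert rep.V_n == node_heterogeneity(karate)
        assert rep.Omega == pytest.approx(neighbourhood_organisation(karate))
        assert rep.R == pytest.approx(hierarchical_complexity(karate))
        assert rep.R_Omega == pytest.approx(hierarchical_complexity_corrected(karate))
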