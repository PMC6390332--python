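import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_stat_table
from fopa import (
    Edge,
    InteractionKind,
    PathwayCollection,
    PathwayGraph,
    compute_parameters,
    diff_term,
    edge_parameters,
    init_parameters,
    interaction_probability,
    random_pathway,
)

ALPHA = 1.0 / 6.0


class TestDiffTerm:
    @pytest.mark.parametrize(
        "de_a,de_b,expected",
        [(False, False, ALPHA), (True, False, 2 * ALPHA), (False, True, 2 * ALPHA), (True, True, 3 * ALPHA)],
    )
    def test_ladder(self, de_a, de_b, expected):
        assert diff_term(de_a, de_b, ALPHA) == pytest.approx(expected, abs=1e-15)

    def test_out_of_range_alpha_rejected(self):
        for bad in (0.0, 0.4, -0.1):
            with pytest.raises(ValueError):
                diff_term(True, True, bad)

    @given(st.floats(0.01, 1 / 3), st.booleans(), st.booleans())
    def test_de_switch_never_decreases(self, alpha, de_a, de_b):
        base = diff_term(de_a, de_b, alpha)
        assert diff_term(True, de_b, alpha) >= base
        assert diff_term(de_a, True, alpha) >= base


def collection_with_edges(specs: list[list[tuple[str, str, int] | str]]) -> PathwayCollection:
    """Each spec: list of edges (src, tgt, polarity) and/or bare node names."""
    paths = []
    for i, spec in enumerate(specs):
        nodes, edges = set(), []
        for item in spec:
            if isinstance(item, str):
                nodes.add(item)
            else:
                s, t, pol = item
                nodes |= {s, t}
                kind = InteractionKind.ACTIVATION if pol > 0 else InteractionKind.INHIBITION
                edges.append(Edge(s, t, kind))
        paths.append(PathwayGraph(id=f"P{i}", nodes=nodes, edges=edges))
    return PathwayCollection(paths)


class TestInteractionProbability:
    def test_two_of_three(self):
        coll = collection_with_edges(
            [[("A", "B", 1)], [("A", "B", 1)], ["A", "B"]]
        )
        assert interaction_probability(coll, "A", "B", "activating") == pytest.approx(2 / 3)

    def test_unique_to_scored_pathway(self):
        coll = collection_with_edges([[("A", "B", 1)], ["C", "D"]])
        assert interaction_probability(coll, "A", "B", "activating") == 1.0

    def test_absent_polarity_zero(self):
        coll = collection_with_edges([[("A", "B", 1)], ["A", "B"]])
        assert interaction_probability(coll, "A", "B", "inhibiting") == 0.0

    def test_no_cooccurrence_raises(self):
        coll = collection_with_edges([[("A", "B", 1)]])
        with pytest.raises(ValueError, match="co-occur"):
            interaction_probability(coll, "A", "Z", "activating")

    @given(st.integers(0, 49))
    def test_matches_bruteforce_on_random_collections(self, seed):
        rng = np.random.default_rng(seed)
        pool = [f"g{i}" for i in range(10)]
        paths = []
        for k in range(4):
            genes = sorted(pool[i] for i in rng.choice(10, size=5, replace=False))
            paths.append(
                random_pathway(5, 6, 0.4, seed=seed * 10 + k, genes=genes, pathway_id=f"P{k}")
            )
        coll = PathwayCollection(paths)
        univ = sorted(coll.gene_universe)
        a, b = rng.choice(univ, size=2, replace=False)
        both = [p for p in coll if {a, b} <= p.gene_nodes()]
        for pol, want in (("activating", 1), ("inhibiting", -1)):
            num = sum(1 for p in both if (a, b, want) in p.edge_set())
            if both:
                assert interaction_probability(coll, a, b, pol) == pytest.approx(
                    num / len(both)
                )
            else:
                with pytest.raises(ValueError):
                    interaction_probability(coll, a, b, pol)


class TestEdgeParameters:
    def test_activation_product(self):
        coll = collection_with_edges([[("A", "B", 1)], [("A", "B", 1)], ["A", "B"]])
        stats = make_stat_table(["A", "B"], de={"A", "B"}, P={"A": 0.4})
        out = edge_parameters(Edge("A", "B", InteractionKind.ACTIVATION), stats, coll)
        # diff = 3a = 1/2, P(A) = 0.4, P(A->B) = 2/3
        assert out["prob_active"] == pytest.approx(0.5 * 0.4 * 2 / 3)

    def test_zero_gene_probability_kills_edge(self):
        coll = collection_with_edges([[("A", "B", 1)]])
        stats = make_stat_table(["A", "B"], de={"A"}, P={"A": 0.0})
        out = edge_parameters(Edge("A", "B", InteractionKind.ACTIVATION), stats, coll)
        assert out["prob_active"] == 0.0

    def test_inhibition_pair_asymmetry(self):
        # prob_inhibit1 is the raw interaction frequency; prob_inhibit2 is damped
        coll = collection_with_edges(
            [[("A", "B", -1)], [("A", "B", -1)], [("A", "B", -1)], [("A", "B", -1)], ["A", "B"]]
        )
        stats = make_stat_table(["A", "B"], de=set(), P={"A": 0.3})
        out = edge_parameters(
            Edge("A", "B", InteractionKind.INHIBITION), stats, coll, alpha_weight=1 / 3
        )
        assert out["prob_inhibit1"] == pytest.approx(0.8)
        assert out["prob_inhibit2"] == pytest.approx((1 / 3) * 0.3 * 0.8)


class TestInitParameters:
    def test_non_de_gene(self):
        stats = make_stat_table(["A"], P={"A": 0.7})
        assert init_parameters("A", False, 0.05, stats) == (0.95, 0.05, 0.7)

    def test_de_gene(self):
        stats = make_stat_table(["A"], P={"A": 0.7})
        assert init_parameters("A", True, 0.05, stats) == (0.05, 0.95, 0.7)

    def test_zero_error_deterministic(self):
        stats = make_stat_table(["A"])
        assert init_parameters("A", False, 0.0, stats)[:2] == (1.0, 0.0)
        assert init_parameters("A", True, 0.0, stats)[:2] == (0.0, 1.0)


class TestComputeParameters:
    def make_inputs(self, seed=0):
        rng = np.random.default_rng(seed)
        pool = [f"g{i}" for i in range(14)]
        paths = [
            random_pathway(
                6, 7, 0.3, seed=seed * 7 + k,
                genes=sorted(pool[i] for i in rng.choice(14, size=6, replace=False)),
                pathway_id=f"P{k}",
            )
            for k in range(3)
        ]
        coll = PathwayCollection(paths)
        genes = sorted(coll.gene_universe)
        de = {g for g in genes if rng.random() < 0.3}
        P = {g: float(rng.random()) for g in genes}
        return coll, make_stat_table(genes, de=de, P=P), de

    def test_cardinality(self):
        coll, stats, _ = self.make_inputs()
        g = coll.pathways[0]
        params = compute_parameters(g, stats, coll)
        n_act = sum(1 for e in g.edges if e.polarity > 0)
        n_inh = len(g.edges) - n_act
        assert len(params.edge_params) == n_act + n_inh
        assert len(params.gene_params) == len(g.gene_nodes())
        inh = [v for v in params.edge_params.values() if "prob_inhibit1" in v]
        assert len(inh) == n_inh

    def test_deterministic(self):
        coll, stats, _ = self.make_inputs(3)
        g = coll.pathways[1]
        a = compute_parameters(g, stats, coll)
        b = compute_parameters(g, stats, coll)
        assert a.edge_params == b.edge_params and a.gene_params == b.gene_params

    def test_all_zero_probability_genes(self):
        coll, stats, _ = self.make_inputs(5)
        zero = make_stat_table(sorted(coll.gene_universe))  # P = 0, no DE
        params = compute_parameters(coll.pathways[0], zero, coll)
        for v in params.edge_params.values():
            if "prob_active" in v:
                assert v["prob_active"] == 0.0

    def test_pathway_outside_collection_rejected(self):
        coll, stats, _ = self.make_inputs(1)
        stranger = random_pathway(4, 3, 0.0, seed=99, pathway_id="alien")
        with pytest.raises(ValueError, match="not in the collection"):
            compute_parameters(stranger, stats, coll)

    @given(st.integers(0, 20))
    def test_all_probabilities_in_unit_interval(self, seed):
        coll, stats, _ = self.make_inputs(seed)
        for g in coll:
            params = compute_parameters(g, stats, coll)
            params.validate()  # raises on any violation
            for p1, p2, pi in params.gene_params.values():
                assert abs(p1 + p2 - 1) < 1e-12 and 0 <= pi <= 1
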