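import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from fopa import (
    PathwayCollection,
    adjust_fdr,
    build_gene_stats,
    flag_de,
    frequency_weight,
    gene_frequencies,
    gene_probability,
    moderated_t,
    random_pathway,
)
from fopa.stats import CASE, CONTROL, ExpressionDataset


def dataset(values: np.ndarray, n_ctrl: int, n_case: int) -> ExpressionDataset:
    cols = [f"s{i}" for i in range(n_ctrl + n_case)]
    return ExpressionDataset(
        pd.DataFrame(values, index=[f"g{i}" for i in range(len(values))], columns=cols),
        pd.Series([CONTROL] * n_ctrl + [CASE] * n_case, index=cols),
    )


# Fixture matrix: rng(42) normals rounded to 6 decimals, gene 0 shifted +2 in
# the case group.  Expected values computed with an independent reference
# implementation of the empirical-Bayes moderated-t equations.
FIXTURE_6X6 = np.array(
    [
        [0.304717, -1.039984, 0.750451, 2.940565, 0.048965, 0.697820],
        [0.127840, -0.316243, -0.016801, -0.853044, 0.879398, 0.777792],
        [0.066031, 1.127241, 0.467509, -0.859292, 0.368751, -0.958883],
        [0.878450, -0.049926, -0.184862, -0.680930, 1.222541, -0.154529],
        [-0.428328, -0.352134, 0.532309, 0.365444, 0.412733, 0.430821],
        [2.141648, -0.406415, -0.512243, -0.813773, 0.615979, 1.128972],
    ]
)
# reference moderated t and two-sided p for FIXTURE_6X6 (3 control, 3 case)
REF_T = np.array(
    [1.538661310173, 0.504052664662, -1.578201856867, -0.124515895006, 0.783464205642, -0.121442149093]
)
REF_P = np.array(
    [0.144081185278, 0.621324288996, 0.134738422317, 0.902509820037, 0.445180168304, 0.904903699814]
)


class TestModeratedT:
    def test_matches_reference_implementation(self):
        res = moderated_t(dataset(FIXTURE_6X6, 3, 3))
        np.testing.assert_allclose(res["T"].to_numpy(), REF_T, atol=1e-8)
        np.testing.assert_allclose(res["p"].to_numpy(), REF_P, atol=1e-8)

    def test_constant_gene_gives_zero_t(self):
        X = np.vstack([np.ones(8), np.random.default_rng(0).normal(size=(4, 8))])
        res = moderated_t(dataset(X, 4, 4))
        assert res["T"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_no_shrinkage_recovers_plain_t(self):
        from scipy import stats as sps

        X = np.random.default_rng(1).normal(size=(30, 10))
        res = moderated_t(dataset(X, 5, 5), d0_override=0)
        t_ref, _ = sps.ttest_ind(X[:, 5:], X[:, :5], axis=1, equal_var=True)
        np.testing.assert_allclose(res["T"].to_numpy(), t_ref, atol=1e-10)

    def test_small_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError):
            dataset(X, 1, 2)

    def test_null_type_one_error_calibrated(self):
        """Raw p < 0.05 fraction stays near nominal under the null."""
        rng = np.random.default_rng(7)
        fracs = []
        for _ in range(20):
            X = rng.normal(size=(1000, 20))
            res = moderated_t(dataset(X, 10, 10))
            fracs.append((res["p"] < 0.05).mean())
        assert abs(np.mean(fracs) - 0.05) < 0.02


class TestFdr:
    def test_step_up_hand_computed(self):
        np.testing.assert_allclose(adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        np.testing.assert_allclose(
            adjust_fdr([0.01, 0.04, 0.03, 0.005]), [0.02, 0.04, 0.04, 0.02]
        )

    def test_degenerate_vectors(self):
        np.testing.assert_allclose(adjust_fdr([0.2]), [0.2])
        np.testing.assert_allclose(adjust_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    def test_invariant_under_input_order(self, ps):
        a = np.sort(adjust_fdr(np.array(ps)))
        b = np.sort(adjust_fdr(np.array(ps[::-1])))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_flags(self):
        assert flag_de(np.array([0.04, 0.06]), 0.05).tolist() == [True, False]
        assert not flag_de(np.ones(5)).any()


def three_pathway_collection() -> PathwayCollection:
    g1 = random_pathway(4, 3, 0.0, seed=1, genes=["a", "b", "c", "d"], pathway_id="P1")
    g2 = random_pathway(4, 3, 0.0, seed=2, genes=["a", "b", "e", "f"], pathway_id="P2")
    g3 = random_pathway(4, 3, 0.0, seed=3, genes=["a", "g", "h", "i"], pathway_id="P3")
    return PathwayCollection([g1, g2, g3])


class TestFrequencies:
    def test_counts(self):
        f = gene_frequencies(three_pathway_collection())
        assert f["a"] == 3 and f["b"] == 2 and f["c"] == 1

    @given(st.integers(0, 9))
    def test_matches_bruteforce_counter(self, seed):
        rng = np.random.default_rng(seed)
        pool = [f"g{i}" for i in range(12)]
        paths = []
        for k in range(4):
            genes = [pool[i] for i in rng.choice(12, size=5, replace=False)]
            paths.append(random_pathway(5, 4, 0.2, seed=k, genes=genes, pathway_id=f"P{k}"))
        coll = PathwayCollection(paths)
        f = gene_frequencies(coll)
        for gene in coll.gene_universe:
            brute = sum(1 for p in coll if gene in p.gene_nodes())
            assert f[gene] == brute

    def test_weight_endpoints(self):
        f = pd.Series({"lo": 1, "mid": 3, "hi": 5})
        w = frequency_weight(f, mode="literal")
        assert w["lo"] == 0.0 and w["hi"] == 1.0
        assert w["mid"] == pytest.approx(np.sqrt(0.5))
        wi = frequency_weight(f, mode="inverted")
        assert wi["lo"] == 1.0 and wi["hi"] == 0.0

    def test_weight_degenerate_all_equal(self):
        w = frequency_weight(pd.Series({"a": 2, "b": 2}))
        assert (w == 1.0).all()


class TestGeneProbability:
    def test_zero_t_gives_zero(self):
        T = pd.Series({"a": 0.0, "b": 5.0})
        Fn = pd.Series({"a": 1.0, "b": 1.0})
        for mode in ("max_normalize", "clip"):
            assert gene_probability(T, Fn, mode)["a"] == 0.0

    def test_clip_mode(self):
        T = pd.Series({"a": -3.0})
        Fn = pd.Series({"a": 0.5})
        assert gene_probability(T, Fn, "clip")["a"] == 1.0

    def test_max_normalize(self):
        T = pd.Series({"a": 2.0, "b": 5.0})
        Fn = pd.Series({"a": 0.5, "b": 1.0})
        assert gene_probability(T, Fn)["a"] == pytest.approx(0.2)

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=10),
        st.lists(st.floats(0, 1), min_size=10, max_size=10),
    )
    def test_always_in_unit_interval(self, ts, fns):
        genes = [f"g{i}" for i in range(len(ts))]
        T = pd.Series(ts, index=genes)
        Fn = pd.Series(fns[: len(ts)], index=genes)
        for mode in ("max_normalize", "clip"):
            P = gene_probability(T, Fn, mode)
            assert ((P >= 0) & (P <= 1)).all()


class TestBuildGeneStats:
    def test_unmeasured_pathway_gene_defaults(self):
        coll = three_pathway_collection()
        X = np.random.default_rng(0).normal(size=(3, 8))
        cols = [f"s{i}" for i in range(8)]
        data = ExpressionDataset(
            pd.DataFrame(X, index=["a", "b", "zz"], columns=cols),
            pd.Series([CONTROL] * 4 + [CASE] * 4, index=cols),
        )
        stats = build_gene_stats(data, coll)
        assert stats.table.loc["c", "T"] == 0.0
        assert not stats.table.loc["c", "is_de"]
        assert stats.table.loc["c", "P"] == 0.0
        # every pathway gene is present
        assert set(coll.gene_universe) <= set(stats.table.index)

    def test_precomputed_table_bypasses_t(self):
        coll = three_pathway_collection()
        pre = pd.DataFrame({"T": [4.0, 0.5], "q": [0.01, 0.9]}, index=["a", "b"])
        stats = build_gene_stats(None, coll, precomputed=pre)
        assert stats.is_de("a") and not stats.is_de("b")
        assert stats.P("a") > stats.P("b")
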