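import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tmmkit.group_stats import (
    bh_adjust,
    cnv_burden,
    contingency_chisq,
    correlation_matrix,
    hypergeom_ora,
    mannwhitney,
    moderated_t_deg,
    mutation_frequency_compare,
    tmb,
)
from tmmkit.io_formats import (
    CNVSegmentTable,
    ExpressionMatrix,
    GeneSetCollection,
    MutationTable,
)

from .oracles import brute_force_bh, brute_force_moderated_t, exact_mannwhitney_p


def _em(x):
    g, n = np.asarray(x).shape
    return ExpressionMatrix(
        pd.DataFrame(
            x, index=[f"G{i}" for i in range(g)],
            columns=[f"S{i}" for i in range(n)],
        )
    )


class TestModeratedT:
    def test_identical_groups(self, rng):
        x = rng.normal(size=(20, 4))
        em = _em(np.concatenate([x, x], axis=1))
        a = [f"S{i}" for i in range(4)]
        b = [f"S{i}" for i in range(4, 8)]
        out = moderated_t_deg(em, a, b)
        assert np.allclose(out["log_fc"], 0)
        assert np.allclose(out["t_mod"], 0)
        assert np.allclose(out["p_value"], 1)

    def test_matches_independent_oracle(self, rng):
        xa = rng.normal(0, 1, size=(200, 6)) * rng.uniform(0.5, 2, (200, 1))
        xb = rng.normal(0, 1, size=(200, 8)) * rng.uniform(0.5, 2, (200, 1))
        em = _em(np.concatenate([xa, xb], axis=1))
        a = [f"S{i}" for i in range(6)]
        b = [f"S{i}" for i in range(6, 14)]
        out = moderated_t_deg(em, a, b)
        d0, s0, t, p = brute_force_moderated_t(xa, xb)
        assert out["d0"].iloc[0] == pytest.approx(d0, rel=1e-6)
        assert out["s0_sq"].iloc[0] == pytest.approx(s0, rel=1e-6)
        assert np.allclose(out["t_mod"], t, atol=1e-6)
        assert np.allclose(out["p_value"], p, atol=1e-6)

    def test_d0_zero_reduces_to_pooled_t(self, rng):
        xa = rng.normal(size=(50, 5))
        xb = rng.normal(size=(50, 7))
        em = _em(np.concatenate([xa, xb], axis=1))
        a = [f"S{i}" for i in range(5)]
        b = [f"S{i}" for i in range(5, 12)]
        out = moderated_t_deg(em, a, b, d0_override=0)
        t_ref, p_ref = stats.ttest_ind(xa, xb, axis=1, equal_var=True)
        assert np.allclose(out["t_mod"], t_ref, atol=1e-9)
        assert np.allclose(out["p_value"], p_ref, atol=1e-9)

    def test_d0_infinity_limit(self, rng):
        xa = rng.normal(size=(50, 5))
        xb = rng.normal(size=(50, 5))
        em = _em(np.concatenate([xa, xb], axis=1))
        a = [f"S{i}" for i in range(5)]
        b = [f"S{i}" for i in range(5, 10)]
        out = moderated_t_deg(em, a, b, d0_override=np.inf)
        s0 = out["s0_sq"].iloc[0]
        expected = out["log_fc"] / np.sqrt(s0 * (1 / 5 + 1 / 5))
        assert np.allclose(out["t_mod"], expected, atol=1e-9)

    def test_shrinkage_bounds(self, rng):
        xa = rng.normal(size=(100, 5))
        xb = rng.normal(size=(100, 5))
        em = _em(np.concatenate([xa, xb], axis=1))
        a = [f"S{i}" for i in range(5)]
        b = [f"S{i}" for i in range(5, 10)]
        out = moderated_t_deg(em, a, b)
        s2 = np.concatenate([xa, xb], axis=1)
        ssa = ((xa - xa.mean(1, keepdims=True)) ** 2).sum(1)
        ssb = ((xb - xb.mean(1, keepdims=True)) ** 2).sum(1)
        s2_g = (ssa + ssb) / 8
        s0 = out["s0_sq"].iloc[0]
        lo = np.minimum(s2_g, s0)
        hi = np.maximum(s2_g, s0)
        assert ((out["s2_post"] >= lo - 1e-12) & (out["s2_post"] <= hi + 1e-12)).all()

    def test_small_group_rejected(self, rng):
        em = _em(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError, match=">= 2 samples"):
            moderated_t_deg(em, ["S0"], ["S1", "S2"])

    def test_overlapping_groups_rejected(self, rng):
        em = _em(rng.normal(size=(5, 4)))
        with pytest.raises(ValueError, match="overlap"):
            moderated_t_deg(em, ["S0", "S1"], ["S1", "S2"])


class TestBHAdjust:
    def test_single_p(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_hand_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_brute_force_random(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 30))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_order_preserving(self, p):
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()
        assert ((q >= np.asarray(p) - 1e-12) & (q <= 1 + 1e-12)).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestHypergeomORA:
    def test_exact_1_over_252(self):
        universe = [f"g{i}" for i in range(10)]
        query = universe[:5]
        ann = GeneSetCollection({"SET": universe[:5]})
        out = hypergeom_ora(query, universe, ann)
        assert out["p_value"].iloc[0] == pytest.approx(1 / 252, rel=1e-9)
        assert out["overlap"].iloc[0] == 5

    def test_zero_overlap_p_is_one(self):
        universe = [f"g{i}" for i in range(10)]
        ann = GeneSetCollection({"SET": universe[5:]})
        out = hypergeom_ora(universe[:5], universe, ann)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_null_pvalues_roughly_uniform(self, rng):
        universe = [f"g{i}" for i in range(60)]
        ann = GeneSetCollection({"SET": universe[:15]})
        pvals = []
        for _ in range(300):
            q = [universe[i] for i in rng.choice(60, 10, replace=False)]
            pvals.append(hypergeom_ora(q, universe, ann)["p_value"].iloc[0])
        # discrete p-values are super-uniform: check the upper tail only
        assert np.mean(np.asarray(pvals) <= 0.05) <= 0.08

    def test_query_outside_universe_rejected(self):
        ann = GeneSetCollection({"SET": ["a"]})
        with pytest.raises(ValueError, match="outside"):
            hypergeom_ora(["zz"], ["a", "b"], ann)

    def test_empty_inputs_rejected(self):
        ann = GeneSetCollection({"SET": ["a"]})
        with pytest.raises(ValueError, match="empty query"):
            hypergeom_ora([], ["a"], ann)
        with pytest.raises(ValueError, match="empty universe"):
            hypergeom_ora(["a"], [], ann)


class TestMannWhitney:
    def test_complete_separation_enumeration(self):
        u, p = mannwhitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_multisets(self):
        _, p = mannwhitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exact_matches_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 6))
            b = rng.normal(size=rng.integers(2, 6))
            u, p = mannwhitney(a, b)
            u_ref, p_ref = exact_mannwhitney_p(a, b)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref)

    def test_normal_approx_matches_scipy(self, rng):
        a = rng.normal(size=40)
        b = rng.normal(0.5, 1, size=35)
        _, p = mannwhitney(a, b)
        p_ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                   use_continuity=True).pvalue
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_normal_approx_with_ties_matches_scipy(self, rng):
        a = rng.integers(0, 5, size=30).astype(float)
        b = rng.integers(0, 5, size=25).astype(float)
        _, p = mannwhitney(a, b)
        p_ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                   use_continuity=True).pvalue
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_exhaustive_small_case_accuracy(self, rng):
        # on <= 12-subject no-tie instances the normal approximation should
        # track the exact enumeration within 0.05
        worst = 0.0
        for _ in range(40):
            na = int(rng.integers(3, 7))
            nb = int(rng.integers(3, 7))
            a = rng.normal(size=na)
            b = rng.normal(size=nb)
            _, p_exact = exact_mannwhitney_p(a, b)
            n = na + nb
            u, _ = mannwhitney(a, b)
            center = na * nb / 2
            sigma = np.sqrt(na * nb * (n + 1) / 12)
            z = (abs(u - center) - 0.5) / sigma
            p_approx = min(1.0, 2 * stats.norm.sf(max(z, 0)))
            worst = max(worst, abs(p_approx - p_exact))
        assert worst < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mannwhitney([], [1.0])


class TestTMB:
    def _mut(self, rows):
        return MutationTable(
            pd.DataFrame(
                rows, columns=["sample_id", "gene_id", "variant_classification"]
            )
        )

    def test_filter_count(self):
        rows = [("S1", "KRAS", "Missense_Mutation")] * 3 + [
            ("S1", "TP53", "Silent")
        ] * 2
        counts = tmb(self._mut(rows))
        assert counts["S1"] == 3

    def test_absent_samples_zero(self):
        rows = [("S1", "KRAS", "Missense_Mutation")]
        counts = tmb(self._mut(rows), sample_ids=["S1", "S2"])
        assert counts["S2"] == 0

    def test_empty_table(self):
        counts = tmb(self._mut([]), sample_ids=["S1", "S2"])
        assert (counts == 0).all()

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            tmb(self._mut([]), nonsyn_classes=["NotAClass"])

    def test_record_order_invariance(self, rng):
        rows = [
            (f"S{rng.integers(3)}", "KRAS", "Missense_Mutation")
            for _ in range(20)
        ]
        shuffled = list(rows)
        rng.shuffle(shuffled)
        pd.testing.assert_series_equal(
            tmb(self._mut(rows), ["S0", "S1", "S2"]),
            tmb(self._mut(shuffled), ["S0", "S1", "S2"]),
        )


class TestCNVBurden:
    def _seg(self, rows):
        return CNVSegmentTable(
            pd.DataFrame(
                rows,
                columns=["sample_id", "chromosome", "start", "end", "seg_mean"],
            )
        )

    def test_two_segment_arithmetic(self):
        seg = self._seg(
            [("S1", "1", 0, 100, 0.5), ("S1", "1", 100, 200, 0.0)]
        )
        fga = cnv_burden(seg, seg_mean_threshold=0.2)
        assert fga["S1"] == pytest.approx(0.5)

    def test_all_neutral(self):
        seg = self._seg(
            [("S1", "1", 0, 100, 0.0), ("S1", "1", 100, 200, 0.0)]
        )
        assert cnv_burden(seg)["S1"] == 0.0

    def test_negative_seg_mean_counts(self):
        seg = self._seg([("S1", "1", 0, 100, -0.9), ("S1", "1", 100, 200, 0.0)])
        assert cnv_burden(seg)["S1"] == pytest.approx(0.5)


class TestMutationFrequencyCompare:
    def _labels(self, mapping):
        return pd.DataFrame(
            {"sample_id": list(mapping), "label": list(mapping.values())}
        )

    def test_fisher_hand_case(self):
        # gene mutated in 3/3 of ALT and 0/3 of NDTMM -> p = 0.1
        labels = self._labels(
            {f"A{i}": "ALT" for i in range(3)} | {f"N{i}": "NDTMM" for i in range(3)}
        )
        rows = [(f"A{i}", "KRAS", "Missense_Mutation") for i in range(3)]
        mut = MutationTable(
            pd.DataFrame(
                rows, columns=["sample_id", "gene_id", "variant_classification"]
            )
        )
        out = mutation_frequency_compare(mut, labels, "ALT", "NDTMM")
        row = out.set_index("gene_id").loc["KRAS"]
        assert row["freq_a"] == 1.0 and row["freq_b"] == 0.0
        assert row["p_value"] == pytest.approx(0.1)

    def test_empty_group_rejected(self):
        labels = self._labels({"A1": "ALT"})
        mut = MutationTable(
            pd.DataFrame(
                [("A1", "KRAS", "Silent")],
                columns=["sample_id", "gene_id", "variant_classification"],
            )
        )
        with pytest.raises(ValueError, match="empty group"):
            mutation_frequency_compare(mut, labels, "ALT", "NDTMM")


class TestContingency:
    def _labels(self, labels):
        return pd.DataFrame(
            {"sample_id": [f"S{i}" for i in range(len(labels))],
             "label": labels}
        )

    def test_perfect_association(self):
        labels = self._labels(["ALT"] * 10 + ["NDTMM"] * 10)
        cat = pd.Series(
            ["g3"] * 10 + ["g4"] * 10,
            index=[f"S{i}" for i in range(20)],
        )
        counts, props, chi2_stat, df, p, low = contingency_chisq(labels, cat)
        assert chi2_stat == pytest.approx(20.0)
        assert df == 1
        assert np.allclose(props.sum(axis=0), 1.0)

    def test_degenerate_margin_rejected(self):
        labels = self._labels(["ALT"] * 4)
        cat = pd.Series(["g1", "g1", "g2", "g2"],
                        index=[f"S{i}" for i in range(4)])
        with pytest.raises(ValueError, match=">= 2 levels"):
            contingency_chisq(labels, cat)

    def test_null_p_roughly_uniform(self, rng):
        pvals = []
        for _ in range(200):
            labels = self._labels(rng.choice(["ALT", "TEL"], 60))
            cat = pd.Series(rng.choice(["a", "b"], 60),
                            index=[f"S{i}" for i in range(60)])
            try:
                pvals.append(contingency_chisq(labels, cat)[4])
            except ValueError:
                continue
        assert 0.2 < np.mean(pvals) < 0.8


class TestCorrelationMatrix:
    def test_self_and_anti(self):
        x = np.array([[1.0, 2.0, 3.0, 4.0]])
        em = _em(np.concatenate([x, -x, x * 0 + 5], axis=0))
        res = correlation_matrix(em, ["G0"], ["G0", "G1", "G2"])
        assert res.r.loc["G0", "G0"] == pytest.approx(1.0)
        assert res.r.loc["G0", "G1"] == pytest.approx(-1.0)
        assert not res.defined.loc["G0", "G2"]
        assert np.isnan(res.r.loc["G0", "G2"])

    def test_matches_direct_formula(self, rng):
        x = rng.normal(size=(5, 12))
        em = _em(x)
        genes = [f"G{i}" for i in range(5)]
        res = correlation_matrix(em, genes, genes)
        ref = np.corrcoef(x)
        assert np.allclose(res.r.to_numpy(), ref, atol=1e-12)

    def test_missing_gene_rejected(self, rng):
        em = _em(rng.normal(size=(3, 5)))
        with pytest.raises(KeyError):
            correlation_matrix(em, ["G0"], ["NOPE"])

    def test_too_few_samples_rejected(self, rng):
        em = _em(rng.normal(size=(3, 2)))
        with pytest.raises(ValueError, match=">= 3 samples"):
            correlation_matrix(em, ["G0"], ["G1"])
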