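"""Normalization, filtering, permutation-FDR and classification against
brute-force / enumeration oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circqpcr import circcompare as cc
from circqpcr import simulate
from circqpcr.types import ValidationError


def _table(arr, samples=None):
    arr = np.asarray(arr)
    samples = samples or [f"s{i+1}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"f{i+1}" for i in range(arr.shape[0])],
                        columns=samples)


class TestNormalize:
    def test_equal_libraries_identity(self):
        t = _table([[10, 10], [30, 30]])
        norm, lib = cc.normalize_counts(t)
        pd.testing.assert_frame_equal(norm, t.astype(float))

    def test_double_library_halved(self):
        t = _table([[10, 20], [30, 60]])  # s2 has exactly double the depth
        norm, _ = cc.normalize_counts(t)
        np.testing.assert_allclose(norm["s2"], norm["s1"])

    def test_three_sample_hand_oracle(self):
        t = _table([[4, 10, 2], [6, 10, 8]])
        norm, lib = cc.normalize_counts(t)
        libs = np.array([10.0, 20.0, 10.0])
        med = 10.0
        expect = t.to_numpy() * (med / libs)
        np.testing.assert_allclose(norm.to_numpy(), expect)

    def test_zero_library_rejected(self):
        t = _table([[0, 5], [0, 5]])
        with pytest.raises(ValidationError, match="s1"):
            cc.normalize_counts(t)


class TestFilter:
    def test_all_zero_removed(self):
        t = _table([[0, 0, 0], [5, 5, 5]])
        kept, removed = cc.filter_min_bsj(t)
        assert list(removed.index) == ["f1"]

    def test_boundary_is_inclusive(self):
        t = pd.DataFrame(
            {"s1": [2.9, 3.0, 10.0], "s2": [2.9, 3.0, 10.0]},
            index=["low", "edge", "high"],
        )
        kept, removed = cc.filter_min_bsj(t, threshold=3.0)
        assert list(kept.index) == ["edge", "high"]
        assert list(removed.index) == ["low"]

    def test_partition_matches_brute_force(self):
        rng = np.random.default_rng(2)
        t = _table(rng.poisson(4.0, size=(20, 6)))
        kept, removed = cc.filter_min_bsj(t, threshold=3.0)
        for f in t.index:
            manual = t.loc[f].mean() >= 3.0
            assert (f in kept.index) == manual
            assert (f in removed.index) == (not manual)
        assert len(kept) + len(removed) == len(t)


GROUPS6 = pd.Series(["wt"] * 3 + ["hom"] * 3, index=[f"s{i+1}" for i in range(6)])


class TestLog2FC:
    def test_equal_means_zero(self):
        t = _table([[5, 5, 5, 5, 5, 5]])
        assert cc.log2fc(t, GROUPS6, "wt", "hom", pseudocount=0.0)["f1"] == 0.0

    def test_quadrupling_is_plus_two(self):
        t = _table([[2, 2, 2, 8, 8, 8]])
        assert cc.log2fc(t, GROUPS6, "wt", "hom", pseudocount=0.0)["f1"] == pytest.approx(2.0)

    def test_pseudocount_hand_arithmetic(self):
        t = _table([[0, 0, 0, 3, 5, 4]])
        got = cc.log2fc(t, GROUPS6, "wt", "hom", pseudocount=0.5)["f1"]
        assert got == pytest.approx(np.log2((4.0 + 0.5) / (0.0 + 0.5)))


class TestPermutationFdr:
    def test_constant_feature_has_p_one(self):
        t = _table([[7, 7, 7, 7, 7, 7], [1, 1, 1, 9, 9, 9]])
        res = cc.permutation_fdr(t, GROUPS6, "wt", "hom")
        assert res.loc["f1", "p_value"] == pytest.approx(1.0)

    def test_exhaustive_equals_independent_enumeration(self):
        """3v3: p-values must equal a from-scratch enumeration over all 20
        label splits: p = #{splits with |lfc_perm| >= |lfc_obs|} / 20 (the
        observed split counts itself, keeping p > 0)."""
        rng = np.random.default_rng(5)
        t = _table(rng.poisson(20.0, size=(6, 6)))
        res = cc.permutation_fdr(t, GROUPS6, "wt", "hom", pseudocount=0.5)
        mat = t.to_numpy(dtype=float)
        for fi, f in enumerate(t.index):
            def lfc(bidx):
                b = mat[fi, list(bidx)].mean()
                a = np.delete(mat[fi], list(bidx)).mean()
                return np.log2((b + 0.5) / (a + 0.5))
            obs = abs(lfc([3, 4, 5]))
            count = sum(abs(lfc(c)) >= obs - 1e-12 for c in combinations(range(6), 3))
            assert res.loc[f, "p_value"] == pytest.approx(count / 20)

    def test_monte_carlo_agrees_with_exhaustive_within_binomial_error(self):
        rng = np.random.default_rng(9)
        t = _table(rng.poisson(15.0, size=(5, 6)))
        ex = cc.permutation_fdr(t, GROUPS6, "wt", "hom", exhaustive=True)
        mc = cc.permutation_fdr(t, GROUPS6, "wt", "hom", exhaustive=False,
                                n_permutations=10_000, seed=4)
        for f in t.index:
            p = ex.loc[f, "p_value"]
            tol = 4 * np.sqrt(p * (1 - p) / 10_000) + 2e-3
            assert abs(mc.loc[f, "p_value"] - p) < tol

    def test_bh_adjustment_closed_form(self):
        """BH on p = {0.01, 0.02, 0.03} yields {0.03, 0.03, 0.03}."""
        from statsmodels.stats.multitest import multipletests

        _, fdr, _, _ = multipletests([0.01, 0.02, 0.03], method="fdr_bh")
        np.testing.assert_allclose(fdr, [0.03, 0.03, 0.03])

    def test_too_few_permutations_rejected(self):
        t = _table([[1, 2, 3, 4]])
        groups = pd.Series(["wt", "wt", "hom", "hom"], index=t.columns)
        with pytest.raises(ValidationError, match="6"):
            cc.permutation_fdr(t, groups, "wt", "hom")

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(scale=st.floats(0.5, 20.0))
    def test_pipeline_invariant_to_uniform_library_scaling(self, scale):
        rng = np.random.default_rng(12)
        t = _table(rng.poisson(30.0, size=(8, 6)))
        base_n, _ = cc.normalize_counts(t)
        scaled_n, _ = cc.normalize_counts(t * scale)
        k0, _ = cc.filter_min_bsj(base_n)
        lf0 = cc.log2fc(base_n, GROUPS6, "wt", "hom")
        lf1 = cc.log2fc(scaled_n / scale, GROUPS6, "wt", "hom")
        np.testing.assert_allclose(lf0, lf1)
        # normalized values scale linearly, so the filter partition at a
        # scaled threshold matches
        k1, _ = cc.filter_min_bsj(scaled_n, threshold=3.0 * scale)
        assert list(k0.index) == list(k1.index)


class TestClassification:
    def _circ(self, rows):
        df = pd.DataFrame(rows, columns=["host_gene", "log2fc", "fdr", "filtered"])
        df.index = [f"c{i+1}" for i in range(len(rows))]
        return df

    def _linear(self, rows):
        df = pd.DataFrame(rows, columns=["log2fc", "fdr"])
        df.index = [f"G{i+1}" for i in range(len(rows))]
        return df

    def test_amplified_and_inverse_single_cases(self):
        linear = self._linear([(0.5, 0.01), (1.5, 0.01)])
        circ = self._circ([("G1", 2.0, 0.01, False), ("G2", -2.0, 0.01, False)])
        out = cc.classify_circ_vs_host(circ, linear)
        assert out.loc["c1", "category"] == "circ_amplified"
        assert out.loc["c2", "category"] == "inverse"

    def test_eight_feature_decision_table(self):
        """Categories must match a hand-walked decision table covering every
        branch (filtered, not significant, circ_only, inverse, amplified,
        concordant)."""
        linear = self._linear(
            [
                (0.2, 0.8),    # G1: host null
                (1.5, 0.01),   # G2: host up, significant
                (-1.2, 0.01),  # G3: host down, significant
                (2.5, 0.01),   # G4: host strongly up
                (0.9, 0.01),   # G5: reliably detected sub-twofold host shift
            ]
        )
        circ = self._circ(
            [
                ("G1", 2.0, 0.01, False),    # host null -> circ_only
                ("G2", -2.0, 0.01, False),   # opposite signs -> inverse
                ("G2", 3.0, 0.01, False),    # same sign, larger -> circ_amplified
                ("G4", 1.5, 0.01, False),    # same sign, smaller -> concordant
                ("G3", -3.0, 0.01, False),   # same sign (down), larger -> circ_amplified
                ("G1", 0.5, 0.01, False),    # small effect -> not significant
                ("G2", 2.0, 0.50, False),    # high fdr -> not significant
                ("G5", 2.0, 0.01, True),     # below BSJ filter -> filtered
            ]
        )
        out = cc.classify_circ_vs_host(circ, linear)
        expect = ["circ_only", "inverse", "circ_amplified", "concordant",
                  "circ_amplified", "not_significant", "not_significant", "filtered"]
        assert list(out["category"]) == expect
        # every feature gets exactly one category
        assert out["category"].isin(cc.CATEGORIES).all()

    def test_host_significance_judged_on_fdr_not_magnitude(self):
        """A reliably detected sub-twofold host shift is a host response
        (concordant/amplified), not circ_only; an unreliable one is."""
        linear = self._linear([(0.9, 0.01), (0.9, 0.60)])
        circ = self._circ([("G1", 2.0, 0.01, False), ("G2", 2.0, 0.01, False)])
        out = cc.classify_circ_vs_host(circ, linear)
        assert out.loc["c1", "category"] == "circ_amplified"
        assert out.loc["c2", "category"] == "circ_only"

    def test_missing_host_rejected(self):
        circ = self._circ([("Ghost", 2.0, 0.01, False)])
        with pytest.raises(ValidationError, match="Ghost"):
            cc.classify_circ_vs_host(circ, self._linear([(0.0, 1.0)]))


class TestPipeline:
    def test_end_to_end_recovers_strong_effects(self):
        params = simulate.default_count_params(n_wt=5, n_hom=5, n_circ=20)
        bsj, genes, truth = simulate.simulate_count_tables(params, seed=8)
        res = cc.circ_linear_pipeline(bsj, genes, n_permutations=500, seed=1)
        out = res["results"]
        truth_c = truth[truth["kind"] == "circ"].set_index("feature")
        strong = truth_c[(truth_c["true_log2fc"].abs() >= 2.0)].index
        called = out[out["category"].isin(["circ_only", "inverse", "circ_amplified",
                                           "concordant"])].index
        # abundant, strongly shifted circRNAs should mostly be called
        abundant = out.loc[out.index.isin(strong) & (out["mean_norm_bsj"] > 20)]
        if len(abundant):
            assert (abundant["category"] != "not_significant").mean() > 0.5
        nulls = truth_c[truth_c["true_log2fc"] == 0.0].index
        fp = out.loc[out.index.isin(nulls) & out.index.isin(called)]
        assert len(fp) <= max(2, 0.2 * len(nulls))

    def test_summary_counts_match_thresholds(self):
        params = simulate.default_count_params(n_wt=4, n_hom=4, n_circ=12)
        bsj, genes, _ = simulate.simulate_count_tables(params, seed=3)
        res = cc.circ_linear_pipeline(bsj, genes, n_permutations=200, seed=0)
        kept = res["results"][~res["results"]["filtered"]]
        assert res["summary"]["n_up_twofold"] == int((kept["log2fc"] > 1).sum())
        assert res["summary"]["n_down_twofold"] == int((kept["log2fc"] < -1).sum())
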