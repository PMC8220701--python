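"""Normalization, probe collapsing, moderated statistics and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from suppnet import PipelineConfig
from suppnet.data import ExpressionMatrix
from suppnet.de import (
    apply_thresholds,
    bh_adjust,
    collapse_probes,
    de_flag_matrix,
    de_table,
    moderated_de,
    pca_qc,
    quantile_normalize,
)
from suppnet.simulate import generate_expression


def _matrix(values: np.ndarray, lines, n_rep=3, genes=None) -> ExpressionMatrix:
    cols = [f"{line}_r{r}" for line in lines for r in range(1, n_rep + 1)]
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = pd.DataFrame(
        {"line": [c.rsplit("_r", 1)[0] for c in cols],
         "replicate": [int(c[-1]) for c in cols]},
        index=pd.Index(cols, name="sample"))
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols),
                            samples)


class TestQuantileNormalize:
    def test_two_sample_hand_oracle(self):
        df = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]})
        out = quantile_normalize(df)
        expected = [2.5, 3.5, 4.5]
        assert np.allclose(out["s1"], expected)
        assert np.allclose(out["s2"], expected)

    def test_identical_samples_fixed_point(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        assert np.allclose(quantile_normalize(df), df)

    def test_sorted_columns_identical_afterward(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(50, 4)))
        out = quantile_normalize(df).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 4):
            assert np.allclose(np.sort(out[:, j]), ref)

    def test_ties_get_mean_of_spanned_quantiles(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(df)
        means = np.sort(df.to_numpy(), axis=0).mean(axis=1)
        assert np.allclose(out["a"][:2], (means[0] + means[1]) / 2)

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            quantile_normalize(pd.DataFrame({"a": [1.0, np.nan], "b": [1, 2]}))


class TestCollapseProbes:
    def test_average_and_nonunique_removed(self):
        m = _matrix(np.array([[2.0] * 6, [4.0] * 6, [9.0] * 6]),
                    ["WS2", "mut"], genes=["p1", "p2", "p3"])
        out = collapse_probes(m, {"p1": ["gA"], "p2": ["gA"],
                                  "p3": ["gA", "gB"]})
        assert list(out.values.index) == ["gA"]
        assert np.allclose(out.values.loc["gA"], 3.0)

    def test_single_probe_identity(self):
        m = _matrix(np.arange(12, dtype=float).reshape(2, 6), ["WS2", "mut"],
                    genes=["p1", "p2"])
        out = collapse_probes(m, {"p1": "g1", "p2": "g2"})
        assert np.allclose(out.values.loc["g1"], m.values.loc["p1"])
        assert np.allclose(out.values.loc["g2"], m.values.loc["p2"])


class TestModeratedDE:
    def _noise_matrix(self, rng, n_genes=60):
        vals = rng.normal(8, 0.3, size=(n_genes, 6))
        return _matrix(vals, ["WS2", "mut"])

    def test_identical_group_means_give_null_result(self):
        vals = np.array([[5.0, 6.0, 7.0, 5.0, 6.0, 7.0],
                         [1.0, 2.0, 3.0, 3.0, 2.0, 1.0],
                         [4.0, 5.0, 9.0, 2.0, 2.0, 2.0]])
        res = moderated_de(_matrix(vals, ["WS2", "mut"]), "mut", "WS2")
        assert res.loc["g0", "logFC"] == pytest.approx(0.0)
        assert res.loc["g0", "t"] == pytest.approx(0.0)
        assert res.loc["g0", "p"] == pytest.approx(1.0)

    def test_zero_prior_df_equals_ordinary_pooled_t(self):
        rng = np.random.default_rng(1)
        m = self._noise_matrix(rng)
        res = moderated_de(m, "mut", "WS2", prior_df=0)
        a = m.line_values("mut").to_numpy()
        b = m.line_values("WS2").to_numpy()
        ref = stats.ttest_ind(a, b, axis=1, equal_var=True)
        assert np.allclose(res["t"], ref.statistic, atol=1e-10)
        assert np.allclose(res["p"], ref.pvalue, atol=1e-10)

    def test_invariant_to_per_gene_constant_shift(self):
        rng = np.random.default_rng(2)
        m = self._noise_matrix(rng)
        shifted = ExpressionMatrix(
            m.values + rng.normal(size=(len(m.values), 1)), m.samples.copy())
        res1 = moderated_de(m, "mut", "WS2")
        res2 = moderated_de(shifted, "mut", "WS2")
        assert np.allclose(res1["t"], res2["t"], atol=1e-8)

    def test_null_pvalues_uniform(self):
        """5,000 pure-noise genes give a uniform raw-p distribution."""
        matrix, _ = generate_expression(n_genes=5000, labels_spec={},
                                        rng_seed=0)
        res = moderated_de(matrix, "bri1-5", "WS2")
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_single_replicate_rejected(self):
        vals = np.arange(8, dtype=float).reshape(2, 4)
        m = _matrix(vals, ["WS2", "mut"], n_rep=2)
        m2 = ExpressionMatrix(m.values.iloc[:, :3],
                              m.samples.iloc[:3].copy())
        with pytest.raises(ValueError, match="replicates"):
            moderated_de(m2, "mut", "WS2")


class TestBHAdjust:
    def test_textbook_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_and_equal_values_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @staticmethod
    def _brute_force(p):
        """Step-up definition: adj p(i) = min over j >= i of p(j)*m/j."""
        p = np.asarray(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        out = np.empty(m)
        for rank, idx in enumerate(order, start=1):
            out[idx] = min(
                p[order[j - 1]] * m / j for j in range(rank, m + 1)
            )
        return np.minimum(out, 1.0)

    def test_matches_brute_force_on_permutations(self):
        rng = np.random.default_rng(4)
        base = rng.random(6)
        from itertools import permutations
        for perm in permutations(range(6)):
            p = base[list(perm)]
            assert np.allclose(bh_adjust(p), self._brute_force(p))

    def test_properties_hold_for_arbitrary_inputs(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(derandomize=True, max_examples=60, deadline=None)
        @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                        max_size=40))
        def check(p):
            adj = bh_adjust(p)
            assert ((adj >= np.asarray(p) - 1e-12) & (adj <= 1.0)).all()
            order = np.argsort(p, kind="stable")
            assert (np.diff(adj[order]) >= -1e-12).all()  # monotone in rank

        check()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(5)
        p = rng.random(200)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), ref)


class TestThresholdsAndQC:
    @pytest.mark.parametrize("logfc,adj_p,expected", [
        (0.60, 0.01, True),    # 0.60 > log2(1.5) ~ 0.585
        (2.0, 0.06, False),    # fails FDR
        (-0.7, 0.001, True),   # two-sided
        (0.5, 0.01, False),    # below fold-change bound
    ])
    def test_flag_rule(self, logfc, adj_p, expected):
        de = pd.DataFrame({"logFC": [logfc], "adj_p": [adj_p]})
        assert bool(apply_thresholds(de, 1.5, 0.05).iloc[0]) is expected

    def test_de_flag_invariant_holds_on_full_table(self, small_de,
                                                   small_config):
        bound = small_config.log_fc_threshold
        expected = ((small_de["adj_p"] <= small_config.fdr_threshold)
                    & (small_de["logFC"].abs() >= bound))
        assert (small_de["de_flag"] == expected).all()
        assert (small_de["adj_p"] >= small_de["p"] - 1e-12).all()

    def test_pca_separates_lines_with_tiny_noise(self):
        rng = np.random.default_rng(6)
        base = rng.normal(8, 2, size=(40, 1))
        offsets = {"WS2": 0.0, "mut": 3.0}
        cols = []
        for line, off in offsets.items():
            for _ in range(3):
                cols.append(base[:, 0] + off * rng.normal(1, 0.01, 40)
                            + rng.normal(0, 0.01, 40))
        m = _matrix(np.column_stack(cols), ["WS2", "mut"])
        scores = pca_qc(m)
        assert scores.attrs["within_line"] < scores.attrs["between_line"]

    def test_pca_identical_samples_and_orthogonality(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(30, 6))
        vals[:, 1] = vals[:, 0]
        m = _matrix(vals, ["WS2", "mut"])
        scores = pca_qc(m)
        s0 = scores.iloc[0][["PC1", "PC2"]].to_numpy(dtype=float)
        s1 = scores.iloc[1][["PC1", "PC2"]].to_numpy(dtype=float)
        assert np.allclose(s0, s1, atol=1e-8)
        pcs = scores[["PC1", "PC2"]].to_numpy(dtype=float)
        assert abs(float(pcs[:, 0] @ pcs[:, 1])) < 1e-8


class TestFullDEStage:
    def test_sensitivity_and_fdr_on_planted_truth(self):
        """Planted effects are recovered with sensitivity >= 0.9, FDR <= 0.1."""
        matrix, truth = generate_expression(n_genes=5000, rng_seed=9)
        config = PipelineConfig()
        de = de_table(matrix, config)
        flags = de_flag_matrix(de)
        tp = fp = fn = 0
        for line in config.non_reference_lines:
            called = set(flags.index[flags[line]])
            true = {g for (g, l) in truth.effect_of if l == line}
            tp += len(called & true)
            fp += len(called - true)
            fn += len(true - called)
        assert tp / (tp + fn) >= 0.9
        assert fp / max(tp + fp, 1) <= 0.1
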