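import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import immunotype as it
from immunotype.scoring import PURITY_INTERCEPT, PURITY_SLOPE

from conftest import ssgsea_oracle


def _expr(values: np.ndarray, genes=None) -> it.ExpressionMatrix:
    n, s = values.shape
    genes = genes or [f"g{i}" for i in range(n)]
    return it.ExpressionMatrix(values=pd.DataFrame(
        values, index=pd.Index(genes, name="gene_id"),
        columns=[f"smp{j}" for j in range(s)]))


class TestSsgsea:
    def test_worked_running_sum_example(self, small_expr, toy_sets):
        es = it.ssgsea_score(small_expr, toy_sets, alpha=0.25, normalize=False)
        # hand oracle: weights 4**0.25, 3**0.25; step diffs 0.5180, 1, 0.5, 0
        assert es.scores.loc["top2", "A"] == pytest.approx(2.0180, abs=5e-5)

    def test_identical_samples_identical_scores(self, small_expr, toy_sets):
        es = it.ssgsea_score(small_expr, toy_sets, normalize=False)
        assert (es.scores["A"] == es.scores["B"]).all()

    def test_alpha_zero_is_unweighted_kolmogorov_sum(self):
        rng = np.random.default_rng(0)
        vals = np.sort(rng.normal(size=8))[::-1].reshape(-1, 1)
        vals = np.hstack([vals, vals])
        expr = _expr(vals)
        top_half = {"g0", "g1", "g2", "g3"}
        es = it.ssgsea_score(expr, it.GeneSetCollection(sets={"s": sorted(top_half)}),
                             alpha=0.0, normalize=False)
        # brute-force unweighted running sum
        cum_in = cum_out = total = 0.0
        for i in range(8):
            if f"g{i}" in top_half:
                cum_in += 1 / 4
            else:
                cum_out += 1 / 4
            total += cum_in - cum_out
        assert es.scores.loc["s", "smp0"] == pytest.approx(total, abs=1e-12)

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(3, 11))
            vals = np.round(rng.normal(size=(n, 2)), 2)  # rounding induces ties
            k = int(rng.integers(1, n))
            members = sorted(rng.choice(n, size=k, replace=False))
            genes = [f"g{i}" for i in range(n)]
            expr = _expr(vals, genes)
            sets = it.GeneSetCollection(sets={"s": [genes[i] for i in members]})
            alpha = float(rng.choice([0.0, 0.25, 1.0]))
            es = it.ssgsea_score(expr, sets, alpha=alpha, normalize=False)
            for j, smp in enumerate(expr.sample_ids):
                expected = ssgsea_oracle(vals[:, j], genes,
                                         {genes[i] for i in members}, alpha)
                assert es.scores.loc["s", smp] == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-50, 50), min_size=5, max_size=10, unique=True),
           st.integers(1, 3))
    def test_invariant_to_monotone_transform(self, values, set_size):
        vals = np.array(values, dtype=float)[:, None]
        expr_a = _expr(np.hstack([vals, vals]))
        expr_b = _expr(np.hstack([np.exp(vals / 25), np.exp(vals / 25)]))
        sets = it.GeneSetCollection(sets={"s": [f"g{i}" for i in range(set_size)]})
        es_a = it.ssgsea_score(expr_a, sets, normalize=False)
        es_b = it.ssgsea_score(expr_b, sets, normalize=False)
        np.testing.assert_allclose(es_a.scores, es_b.scores, atol=1e-9)

    def test_range_normalized_in_unit_interval(self, small_cohort):
        es = it.ssgsea_score(small_cohort.expression, small_cohort.gene_sets,
                             normalize=True)
        vals = es.scores.to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0
        assert es.normalization == "range"

    def test_no_overlap_set_flagged_missing(self, small_expr):
        sets = it.GeneSetCollection(sets={"gone": ["zz"], "ok": ["g1"]})
        with pytest.warns(UserWarning, match="no overlapping"):
            es = it.ssgsea_score(small_expr, sets, normalize=False)
        assert es.missing_sets == ["gone"]
        assert es.scores.loc["gone"].isna().all()
        assert es.scores.loc["ok"].notna().all()

    def test_full_coverage_set_rejected(self, small_expr):
        sets = it.GeneSetCollection(sets={"all": ["g1", "g2", "g3", "g4"]})
        with pytest.raises(ValueError, match="every gene"):
            it.ssgsea_score(small_expr, sets)

    def test_negative_alpha_rejected(self, small_expr, toy_sets):
        with pytest.raises(ValueError, match="alpha"):
            it.ssgsea_score(small_expr, toy_sets, alpha=-1)


class TestEstimate:
    def test_purity_closed_form_at_zero(self):
        assert np.cos(PURITY_INTERCEPT) == pytest.approx(0.8225, abs=2e-4)

    def test_additivity_and_purity_formula(self, small_cohort):
        sets = small_cohort.gene_sets
        scores = it.estimate_scores(small_cohort.expression,
                                    immune_sig=sets["estimate_immune"],
                                    stromal_sig=sets["estimate_stromal"])
        t = scores.table
        np.testing.assert_allclose(t["estimate_score"],
                                   t["immune_score"] + t["stromal_score"])
        np.testing.assert_allclose(
            t["purity_raw"], np.cos(PURITY_INTERCEPT + PURITY_SLOPE * t["estimate_score"]))
        assert t["purity"].between(0, 1).all()

    def test_immune_score_monotone_in_signature_expression(self):
        genes = [f"g{i}" for i in range(20)]
        rng = np.random.default_rng(3)
        base = rng.normal(size=20)
        vals = np.column_stack([base.copy(), base.copy()])
        vals[:5, 0] += 2.0  # sample 0 higher on every immune-signature gene
        scores = it.estimate_scores(_expr(vals, genes),
                                    immune_sig=genes[:5], stromal_sig=genes[5:8])
        assert scores.immune_score["smp0"] > scores.immune_score["smp1"]

    def test_purity_decreases_with_estimate_score(self, small_cohort):
        sets = small_cohort.gene_sets
        scores = it.estimate_scores(small_cohort.expression,
                                    immune_sig=sets["estimate_immune"],
                                    stromal_sig=sets["estimate_stromal"])
        ordered = scores.table.sort_values("estimate_score")
        assert ordered["purity_raw"].is_monotonic_decreasing

    def test_packaged_signatures_load(self):
        sig, scale = it.scoring.load_estimate_signatures()
        assert set(sig.names()) == {"immune_signature", "stromal_signature"}
        assert scale > 0

    def test_empty_overlap_errors(self, small_expr):
        with pytest.raises(ValueError, match="no genes"):
            it.estimate_scores(small_expr, immune_sig=["nope"], stromal_sig=["g1"])


class TestSignatureRatio:
    def test_log2_of_quotient_of_means(self):
        vals = np.log2(np.array([[8.0, 8.0], [2.0, 2.0]]))
        ratio = it.signature_ratio(_expr(vals, ["a", "b"]), ["a"], ["b"])
        assert ratio["smp0"] == pytest.approx(2.0)

    def test_identity_and_antisymmetry(self, small_cohort):
        expr = small_cohort.expression
        cd8 = small_cohort.gene_sets["sig_cd8"]
        treg = small_cohort.gene_sets["sig_treg"]
        np.testing.assert_allclose(it.signature_ratio(expr, cd8, cd8), 0.0, atol=1e-12)
        fwd = it.signature_ratio(expr, cd8, treg)
        rev = it.signature_ratio(expr, treg, cd8)
        np.testing.assert_allclose(fwd, -rev, atol=1e-12)

    def test_non_positive_mean_instructs_linear_path(self):
        vals = np.array([[-1.0, -1.0], [1.0, 1.0]])
        expr = _expr(vals, ["a", "b"])
        expr.is_log2 = False  # linear-scale declaration with negative values
        with pytest.raises(ValueError, match="linear-scale"):
            it.signature_ratio(expr, ["a"], ["b"])
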