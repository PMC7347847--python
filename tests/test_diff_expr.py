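
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gep_panel import (
    ExpressionStudy,
    SimulationSpec,
    bh_adjust,
    comparison_summary,
    pairwise_test,
    run_comparisons,
    select_panel,
    simulate_study,
    table2_profile,
)


def _two_group_study(xa, xb):
    xa, xb = np.atleast_2d(xa), np.atleast_2d(xb)
    matrix = np.hstack([xa, xb])
    j = matrix.shape[0]
    return ExpressionStudy(
        matrix=matrix,
        probe_ids=[f"P{i}" for i in range(j)],
        gene_symbols=[f"G{i}" for i in range(j)],
        sample_ids=[f"S{i}" for i in range(matrix.shape[1])],
        group=["A"] * xa.shape[1] + ["B"] * xb.shape[1],
        batch=["X"] * matrix.shape[1],
    )


class TestPairwiseTest:
    def test_identical_group_means_give_null_statistic(self):
        block = np.array([[1.0, 2.0, 3.0]])
        study = _two_group_study(block, block)
        rec = pairwise_test(study, "A", "B", moderated=False)
        assert rec.loc[0, "t_stat"] == 0.0
        assert rec.loc[0, "p_raw"] == 1.0

    def test_moderated_with_zero_prior_df_equals_ordinary_t(self):
        rng = np.random.default_rng(0)
        study = _two_group_study(rng.normal(size=(50, 8)), rng.normal(size=(50, 9)))
        plain = pairwise_test(study, "A", "B", moderated=False)
        mod0 = pairwise_test(study, "A", "B", moderated=True, d0_override=0.0)
        assert np.allclose(plain["t_stat"], mod0["t_stat"], atol=1e-12)
        assert np.allclose(plain["p_raw"], mod0["p_raw"], atol=1e-12)

    def test_ordinary_t_matches_scipy(self):
        rng = np.random.default_rng(5)
        study = _two_group_study(rng.normal(size=(30, 6)), rng.normal(1, 1, (30, 11)))
        rec = pairwise_test(study, "A", "B", moderated=False)
        ref = stats.ttest_ind(study.matrix[:, :6], study.matrix[:, 6:], axis=1)
        assert np.allclose(rec["t_stat"], ref.statistic, atol=1e-10)
        assert np.allclose(rec["p_raw"], ref.pvalue, atol=1e-10)

    def test_record_invariants_hold_on_simulated_data(self, default_sim):
        study, _ = default_sim
        rec = pairwise_test(study, "DA", "GBM")
        assert np.allclose(rec["fc"], 2 ** (rec["mean_a"] - rec["mean_b"]).abs())
        assert (rec["p_adj"] >= rec["p_raw"] - 1e-15).all()
        up_a = rec["direction"] == "up in DA"
        assert ((rec["mean_a"] >= rec["mean_b"]) == up_a).all()
        assert (rec["fc"] >= 1).all()

    def test_zero_variance_probe_gets_decisive_p(self):
        xa = np.array([[5.0, 5.0, 5.0], [4.0, 4.0, 4.0]])
        xb = np.array([[7.0, 7.0, 7.0], [4.0, 4.0, 4.0]])
        rec = pairwise_test(_two_group_study(xa, xb), "A", "B", moderated=False)
        assert rec.loc[0, "p_raw"] == 0.0
        assert rec.loc[1, "p_raw"] == 1.0

    def test_small_group_rejected(self):
        study = _two_group_study(np.ones((3, 1)), np.ones((3, 4)))
        with pytest.raises(ValueError, match=">= 2 samples"):
            pairwise_test(study, "A", "B")

    def test_moderated_type_one_error_is_calibrated(self):
        # null genes with heteroscedastic true variances from the conjugate
        # prior; rejection rate at alpha=0.05 must sit inside the binomial
        # 99.9% band around 0.05
        rng = np.random.default_rng(77)
        j = 10_000
        sig2 = 0.25 * 4.0 / rng.chisquare(4.0, j)
        x = rng.standard_normal((j, 20)) * np.sqrt(sig2)[:, None]
        study = _two_group_study(x[:, :10], x[:, 10:])
        rec = pairwise_test(study, "A", "B", moderated=True)
        rate = (rec["p_raw"] < 0.05).mean()
        assert abs(rate - 0.05) < 3.29 * np.sqrt(0.05 * 0.95 / j)


def _bh_oracle(p):
    """Adjusted p_i = smallest level q at which BH rejects hypothesis i."""
    m = len(p)
    out = []
    candidates = sorted({p[j] * m / k for j in range(m) for k in range(1, m + 1)} | {1.0})
    eps = 1e-12  # guards against ulp loss in the q = p*m/k round trip
    for i in range(m):
        best = 1.0
        for q in candidates:
            ps = np.sort(p)
            thresh = [k for k in range(1, m + 1) if ps[k - 1] <= q * k / m + eps]
            n_rej = max(thresh) if thresh else 0
            if n_rej and p[i] <= ps[n_rej - 1]:
                best = min(best, q)
        out.append(min(best, 1.0))
    return np.array(out)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_edge_cases(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_matches_rejection_set_oracle(self, p):
        assert np.allclose(bh_adjust(p), _bh_oracle(p), atol=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_statsmodels(self, p):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        ref = sm.multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), ref, atol=1e-12)


class TestSelectPanel:
    def test_fold_change_threshold_is_inclusive_at_four(self):
        # a probe at FC 9.14 passes, one at 3.99 fails
        xa = np.tile([[10.0], [6.0]], (1, 5)) + 0.0
        xb = np.vstack([xa[0] - np.log2(9.14), xa[1] - np.log2(3.99)])
        study = _two_group_study(xa, xb)
        rec = pairwise_test(study, "A", "B", moderated=False)
        rec.loc[:, "p_adj"] = 1e-6
        panel = select_panel(rec, alpha=0.05, fc_min=4.0)
        assert panel.genes == ["G0"]

    def test_probes_of_one_gene_collapse(self):
        xa = np.tile([[9.0], [9.2]], (1, 6))
        xb = xa - 3.0
        study = _two_group_study(xa, xb)
        study.gene_symbols[0] = study.gene_symbols[1] = "SHARED"
        rec = pairwise_test(study, "A", "B", moderated=False)
        rec.loc[:, "p_adj"] = 1e-9
        panel = select_panel(rec, alpha=0.05, fc_min=4.0)
        assert panel.genes == ["SHARED"]
        assert sorted(panel.probes["SHARED"]) == ["P0", "P1"]
        assert panel.direction["SHARED"] == "up in A"

    def test_selection_is_monotone_in_thresholds(self, default_sim):
        study, _ = default_sim
        rec = run_comparisons(study, [("DA", "GBM"), ("AA", "GBM")])
        loose = set(select_panel(rec, alpha=0.05, fc_min=2.0).genes)
        tight_fc = set(select_panel(rec, alpha=0.05, fc_min=4.0).genes)
        tight_alpha = set(select_panel(rec, alpha=0.001, fc_min=2.0).genes)
        assert tight_fc <= loose
        assert tight_alpha <= loose

    def test_noiseless_panel_is_exactly_the_wide_gap_genes(self):
        study, _ = simulate_study(SimulationSpec(seed=9, noise_sd=0.0))
        rec = pairwise_test(study, "DA", "GBM")
        panel = select_panel(rec, alpha=0.05, fc_min=4.0)
        prof = table2_profile()
        expected = set(prof.index[(prof["DA"] - prof["GBM"]).abs() >= 2.0])
        assert set(panel.genes) == expected

    def test_empty_records_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            select_panel(pd.DataFrame())


class TestComparisonSummary:
    def test_no_significant_records_gives_zero_counts(self):
        rng = np.random.default_rng(2)
        study = _two_group_study(rng.normal(size=(20, 5)), rng.normal(size=(20, 5)))
        rec = pairwise_test(study, "A", "B")
        rec.loc[:, "p_adj"] = 1.0
        summary = comparison_summary(rec)["per_comparison"]
        assert summary["n_significant"].tolist() == [0]

    def test_counts_invariant_to_record_order(self, default_sim):
        study, _ = default_sim
        rec = run_comparisons(study, [("DA", "GBM"), ("AA", "GBM")])
        a = comparison_summary(rec)
        shuffled = rec.sample(frac=1.0, random_state=0).reset_index(drop=True)
        b = comparison_summary(shuffled)
        for comp in a["per_comparison"]["comparison"]:
            ra = a["per_comparison"].set_index("comparison").loc[comp]
            rb = b["per_comparison"].set_index("comparison").loc[comp]
            assert ra.equals(rb)
        assert a["intersections"] == b["intersections"]

    def test_planted_up_genes_are_counted_in_the_right_direction(self):
        # 50 genes up in group A by 2 log2 units over 450 null genes
        rng = np.random.default_rng(8)
        xa = rng.normal(7, 0.3, size=(500, 15))
        xb = rng.normal(7, 0.3, size=(500, 15))
        xa[:50] += 2.0
        rec = pairwise_test(_two_group_study(xa, xb), "A", "B")
        summary = comparison_summary(rec, alpha=0.05)["per_comparison"].iloc[0]
        assert summary["up_in_first"] >= 48
        assert summary["up_in_second"] <= 460 * 0.05 * 3
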