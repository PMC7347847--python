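import logging

import numpy as np
import pytest

from gep_panel import (
    BatchParams,
    ExpressionStudy,
    SimulationSpec,
    combat_adjust,
    pca_scores,
    simulate_study,
    table2_profile,
)


def _batch_study(n_genes=30, n_per_batch=40, shift=2.0, noise=0.0, seed=0):
    """Two batches differing by a constant location shift."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(5, 10, size=(n_genes, 1))
    n = 2 * n_per_batch
    matrix = np.tile(base, (1, n)) + rng.normal(0, noise, size=(n_genes, n))
    matrix[:, n_per_batch:] += shift
    return ExpressionStudy(
        matrix=matrix,
        probe_ids=[f"P{i}" for i in range(n_genes)],
        gene_symbols=[f"G{i}" for i in range(n_genes)],
        sample_ids=[f"S{i}" for i in range(n)],
        group=["A"] * n,
        batch=["B1"] * n_per_batch + ["B2"] * n_per_batch,
    )


class TestCombatAdjust:
    def test_single_batch_rejected(self, toy_study):
        solo = ExpressionStudy(
            matrix=toy_study.matrix,
            probe_ids=toy_study.probe_ids,
            gene_symbols=toy_study.gene_symbols,
            sample_ids=toy_study.sample_ids,
            group=toy_study.group,
            batch=["X"] * toy_study.n_samples,
        )
        with pytest.raises(ValueError, match="two batches"):
            combat_adjust(solo)

    def test_singleton_batch_rejected(self, toy_study):
        bad = ExpressionStudy(
            matrix=toy_study.matrix,
            probe_ids=toy_study.probe_ids,
            gene_symbols=toy_study.gene_symbols,
            sample_ids=toy_study.sample_ids,
            group=toy_study.group,
            batch=["X"] * 7 + ["Y"],
        )
        with pytest.raises(ValueError, match="fewer than two"):
            combat_adjust(bad)

    def test_pure_location_shift_removed_exactly(self):
        study = _batch_study(shift=2.0, noise=0.0)
        adjusted, _ = combat_adjust(study)
        b1 = adjusted.matrix[:, study.batch_indices("B1")].mean(axis=1)
        b2 = adjusted.matrix[:, study.batch_indices("B2")].mean(axis=1)
        assert np.max(np.abs(b1 - b2)) < 1e-9
        # grand mean per gene preserved (balanced batches)
        assert np.allclose(
            adjusted.matrix.mean(axis=1), study.matrix.mean(axis=1), atol=1e-9
        )

    def test_adjustment_idempotent_in_location_only_case(self):
        study = _batch_study(shift=3.0, noise=0.0)
        once, _ = combat_adjust(study)
        twice, _ = combat_adjust(once)
        assert np.max(np.abs(twice.matrix - once.matrix)) < 1e-9

    def test_shrinkage_is_monotone_toward_prior_mean(self):
        study = _batch_study(shift=1.0, noise=0.6, seed=3)
        _, model = combat_adjust(study)
        for b in model.gamma_hat.columns:
            raw = model.gamma_hat[b] - model.gamma_bar[b]
            shrunk = model.gamma_star[b] - model.gamma_bar[b]
            assert (shrunk.abs() <= raw.abs() + 1e-12).all()

    def test_recovers_injected_batch_locations(self):
        spec = SimulationSpec(
            seed=11,
            n_per_group={"DA": 80, "GBM": 80},
            n_background_genes=300,
            de_profile=table2_profile().iloc[:0],
            probes_per_gene=(1, 1),
            n_batches=2,
            batch_spec={
                "B1": BatchParams(),
                "B2": BatchParams(shift_mean=1.0, shift_sd=0.5,
                                  log_scale_mean=np.log(1.3), log_scale_sd=0.1),
            },
        )
        study, truth = simulate_study(spec)
        _, model = combat_adjust(study)
        injected = truth.gamma.sub(truth.gamma.mean(axis=1), axis=0)
        recovered = model.gamma_star_log2()
        mae = (recovered - injected).abs().to_numpy().mean()
        assert mae < 0.1

    def test_zero_variance_gene_set_to_grand_mean(self, caplog):
        study = _batch_study(shift=2.0, noise=0.3, seed=1)
        study.matrix[0] = 6.5  # flat probe
        with caplog.at_level(logging.WARNING):
            adjusted, model = combat_adjust(study)
        assert "zero-variance" in caplog.text
        assert model.degenerate_probes == ["P0"]
        assert np.allclose(adjusted.matrix[0], 6.5)

    def test_matches_independent_combat_implementation(self):
        pytest.importorskip("anndata")
        import anndata
        import scanpy as sc

        study = _batch_study(n_genes=40, n_per_batch=25, shift=1.5, noise=0.5, seed=9)
        adjusted, _ = combat_adjust(study)
        ad = anndata.AnnData(
            X=study.matrix.T.copy(),
            obs={"batch": study.batch},
        )
        ad.obs["batch"] = ad.obs["batch"].astype("category")
        sc.pp.combat(ad, key="batch")
        # the two EB iterations use different convergence criteria, so
        # agreement is to ~1e-2 on log2 values near 10
        assert np.allclose(adjusted.matrix, ad.X.T, atol=1e-2)
        assert np.corrcoef(adjusted.matrix.ravel(), ad.X.T.ravel())[0, 1] > 0.9999


class TestPcaScores:
    def test_scores_are_centered_with_nonincreasing_variance(self, toy_study):
        scores = pca_scores(toy_study, 3)
        assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-10)
        variances = scores.var(axis=0).to_numpy()
        assert np.all(np.diff(variances) <= 1e-12)

    def test_rank_one_data_has_null_second_component(self):
        u = np.linspace(1, 2, 5)[:, None]
        v = np.linspace(-1, 1, 6)[None, :]
        study = ExpressionStudy(
            matrix=u @ v,
            probe_ids=[f"P{i}" for i in range(5)],
            gene_symbols=[f"G{i}" for i in range(5)],
            sample_ids=[f"S{i}" for i in range(6)],
            group=["A"] * 6,
            batch=["X"] * 6,
        )
        scores = pca_scores(study, 2)
        assert scores["PC2"].var() < 1e-20

    def test_excessive_components_rejected(self, toy_study):
        with pytest.raises(ValueError, match="exceeds"):
            pca_scores(toy_study, 8)

    def test_batch_share_of_pc1_drops_after_adjustment(self):
        spec = SimulationSpec(
            seed=4, n_background_genes=100, n_batches=2,
            batch_spec={"B1": BatchParams(), "B2": BatchParams(shift_mean=2.0)},
        )
        study, _ = simulate_study(spec)

        def pc1_batch_r2(s):
            pc1 = pca_scores(s, 1)["PC1"].to_numpy()
            b = np.array([1.0 if x == "B2" else 0.0 for x in s.batch])
            return np.corrcoef(pc1, b)[0, 1] ** 2

        before = pc1_batch_r2(study)
        adjusted, _ = combat_adjust(study)
        after = pc1_batch_r2(adjusted)
        assert after < before
        assert after < 0.1
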