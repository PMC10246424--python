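import numpy as np
import pytest
from scipy import stats

from myelodiv.diversity import diversity_table, shannon_index
from myelodiv.outcome_association import fit_cox, fit_logistic_response
from myelodiv.synthetic_cohort import (
    SimulationConfig,
    _ground_truth,
    simulate_bulk,
    simulate_clinical,
    simulate_mutations,
    simulate_single_cell,
)
from tests.conftest import fractions_from_truth


class TestConfigValidation:
    def test_rejects_small_k(self):
        with pytest.raises(ValueError, match="K >= 2"):
            SimulationConfig(n_subgroups=1)

    def test_rejects_zero_cells(self):
        with pytest.raises(ValueError, match="n_cells_per_subgroup"):
            SimulationConfig(n_cells_per_subgroup=0)

    def test_rejects_bad_censoring(self):
        with pytest.raises(ValueError, match="censoring_rate"):
            SimulationConfig(censoring_rate=1.5)

    def test_rejects_nan_hazard(self):
        with pytest.raises(ValueError, match="NaN"):
            SimulationConfig(hazard_coefficient=float("nan"))

    def test_rejects_bad_concentration(self):
        with pytest.raises(ValueError, match="mixture_concentration"):
            SimulationConfig(n_subgroups=3, mixture_concentration=(1.0, -1.0, 1.0))


class TestSingleCell:
    def test_noiseless_markers_at_background_outside_own_subgroup(self):
        cfg = SimulationConfig(n_subgroups=3, n_marker_genes_per_subgroup=1,
                               n_background_genes=5, n_cells_per_subgroup=4,
                               noise_sd=0.0, seed=1)
        sc, labels, truth = simulate_single_cell(cfg)
        for k, sg in enumerate(cfg.subgroup_ids):
            marker = truth.marker_genes[sg][0]
            row = sc.gene_ids.index(marker)
            for other in cfg.subgroup_ids:
                cols = [sc.sample_ids.index(c) for c in labels.cells_of(other)]
                mean = sc.values[row, cols].mean()
                if other == sg:
                    assert mean == cfg.marker_fold * cfg.background_mean
                else:
                    assert mean == cfg.background_mean

    def test_determinism(self):
        cfg = SimulationConfig(n_subgroups=3, n_cells_per_subgroup=10,
                               n_background_genes=20, seed=11)
        a, la, _ = simulate_single_cell(cfg)
        b, lb, _ = simulate_single_cell(cfg)
        np.testing.assert_array_equal(a.values, b.values)
        assert la.labels == lb.labels

    def test_different_seeds_differ(self):
        cfg1 = SimulationConfig(n_subgroups=3, seed=1)
        cfg2 = SimulationConfig(n_subgroups=3, seed=2)
        a, _, _ = simulate_single_cell(cfg1)
        b, _, _ = simulate_single_cell(cfg2)
        assert not np.array_equal(a.values, b.values)

    def test_empirical_marker_means_match_configured(self):
        cfg = SimulationConfig(n_subgroups=3, n_marker_genes_per_subgroup=4,
                               n_background_genes=10, n_cells_per_subgroup=50,
                               noise_sd=0.1, seed=5)
        sc, labels, truth = simulate_single_cell(cfg)
        for k, sg in enumerate(cfg.subgroup_ids):
            cols = [sc.sample_ids.index(c) for c in labels.cells_of(sg)]
            for g in truth.marker_genes[sg]:
                row = sc.gene_ids.index(g)
                vals = sc.values[row, cols]
                se = vals.std(ddof=1) / np.sqrt(len(vals))
                target = cfg.marker_fold * cfg.background_mean
                assert abs(vals.mean() - target) <= 3 * se + 1e-9

    def test_labels_cover_all_subgroups(self, small_config):
        _, labels, _ = simulate_single_cell(small_config)
        assert sorted(labels.vocabulary) == small_config.subgroup_ids


class TestGroundTruth:
    def test_fraction_rows_are_simplex(self, small_config):
        truth = _ground_truth(small_config)
        np.testing.assert_allclose(truth.true_fractions.sum(axis=1), 1.0, atol=1e-12)

    def test_diversity_matches_diversity_module(self, small_config):
        truth = _ground_truth(small_config)
        dt = diversity_table(fractions_from_truth(truth))
        np.testing.assert_allclose(dt.df["shannon"].to_numpy(),
                                   truth.true_diversity, atol=1e-12)

    def test_recompute_matches_shannon(self, small_config):
        truth = _ground_truth(small_config)
        for row, d in zip(truth.true_fractions, truth.true_diversity):
            assert shannon_index(row) == pytest.approx(d, abs=1e-12)


class TestBulk:
    def _noiseless_cfg(self, **kw):
        base = dict(n_subgroups=3, n_marker_genes_per_subgroup=2,
                    n_background_genes=5, n_bulk_samples=4, noise_sd=0.0,
                    n_surrogate_genes=0, n_module_noise_genes=0, seed=3)
        base.update(kw)
        return SimulationConfig(**base)

    def test_pure_fraction_recovers_profile_column(self):
        cfg = self._noiseless_cfg()
        truth = _ground_truth(cfg)
        truth.true_fractions[0] = [1.0, 0.0, 0.0]
        truth.true_diversity[0] = 0.0
        bulk = simulate_bulk(cfg, truth)
        np.testing.assert_allclose(bulk.values[:, 0], truth.subgroup_profiles[:, 0],
                                   atol=1e-12)

    def test_uniform_fractions_give_row_mean(self):
        cfg = self._noiseless_cfg()
        truth = _ground_truth(cfg)
        truth.true_fractions[1] = [1 / 3] * 3
        truth.true_diversity[1] = shannon_index([1 / 3] * 3)
        bulk = simulate_bulk(cfg, truth)
        np.testing.assert_allclose(bulk.values[:, 1],
                                   truth.subgroup_profiles.mean(axis=1), atol=1e-12)

    def test_noiseless_equals_exact_mixture(self):
        cfg = self._noiseless_cfg()
        truth = _ground_truth(cfg)
        bulk = simulate_bulk(cfg, truth)
        np.testing.assert_allclose(
            bulk.values, truth.subgroup_profiles @ truth.true_fractions.T, atol=1e-12
        )

    def test_log_residual_sd_matches_noise(self):
        cfg = SimulationConfig(n_subgroups=3, n_marker_genes_per_subgroup=2,
                               n_background_genes=40, n_bulk_samples=200,
                               noise_sd=0.1, n_surrogate_genes=0,
                               n_module_noise_genes=0, seed=4)
        truth = _ground_truth(cfg)
        noisy = simulate_bulk(cfg, truth).values
        clean = truth.subgroup_profiles @ truth.true_fractions.T
        resid_sd = np.log(noisy / clean).std()
        assert abs(resid_sd - 0.1) / 0.1 < 0.15

    def test_dimension_mismatch_errors(self, small_config):
        truth = _ground_truth(small_config)
        truth.subgroup_profiles = truth.subgroup_profiles[:, :-1]
        with pytest.raises(ValueError, match="disagree on K"):
            simulate_bulk(small_config, truth)

    def test_module_block_appended(self, truth_and_bulk):
        truth, bulk = truth_and_bulk
        for g in truth.planted_surrogate_genes:
            assert g in bulk.gene_ids


class TestClinical:
    def test_null_hazard_gives_uniform_logrank_p(self):
        # beta = 0: high/low diversity strata have identical survival
        from myelodiv.diversity import stratify_by_quantile
        from myelodiv.outcome_association import km_logrank

        pvals = []
        for seed in range(40):
            cfg = SimulationConfig(n_subgroups=5, n_bulk_samples=80,
                                   hazard_coefficient=0.0, seed=seed,
                                   n_surrogate_genes=0, n_module_noise_genes=0)
            truth = _ground_truth(cfg)
            clin = simulate_clinical(cfg, truth)
            dt = diversity_table(fractions_from_truth(truth))
            strata = stratify_by_quantile(dt)
            km = km_logrank(clin, strata)
            pvals.append(km.logrank_p)
        # under the null p-values should not pile up at small values
        assert np.mean(np.array(pvals) < 0.05) < 0.2

    def test_protective_diversity_gives_hr_below_one(self):
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(n_subgroups=5, n_bulk_samples=500,
                                   hazard_coefficient=-1.0, seed=seed)
            truth = _ground_truth(cfg)
            clin = simulate_clinical(cfg, truth)
            div = np.asarray(truth.true_diversity)
            import pandas as pd

            pred = pd.Series(div, index=clin.df["sample_id"].astype(str), name="div")
            aligned = pred.loc[clin.df["sample_id"].astype(str)].reset_index(drop=True)
            aligned.name = "div"
            res = fit_cox(clin, [aligned])[0]
            hits += res.hazard_ratio < 1
        assert hits >= 19

    def test_null_response_slope_covers_or_one(self):
        covered = 0
        for seed in range(30):
            cfg = SimulationConfig(n_subgroups=5, n_bulk_samples=200,
                                   response_slope=0.0, seed=seed)
            truth = _ground_truth(cfg)
            clin = simulate_clinical(cfg, truth)
            import pandas as pd

            pred = pd.Series(truth.true_diversity,
                             index=clin.df["sample_id"].astype(str))
            res = fit_logistic_response(clin, pred)
            covered += res.ci_lower <= 1.0 <= res.ci_upper
        assert covered >= 24  # ~95% nominal coverage

    def test_censoring_rate_approximate(self):
        cfg = SimulationConfig(n_subgroups=5, n_bulk_samples=2000,
                               censoring_rate=0.3, seed=8)
        truth = _ground_truth(cfg)
        clin = simulate_clinical(cfg, truth)
        frac_censored = 1 - clin.df["event"].mean()
        assert abs(frac_censored - 0.3) < 0.07


class TestMutations:
    def test_equal_rates_give_null_or(self):
        ors = []
        for seed in range(10):
            cfg = SimulationConfig(n_subgroups=5, n_bulk_samples=300,
                                   mutation_rate_high=0.3, mutation_rate_low=0.3,
                                   seed=seed)
            truth = _ground_truth(cfg)
            mut = simulate_mutations(cfg, truth)
            div = truth.true_diversity
            hi = set(np.array(truth.sample_ids)[div >= np.quantile(div, 0.75)])
            lo = set(np.array(truth.sample_ids)[div <= np.quantile(div, 0.25)])
            pres = mut.df[mut.df["gene"].isin(truth.mutation_panel_genes)]
            pres = pres[["sample_id", "gene"]].drop_duplicates()
            a = len(set(pres["sample_id"]) & hi)
            c = len(set(pres["sample_id"]) & lo)
            ors.append((a + 0.5) / (c + 0.5))
        assert 0.5 < np.median(ors) < 2.0

    def test_planted_contrast_detectable(self):
        cfg = SimulationConfig(n_subgroups=5, n_bulk_samples=400,
                               mutation_rate_high=0.4, mutation_rate_low=0.1, seed=2)
        truth = _ground_truth(cfg)
        mut = simulate_mutations(cfg, truth)
        div = truth.true_diversity
        hi = set(np.array(truth.sample_ids)[div >= np.quantile(div, 0.75)])
        gene = truth.mutation_panel_genes[0]
        pres = mut.df[mut.df["gene"] == gene][["sample_id"]].drop_duplicates()
        in_hi = len(set(pres["sample_id"].astype(str)) & hi)
        in_rest = len(pres) - in_hi
        n_hi = len(hi)
        n_rest = len(truth.sample_ids) - n_hi
        table = [[in_hi, n_hi - in_hi], [in_rest, n_rest - in_rest]]
        _, p = stats.fisher_exact(table)
        assert p < 0.01

    def test_zero_rate_gene_absent(self):
        cfg = SimulationConfig(n_subgroups=5, n_bulk_samples=50,
                               mutation_rate_high=0.0, mutation_rate_low=0.0,
                               mutation_background_rate=0.05, seed=3)
        truth = _ground_truth(cfg)
        mut = simulate_mutations(cfg, truth)
        assert not set(truth.mutation_panel_genes) & set(mut.df["gene"])

    def test_rates_validated(self):
        with pytest.raises(ValueError, match="mutation_rate_high"):
            SimulationConfig(mutation_rate_high=1.2)

    def test_determinism(self):
        cfg = SimulationConfig(n_subgroups=4, n_bulk_samples=40, seed=9)
        truth = _ground_truth(cfg)
        a = simulate_mutations(cfg, truth)
        b = simulate_mutations(cfg, truth)
        assert a.df.equals(b.df)
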