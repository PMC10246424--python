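import numpy as np
import pandas as pd
import pytest
from scipy import stats

from myelodiv.diversity import DiversityTable
from myelodiv.io_formats import ClinicalTable, ExpressionMatrix
from myelodiv.surrogate_model import (
    ImportanceRanking,
    PUBLISHED_SURROGATE_GENES,
    SurrogateModel,
    combine_and_filter,
    fit_surrogate,
    rank_importance,
    score_samples,
    validate_surrogate,
)


def _dt(div, ids):
    return DiversityTable(pd.DataFrame({
        "sample_id": ids, "shannon": div, "gini_simpson": div, "pielou": div,
        "n": 5, "degenerate": False}))


def _expr(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i:03d}" for i in range(values.shape[0])]
    return ExpressionMatrix(genes, [f"s{j:03d}" for j in range(values.shape[1])],
                            values)


class TestRankImportance:
    def test_planted_linear_gene_ranks_first(self):
        rng = np.random.default_rng(0)
        n = 100
        signal = rng.uniform(1, 5, size=n)
        noise = rng.uniform(1, 5, size=(9, n))
        expr = _expr(np.vstack([signal, noise]))
        dt = _dt(0.8 * signal + 0.2, expr.sample_ids)
        ranking = rank_importance(expr, dt, expr.gene_ids, seed=1, n_trees=100)
        assert ranking.importances.index[0] == "g000"
        assert ranking.importances.iloc[0] > 3 * ranking.importances.iloc[1]
        assert ranking.heldout_correlation > 0.9

    def test_all_noise_module_warns_and_is_flat(self):
        rng = np.random.default_rng(1)
        expr = _expr(rng.uniform(1, 5, size=(10, 80)))
        dt = _dt(rng.uniform(0, 2, size=80), expr.sample_ids)
        with pytest.warns(UserWarning, match="weakly predictive"):
            ranking = rank_importance(expr, dt, expr.gene_ids, seed=2, n_trees=100)
        imp = ranking.importances.to_numpy()
        assert imp.max() <= 0.25  # no dominant gene on pure noise

    def test_too_few_samples(self):
        rng = np.random.default_rng(2)
        expr = _expr(rng.uniform(1, 5, size=(4, 10)))
        dt = _dt(rng.uniform(0, 2, size=10), expr.sample_ids)
        with pytest.raises(ValueError, match="30 samples"):
            rank_importance(expr, dt, expr.gene_ids)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        expr = _expr(rng.uniform(1, 5, size=(6, 60)))
        dt = _dt(rng.uniform(0, 2, size=60), expr.sample_ids)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = rank_importance(expr, dt, expr.gene_ids, seed=9, n_trees=50)
            r2 = rank_importance(expr, dt, expr.gene_ids, seed=9, n_trees=50)
        pd.testing.assert_series_equal(r1.importances, r2.importances)


def _ranking(order_scores: dict, cohort="c"):
    s = pd.Series(order_scores, dtype=float).sort_values(ascending=False)
    return ImportanceRanking(s, 0.9, 0, cohort)


class TestCombineAndFilter:
    def test_duplicated_gene_keeps_higher_ranked(self):
        base = np.linspace(1, 10, 30)
        rng = np.random.default_rng(4)
        other = rng.uniform(1, 10, size=30)
        expr = _expr([base, base * 2.0, other], genes=["A", "B", "C"])
        ranking = _ranking({"A": 3.0, "B": 2.0, "C": 1.0})
        kept = combine_and_filter([ranking], expr, top_k=3)
        assert kept == ["A", "C"]

    def test_orthogonal_genes_all_kept(self):
        rng = np.random.default_rng(5)
        expr = _expr(rng.normal(10, 1, size=(4, 200)).clip(0),
                     genes=["A", "B", "C", "D"])
        ranking = _ranking({"A": 4.0, "B": 3.0, "C": 2.0, "D": 1.0})
        kept = combine_and_filter([ranking], expr, top_k=4)
        assert kept == ["A", "B", "C", "D"]

    def test_greedy_chain(self):
        # A-B r=0.8, B-C r=0.8, A-C r=0.3, importance A > B > C -> keep {A, C}
        rng = np.random.default_rng(6)
        n = 5000
        zb = rng.normal(size=n)
        za = 0.8 * zb + np.sqrt(1 - 0.64) * rng.normal(size=n)
        # construct C correlated 0.8 with B and ~0.3 with A
        resid = rng.normal(size=n)
        zc = 0.8 * zb - 0.45 * (za - 0.8 * zb) / np.sqrt(1 - 0.64) + 0.3 * resid
        expr = _expr(np.vstack([za, zb, zc]) + 10.0, genes=["A", "B", "C"])
        r_ab = abs(np.corrcoef(za, zb)[0, 1])
        r_ac = abs(np.corrcoef(za, zc)[0, 1])
        assert r_ab > 0.75 and r_ac < 0.75
        ranking = _ranking({"A": 3.0, "B": 2.0, "C": 1.0})
        kept = combine_and_filter([ranking], expr, top_k=3)
        assert kept == ["A", "C"]

    def test_union_across_cohorts(self):
        rng = np.random.default_rng(7)
        expr = _expr(rng.normal(10, 1, size=(4, 100)).clip(0),
                     genes=["A", "B", "C", "D"])
        r1 = _ranking({"A": 4.0, "B": 3.0, "C": 0.1, "D": 0.0}, "c1")
        r2 = _ranking({"C": 5.0, "D": 4.0, "A": 0.1, "B": 0.0}, "c2")
        kept = combine_and_filter([r1, r2], expr, top_k=2)
        assert set(kept) == {"A", "B", "C", "D"}
        # disjoint top lists: intersection is empty, which is an error
        with pytest.raises(ValueError, match="empty candidate pool"):
            combine_and_filter([r1, r2], expr, top_k=2, combine="intersection")
        inter = combine_and_filter([r1, r2], expr, top_k=3, combine="intersection")
        assert set(inter) <= {"A", "B", "C", "D"}

    def test_empty_pool_errors(self):
        with pytest.raises(ValueError, match="at least one"):
            combine_and_filter([], None)


class TestFitSurrogate:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(8)
        n = 50
        X = rng.uniform(1, 5, size=(3, n))
        z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        coefs = np.array([0.5, -0.3, 0.2])
        div = 1.0 + coefs @ z
        expr = _expr(X, genes=["A", "B", "C"])
        dt = _dt(div, expr.sample_ids)
        model = fit_surrogate(expr, dt, ["A", "B", "C"])
        np.testing.assert_allclose(model.coefficients, coefs, atol=1e-8)
        assert model.intercept == pytest.approx(1.0, abs=1e-8)
        assert model.provenance["in_sample_spearman"] == pytest.approx(1.0)

    def test_noisy_coefficients_within_sampling_error(self):
        rng = np.random.default_rng(9)
        n = 300
        X = rng.normal(10, 2, size=(3, n)).clip(0)
        z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        coefs = np.array([0.6, 0.4, -0.5])
        div = 2.0 + coefs @ z + rng.normal(0, 0.1, size=n)
        expr = _expr(X, genes=["A", "B", "C"])
        dt = _dt(div, expr.sample_ids)
        model = fit_surrogate(expr, dt, ["A", "B", "C"])
        se = 0.1 / np.sqrt(n)  # ≈ per-coefficient SE with orthonormal design
        np.testing.assert_allclose(model.coefficients, coefs, atol=3 * se * 2)

    def test_intercept_only_model(self):
        rng = np.random.default_rng(10)
        div = rng.uniform(0, 2, size=40)
        expr = _expr(rng.uniform(1, 5, size=(2, 40)))
        dt = _dt(div, expr.sample_ids)
        model = fit_surrogate(expr, dt, [])
        scores = score_samples(model, expr)
        np.testing.assert_allclose(scores.to_numpy(), div.mean(), atol=1e-12)

    def test_collinear_pair_rejected(self):
        base = np.linspace(1, 10, 40)
        expr = _expr([base, 2 * base], genes=["A", "B"])
        dt = _dt(base / 5, expr.sample_ids)
        with pytest.raises(ValueError, match="collinear"):
            fit_surrogate(expr, dt, ["A", "B"])

    def test_model_never_contains_high_r_pair(self):
        rng = np.random.default_rng(11)
        n = 120
        expr = _expr(rng.normal(10, 1, size=(6, n)).clip(0))
        dt = _dt(rng.uniform(0, 2, size=n), expr.sample_ids)
        model = fit_surrogate(expr, dt, list(expr.gene_ids))
        vals = expr.values
        for i in range(6):
            for j in range(i + 1, 6):
                assert abs(np.corrcoef(vals[i], vals[j])[0, 1]) < 0.75


class TestScoring:
    def _model(self):
        return SurrogateModel(["A", "B"], 1.0, np.array([0.5, -0.5]),
                              np.array([2.0, 3.0]), np.array([1.0, 2.0]))

    def test_training_scores_reproduce_fitted_values(self):
        rng = np.random.default_rng(12)
        n = 60
        X = rng.uniform(1, 5, size=(2, n))
        expr = _expr(X, genes=["A", "B"])
        div = 0.4 * X[0] - 0.1 * X[1] + 1.0
        dt = _dt(div, expr.sample_ids)
        model = fit_surrogate(expr, dt, ["A", "B"])
        scores = score_samples(model, expr)
        z = (X - np.array([model.scaler_mean]).T) / np.array([model.scaler_sd]).T
        fitted = model.intercept + model.coefficients @ z
        np.testing.assert_array_equal(scores.to_numpy(), fitted)

    def test_extra_genes_ignored(self):
        model = self._model()
        e1 = _expr([[3.0, 4.0], [5.0, 1.0]], genes=["A", "B"])
        e2 = _expr([[3.0, 4.0], [9.9, 9.9], [5.0, 1.0]], genes=["A", "X", "B"])
        pd.testing.assert_series_equal(score_samples(model, e1),
                                       score_samples(model, e2))

    def test_identical_columns_identical_scores(self):
        model = self._model()
        expr = _expr([[3.0, 3.0], [5.0, 5.0]], genes=["A", "B"])
        s = score_samples(model, expr)
        assert s.iloc[0] == s.iloc[1]

    def test_missing_gene_errors_unless_imputed(self):
        model = self._model()
        expr = _expr([[3.0, 4.0]], genes=["A"])
        with pytest.raises(KeyError, match="B"):
            score_samples(model, expr)
        scores = score_samples(model, expr, impute_missing=True)
        assert np.isfinite(scores).all()

    def test_json_round_trip(self, tmp_path):
        model = self._model()
        model.to_json(tmp_path / "m.json")
        back = SurrogateModel.from_json(tmp_path / "m.json")
        assert back.gene_ids == model.gene_ids
        np.testing.assert_array_equal(back.coefficients, model.coefficients)

    def test_published_gene_fixture(self):
        assert PUBLISHED_SURROGATE_GENES == ("C3", "CD27", "GFPT2", "GMFG", "HLA-DPB1")


class TestValidate:
    def test_constant_scores_hr_one(self):
        rng = np.random.default_rng(13)
        n = 40
        clin = ClinicalTable(pd.DataFrame({
            "sample_id": [f"s{i:03d}" for i in range(n)],
            "time": rng.exponential(size=n), "event": np.ones(n, int)}))
        scores = pd.Series(np.ones(n), index=clin.df["sample_id"].astype(str))
        res, risk = validate_surrogate(scores, clin)
        assert res.hazard_ratio == 1.0
        assert (risk["surrogate_index"].diff().dropna() >= 0).all()

    def test_protective_score_hr_below_one(self):
        rng = np.random.default_rng(14)
        n = 200
        score = rng.normal(size=n)
        # higher score -> longer expected survival (scale = 1/rate)
        t = rng.exponential(np.exp(0.8 * score))
        clin = ClinicalTable(pd.DataFrame({
            "sample_id": [f"s{i:03d}" for i in range(n)],
            "time": t, "event": np.ones(n, int)}))
        s = pd.Series(score, index=clin.df["sample_id"].astype(str))
        res, _ = validate_surrogate(s, clin)
        assert res.hazard_ratio < 1 and res.p_value < 0.01

    def test_permuted_scores_cover_one(self):
        rng = np.random.default_rng(15)
        covered = 0
        for _ in range(30):
            n = 80
            score = rng.normal(size=n)
            t = rng.exponential(size=n)
            clin = ClinicalTable(pd.DataFrame({
                "sample_id": [f"s{i:03d}" for i in range(n)],
                "time": t, "event": np.ones(n, int)}))
            s = pd.Series(score, index=clin.df["sample_id"].astype(str))
            res, _ = validate_surrogate(s, clin)
            covered += res.ci_lower <= 1.0 <= res.ci_upper
        assert covered >= 25
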