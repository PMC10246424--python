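"""Small-gene linear surrogate of the diversity index.

Pipeline: random-forest regression of Shannon diversity on module genes with
permutation importance on a held-out split; union of top-ranked genes across
cohorts; greedy collinearity filtering (drop any gene correlated at or above
the threshold with an already-kept, higher-ranked gene); ordinary least
squares on z-scored expression; scoring and survival validation of the
resulting index.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

from .diversity import DiversityTable
from .io_formats import ClinicalTable, ExpressionMatrix
from .outcome_association import CoxResult, fit_cox

__all__ = ["ImportanceRanking", "SurrogateModel", "rank_importance",
           "combine_and_filter", "fit_surrogate", "score_samples",
           "validate_surrogate", "PUBLISHED_SURROGATE_GENES"]

# exemplar 5-gene panel users can refit on their own cohort
PUBLISHED_SURROGATE_GENES = ("C3", "CD27", "GFPT2", "GMFG", "HLA-DPB1")


@dataclass
class ImportanceRanking:
    """Per-gene permutation importances plus fit diagnostics."""

    importances: pd.Series        # gene -> importance, sorted descending
    heldout_correlation: float
    split_seed: int
    cohort: str = "cohort"

    def top(self, k: int) -> list[str]:
        return list(self.importances.index[:k])


@dataclass
class SurrogateModel:
    gene_ids: list[str]
    intercept: float
    coefficients: np.ndarray
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.isfinite(self.coefficients).all() or not np.isfinite(self.intercept):
            raise ValueError("surrogate coefficients must be finite")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_ids": self.gene_ids,
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "scaler_mean": np.asarray(self.scaler_mean).tolist(),
            "scaler_sd": np.asarray(self.scaler_sd).tolist(),
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SurrogateModel":
        d = json.loads(Path(path).read_text())
        return cls(d["gene_ids"], d["intercept"], np.array(d["coefficients"]),
                   np.array(d["scaler_mean"]), np.array(d["scaler_sd"]),
                   d.get("provenance", {}))


def _aligned_xy(expr: ExpressionMatrix, dt: DiversityTable, genes: list[str]):
    shannon = dt.df.loc[~dt.df["degenerate"]].set_index("sample_id")["shannon"]
    common = [s for s in expr.sample_ids if s in shannon.index]
    sub = expr.subset_genes(genes)
    pos = {s: i for i, s in enumerate(sub.sample_ids)}
    X = sub.values[:, [pos[s] for s in common]].T  # samples x genes
    y = shannon.loc[common].to_numpy(dtype=float)
    return X, y, common


def rank_importance(
    expr: ExpressionMatrix,
    dt: DiversityTable,
    module_genes: list[str],
    seed: int = 0,
    n_trees: int = 500,
    test_fraction: float = 0.3,
    correlation_floor: float = 0.5,
    n_permutations: int = 10,
    cohort: str = "cohort",
) -> ImportanceRanking:
    """Random-forest importance of module genes for predicting diversity.

    Features are z-scored; a seeded 70/30 split trains the forest and
    permutation importance is measured on the held-out 30%. Ties in
    importance break lexicographically by gene ID.
    """
    X, y, _ = _aligned_xy(expr, dt, module_genes)
    if X.shape[0] < 30:
        raise ValueError("need at least 30 samples to rank importance")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    X_tr, X_te, y_tr, y_te = train_test_split(Xs, y, test_size=test_fraction,
                                              random_state=seed)
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X_tr, y_tr)
    pred = rf.predict(X_te)
    r = float(np.corrcoef(pred, y_te)[0, 1]) if pred.std() > 0 else 0.0
    if r < correlation_floor:
        warnings.warn(
            f"module weakly predictive of diversity (held-out r={r:.3f} "
            f"< {correlation_floor}); ranking returned anyway",
            stacklevel=2,
        )
    mean_imp = _permutation_importance(rf, X_te, y_te, n_permutations,
                                       np.random.default_rng(seed))
    imp = pd.Series(np.clip(mean_imp, 0.0, None), index=module_genes)
    order = sorted(imp.index, key=lambda g: (-imp[g], g))
    return ImportanceRanking(imp.loc[order], r, seed, cohort)


def _permutation_importance(model, X, y, n_repeats: int, rng) -> np.ndarray:
    """Mean decrease in held-out R^2 when one feature is shuffled.

    Semantics match scikit-learn's ``permutation_importance`` with the
    default scorer, but all permuted copies are scored in one batched
    ``predict`` call, which is far faster for many features.
    """
    n, p = X.shape
    var_y = ((y - y.mean()) ** 2).sum()
    if var_y == 0:
        return np.zeros(p)
    base_r2 = 1.0 - ((y - model.predict(X)) ** 2).sum() / var_y
    batch = np.tile(X, (p * n_repeats, 1, 1))  # (p*repeats, n, p)
    for rep in range(n_repeats):
        for j in range(p):
            perm = rng.permutation(n)
            batch[rep * p + j, :, j] = X[perm, j]
    preds = model.predict(batch.reshape(-1, p)).reshape(p * n_repeats, n)
    sse = ((preds - y[None, :]) ** 2).sum(axis=1)
    r2 = 1.0 - sse / var_y
    drops = base_r2 - r2.reshape(n_repeats, p)
    return drops.mean(axis=0)


def combine_and_filter(
    rankings: list[ImportanceRanking],
    training_expr: ExpressionMatrix,
    top_k: int = 15,
    r_threshold: float = 0.75,
    combine: str = "union",
) -> list[str]:
    """Union (or intersection) of top-``top_k`` genes per cohort, then greedy
    collinearity filtering on the training expression.

    Genes are visited in descending best-rank importance; a gene is dropped
    when its training-set |Pearson r| with an already-kept gene reaches the
    threshold.
    """
    if not rankings:
        raise ValueError("need at least one importance ranking")
    tops = [set(r.top(top_k)) for r in rankings]
    if combine == "union":
        pool = set().union(*tops)
    elif combine == "intersection":
        pool = set.intersection(*tops)
    else:
        raise ValueError(f"unknown combine mode {combine!r}")
    if not pool:
        raise ValueError("empty candidate pool after combining rankings")
    best_imp = {g: max(float(r.importances.get(g, 0.0)) for r in rankings) for g in pool}
    ordered = sorted(pool, key=lambda g: (-best_imp[g], g))
    sub = training_expr.subset_genes(ordered)
    mat = sub.values  # genes x samples
    kept: list[str] = []
    kept_rows: list[int] = []
    for i, g in enumerate(ordered):
        ok = True
        for j in kept_rows:
            sd_i, sd_j = mat[i].std(), mat[j].std()
            if sd_i == 0 or sd_j == 0:
                continue
            r = abs(np.corrcoef(mat[i], mat[j])[0, 1])
            if r >= r_threshold:
                ok = False
                break
        if ok:
            kept.append(g)
            kept_rows.append(i)
    if not kept:
        raise ValueError("collinearity filter removed every candidate gene")
    return kept


def fit_surrogate(
    expr: ExpressionMatrix,
    dt: DiversityTable,
    genes: list[str],
    external: tuple[ExpressionMatrix, DiversityTable] | None = None,
    r_threshold: float = 0.75,
) -> SurrogateModel:
    """OLS of Shannon diversity on z-scored expression of the given genes.

    An empty gene list yields the intercept-only model (constant prediction
    at the mean diversity). In-sample and, when an external cohort is given,
    external predicted-vs-actual Spearman correlations are stored in the
    provenance.
    """
    from scipy import stats

    if genes:
        X, y, _ = _aligned_xy(expr, dt, list(genes))
    else:
        shannon = dt.df.loc[~dt.df["degenerate"]]["shannon"].to_numpy()
        X, y = np.empty((len(shannon), 0)), shannon
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more samples than genes + 1 for OLS")
    # guard: the collinearity filter should preclude near-duplicate columns
    for i in range(p):
        for j in range(i + 1, p):
            if X[:, i].std() > 0 and X[:, j].std() > 0:
                r = abs(np.corrcoef(X[:, i], X[:, j])[0, 1])
                if r >= r_threshold:
                    raise ValueError(
                        f"collinear gene pair in model: {genes[i]}, {genes[j]} (|r|={r:.3f})"
                    )
    mu = X.mean(axis=0) if p else np.empty(0)
    sd = X.std(axis=0) if p else np.empty(0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd if p else X
    design = np.column_stack([np.ones(n), Xs])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise ValueError(f"rank-deficient design over genes {list(genes)}")
    fitted = design @ coef
    prov: dict = {"n_training_samples": n, "r_threshold": r_threshold}
    if p and fitted.std() > 0:
        prov["in_sample_spearman"] = float(stats.spearmanr(fitted, y).statistic)
    model = SurrogateModel(list(genes), float(coef[0]), coef[1:], mu, sd, prov)
    if external is not None:
        ext_expr, ext_dt = external
        scores = score_samples(model, ext_expr)
        ext_sh = ext_dt.df.loc[~ext_dt.df["degenerate"]].set_index("sample_id")["shannon"]
        common = [s for s in scores.index if s in ext_sh.index]
        if len(common) >= 3 and genes:
            prov["external_spearman"] = float(
                stats.spearmanr(scores.loc[common], ext_sh.loc[common]).statistic
            )
    return model


def score_samples(
    model: SurrogateModel,
    expr: ExpressionMatrix,
    impute_missing: bool = False,
) -> pd.Series:
    """Apply the stored scaler and linear predictor to an expression matrix.

    Extra genes in the matrix are ignored. Missing model genes are an error
    unless ``impute_missing`` is set, in which case they score at the
    training mean (zero after scaling).
    """
    present = set(expr.gene_ids)
    missing = [g for g in model.gene_ids if g not in present]
    if missing and not impute_missing:
        raise KeyError(f"model genes absent from expression matrix: {missing}")
    n = expr.n_samples
    z = np.zeros((n, len(model.gene_ids)))
    gidx = {g: i for i, g in enumerate(expr.gene_ids)}
    for j, g in enumerate(model.gene_ids):
        if g in gidx:
            col = expr.values[gidx[g], :]
            z[:, j] = (col - model.scaler_mean[j]) / model.scaler_sd[j]
    scores = model.intercept + z @ model.coefficients
    return pd.Series(scores, index=expr.sample_ids, name="surrogate_index")


def validate_surrogate(
    scores: pd.Series,
    clin: ClinicalTable,
    endpoint: str = "OS",
) -> tuple[CoxResult, pd.DataFrame]:
    """Univariate Cox of the endpoint on the surrogate index, plus a
    risk-plot table (samples ranked by score with time and event)."""
    ids = clin.df["sample_id"].astype(str)
    common = ids[ids.isin(scores.index)]
    if len(common) < 10:
        raise ValueError("need >= 10 overlapping samples for validation")
    sub = ClinicalTable(clin.df[ids.isin(scores.index)].reset_index(drop=True))
    aligned = scores.loc[sub.df["sample_id"].astype(str)].reset_index(drop=True)
    aligned.name = "surrogate_index"
    result = fit_cox(sub, [aligned], endpoint=endpoint)[0]
    risk = sub.df[["sample_id", "time", "event"]].copy()
    risk["surrogate_index"] = aligned.to_numpy()
    risk = risk.sort_values("surrogate_index", kind="mergesort").reset_index(drop=True)
    return result, risk
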