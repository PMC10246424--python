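"""Single-sample gene-set enrichment scoring (rank-weighted running sum).

Genes are ranked by expression (descending). The score for a set is the sum
over ranked positions of the difference between the weighted in-set
cumulative distribution and the uniform out-of-set one. Weights use integer
ranks raised to ``alpha`` (GSVA-style), which makes scores invariant under
any strictly monotone transform of the expression column; raw-value
weighting is available via ``weight="value"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, GeneSetCollection

__all__ = ["ssgsea_score", "score_matrix", "EnrichmentTable", "immunity_cycle_correlation"]


@dataclass
class EnrichmentTable:
    """Sample (or subgroup) x gene-set matrix of enrichment scores."""

    df: pd.DataFrame  # rows = samples, columns = gene sets
    normalized: bool = False

    def normalize(self) -> "EnrichmentTable":
        """Divide each column by its (max - min) across samples."""
        out = self.df.copy()
        span = out.max() - out.min()
        span = span.replace(0, np.nan)
        return EnrichmentTable(out / span, normalized=True)


def _ranked_order(values: np.ndarray, gene_ids: list[str]) -> np.ndarray:
    """Indices ordering genes by expression descending; ties broken by
    descending gene ID (deterministic)."""
    keys = sorted(range(len(gene_ids)),
                  key=lambda i: (-values[i], _neg_str(gene_ids[i])))
    return np.asarray(keys)


def _neg_str(s: str):
    # sort key that inverts lexicographic order
    return tuple(-ord(c) for c in s)


def ssgsea_score(
    expr_column,
    gene_ids: list[str],
    gene_set,
    alpha: float = 0.25,
    min_overlap: int = 5,
    weight: str = "rank",
) -> float:
    """Score one sample's expression column against one gene set.

    Returns NaN (with a warning) when the set does not overlap the universe.
    A set covering the whole universe scores 0 by convention (the out-of-set
    step is degenerate).
    """
    values = np.asarray(expr_column, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 genes in the ranked universe")
    if len(gene_ids) != n:
        raise ValueError("expr_column and gene_ids length mismatch")
    in_set = np.array([g in set(gene_set) for g in gene_ids])
    n_hit = int(in_set.sum())
    if n_hit == 0:
        warnings.warn("gene set has no overlap with the universe; score is NaN",
                      stacklevel=2)
        return float("nan")
    if n_hit < min_overlap:
        warnings.warn(
            f"gene-set overlap {n_hit} below min_overlap={min_overlap}; scoring anyway",
            stacklevel=2,
        )
    if n_hit == n:
        return 0.0
    order = _ranked_order(values, gene_ids)
    hits = in_set[order]
    if weight == "rank":
        # position 0 (top expression) gets rank n, the bottom gets 1
        w = (n - np.arange(n)).astype(float) ** alpha
    elif weight == "value":
        w = np.abs(values[order]) ** alpha
    else:
        raise ValueError(f"unknown weight mode {weight!r}")
    w_in = np.where(hits, w, 0.0)
    denom_in = w_in.sum()
    p_in = np.cumsum(w_in) / denom_in if denom_in > 0 else np.cumsum(hits) / n_hit
    p_out = np.cumsum(~hits) / (n - n_hit)
    return float((p_in - p_out).sum())


def score_matrix(
    expr: ExpressionMatrix,
    gene_sets: GeneSetCollection,
    alpha: float = 0.25,
    min_overlap: int = 5,
    weight: str = "rank",
    normalize: bool = False,
) -> EnrichmentTable:
    """Score every sample against every gene set."""
    scores = np.empty((expr.n_samples, len(gene_sets)))
    names = list(gene_sets)
    for j in range(expr.n_samples):
        col = expr.values[:, j]
        for s, name in enumerate(names):
            scores[j, s] = ssgsea_score(col, expr.gene_ids, gene_sets[name],
                                        alpha=alpha, min_overlap=min_overlap,
                                        weight=weight)
    table = EnrichmentTable(pd.DataFrame(scores, index=expr.sample_ids, columns=names))
    return table.normalize() if normalize else table


def immunity_cycle_correlation(dt, scores: EnrichmentTable) -> pd.DataFrame:
    """Spearman correlation of each enrichment column with Shannon diversity.

    Returns a frame with raw and Benjamini-Hochberg adjusted p-values, one
    row per gene set ("immunity-cycle step").
    """
    shannon = dt.df.loc[~dt.df["degenerate"]].set_index("sample_id")["shannon"]
    common = [s for s in scores.df.index if s in shannon.index]
    if len(common) < 10:
        raise ValueError(f"need >= 10 overlapping samples, got {len(common)}")
    div = shannon.loc[common].to_numpy()
    rows = []
    for name in scores.df.columns:
        vec = scores.df.loc[common, name].to_numpy(dtype=float)
        if np.nanstd(vec) == 0 or np.isnan(vec).all():
            warnings.warn(f"constant or empty score vector for {name!r}; "
                          "correlation undefined", stacklevel=2)
            rows.append((name, np.nan, np.nan))
            continue
        rho, p = stats.spearmanr(div, vec)
        rows.append((name, float(rho), float(p)))
    out = pd.DataFrame(rows, columns=["gene_set", "spearman_rho", "p_value"])
    ok = out["p_value"].notna()
    adj = np.full(len(out), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
    out["p_adjusted"] = adj
    return out
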