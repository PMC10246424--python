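"""Lightweight co-expression module detection.

Unsigned soft-threshold adjacency, topological overlap, average-linkage
hierarchical clustering with a static tree cut, module eigengenes (first
principal component of the standardized module expression, sign fixed by
positive mean loading), and module-trait correlation against the Shannon
diversity index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .diversity import DiversityTable
from .io_formats import ExpressionMatrix

logger = logging.getLogger("myelodiv")

__all__ = ["NetworkConfig", "GeneModule", "build_adjacency", "topological_overlap",
           "detect_modules", "module_trait_correlation"]

# WGCNA-style color sequence for size-ranked module labels
_MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
)


@dataclass
class NetworkConfig:
    soft_power: int = 8
    min_module_size: int = 30
    cut_height: float = 0.99
    merge_cut: float = 0.25     # reserved for eigengene merging (not applied)
    signed: bool = False
    top_variable_genes: int = 5000

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")


@dataclass
class GeneModule:
    label: str
    gene_ids: list[str]
    eigengene: np.ndarray        # per-sample scores, zero mean / unit variance
    variance_explained: float
    sample_ids: list[str]


def _expression_for_network(expr: ExpressionMatrix, cfg: NetworkConfig):
    """Drop zero-variance genes, keep the top-variable subset."""
    var = expr.values.var(axis=1)
    keep = var > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d zero-variance genes before network construction", dropped)
    idx = np.nonzero(keep)[0]
    if len(idx) > cfg.top_variable_genes:
        order = idx[np.argsort(var[idx])[::-1][: cfg.top_variable_genes]]
        idx = np.sort(order)
    genes = [expr.gene_ids[i] for i in idx]
    return genes, expr.values[idx, :]


def build_adjacency(expr: ExpressionMatrix, cfg: NetworkConfig | None = None):
    """Soft-thresholded adjacency a_ij = |cor(g_i, g_j)|^beta (unsigned).

    Returns ``(gene_ids, adjacency)`` over the filtered gene universe.
    """
    cfg = cfg or NetworkConfig()
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    genes, values = _expression_for_network(expr, cfg)
    corr = np.corrcoef(values)
    corr = np.atleast_2d(corr)
    if cfg.signed:
        sim = (1 + corr) / 2
    else:
        sim = np.abs(corr)
    adj = sim**cfg.soft_power
    np.fill_diagonal(adj, 1.0)
    return genes, adj


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), where
    the shared-neighbor sum excludes u in {i, j} and k is the connectivity
    (row sum minus the diagonal)."""
    a = np.asarray(adjacency, dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if np.abs(a - a.T).max() > 1e-9:
        raise ValueError("adjacency must be symmetric")
    k = a.sum(axis=0) - np.diag(a)
    prod = a @ a
    # remove the u == i and u == j terms from the shared-neighbor sums
    shared = prod - np.diag(a)[:, None] * a - a * np.diag(a)[None, :]
    num = shared + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _eigengene(block: np.ndarray):
    """First PC of the standardized genes-x-samples block, standardized to
    zero mean / unit variance and oriented to positive mean gene loading."""
    z = (block - block.mean(axis=1, keepdims=True))
    sd = block.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = z / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    pc = vt[0]
    loadings = u[:, 0]
    if loadings.mean() < 0:
        pc, loadings = -pc, -loadings
    sd_pc = pc.std()
    pc = (pc - pc.mean()) / (sd_pc if sd_pc > 0 else 1.0)
    var_explained = float(s[0] ** 2 / (s**2).sum()) if s.size else 0.0
    return pc, var_explained


def detect_modules(
    expr: ExpressionMatrix,
    tom: np.ndarray,
    gene_ids: list[str],
    cfg: NetworkConfig | None = None,
) -> list[GeneModule]:
    """Cluster 1-TOM by average linkage, cut statically, enforce minimum size.

    Clusters below ``min_module_size`` fall into the ``grey`` (unassigned)
    module. Modules are labelled by size rank with WGCNA-style color names.
    """
    cfg = cfg or NetworkConfig()
    n = len(gene_ids)
    if tom.shape != (n, n):
        raise ValueError("TOM shape does not match gene list")
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2
    Z = linkage(squareform(diss, checks=False), method="average")
    assignment = fcluster(Z, t=cfg.cut_height, criterion="distance")

    gidx = {g: i for i, g in enumerate(expr.gene_ids)}
    groups: dict[int, list[str]] = {}
    for g, c in zip(gene_ids, assignment):
        groups.setdefault(int(c), []).append(g)
    sized = [(genes) for genes in groups.values() if len(genes) >= cfg.min_module_size]
    # deterministic label order: by size desc, then first gene ID
    sized.sort(key=lambda gs: (-len(gs), sorted(gs)[0]))
    grey = sorted(
        g for genes in groups.values() if len(genes) < cfg.min_module_size for g in genes
    )
    modules: list[GeneModule] = []
    for rank, genes in enumerate(sized):
        label = _MODULE_COLORS[rank] if rank < len(_MODULE_COLORS) else f"module{rank + 1}"
        genes = sorted(genes)
        block = expr.values[[gidx[g] for g in genes], :]
        pc, ve = _eigengene(block)
        modules.append(GeneModule(label, genes, pc, ve, list(expr.sample_ids)))
    if grey:
        block = expr.values[[gidx[g] for g in grey], :]
        pc, ve = _eigengene(block)
        modules.append(GeneModule("grey", grey, pc, ve, list(expr.sample_ids)))
    if not sized:
        logger.warning("all genes fell into grey; no modules detected")
    return modules


def module_trait_correlation(
    modules: list[GeneModule],
    dt: DiversityTable,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, GeneModule | None]:
    """Pearson correlation of each module eigengene with Shannon diversity.

    The best module maximizes |rho| among significant (p < alpha) non-grey
    modules; its eigengene sign is flipped if needed so the reported
    correlation is nonnegative. Returns (table, best_module_or_None).
    """
    shannon = dt.df.loc[~dt.df["degenerate"]].set_index("sample_id")["shannon"]
    rows = []
    candidates: list[tuple[float, float, GeneModule]] = []
    for mod in modules:
        common = [s for s in mod.sample_ids if s in shannon.index]
        if len(common) < 10:
            raise ValueError("need >= 10 overlapping samples for module-trait correlation")
        pos = {s: i for i, s in enumerate(mod.sample_ids)}
        eg = mod.eigengene[[pos[s] for s in common]]
        div = shannon.loc[common].to_numpy()
        rho, p = stats.pearsonr(eg, div)
        rows.append({"module": mod.label, "n_genes": len(mod.gene_ids),
                     "pearson_rho": float(rho), "p_value": float(p)})
        if mod.label != "grey":
            candidates.append((abs(rho), float(p), mod if rho >= 0 else _flip(mod)))
    table = pd.DataFrame(rows)
    significant = [(a, p, m) for a, p, m in candidates if p < alpha]
    if not significant:
        return table, None
    best = max(significant, key=lambda t: t[0])[2]
    return table, best


def _flip(mod: GeneModule) -> GeneModule:
    return GeneModule(mod.label, mod.gene_ids, -mod.eigengene,
                      mod.variance_explained, mod.sample_ids)
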