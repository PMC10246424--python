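"""Build a marker-gene x subgroup signature matrix from labelled single cells.

Marker selection uses a transparent one-vs-rest fold-change rule on
log1p-transformed expression; signature entries are arithmetic means of the
untransformed expression per subgroup. Ranking ties break lexicographically
by gene ID so the output is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CellLabeling, ExpressionMatrix

__all__ = ["MarkerParams", "SignatureMatrix", "select_markers", "build_signature"]


@dataclass
class MarkerParams:
    top_n: int = 50           # markers kept per subgroup
    min_fold: float = 2.0     # minimum one-vs-rest fold change (linear scale)
    min_frac: float = 0.25    # minimum expressing fraction within the subgroup
    min_cells: int = 10       # minimum cells per subgroup
    allow_relaxed: bool = False


@dataclass
class SignatureMatrix:
    """Mean expression of each marker gene per subgroup, with provenance."""

    marker_gene_ids: list[str]
    subgroup_ids: list[str]
    values: np.ndarray  # markers x K, nonnegative
    provenance: pd.DataFrame  # gene, subgroup, log2_fold_change, expressing_fraction

    def __post_init__(self) -> None:
        if len(self.subgroup_ids) < 2:
            raise ValueError("signature needs at least 2 subgroups")
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("signature values must be nonnegative")
        zero_rows = np.nonzero(self.values.sum(axis=1) == 0)[0]
        if zero_rows.size:
            bad = [self.marker_gene_ids[i] for i in zero_rows]
            raise ValueError(f"all-zero signature rows: {bad}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.marker_gene_ids,
                            columns=self.subgroup_ids)

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.values))


def _subgroup_means(sc: ExpressionMatrix, labels: CellLabeling):
    """Per-subgroup mean expression (linear and log1p) and expressing fraction."""
    col = {c: i for i, c in enumerate(sc.sample_ids)}
    vocab = labels.vocabulary
    n_g = sc.n_genes
    lin = np.empty((n_g, len(vocab)))
    logm = np.empty((n_g, len(vocab)))
    frac = np.empty((n_g, len(vocab)))
    counts = []
    for j, sg in enumerate(vocab):
        idx = [col[c] for c in labels.cells_of(sg)]
        counts.append(len(idx))
        block = sc.values[:, idx]
        lin[:, j] = block.mean(axis=1)
        logm[:, j] = np.log1p(block).mean(axis=1)
        frac[:, j] = (block > 0).mean(axis=1)
    return vocab, lin, logm, frac, counts


def select_markers(
    sc: ExpressionMatrix, labels: CellLabeling, params: MarkerParams | None = None
) -> pd.DataFrame:
    """Nominate marker genes per subgroup by one-vs-rest log fold-change.

    Returns a provenance frame (gene, subgroup, log2_fold_change,
    expressing_fraction) with one row per nomination; the deduplicated gene
    union is the marker list.
    """
    params = params or MarkerParams()
    labels.validate_against(sc)
    vocab, lin, logm, frac, counts = _subgroup_means(sc, labels)
    for sg, n in zip(vocab, counts):
        if n < params.min_cells:
            raise ValueError(f"subgroup {sg!r} has {n} cells (< min_cells={params.min_cells})")
    min_l2fc = np.log2(params.min_fold)
    rows = []
    for j, sg in enumerate(vocab):
        rest = np.delete(logm, j, axis=1).mean(axis=1)
        # one-vs-rest log2 fold-change on log1p scale
        l2fc = (logm[:, j] - rest) / np.log(2)
        cand = pd.DataFrame(
            {
                "gene": sc.gene_ids,
                "subgroup": sg,
                "log2_fold_change": l2fc,
                "expressing_fraction": frac[:, j],
            }
        )
        qual = cand[(cand["log2_fold_change"] >= min_l2fc)
                    & (cand["expressing_fraction"] >= params.min_frac)]
        if qual.empty:
            if not params.allow_relaxed:
                raise ValueError(
                    f"subgroup {sg!r} has no qualifying marker gene; "
                    "set allow_relaxed=True to keep its best-ranked genes"
                )
            warnings.warn(f"subgroup {sg!r}: no gene passes thresholds, relaxing", stacklevel=2)
            qual = cand[cand["expressing_fraction"] > 0]
        top = qual.sort_values(
            ["log2_fold_change", "gene"], ascending=[False, True], kind="mergesort"
        ).head(params.top_n)
        rows.append(top)
    prov = pd.concat(rows, ignore_index=True)
    return prov


def build_signature(
    sc: ExpressionMatrix,
    labels: CellLabeling,
    markers: pd.DataFrame | list[str],
) -> SignatureMatrix:
    """Aggregate marker expression into the signature matrix.

    Entry (g, k) is the arithmetic mean of gene g's untransformed expression
    over cells labelled k. Column order follows the subgroup vocabulary.
    """
    if isinstance(markers, pd.DataFrame):
        prov = markers
        gene_list = sorted(prov["gene"].unique())
    else:
        gene_list = list(dict.fromkeys(markers))
        prov = pd.DataFrame({"gene": gene_list, "subgroup": "user",
                             "log2_fold_change": np.nan, "expressing_fraction": np.nan})
    if not gene_list:
        raise ValueError("marker list is empty")
    missing = [g for g in gene_list if g not in set(sc.gene_ids)]
    if missing:
        raise ValueError(f"marker genes absent from matrix: {missing}")
    labels.validate_against(sc)
    vocab, lin, _, _, _ = _subgroup_means(sc, labels)
    gidx = {g: i for i, g in enumerate(sc.gene_ids)}
    values = lin[[gidx[g] for g in gene_list], :]
    return SignatureMatrix(gene_list, vocab, values, prov.reset_index(drop=True))
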