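"""Reference-based deconvolution of bulk expression.

Per-sample abundances are estimated in "absolute mode" — a non-negative
least-squares fit of the bulk column onto the signature columns, with no
sum-to-one constraint — and converted to proportions by dividing each
abundance by the per-sample total. An optional nu-SVR backend (classic
nu grid {0.25, 0.5, 0.75}, best fit kept by correlation) is provided for
comparison; NNLS is the default, deterministic solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io_formats import ExpressionMatrix
from .signature_builder import SignatureMatrix

__all__ = ["DeconvolutionParams", "AbundanceProfile", "FractionProfile",
           "deconvolve", "to_fractions"]


@dataclass
class DeconvolutionParams:
    mode: str = "nnls"          # {"nnls", "svr"}
    min_overlap: float = 0.5    # minimum fraction of signature genes found in bulk
    quantile_scale: bool = False


@dataclass
class AbundanceProfile:
    sample_ids: list[str]
    subgroup_ids: list[str]
    values: np.ndarray                      # samples x K, >= 0
    diagnostics: pd.DataFrame               # sample_id, residual_norm, r_squared
    degenerate: np.ndarray = field(default=None)  # all-zero abundance rows

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("abundances must be finite and nonnegative")
        if self.degenerate is None:
            self.degenerate = self.values.sum(axis=1) == 0
        self.degenerate = np.asarray(self.degenerate, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.subgroup_ids)


@dataclass
class FractionProfile:
    sample_ids: list[str]
    subgroup_ids: list[str]
    values: np.ndarray      # samples x K rows summing to 1 (or 0 if degenerate)
    degenerate: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)
        ok = ~self.degenerate
        sums = self.values[ok].sum(axis=1)
        if ok.any() and not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("non-degenerate fraction rows must sum to 1")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("fractions must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.subgroup_ids)


def _quantile_scale(m: np.ndarray) -> np.ndarray:
    """Map each column onto the mean sorted profile (quantile normalization)."""
    order = np.argsort(m, axis=0)
    ranks = np.empty_like(order)
    rows = np.arange(m.shape[0])
    for j in range(m.shape[1]):
        ranks[order[:, j], j] = rows
    mean_sorted = np.sort(m, axis=0).mean(axis=1)
    return mean_sorted[ranks]


def deconvolve(
    bulk: ExpressionMatrix,
    sig: SignatureMatrix,
    params: DeconvolutionParams | None = None,
) -> AbundanceProfile:
    """Estimate per-sample subgroup abundances from bulk expression.

    Solves ``min ||S x - b||_2, x >= 0`` per sample on the intersection of
    signature and bulk genes (consistently ordered). Raises when the overlap
    falls below ``min_overlap`` of the signature genes or below K genes.
    """
    params = params or DeconvolutionParams()
    bulk_idx = {g: i for i, g in enumerate(bulk.gene_ids)}
    shared = [g for g in sig.marker_gene_ids if g in bulk_idx]
    k = len(sig.subgroup_ids)
    frac_found = len(shared) / len(sig.marker_gene_ids)
    if frac_found < params.min_overlap or len(shared) < k:
        raise ValueError(
            f"signature/bulk gene overlap too small: {len(shared)}/"
            f"{len(sig.marker_gene_ids)} signature genes found "
            f"({frac_found:.1%}; need >= {params.min_overlap:.0%} and >= K={k})"
        )
    sig_rows = [sig.marker_gene_ids.index(g) for g in shared]
    S = sig.values[sig_rows, :]
    B = bulk.values[[bulk_idx[g] for g in shared], :]
    if params.quantile_scale:
        S = _quantile_scale(S)
        B = _quantile_scale(B)
    if np.linalg.matrix_rank(S) < k:
        warnings.warn("signature matrix is rank-deficient; NNLS proceeds without "
                      "pseudoinverse", stacklevel=2)

    n = bulk.n_samples
    X = np.zeros((n, k))
    resid = np.zeros(n)
    r2 = np.zeros(n)
    for j in range(n):
        b = B[:, j]
        if params.mode == "nnls":
            x, rnorm = nnls(S, b)
        elif params.mode == "svr":
            x, rnorm = _svr_solve(S, b)
        else:
            raise ValueError(f"unknown deconvolution mode {params.mode!r}")
        X[j] = x
        resid[j] = rnorm
        tss = ((b - b.mean()) ** 2).sum()
        r2[j] = 1.0 - rnorm**2 / tss if tss > 0 else np.nan
    diag = pd.DataFrame({"sample_id": bulk.sample_ids, "residual_norm": resid,
                         "r_squared": r2})
    return AbundanceProfile(list(bulk.sample_ids), list(sig.subgroup_ids), X, diag)


def _svr_solve(S: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float]:
    """nu-SVR backend: fit at nu in {0.25, 0.5, 0.75}, keep best by correlation,
    clip negative coefficients to zero (CIBERSORT convention)."""
    from sklearn.svm import NuSVR

    best_x, best_corr, best_rnorm = None, -np.inf, np.inf
    for nu in (0.25, 0.5, 0.75):
        model = NuSVR(kernel="linear", nu=nu, C=1.0)
        model.fit(S, b)
        x = np.clip(model.coef_.ravel(), 0.0, None)
        pred = S @ x
        rnorm = float(np.linalg.norm(b - pred))
        sd = pred.std()
        corr = float(np.corrcoef(pred, b)[0, 1]) if sd > 0 else -np.inf
        if corr > best_corr:
            best_x, best_corr, best_rnorm = x, corr, rnorm
    if best_x is None:
        best_x, best_rnorm = np.zeros(S.shape[1]), float(np.linalg.norm(b))
    return best_x, best_rnorm


def to_fractions(ab: AbundanceProfile) -> FractionProfile:
    """Row-normalize abundances to proportions; all-zero rows are flagged
    degenerate and left at zero rather than imputed."""
    totals = ab.values.sum(axis=1)
    degenerate = totals == 0
    values = np.zeros_like(ab.values)
    ok = ~degenerate
    values[ok] = ab.values[ok] / totals[ok, None]
    return FractionProfile(list(ab.sample_ids), list(ab.subgroup_ids), values, degenerate)
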