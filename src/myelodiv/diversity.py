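"""Ecological diversity indices over per-sample subgroup fractions.

Shannon entropy (natural log) is the primary index; Gini-Simpson and Pielou
evenness are computed alongside. Pielou's denominator uses the total number
of subgroups in the profile by default (keeping the index comparable across
samples); an observed-richness variant is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "shannon_index",
    "gini_simpson_index",
    "pielou_index",
    "diversity_table",
    "stratify_by_quantile",
    "DiversityTable",
    "StratifiedCohort",
]

_SIMPLEX_TOL = 1e-9


def _validate_simplex(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("fraction vector must be one-dimensional")
    if (p < 0).any():
        raise ValueError("fractions must be nonnegative")
    total = p.sum()
    if abs(total - 1.0) > _SIMPLEX_TOL:
        raise ValueError(f"fractions must sum to 1 (got {total!r})")
    return p


def shannon_index(p) -> float:
    """H = -sum p_i ln p_i, with 0*ln(0) taken as 0."""
    p = _validate_simplex(p)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def gini_simpson_index(p) -> float:
    """1 - sum p_i^2."""
    p = _validate_simplex(p)
    return float(1.0 - (p**2).sum())


def pielou_index(p, n: int) -> float:
    """Evenness H / ln(n); requires at least two categories."""
    if n < 2:
        raise ValueError("Pielou index requires n >= 2 categories")
    return shannon_index(p) / float(np.log(n))


@dataclass
class DiversityTable:
    """Per-sample diversity indices; Shannon is the primary index."""

    df: pd.DataFrame  # columns: sample_id, shannon, gini_simpson, pielou, n, degenerate

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].astype(str).tolist()

    def shannon(self) -> pd.Series:
        s = self.df.set_index("sample_id")["shannon"]
        return s[~self.df.set_index("sample_id")["degenerate"]]


@dataclass
class StratifiedCohort:
    """sample -> stratum label in {high, low, middle-excluded}."""

    labels: dict[str, str]
    thresholds: dict[str, float]
    scheme: str

    @property
    def high(self) -> list[str]:
        return [s for s, l in self.labels.items() if l == "high"]

    @property
    def low(self) -> list[str]:
        return [s for s, l in self.labels.items() if l == "low"]


def diversity_table(fractions, use_observed_richness: bool = False) -> DiversityTable:
    """Compute Shannon, Gini-Simpson and Pielou per sample.

    ``fractions`` is a :class:`~myelodiv.deconvolution.FractionProfile` or any
    object exposing ``sample_ids``, ``subgroup_ids``, ``values`` (samples x K)
    and optionally ``degenerate`` (boolean per-sample mask). Degenerate rows
    carry missing indices.
    """
    values = np.asarray(fractions.values, dtype=float)
    sample_ids = list(fractions.sample_ids)
    k_total = values.shape[1]
    degenerate = np.asarray(
        getattr(fractions, "degenerate", np.zeros(len(sample_ids), bool)), dtype=bool
    )

    rows = []
    for i, sid in enumerate(sample_ids):
        if degenerate[i]:
            rows.append((sid, np.nan, np.nan, np.nan, 0, True))
            continue
        p = values[i]
        n = int((p > 0).sum()) if use_observed_richness else k_total
        h = shannon_index(p)
        gs = gini_simpson_index(p)
        j = h / np.log(n) if n >= 2 else np.nan
        rows.append((sid, h, gs, j, n, False))
    df = pd.DataFrame(
        rows, columns=["sample_id", "shannon", "gini_simpson", "pielou", "n", "degenerate"]
    )
    return DiversityTable(df)


def stratify_by_quantile(
    dt: DiversityTable,
    q: float = 0.25,
    scheme: str = "quartile-extremes",
    index: str = "shannon",
) -> StratifiedCohort:
    """Split samples into high/low strata by a diversity index.

    ``quartile-extremes``: top ``q`` and bottom ``q``, middle excluded.
    ``median-split``: two halves, no exclusion. Ties are resolved so group
    sizes stay closest to nominal, breaking further ties by sample ID.
    """
    if not (0 < q <= 0.5):
        raise ValueError("q must lie in (0, 0.5]")
    if scheme not in ("quartile-extremes", "median-split"):
        raise ValueError(f"unknown stratification scheme {scheme!r}")
    sub = dt.df[~dt.df["degenerate"]]
    if len(sub) < 8:
        raise ValueError("need at least 8 non-degenerate samples to stratify")
    vals = sub[index].to_numpy(dtype=float)
    if np.min(vals) == np.max(vals):
        raise ValueError("no variation to stratify")
    # deterministic order: by value then sample ID
    order = sub.assign(_v=vals).sort_values(["_v", "sample_id"], kind="mergesort")
    ids = order["sample_id"].astype(str).tolist()
    n = len(ids)
    labels: dict[str, str] = {}
    if scheme == "median-split":
        cut = n // 2
        for s in ids[:cut]:
            labels[s] = "low"
        for s in ids[cut:]:
            labels[s] = "high"
        thresholds = {"median": float(np.median(vals))}
    else:
        n_tail = max(1, int(np.floor(q * n)))
        for s in ids[:n_tail]:
            labels[s] = "low"
        for s in ids[n_tail : n - n_tail]:
            labels[s] = "middle-excluded"
        for s in ids[n - n_tail :]:
            labels[s] = "high"
        svals = order["_v"].to_numpy()
        thresholds = {
            "low_max": float(svals[n_tail - 1]),
            "high_min": float(svals[n - n_tail]),
        }
    for sid in dt.df.loc[dt.df["degenerate"], "sample_id"]:
        labels[str(sid)] = "middle-excluded"
    return StratifiedCohort(labels, thresholds, scheme)
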