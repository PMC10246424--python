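"""Somatic-mutation contrasts between diversity strata.

Differential prevalence (per-gene chi-square on 2x2 mutated-by-stratum
tables), pairwise co-occurrence / mutual exclusivity (two-sided Fisher exact
tests), tumor mutation burden (mutations per megabase), and a "signature"
TMB restricted to a panel of stratum-relevant genes.

Conventions: a gene counts once per sample for presence-based statistics
(variants are deduplicated per sample-gene pair) while raw variant rows are
what TMB counts; the 2x2 odds ratio puts the high-diversity stratum in the
first row and mutated samples in the first column, with a Haldane-Anscombe
+0.5 correction when any cell is zero; silent variants are excluded from
prevalence and TMB by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import StratifiedCohort
from .io_formats import MutationTable, NON_SYNONYMOUS_CLASSES

__all__ = ["differential_prevalence", "somatic_interactions", "compute_tmb",
           "mutation_waterfall_summary", "build_signature_panel", "TMBResult"]


@dataclass
class TMBResult:
    df: pd.DataFrame          # sample, tmb_all, tmb_signature
    panel: list[str]
    genome_size_mb: float


def _presence(mut: MutationTable, non_synonymous_only: bool = True) -> pd.DataFrame:
    """Per-sample-per-gene deduplicated presence records."""
    df = mut.df
    if non_synonymous_only:
        df = df[df["variant_classification"].isin(NON_SYNONYMOUS_CLASSES)]
    return df[["sample_id", "gene"]].astype(str).drop_duplicates()


def _tier(p: float) -> str:
    if p < 0.0001:
        return "***"
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def differential_prevalence(
    mut: MutationTable,
    strata: StratifiedCohort,
    min_mutated: int = 3,
    yates: bool = False,
    non_synonymous_only: bool = True,
    differential_p: float = 0.01,
) -> pd.DataFrame:
    """Per-gene 2x2 chi-square contrast of mutation prevalence between strata.

    Returns one row per gene mutated in at least ``min_mutated`` samples
    overall, with counts, odds ratio (high stratum in the numerator),
    chi-square statistic, p-value, significance tier and a ``differential``
    flag at ``p < differential_p``.
    """
    high = set(strata.high)
    low = set(strata.low)
    if not high or not low:
        raise ValueError("both strata must be nonempty")
    pres = _presence(mut, non_synonymous_only)
    pres = pres[pres["sample_id"].isin(high | low)]
    n_high, n_low = len(high), len(low)
    rows = []
    for gene, grp in pres.groupby("gene", sort=True):
        samples = set(grp["sample_id"])
        if len(samples) < min_mutated:
            continue
        a = len(samples & high)          # high, mutated
        b = n_high - a                   # high, wild-type
        c = len(samples & low)           # low, mutated
        d = n_low - c                    # low, wild-type
        corrected = 0 in (a, b, c, d)
        if corrected:
            orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orat = (a * d) / (b * c)
        table = np.array([[a, b], [c, d]])
        if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
        rows.append(
            {
                "gene": gene,
                "count_high": a,
                "n_high": n_high,
                "count_low": c,
                "n_low": n_low,
                "odds_ratio": float(orat),
                "chi_square": float(chi2),
                "p_value": float(p),
                "tier": _tier(p),
                "differential": p < differential_p,
                "continuity_corrected": corrected,
            }
        )
    return pd.DataFrame(rows)


def somatic_interactions(
    mut: MutationTable,
    samples: list[str] | None = None,
    min_mutated: int = 5,
    top_genes: int = 25,
    non_synonymous_only: bool = True,
) -> pd.DataFrame:
    """Pairwise co-occurrence / mutual exclusivity by two-sided Fisher test.

    Only genes mutated in at least ``min_mutated`` of the given samples are
    tested, restricted to the ``top_genes`` most prevalent (the conventional
    default scope for this analysis; pass ``top_genes=None`` for all).
    Reported as one row per unordered pair with the exact p, the signed
    -log10 p (positive = co-occurring, negative = mutually exclusive) and a
    direction label, by the odds ratio of the 2x2 presence table.
    """
    pres = _presence(mut, non_synonymous_only)
    if samples is None:
        samples = sorted(pres["sample_id"].unique())
    sample_set = set(map(str, samples))
    pres = pres[pres["sample_id"].isin(sample_set)]
    n = len(sample_set)
    by_gene = {g: set(grp["sample_id"]) for g, grp in pres.groupby("gene")}
    genes = sorted(g for g, s in by_gene.items() if len(s) >= min_mutated)
    if top_genes is not None and len(genes) > top_genes:
        genes = sorted(
            sorted(genes, key=lambda g: (-len(by_gene[g]), g))[:top_genes]
        )
    if len(genes) < 2:
        raise ValueError(
            f"need >= 2 genes mutated in >= {min_mutated} samples, got {len(genes)}"
        )
    rows = []
    for i, g1 in enumerate(genes):
        for g2 in genes[i + 1 :]:
            s1, s2 = by_gene[g1], by_gene[g2]
            a = len(s1 & s2)
            b = len(s1) - a
            c = len(s2) - a
            d = n - a - b - c
            orat, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            direction = "co-occurring" if orat > 1 else "mutually-exclusive"
            sign = 1.0 if orat > 1 else -1.0
            log10p = -np.log10(max(p, 1e-300))
            rows.append(
                {
                    "gene1": g1,
                    "gene2": g2,
                    "n_both": a,
                    "p_value": float(p),
                    "signed_log10_p": float(sign * log10p),
                    "odds_ratio": float(orat) if np.isfinite(orat) else np.inf,
                    "direction": direction,
                }
            )
    return pd.DataFrame(rows)


def build_signature_panel(
    mut: MutationTable,
    strata: StratifiedCohort,
    top_k: int = 10,
    interaction_p: float = 0.05,
    differential_p: float = 0.01,
) -> list[str]:
    """Panel for signature TMB: the top-``top_k`` prevalent genes of each
    stratum, genes in significant pairwise interactions, and genes passing
    the differential-prevalence filter."""
    panel: set[str] = set()
    for grid in mutation_waterfall_summary(mut, strata, top_k=top_k).values():
        panel.update(grid.index)
    strat_samples = list(set(strata.high) | set(strata.low))
    try:
        inter = somatic_interactions(mut, strat_samples)
        sig = inter[inter["p_value"] < interaction_p]
        panel.update(sig["gene1"])
        panel.update(sig["gene2"])
    except ValueError:
        warnings.warn("too few recurrently mutated genes for interaction analysis; "
                      "panel built without interactions", stacklevel=2)
    diff = differential_prevalence(mut, strata, differential_p=differential_p)
    if len(diff):
        panel.update(diff.loc[diff["differential"], "gene"])
    return sorted(panel)


def compute_tmb(
    mut: MutationTable,
    genome_size_mb: float = 38.0,
    panel: list[str] | None = None,
    non_synonymous_only: bool = True,
    samples: list[str] | None = None,
) -> TMBResult:
    """Mutations per megabase, overall and restricted to a gene panel.

    Counts raw qualifying variant rows (not deduplicated presence). Samples
    without any qualifying mutation get TMB 0 when listed in ``samples``.
    """
    if genome_size_mb <= 0:
        raise ValueError("genome_size_mb must be positive")
    df = mut.df
    if non_synonymous_only:
        df = df[df["variant_classification"].isin(NON_SYNONYMOUS_CLASSES)]
    if samples is None:
        samples = sorted(df["sample_id"].astype(str).unique())
    counts = df.groupby("sample_id").size()
    panel = list(panel) if panel is not None else []
    panel_counts = df[df["gene"].isin(set(panel))].groupby("sample_id").size()
    rows = []
    for s in samples:
        total = int(counts.get(s, 0))
        sig = int(panel_counts.get(s, 0))
        rows.append({"sample_id": s, "tmb_all": total / genome_size_mb,
                     "tmb_signature": sig / genome_size_mb})
    return TMBResult(pd.DataFrame(rows), panel, genome_size_mb)


def mutation_waterfall_summary(
    mut: MutationTable,
    strata: StratifiedCohort,
    top_k: int = 10,
    non_synonymous_only: bool = True,
) -> dict[str, pd.DataFrame]:
    """Top-``top_k`` gene x sample presence grids per stratum.

    Genes rank by mutated-sample count (descending), ties broken
    lexicographically by gene ID. Grid cells hold the variant-class label
    (first by canonical order when a sample carries several) or ''.
    """
    out: dict[str, pd.DataFrame] = {}
    df = mut.df
    if non_synonymous_only:
        df = df[df["variant_classification"].isin(NON_SYNONYMOUS_CLASSES)]
    for name in ("high", "low"):
        ids = set(getattr(strata, name))
        if not ids:
            raise ValueError(f"stratum {name!r} is empty")
        sub = df[df["sample_id"].astype(str).isin(ids)]
        pres = sub[["sample_id", "gene"]].astype(str).drop_duplicates()
        freq = pres.groupby("gene").size().reset_index(name="count")
        freq = freq.sort_values(["count", "gene"], ascending=[False, True],
                                kind="mergesort").head(top_k)
        genes = freq["gene"].tolist()
        ordered = sorted(ids)
        grid = pd.DataFrame("", index=genes, columns=ordered)
        cls = sub[sub["gene"].isin(genes)].sort_values("variant_classification")
        for (g, s), grp in cls.groupby(["gene", "sample_id"]):
            grid.loc[g, str(s)] = grp["variant_classification"].iloc[0]
        out[name] = grid
    return out
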