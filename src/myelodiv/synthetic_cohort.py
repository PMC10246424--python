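"""Synthetic cohort generator.

Produces labelled single-cell expression, bulk expression, clinical outcomes
and somatic mutations with the statistical structure the analysis pipeline
assumes, so every downstream stage can be tested against ground truth:

* K subgroups with planted marker genes (fold ``marker_fold`` over background);
* bulk samples as noisy convex mixtures of the subgroup mean profiles;
* a co-expressed "module" gene block appended to the bulk matrix whose
  planted predictor genes are linear in the true Shannon diversity;
* exponential survival times whose log-hazard is linear in true diversity;
* binary response through a logistic link on diversity;
* per-gene mutation rates that differ between high/low diversity strata.

All randomness fans out from a single seed through named substreams
(:mod:`myelodiv._rng`), so changing one component's parameters does not
perturb the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import substream
from .diversity import shannon_index
from .io_formats import CellLabeling, ClinicalTable, ExpressionMatrix, MutationTable

__all__ = ["SimulationConfig", "GroundTruth", "simulate_single_cell", "simulate_bulk",
           "simulate_clinical", "simulate_mutations", "simulate_cohort"]


@dataclass
class SimulationConfig:
    # cohort shape
    n_subgroups: int = 15
    n_marker_genes_per_subgroup: int = 20
    n_background_genes: int = 200
    n_cells_per_subgroup: int = 50
    n_bulk_samples: int = 200
    mixture_concentration: tuple = ()  # empty -> flat Dirichlet(1,...,1)
    # expression model
    marker_fold: float = 8.0
    background_mean: float = 5.0
    nb_dispersion: float = 0.5
    noise_sd: float = 0.1
    # diversity-linked module block in bulk
    n_surrogate_genes: int = 5
    n_module_noise_genes: int = 95
    # clinical model
    baseline_hazard: float = 0.1
    hazard_coefficient: float = -1.0
    censoring_rate: float = 0.2
    response_intercept: float = -1.0
    response_slope: float = 1.0
    # mutation model
    n_mutation_panel_genes: int = 10
    n_mutation_background_genes: int = 600
    mutation_rate_high: float = 0.4
    mutation_rate_low: float = 0.1
    mutation_background_rate: float = 0.15
    tmb_dispersion: float = 0.9
    silent_fraction: float = 0.1
    genome_size_mb: float = 38.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subgroups < 2:
            raise ValueError("need at least 2 subgroups (K >= 2)")
        for name in ("n_marker_genes_per_subgroup", "n_cells_per_subgroup", "n_bulk_samples"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        self.mixture_concentration = tuple(float(a) for a in self.mixture_concentration)
        if self.mixture_concentration and (
            len(self.mixture_concentration) != self.n_subgroups
            or any(a <= 0 for a in self.mixture_concentration)
        ):
            raise ValueError("mixture_concentration must be K strictly positive reals")
        if np.isnan(self.hazard_coefficient):
            raise ValueError("hazard_coefficient must not be NaN")
        if not (0 <= self.censoring_rate <= 1):
            raise ValueError("censoring_rate must lie in [0, 1]")
        for name in ("mutation_rate_high", "mutation_rate_low", "mutation_background_rate",
                     "silent_fraction"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.genome_size_mb <= 0:
            raise ValueError("genome_size_mb must be positive")

    @property
    def concentration(self) -> np.ndarray:
        if self.mixture_concentration:
            return np.asarray(self.mixture_concentration, dtype=float)
        return np.ones(self.n_subgroups)

    @property
    def subgroup_ids(self) -> list[str]:
        return [f"SG{k + 1:02d}" for k in range(self.n_subgroups)]

    @property
    def marker_gene_ids(self) -> list[str]:
        return [
            f"MK{k + 1:02d}_{j + 1:03d}"
            for k in range(self.n_subgroups)
            for j in range(self.n_marker_genes_per_subgroup)
        ]

    @property
    def background_gene_ids(self) -> list[str]:
        return [f"BG{j + 1:04d}" for j in range(self.n_background_genes)]

    @property
    def surrogate_gene_ids(self) -> list[str]:
        return [f"SUR{j + 1:02d}" for j in range(self.n_surrogate_genes)]

    @property
    def module_noise_gene_ids(self) -> list[str]:
        return [f"MODN{j + 1:03d}" for j in range(self.n_module_noise_genes)]


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream recovery checks."""

    true_fractions: np.ndarray  # samples x K, simplex rows
    true_diversity: np.ndarray  # Shannon of each fraction row
    subgroup_profiles: np.ndarray  # mixture genes x K nonnegative means
    profile_gene_ids: list[str]
    subgroup_ids: list[str]
    sample_ids: list[str]
    planted_surrogate_genes: list[str]
    planted_coefficients: np.ndarray
    marker_genes: dict[str, list[str]] = field(default_factory=dict)
    mutation_panel_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        row_sums = self.true_fractions.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise ValueError("ground-truth fraction rows must be exact simplex points")
        recomputed = np.array([shannon_index(r) for r in self.true_fractions])
        if not np.allclose(recomputed, self.true_diversity, atol=1e-12):
            raise ValueError("stored true_diversity inconsistent with fractions")


# ---------------------------------------------------------------------------
# shared pieces
# ---------------------------------------------------------------------------


def _subgroup_profiles(config: SimulationConfig) -> tuple[list[str], np.ndarray]:
    """Gene x K mean-expression profiles for marker + background genes."""
    rng = substream(config.seed, "profiles")
    K = config.n_subgroups
    genes = config.marker_gene_ids + config.background_gene_ids
    n_mk = len(config.marker_gene_ids)
    profiles = np.empty((len(genes), K))
    profiles[:n_mk] = config.background_mean
    for k in range(K):
        lo = k * config.n_marker_genes_per_subgroup
        hi = lo + config.n_marker_genes_per_subgroup
        profiles[lo:hi, k] = config.marker_fold * config.background_mean
    # background genes share a per-gene mean across subgroups
    bg_means = config.background_mean * rng.lognormal(mean=0.0, sigma=0.5,
                                                      size=config.n_background_genes)
    profiles[n_mk:] = bg_means[:, None]
    return genes, profiles


def _ground_truth(config: SimulationConfig) -> GroundTruth:
    genes, profiles = _subgroup_profiles(config)
    rng = substream(config.seed, "fractions")
    fractions = rng.dirichlet(config.concentration, size=config.n_bulk_samples)
    fractions /= fractions.sum(axis=1, keepdims=True)  # exact simplex rows
    div = np.array([shannon_index(r) for r in fractions])
    rng_c = substream(config.seed, "surrogate-coefs")
    coefs = rng_c.uniform(0.8, 1.0, size=config.n_surrogate_genes)
    markers = {
        sg: config.marker_gene_ids[
            k * config.n_marker_genes_per_subgroup : (k + 1) * config.n_marker_genes_per_subgroup
        ]
        for k, sg in enumerate(config.subgroup_ids)
    }
    return GroundTruth(
        true_fractions=fractions,
        true_diversity=div,
        subgroup_profiles=profiles,
        profile_gene_ids=genes,
        subgroup_ids=config.subgroup_ids,
        sample_ids=[f"S{i + 1:04d}" for i in range(config.n_bulk_samples)],
        planted_surrogate_genes=config.surrogate_gene_ids,
        planted_coefficients=coefs,
        marker_genes=markers,
        mutation_panel_genes=[f"DIV{j + 1:02d}" for j in range(config.n_mutation_panel_genes)],
    )


# ---------------------------------------------------------------------------
# single cell
# ---------------------------------------------------------------------------


def simulate_single_cell(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, CellLabeling, GroundTruth]:
    """Labelled single-cell expression with planted subgroup markers.

    With ``noise_sd == 0`` the matrix holds the exact generator means (no
    sampling), so marker structure is noiseless. Otherwise counts are drawn
    from a negative binomial (Gamma-Poisson) with configurable dispersion,
    with a per-cell log-normal mean jitter of scale ``noise_sd``.
    """
    truth = _ground_truth(config)
    genes, profiles = truth.profile_gene_ids, truth.subgroup_profiles
    K = config.n_subgroups
    n_cells = config.n_cells_per_subgroup
    cell_ids: list[str] = []
    labels: dict[str, str] = {}
    cols = []
    rng = substream(config.seed, "single-cell")
    for k, sg in enumerate(config.subgroup_ids):
        mu = profiles[:, k]
        for c in range(n_cells):
            cid = f"{sg}_C{c + 1:04d}"
            cell_ids.append(cid)
            labels[cid] = sg
        if config.noise_sd == 0:
            block = np.repeat(mu[:, None], n_cells, axis=1)
        else:
            jitter = np.exp(rng.normal(0.0, config.noise_sd, size=(len(genes), n_cells))
                            - config.noise_sd**2 / 2)
            mean = mu[:, None] * jitter
            if config.nb_dispersion > 0:
                shape = 1.0 / config.nb_dispersion
                lam = rng.gamma(shape, mean * config.nb_dispersion)
                block = rng.poisson(lam).astype(float)
            else:
                block = rng.poisson(mean).astype(float)
        cols.append(block)
    values = np.concatenate(cols, axis=1)
    return ExpressionMatrix(genes, cell_ids, values), CellLabeling(labels), truth


# ---------------------------------------------------------------------------
# bulk
# ---------------------------------------------------------------------------

# fixed loadings of the appended module block (see module docstring):
# noise genes load on a latent factor F = _F_RHO * z(D) + sqrt(1-_F_RHO^2) * W,
# planted genes load weakly on F and directly on z(D).
_F_RHO = 0.7
_NOISE_F_LOADING = 1.0
_NOISE_RESID_SD = 0.5
_PLANTED_F_LOADING = 0.35
_PLANTED_RESID_SD = 0.9
_MODULE_BASE = 10.0


def simulate_bulk(config: SimulationConfig, truth: GroundTruth) -> ExpressionMatrix:
    """Bulk samples as convex mixtures of the subgroup profiles.

    The mixture genes get multiplicative log-normal noise of scale
    ``noise_sd``. A block of diversity-linked module genes (planted surrogate
    predictors plus co-expressed noise genes) is appended below the mixture
    genes; its values are linear in the standardized true Shannon diversity.
    """
    if truth.subgroup_profiles.shape[1] != truth.true_fractions.shape[1]:
        raise ValueError("subgroup_profiles and true_fractions disagree on K")
    rng = substream(config.seed, "bulk")
    clean = truth.subgroup_profiles @ truth.true_fractions.T  # genes x samples
    if config.noise_sd > 0:
        clean = clean * np.exp(rng.normal(0.0, config.noise_sd, size=clean.shape))
    blocks = [clean]
    gene_ids = list(truth.profile_gene_ids)

    n_sur = len(truth.planted_surrogate_genes)
    n_noise = config.n_module_noise_genes
    if n_sur or n_noise:
        div = truth.true_diversity
        sd = div.std()
        z = (div - div.mean()) / sd if sd > 0 else np.zeros_like(div)
        rng_m = substream(config.seed, "module-block")
        w = rng_m.normal(size=len(z))
        factor = _F_RHO * z + np.sqrt(1 - _F_RHO**2) * w
        if n_sur:
            eps = rng_m.normal(0.0, _PLANTED_RESID_SD, size=(n_sur, len(z)))
            planted = (
                _MODULE_BASE
                + _PLANTED_F_LOADING * factor[None, :]
                + truth.planted_coefficients[:, None] * z[None, :]
                + eps
            )
            blocks.append(np.clip(planted, 0.0, None))
            gene_ids += truth.planted_surrogate_genes
        if n_noise:
            loadings = _NOISE_F_LOADING * rng_m.uniform(0.9, 1.1, size=n_noise)
            eps = rng_m.normal(0.0, _NOISE_RESID_SD, size=(n_noise, len(z)))
            noise_block = _MODULE_BASE + loadings[:, None] * factor[None, :] + eps
            blocks.append(np.clip(noise_block, 0.0, None))
            gene_ids += config.module_noise_gene_ids
    values = np.concatenate(blocks, axis=0)
    return ExpressionMatrix(gene_ids, truth.sample_ids, values)


# ---------------------------------------------------------------------------
# clinical
# ---------------------------------------------------------------------------

_SUBTYPES = ("LuminalA", "LuminalB", "HER2", "Basal")


def simulate_clinical(config: SimulationConfig, truth: GroundTruth) -> ClinicalTable:
    """Exponential survival with log-hazard linear in true diversity.

    Event hazard for sample i is ``baseline_hazard * exp(beta * D_i)``, so a
    Cox model on true diversity recovers ``hazard_coefficient`` exactly in
    expectation. Censoring is an independent exponential calibrated so the
    marginal censored fraction approximates ``censoring_rate``. Response is
    Bernoulli with a logistic link on diversity.
    """
    rng = substream(config.seed, "clinical")
    div = truth.true_diversity
    rates = config.baseline_hazard * np.exp(config.hazard_coefficient * div)
    t_event = rng.exponential(1.0 / rates)
    if config.censoring_rate > 0:
        if config.censoring_rate >= 1:
            raise ValueError("censoring_rate must be < 1 to observe events")
        lam_c = config.censoring_rate / (1 - config.censoring_rate) * np.exp(
            np.mean(np.log(rates))
        )
        t_cens = rng.exponential(1.0 / lam_c, size=len(div))
    else:
        t_cens = np.full(len(div), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    p_resp = expit(config.response_intercept + config.response_slope * div)
    response = rng.binomial(1, p_resp)
    age = np.round(rng.normal(58, 12, size=len(div)).clip(25, 90), 1)
    subtype = rng.choice(_SUBTYPES, size=len(div))
    df = pd.DataFrame(
        {
            "sample_id": truth.sample_ids,
            "time": time,
            "event": event,
            "response": response,
            "age": age,
            "subtype": subtype,
        }
    )
    return ClinicalTable(df)


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

_NONSYN_DRAW = (
    ("Missense_Mutation", 0.6),
    ("Nonsense_Mutation", 0.1),
    ("Frame_Shift_Del", 0.1),
    ("Frame_Shift_Ins", 0.05),
    ("In_Frame_Del", 0.05),
    ("Splice_Site", 0.1),
)


def simulate_mutations(config: SimulationConfig, truth: GroundTruth) -> MutationTable:
    """MAF-style somatic events with stratum-dependent rates on a planted panel.

    Samples in the top quartile of true diversity draw panel-gene mutations
    at ``mutation_rate_high``; all other samples at ``mutation_rate_low``.
    Background genes mutate at a common rate modulated per sample by a
    log-normal multiplier of scale ``tmb_dispersion`` (mean 1), mimicking
    the heavy-tailed per-patient mutation burden seen in real cohorts.
    """
    rng = substream(config.seed, "mutations")
    div = truth.true_diversity
    hi_cut = np.quantile(div, 0.75)
    is_high = div >= hi_cut

    classes = [c for c, _ in _NONSYN_DRAW]
    probs = np.array([p for _, p in _NONSYN_DRAW])
    probs = probs / probs.sum()

    bg_genes = np.array(
        [f"MBG{j + 1:04d}" for j in range(config.n_mutation_background_genes)]
    )
    panel = np.array(truth.mutation_panel_genes)
    burden = np.exp(
        rng.normal(-config.tmb_dispersion**2 / 2, config.tmb_dispersion, size=len(div))
    )
    sample_col: list[str] = []
    gene_col: list[str] = []
    for i, sid in enumerate(truth.sample_ids):
        rate_panel = config.mutation_rate_high if is_high[i] else config.mutation_rate_low
        hit_p = panel[rng.random(len(panel)) < rate_panel] if len(panel) else panel
        p_bg = min(1.0, config.mutation_background_rate * burden[i])
        hit_b = bg_genes[rng.random(len(bg_genes)) < p_bg] if p_bg > 0 else bg_genes[:0]
        hits = np.concatenate([hit_p, hit_b])
        sample_col += [sid] * len(hits)
        gene_col += hits.tolist()
    n_rows = len(gene_col)
    vc = np.array(classes, dtype=object)[rng.choice(len(classes), size=n_rows, p=probs)]
    if config.silent_fraction > 0:
        vc[rng.random(n_rows) < config.silent_fraction] = "Silent"
    df = pd.DataFrame(
        {
            "sample_id": sample_col,
            "gene": gene_col,
            "variant_classification": vc,
            "protein_position": rng.integers(1, 1001, size=n_rows),
        }
    )
    df["protein_position"] = df["protein_position"].astype("Int64")
    return MutationTable(df)


# ---------------------------------------------------------------------------
# convenience
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimulationConfig):
    """Generate every component of a synthetic cohort in one call."""
    sc, labels, truth = simulate_single_cell(config)
    bulk = simulate_bulk(config, truth)
    clinical = simulate_clinical(config, truth)
    mutations = simulate_mutations(config, truth)
    return sc, labels, bulk, clinical, mutations, truth
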