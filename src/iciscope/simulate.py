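"""Synthetic melanoma-like cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* bulk expression as convex mixtures of cell-type signature profiles with
  multiplicative log-normal noise,
* three planted immune subtypes (inflamed / desert / excluded) encoded as
  subtype-specific Dirichlet concentrations over cell-type fractions,
* exponential survival whose hazard depends on a latent immune-activity
  score (proportional hazards hold exactly),
* per-sample somatic mutation tables with group-dependent gene mutation
  rates and Poisson mutation burden,
* ordinal therapy-response labels (CR/PR/SD/PD) from a proportional-odds
  model on the latent immune score.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .deconvolution import CellFractionTable
from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection, MutationTable

#: 22 immune phenotypes, mirroring the usual LM22 panel.
DEFAULT_CELL_TYPES = (
    "B cells naive",
    "B cells memory",
    "Plasma cells",
    "T cells CD8",
    "T cells CD4 naive",
    "T cells CD4 memory resting",
    "T cells CD4 memory activated",
    "T cells follicular helper",
    "T cells regulatory (Tregs)",
    "T cells gamma delta",
    "NK cells resting",
    "NK cells activated",
    "Monocytes",
    "Macrophages M0",
    "Macrophages M1",
    "Macrophages M2",
    "Dendritic cells resting",
    "Dendritic cells activated",
    "Mast cells resting",
    "Mast cells activated",
    "Eosinophils",
    "Neutrophils",
)

#: Effector types of the inflamed phenotype (the subtype-A signature);
#: their summed fraction is the latent immune-activity score that drives
#: survival and response in the cohort.
IMMUNE_ACTIVITY_TYPES = (
    "T cells CD8",
    "NK cells activated",
    "T cells CD4 memory activated",
    "T cells follicular helper",
)

#: Relative Dirichlet weight multipliers per planted subtype: A inflamed
#: (effector-rich), B desert (M0/resting-dominated), C excluded
#: (B cell / Treg / M2-rich).
DEFAULT_SUBTYPE_WEIGHTS = {
    "A": {
        "T cells CD8": 8.0,
        "NK cells activated": 5.0,
        "T cells CD4 memory activated": 5.0,
        "T cells follicular helper": 4.0,
        "Macrophages M1": 3.0,
    },
    "B": {
        "Macrophages M0": 10.0,
        "Mast cells activated": 4.0,
        "NK cells resting": 4.0,
    },
    "C": {
        "B cells naive": 5.0,
        "B cells memory": 4.0,
        "T cells regulatory (Tregs)": 5.0,
        "Macrophages M1": 3.0,
        "Macrophages M2": 5.0,
    },
}

NONSYN_CLASSES = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Nonstop_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
)

RESPONSE_CATEGORIES = ("PD", "SD", "PR", "CR")  # worst to best


def make_signature_matrix(
    n_cell_types: int = 22,
    markers_per_type: int = 10,
    expression_level: float = 100.0,
    background_level: float = 1.0,
    jitter_sd: float = 0.1,
    seed: int | None = None,
    cell_types: tuple[str, ...] | None = None,
) -> ExpressionMatrix:
    """Block-structured cell-type signature matrix (an LM22-style analogue).

    Each cell type owns ``markers_per_type`` marker genes expressed at
    ``expression_level`` in its own column and ``background_level`` elsewhere,
    with gene-wise log-normal jitter of log-sd ``jitter_sd``.
    """
    if n_cell_types < 2 or markers_per_type < 1:
        raise ValueError("need >= 2 cell types and >= 1 marker per type")
    if expression_level <= 0 or background_level < 0:
        raise ValueError("expression_level must be positive, background >= 0")
    if cell_types is None:
        if n_cell_types <= len(DEFAULT_CELL_TYPES):
            cell_types = DEFAULT_CELL_TYPES[:n_cell_types]
        else:
            cell_types = tuple(f"cell_type_{i:02d}" for i in range(n_cell_types))
    rng = np.random.default_rng(seed)
    n_genes = n_cell_types * markers_per_type
    base = np.full((n_genes, n_cell_types), float(background_level))
    gene_ids = []
    for k, ct in enumerate(cell_types):
        sl = slice(k * markers_per_type, (k + 1) * markers_per_type)
        base[sl, k] = expression_level
        short = ct.replace(" ", "_").replace("(", "").replace(")", "")
        gene_ids.extend(f"{short}__marker{i:02d}" for i in range(markers_per_type))
    jitter = np.exp(rng.normal(0.0, jitter_sd, size=base.shape))
    df = pd.DataFrame(base * jitter, index=gene_ids, columns=list(cell_types))
    return ExpressionMatrix(df, scale="linear")


def subtype_alphas(
    cell_types: list[str],
    weights: dict[str, dict[str, float]] | None = None,
    base_alpha: float = 1.0,
) -> dict[str, np.ndarray]:
    """Dirichlet concentration vectors per subtype from relative weights."""
    weights = weights if weights is not None else DEFAULT_SUBTYPE_WEIGHTS
    alphas = {}
    for subtype, w in weights.items():
        alpha = np.full(len(cell_types), base_alpha)
        for ct, mult in w.items():
            if ct in cell_types:
                alpha[cell_types.index(ct)] = base_alpha * mult
        alphas[subtype] = alpha
    return alphas


def simulate_mixtures(
    sig: ExpressionMatrix,
    n_samples: int,
    dirichlet_alpha_per_subtype: dict[str, np.ndarray],
    noise_sd: float = 0.2,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, CellFractionTable, pd.Series]:
    """Draw bulk samples as noisy convex mixtures of signature columns.

    Sample j of subtype s draws fractions f ~ Dirichlet(alpha_s); its bulk
    column is sig @ f, multiplied gene-wise by exp(N(0, noise_sd^2)).
    Subtypes are assigned round-robin so group sizes are balanced.
    """
    n_types = sig.shape[1]
    for subtype, alpha in dirichlet_alpha_per_subtype.items():
        alpha = np.asarray(alpha, dtype=float)
        if len(alpha) != n_types:
            raise ValueError(f"alpha for subtype {subtype!r} has wrong length")
        if (alpha <= 0).any():
            raise ValueError(f"alpha entries for subtype {subtype!r} must be > 0")
    rng = np.random.default_rng(seed)
    subtype_names = sorted(dirichlet_alpha_per_subtype)
    labels = [subtype_names[j % len(subtype_names)] for j in range(n_samples)]
    S = sig.values
    cols, fracs = [], []
    for j in range(n_samples):
        f = rng.dirichlet(dirichlet_alpha_per_subtype[labels[j]])
        clean = S @ f
        noise = np.exp(rng.normal(0.0, noise_sd, size=len(clean))) if noise_sd > 0 else 1.0
        cols.append(clean * noise)
        fracs.append(f)
    sample_ids = [f"S{j:04d}" for j in range(n_samples)]
    bulk = ExpressionMatrix(
        pd.DataFrame(np.column_stack(cols), index=sig.gene_ids, columns=sample_ids),
        scale="linear",
    )
    truth = CellFractionTable(
        pd.DataFrame(fracs, index=sample_ids, columns=sig.data.columns)
    )
    return bulk, truth, pd.Series(labels, index=sample_ids, name="subtype")


def simulate_survival(
    score: pd.Series,
    baseline_hazard: float = 0.01,
    log_hr_per_unit: float = -0.7,
    censor_rate: float = 0.3,
    seed: int | None = None,
    time_unit: str = "days",
) -> ClinicalTable:
    """Exponential survival with hazard = baseline * exp(log_hr * score).

    Censoring is independent Uniform(0, tau) with tau solved numerically so
    the expected censored fraction equals ``censor_rate``; independence keeps
    Cox estimation unbiased.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    hazards = baseline_hazard * np.exp(log_hr_per_unit * score.to_numpy(dtype=float))
    event_times = rng.exponential(1.0 / hazards)
    if censor_rate == 0:
        times, events = event_times, np.ones(len(score), dtype=int)
    else:
        # expected censored fraction under C ~ U(0, tau): mean_i (1-exp(-l_i tau))/(l_i tau)
        def censored_frac(tau: float) -> float:
            x = hazards * tau
            return float(np.mean((1.0 - np.exp(-x)) / x))

        lo, hi = 1e-9, 1.0
        while censored_frac(hi) > censor_rate:
            hi *= 2.0
            if hi > 1e12:
                break
        tau = brentq(lambda t: censored_frac(t) - censor_rate, lo, hi)
        censor_times = rng.uniform(0.0, tau, size=len(score))
        events = (event_times <= censor_times).astype(int)
        times = np.minimum(event_times, censor_times)
    df = pd.DataFrame({"os_time": times, "os_event": events}, index=score.index)
    df.index.name = "sample_id"
    return ClinicalTable(df, time_unit=time_unit)


def simulate_mutations(
    sample_groups: pd.Series,
    genes: list[str],
    base_rate: float = 0.08,
    enriched_genes_with_odds: dict[str, dict[str, float]] | None = None,
    mean_tmb_per_group: dict[str, float] | None = None,
    n_background_genes: int = 300,
    seed: int | None = None,
) -> MutationTable:
    """Somatic mutation records with group-dependent gene rates.

    Per sample: total non-synonymous count ~ Poisson(mean TMB of its group);
    each listed gene mutates with probability base_rate times the group's
    odds multiplier (clipped to [0, 1]); the remaining count is filled with
    background passenger genes so that per-sample burden keeps the Poisson
    marginal.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    enriched = enriched_genes_with_odds or {}
    for g, odds in enriched.items():
        if any(o < 0 for o in odds.values()):
            raise ValueError(f"odds multipliers for {g!r} must be > 0")
    groups = sorted(sample_groups.unique())
    mean_tmb = mean_tmb_per_group or {g: 30.0 for g in groups}
    rng = np.random.default_rng(seed)
    background = [f"PSG{i:04d}" for i in range(n_background_genes)]
    records = []
    for sample, group in sample_groups.items():
        total = rng.poisson(mean_tmb[group])
        hits = []
        for gene in genes:
            p = base_rate * enriched.get(gene, {}).get(group, 1.0)
            p = min(p, 1.0)
            if p > 0 and rng.random() < p:
                hits.append(gene)
        for gene in hits:
            records.append((sample, gene, "Missense_Mutation"))
        n_bg = max(0, total - len(hits))
        for gene in rng.choice(background, size=n_bg, replace=True):
            cls = NONSYN_CLASSES[rng.integers(len(NONSYN_CLASSES))]
            records.append((sample, gene, cls))
    df = pd.DataFrame(records, columns=["sample_id", "gene", "variant_classification"])
    return MutationTable(df)


def simulate_response(
    score: pd.Series,
    beta: float = 1.5,
    thresholds: tuple[float, float, float] = (-0.4, 0.8, 1.8),
    seed: int | None = None,
) -> pd.Series:
    """Ordinal CR/PR/SD/PD response from a proportional-odds model.

    P(response worse or equal to category k | x) = logistic(theta_k - beta*x)
    on the z-scored latent score; beta > 0 means higher immune activity gives
    better response.
    """
    rng = np.random.default_rng(seed)
    x = score.to_numpy(dtype=float)
    z = (x - x.mean()) / x.std() if x.std() > 0 else np.zeros_like(x)
    theta = np.asarray(thresholds)
    cum = 1.0 / (1.0 + np.exp(-(theta[None, :] - beta * z[:, None])))
    u = rng.random(len(z))
    idx = (u[:, None] > cum).sum(axis=1)  # 0=PD .. 3=CR
    return pd.Series(
        [RESPONSE_CATEGORIES[i] for i in idx], index=score.index, name="response"
    )


@dataclass
class SyntheticCohort:
    """A complete simulated cohort with ground truth for every stage."""

    expression: ExpressionMatrix  # linear scale
    signature: ExpressionMatrix
    true_fractions: CellFractionTable
    true_subtype: pd.Series
    immune_activity: pd.Series  # latent score: summed effector fractions
    clinical: ClinicalTable
    mutations: MutationTable
    response: pd.Series
    gene_sets: GeneSetCollection
    seed: int

    def __post_init__(self) -> None:
        ids = list(self.expression.sample_ids)
        for other in (
            self.true_fractions.sample_ids,
            list(self.true_subtype.index),
            self.clinical.sample_ids,
            list(self.response.index),
        ):
            if list(other) != ids:
                raise ValueError("cohort component tables disagree on sample ids")


def simulate_cohort(
    n_samples: int = 300,
    n_cell_types: int = 22,
    markers_per_type: int = 10,
    noise_sd: float = 0.2,
    baseline_hazard: float = 1 / 1200,
    log_hr_per_unit: float = -0.7,
    censor_rate: float = 0.3,
    mutation_genes: list[str] | None = None,
    mutation_odds_low_over_high: float = 2.5,
    mean_tmb: tuple[float, float] = (25.0, 35.0),
    seed: int = 0,
) -> SyntheticCohort:
    """Generate the default study cohort.

    Three planted immune subtypes over ``n_cell_types`` cell types; survival
    hazard decreases with the z-scored latent immune-activity score
    (``log_hr_per_unit`` < 0 gives immune-rich samples longer survival);
    mutation burden and driver-gene rates are higher in the immune-low half,
    mirroring the negative infiltration/TMB association seen in melanoma.
    """
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=5)
    sig = make_signature_matrix(
        n_cell_types, markers_per_type, seed=int(sub_seeds[0])
    )
    cell_types = list(sig.data.columns)
    alphas = subtype_alphas(cell_types)
    bulk, fractions, subtype = simulate_mixtures(
        sig, n_samples, alphas, noise_sd=noise_sd, seed=int(sub_seeds[1])
    )
    activity_cols = [c for c in IMMUNE_ACTIVITY_TYPES if c in cell_types]
    immune_activity = fractions.data[activity_cols].sum(axis=1)
    immune_activity.name = "immune_activity"
    z = (immune_activity - immune_activity.mean()) / immune_activity.std()
    clinical = simulate_survival(
        z,
        baseline_hazard=baseline_hazard,
        log_hr_per_unit=log_hr_per_unit,
        censor_rate=censor_rate,
        seed=int(sub_seeds[2]),
    )
    if mutation_genes is None:
        mutation_genes = [f"DRV{i:02d}" for i in range(12)]
    immune_group = pd.Series(
        np.where(z >= z.median(), "immune_high", "immune_low"),
        index=z.index,
    )
    odds = {
        g: {"immune_low": mutation_odds_low_over_high, "immune_high": 1.0}
        for g in mutation_genes[: len(mutation_genes) // 2]
    }
    mutations = simulate_mutations(
        immune_group,
        mutation_genes,
        enriched_genes_with_odds=odds,
        mean_tmb_per_group={"immune_high": mean_tmb[0], "immune_low": mean_tmb[1]},
        seed=int(sub_seeds[3]),
    )
    response = simulate_response(z, seed=int(sub_seeds[4]))

    # immune set: markers of effector types; "stromal" analogue: markers of
    # the resting/innate types that dominate the excluded phenotype
    gene_ids = sig.gene_ids
    immune_set = [
        g
        for ct in IMMUNE_ACTIVITY_TYPES
        for g in gene_ids
        if g.startswith(ct.replace(" ", "_").replace("(", "").replace(")", "") + "__")
    ]
    stromal_types = ("Mast cells resting", "Macrophages M2", "Dendritic cells resting")
    stromal_set = [
        g
        for ct in stromal_types
        for g in gene_ids
        if g.startswith(ct.replace(" ", "_").replace("(", "").replace(")", "") + "__")
    ]
    gene_sets = GeneSetCollection(
        {"IMMUNE": immune_set or gene_ids[:10], "STROMAL": stromal_set or gene_ids[-10:]}
    )
    clinical.data["response"] = response
    return SyntheticCohort(
        expression=bulk,
        signature=sig,
        true_fractions=fractions,
        true_subtype=subtype,
        immune_activity=immune_activity,
        clinical=clinical,
        mutations=mutations,
        response=response,
        gene_sets=gene_sets,
        seed=seed,
    )
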