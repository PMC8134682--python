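"""Tumor mutation burden and ICI-group somatic-alteration contrasts.

TMB is the count of non-synonymous records per sample (the conventional MAF
classification set). Per-gene mutation frequencies are contrasted between
high and low ICI-score groups with Yates-corrected 2x2 chi-square tests, the
correlation between score and burden is Spearman's rho, and an
oncoprint-style sample x gene classification matrix (multi-hit collapsed)
summarizes the top drivers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .io import ClinicalTable, MutationTable
from .survival import KMCurve, km_by_group, logrank_test

logger = logging.getLogger(__name__)

#: Variant classifications that count toward TMB.
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)


@dataclass
class TMBTable:
    """Per-sample non-synonymous mutation counts and high/low TMB groups."""

    data: pd.DataFrame  # sample-indexed: nonsyn_count, tmb_group
    threshold_used: float

    def __post_init__(self) -> None:
        if (self.data["nonsyn_count"] < 0).any():
            raise ValueError("mutation counts must be non-negative")
        want = np.where(self.data["nonsyn_count"] > self.threshold_used, "high", "low")
        if not (self.data["tmb_group"] == want).all():
            raise ValueError("tmb_group inconsistent with threshold")


@dataclass
class GeneGroupContingency:
    """2x2 wild/mutant x high/low table with Yates-corrected chi-square."""

    gene: str
    high_wild: int
    high_mut: int
    low_wild: int
    low_mut: int
    chi2: float
    p: float
    degenerate: bool = False  # a zero margin makes the test ill-posed


def _nonsyn(mut: MutationTable) -> pd.DataFrame:
    rec = mut.records
    return rec[rec["variant_classification"].isin(NONSYNONYMOUS_CLASSES)]


def compute_tmb(
    mut: MutationTable, sample_ids: list[str], threshold: float | None = None
) -> TMBTable:
    """Count non-synonymous records per sample; split high/low at a threshold.

    Samples absent from the MAF count 0 (logged). The default threshold is
    the cohort median count.
    """
    counts = _nonsyn(mut).groupby("sample_id").size()
    absent = [s for s in sample_ids if s not in counts.index]
    if absent:
        logger.info("%d samples absent from MAF; TMB set to 0", len(absent))
    full = counts.reindex(sample_ids).fillna(0).astype(int)
    thr = float(full.median()) if threshold is None else float(threshold)
    data = pd.DataFrame(
        {
            "nonsyn_count": full,
            "tmb_group": np.where(full > thr, "high", "low"),
        }
    )
    data.index.name = "sample_id"
    return TMBTable(data, threshold_used=thr)


def gene_group_chisq(
    mut: MutationTable, ici_groups: pd.Series, gene: str
) -> GeneGroupContingency:
    """Yates-corrected chi-square for one gene's mutation frequency by group.

    A sample is "mutant" if it carries >= 1 non-synonymous record for the
    gene; samples in ``ici_groups`` but absent from the MAF are wild-type.
    """
    if not {"high", "low"} <= set(ici_groups.unique()):
        raise ValueError("ici_groups must contain both 'high' and 'low'")
    ns = _nonsyn(mut)
    mutated = set(ns.loc[ns["gene"] == gene, "sample_id"])
    is_mut = ici_groups.index.isin(mutated)
    is_high = (ici_groups == "high").to_numpy()
    hw = int((is_high & ~is_mut).sum())
    hm = int((is_high & is_mut).sum())
    lw = int((~is_high & ~is_mut).sum())
    lm = int((~is_high & is_mut).sum())
    return contingency_chisq(gene, hw, hm, lw, lm)


def contingency_chisq(
    gene: str, high_wild: int, high_mut: int, low_wild: int, low_mut: int
) -> GeneGroupContingency:
    """Yates-corrected chi-square on explicit 2x2 counts."""
    table = np.array([[high_wild, high_mut], [low_wild, low_mut]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return GeneGroupContingency(
            gene, high_wild, high_mut, low_wild, low_mut,
            chi2=np.nan, p=np.nan, degenerate=True,
        )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return GeneGroupContingency(
        gene, high_wild, high_mut, low_wild, low_mut, chi2=float(chi2), p=float(p)
    )


def mutation_frequency_table(
    mut: MutationTable, ici_groups: pd.Series, top_n: int = 20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ranked per-gene mutation frequencies plus an oncoprint-style matrix.

    Genes are ranked by overall mutated-sample fraction (ties alphabetical);
    the matrix holds each top gene's classification per sample, with two or
    more distinct records collapsing to ``Multi_Hit``.
    """
    ns = _nonsyn(mut)
    ns = ns[ns["sample_id"].isin(ici_groups.index)]
    n_total = len(ici_groups)
    n_high = int((ici_groups == "high").sum())
    n_low = n_total - n_high
    rows = []
    for gene, sub in ns.groupby("gene"):
        samples = set(sub["sample_id"])
        n_mut = len(samples)
        h_mut = sum(ici_groups.get(s) == "high" for s in samples)
        rows.append(
            {
                "gene": gene,
                "frequency": n_mut / n_total,
                "high_frequency": h_mut / n_high if n_high else np.nan,
                "low_frequency": (n_mut - h_mut) / n_low if n_low else np.nan,
                "n_mutated": n_mut,
            }
        )
    freq = pd.DataFrame(rows)
    if freq.empty:
        return freq, pd.DataFrame(index=ici_groups.index)
    freq = freq.sort_values(["frequency", "gene"], ascending=[False, True])
    freq["rank"] = np.arange(1, len(freq) + 1)
    freq = freq.set_index("gene")
    top_genes = list(freq.index[:top_n])
    sub = ns[ns["gene"].isin(top_genes)]
    onco = pd.DataFrame("", index=list(ici_groups.index), columns=top_genes)
    grouped = sub.groupby(["sample_id", "gene"])["variant_classification"]
    for (sample, gene), classes in grouped:
        onco.loc[sample, gene] = (
            "Multi_Hit" if len(classes) >= 2 else classes.iloc[0]
        )
    return freq, onco


def score_tmb_correlation(ici_scores, tmb) -> tuple[float, float]:
    """Spearman rank correlation (tie-corrected) between score and burden."""
    x = np.asarray(ici_scores, dtype=float)
    y = np.asarray(tmb, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def bivariate_survival(
    tmb_groups: pd.Series, ici_groups: pd.Series, clinical: ClinicalTable
) -> tuple[dict[str, KMCurve], float, float]:
    """KM curves and a global log-rank over the four TMB x ICI groups."""
    df = clinical.data
    combined = (
        "TMB-" + tmb_groups.loc[df.index].astype(str)
        + "/ICI-" + ici_groups.loc[df.index].astype(str)
    )
    sizes = combined.value_counts()
    empty = {
        f"TMB-{a}/ICI-{b}" for a in ("high", "low") for b in ("high", "low")
    } - set(sizes.index)
    if empty:
        logger.warning("empty combination groups dropped: %s", sorted(empty))
    curves = km_by_group(clinical, combined)
    chi2, p = logrank_test(df["os_time"], df["os_event"], combined.to_numpy())
    return curves, chi2, p


def load_published_driver_contingency() -> pd.DataFrame:
    """Published per-gene 2x2 mutation counts for high/low ICI-score groups
    of a TCGA melanoma cohort (197 high / 250 low samples), with the p-values
    as printed; used as a regression fixture for the chi-square machinery."""
    path = resources.files("iciscope.data") / "driver_gene_contingency.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")
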