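"""Moderated-t differential expression with empirical-Bayes shrinkage.

Per-gene two-sample contrasts on log2-scale expression. Residual variances
are shrunk toward a common prior fitted by moment matching on the log
variances (the scaled-F / inverse-chi-square hierarchy): with per-gene
variance s_g^2 on d_g df and prior (d0, s0^2),

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
    t~_g   = log2FC_g / (s~_g * c),   t~_g ~ t on d0 + d_g df under the null,

where c = sqrt(1/n1 + 1/n2). The prior is estimated from the marginal
distribution of log s_g^2 using digamma/trigamma moments, the standard
empirical-Bayes scheme for microarray-scale data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match the scaled-F prior (d0, s0^2) of per-gene variances.

    Works on e_g = log(s_g^2) - digamma(d/2) + log(d/2); under the hierarchy
    var(e) = trigamma(d/2) + trigamma(d0/2), which is solved for d0. Genes
    with zero sample variance carry no information about the prior scale and
    are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if len(pos) < 2:
        return np.inf, float(np.mean(s2)) if len(s2) else 1.0
    e = np.log(pos) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(np.mean(e)))
    else:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_2 = float(
            np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    return d0, s0_2


def moderated_t_test(
    m: ExpressionMatrix,
    group_labels: pd.Series,
    contrast: str,
    prior: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """One-vs-rest moderated t-test for every gene.

    ``contrast`` names the group compared against all other samples;
    log2_fc is mean(contrast) - mean(rest). Returns a gene-indexed frame
    with log2_fc, t, p, df_total, s2_post. ``prior`` overrides the fitted
    (d0, s0^2): (0, .) gives the ordinary two-sample t, (inf, s0^2) the
    z-statistic with a fixed pooled variance.
    """
    if m.scale != "log2":
        raise ValueError("moderated t-test expects log2-scale expression")
    labels = group_labels.loc[m.sample_ids]
    in_grp = (labels == contrast).to_numpy()
    n1, n2 = int(in_grp.sum()), int((~in_grp).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples on each side of the contrast")
    X = m.values
    x1, x2 = X[:, in_grp], X[:, ~in_grp]
    fc = x1.mean(axis=1) - x2.mean(axis=1)
    df_resid = n1 + n2 - 2
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df_resid
    d0, s0_2 = prior if prior is not None else fit_variance_prior(s2, df_resid)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    c = np.sqrt(1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fc / (np.sqrt(s2_post) * c)
    t = np.where(np.isfinite(t), t, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # a gene constant everywhere is evidence of nothing
    constant = (fc == 0) & (s2 == 0)
    p = np.where(constant, 1.0, p)
    return pd.DataFrame(
        {
            "log2_fc": fc,
            "t": t,
            "p": p,
            "df_total": df_total,
            "s2_post": s2_post,
        },
        index=m.gene_ids,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEGTable:
    """Union of one-vs-rest DEG results; one row per gene, best contrast kept."""

    data: pd.DataFrame  # gene-indexed: contrast, log2_fc, t, p, p_adj_bh, passes_threshold
    fc_threshold: float
    alpha: float

    def __post_init__(self) -> None:
        if (self.data["p_adj_bh"] + 1e-12 < self.data["p"]).any():
            raise ValueError("adjusted p must be >= raw p")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index[self.data["passes_threshold"]])


def select_degs(
    m: ExpressionMatrix,
    cluster_labels: pd.Series,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
    fc_scale: str = "log2",
) -> DEGTable:
    """DEGs over one-vs-rest contrasts for every cluster.

    A gene is differentially expressed if, in at least one contrast,
    |log2 fold change| exceeds ``fc_threshold`` (interpreted on the log2
    scale by default; ``fc_scale="linear"`` reads the threshold as a linear
    fold change) and the BH-adjusted p is below ``alpha``. The union is
    deduplicated keeping each gene's best (smallest adjusted-p) contrast.
    """
    clusters = sorted(cluster_labels.loc[m.sample_ids].unique())
    if len(clusters) < 3:
        raise ValueError("DEG selection expects >= 3 clusters")
    log2_thr = fc_threshold if fc_scale == "log2" else np.log2(fc_threshold)
    frames = []
    for contrast in clusters:
        res = moderated_t_test(m, cluster_labels, str(contrast))
        res["p_adj_bh"] = bh_adjust(res["p"].to_numpy())
        res["contrast"] = str(contrast)
        frames.append(res)
    stacked = pd.concat(frames)
    stacked["passes_threshold"] = (
        np.abs(stacked["log2_fc"]) > log2_thr
    ) & (stacked["p_adj_bh"] < alpha)
    # keep each gene's best contrast; a gene passing anywhere is a DEG
    stacked = stacked.rename_axis("gene").reset_index()
    stacked = stacked.sort_values(
        ["gene", "passes_threshold", "p_adj_bh"], ascending=[True, False, True]
    )
    passes_any = stacked.groupby("gene")["passes_threshold"].any()
    best = stacked.drop_duplicates("gene", keep="first").set_index("gene")
    best["passes_threshold"] = passes_any.loc[best.index]
    cols = ["contrast", "log2_fc", "t", "p", "p_adj_bh", "passes_threshold"]
    return DEGTable(best[cols], fc_threshold=fc_threshold, alpha=alpha)
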