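"""Immune-signature construction and the per-sample ICI score.

DEGs are split into signature A (expression rises along the immune-favorable
cluster axis) and signature B (falls); a shadow-feature random-forest pass
(the Boruta scheme) prunes uninformative genes; each signature block is then
summarized by the first principal component of its z-scored expression, and

    ICI score = PC1(signature A) - PC1(signature B)

so higher scores mean a more immune-active, prognostically favorable sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .dge import bh_adjust
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SignaturePartition:
    """Disjoint DEG signatures with each gene's association statistic."""

    genes_A: list[str]
    genes_B: list[str]
    association: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        if set(self.genes_A) & set(self.genes_B):
            raise ValueError("signatures A and B must be disjoint")


def assign_signatures(
    deg_expr: ExpressionMatrix,
    gene_cluster_labels: pd.Series,
    immune_score: pd.Series,
    min_abs_rho: float = 1e-12,
) -> SignaturePartition:
    """Split DEGs into signatures A/B by association with the cluster axis.

    Gene clusters (per-sample labels) are ordered by ascending mean
    ``immune_score``; each gene's Spearman correlation between its expression
    and that ordered cluster rank decides membership: positive -> A
    (immune-activation axis), negative -> B, |rho| below ``min_abs_rho``
    (e.g. constant genes) -> excluded.
    """
    missing = set(deg_expr.sample_ids) - set(gene_cluster_labels.index)
    if missing:
        raise ValueError(f"cluster labels missing for samples: {sorted(missing)[:5]}")
    labels = gene_cluster_labels.loc[deg_expr.sample_ids]
    cluster_means = immune_score.loc[deg_expr.sample_ids].groupby(labels).mean()
    order = {c: r for r, c in enumerate(cluster_means.sort_values().index)}
    axis = labels.map(order).to_numpy(dtype=float)
    genes_a, genes_b, rhos = [], [], {}
    for gene in deg_expr.gene_ids:
        expr = deg_expr.data.loc[gene].to_numpy(dtype=float)
        if np.all(expr == expr[0]):
            rhos[gene] = 0.0
            continue
        rho = stats.spearmanr(expr, axis).statistic
        rho = 0.0 if not np.isfinite(rho) else float(rho)
        rhos[gene] = rho
        if rho > min_abs_rho:
            genes_a.append(gene)
        elif rho < -min_abs_rho:
            genes_b.append(gene)
    return SignaturePartition(genes_a, genes_b, pd.Series(rhos, name="spearman_rho"))


def boruta_select(
    deg_expr: ExpressionMatrix,
    target_labels: pd.Series,
    n_iter: int = 100,
    alpha: float = 0.05,
    seed: int | None = None,
    n_estimators: int = 100,
    include_tentative: bool = False,
) -> dict:
    """Shadow-feature random-forest relevance filter (the Boruta scheme).

    Each iteration appends a column-shuffled "shadow" copy of every feature,
    fits a random-forest classifier, and scores a feature a hit when its
    importance beats the best shadow importance. Features are confirmed or
    rejected by a two-sided binomial test of the hit count against
    Binomial(n_iter, 1/2), BH-corrected across features; the rest stay
    tentative.

    Returns a dict with ``selected`` (confirmed, plus tentative when
    ``include_tentative``), ``confirmed``, ``tentative``, ``rejected`` and the
    per-gene ``hits`` series.
    """
    y = target_labels.loc[deg_expr.sample_ids]
    if y.nunique() < 2:
        raise ValueError("target labels must have at least two classes")
    X = deg_expr.values.T  # samples x genes
    n_samples, n_features = X.shape
    rng = np.random.default_rng(seed)
    hits = np.zeros(n_features, dtype=int)
    for it in range(n_iter):
        shadow = X.copy()
        for j in range(n_features):
            rng.shuffle(shadow[:, j])
        both = np.hstack([X, shadow])
        forest = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
        )
        forest.fit(both, y)
        imp = forest.feature_importances_
        hits += imp[:n_features] > imp[n_features:].max()
    p = np.array(
        [2.0 * min(stats.binom.cdf(h, n_iter, 0.5), stats.binom.sf(h - 1, n_iter, 0.5))
         for h in hits]
    )
    p = np.minimum(p, 1.0)
    p_adj = bh_adjust(p)
    genes = np.array(deg_expr.gene_ids)
    significant = p_adj < alpha
    confirmed = genes[significant & (hits > n_iter / 2)].tolist()
    rejected = genes[significant & (hits < n_iter / 2)].tolist()
    tentative = [g for g in genes if g not in confirmed and g not in rejected]
    selected = confirmed + (tentative if include_tentative else [])
    return {
        "selected": selected,
        "confirmed": confirmed,
        "tentative": tentative,
        "rejected": rejected,
        "hits": pd.Series(hits, index=genes, name="hits"),
    }


def pc1_score(expr_subset: ExpressionMatrix, anchor: str = "mean") -> pd.Series:
    """Per-sample score on the first principal component of a gene block.

    Genes are z-scored across samples; PC1 of the gene x sample matrix is
    projected onto samples. Because a principal axis is defined only up to
    sign, the score's sign is anchored so it correlates positively with the
    mean z-scored expression of the block — negating the raw PC1 never
    changes the result.
    """
    if expr_subset.shape[1] < 3:
        raise ValueError("PC1 scoring needs at least 3 samples")
    Z = expr_subset.data.copy()
    sds = Z.std(axis=1, ddof=1)
    dropped = sds[sds == 0].index.tolist()
    if dropped:
        logger.warning("dropping %d zero-variance genes from PC1 block", len(dropped))
        Z = Z.drop(index=dropped)
    if Z.shape[0] < 2:
        raise ValueError("PC1 scoring needs at least 2 non-constant genes")
    Z = Z.sub(Z.mean(axis=1), axis=0).div(Z.std(axis=1, ddof=1), axis=0)
    # right singular vector of the gene x sample matrix = sample loadings
    _, s, vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    score = s[0] * vt[0]
    mean_z = Z.mean(axis=0).to_numpy()
    if anchor == "mean" and np.dot(score, mean_z) < 0:
        score = -score
    return pd.Series(score, index=expr_subset.sample_ids, name="pc1")


@dataclass
class ICIScoreTable:
    """Per-sample PC1A, PC1B, ICI score, and (once a cutoff is set) group."""

    data: pd.DataFrame  # sample-indexed: pc1a, pc1b, ici_score [, group]
    cutoff_used: float | None = None

    def __post_init__(self) -> None:
        expected = self.data["pc1a"] - self.data["pc1b"]
        if not np.allclose(expected, self.data["ici_score"], atol=1e-12):
            raise ValueError("ici_score must equal pc1a - pc1b")
        if self.cutoff_used is not None and "group" in self.data:
            want = np.where(self.data["ici_score"] > self.cutoff_used, "high", "low")
            if not (self.data["group"] == want).all():
                raise ValueError("group labels inconsistent with cutoff")

    @property
    def scores(self) -> pd.Series:
        return self.data["ici_score"]

    def with_cutoff(self, cutoff: float) -> "ICIScoreTable":
        data = self.data.copy()
        data["group"] = np.where(data["ici_score"] > cutoff, "high", "low")
        return ICIScoreTable(data, cutoff_used=float(cutoff))


def compute_ici_score(
    expr: ExpressionMatrix, partition: SignaturePartition
) -> ICIScoreTable:
    """ICI score per sample: PC1(signature A) - PC1(signature B).

    An empty signature contributes 0 (with a warning); both empty is an
    error, as is a partition with no genes present in the matrix.
    """
    present_a = [g for g in partition.genes_A if g in set(expr.gene_ids)]
    present_b = [g for g in partition.genes_B if g in set(expr.gene_ids)]
    if not present_a and not present_b:
        raise ValueError("no signature genes present in the expression matrix")

    def _block(genes: list[str], name: str) -> pd.Series:
        if not genes:
            logger.warning("signature %s empty; its PC1 term is 0", name)
            return pd.Series(0.0, index=expr.sample_ids)
        if len(genes) == 1:
            # degenerate one-gene block: PC1 is the gene's z-profile
            row = expr.data.loc[genes[0]]
            sd = row.std(ddof=1)
            if sd == 0:
                return pd.Series(0.0, index=expr.sample_ids)
            return (row - row.mean()) / sd
        return pc1_score(expr.subset_genes(genes))

    pc1a = _block(present_a, "A")
    pc1b = _block(present_b, "B")
    data = pd.DataFrame(
        {"pc1a": pc1a, "pc1b": pc1b, "ici_score": pc1a - pc1b}
    )
    return ICIScoreTable(data)
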