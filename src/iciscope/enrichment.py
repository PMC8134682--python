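"""Preranked GSEA and hypergeometric over-representation analysis.

Both operate on user-supplied gene sets (GMT): no ontology database ships
with the package. The GSEA null is gene-label permutation (preranked
semantics), so results are deterministic under a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dge import bh_adjust
from .io import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class GSEAResult:
    name: str
    es: float
    nes: float
    p: float
    fdr_q: float
    size: int
    leading_edge: list[str]

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.es <= 1.0 + 1e-9:
            raise ValueError("|ES| must be <= 1")


def _enrichment_score(
    order: np.ndarray, scores_sorted: np.ndarray, hit: np.ndarray, weight: float
) -> tuple[float, int]:
    """Running-sum ES for one hit mask over an already-sorted ranking.

    Returns (ES, extremum position). Hit steps are |score|^weight normalized
    to total 1; miss steps are 1/(N - |S|).
    """
    n = len(hit)
    n_hit = int(hit.sum())
    w = np.where(hit, np.abs(scores_sorted) ** weight, 0.0)
    total = w.sum()
    if total == 0:  # all hit scores are zero: fall back to unweighted steps
        w = hit.astype(float)
        total = w.sum()
    steps = np.where(hit, w / total, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    pos = int(np.argmax(np.abs(running)))
    return float(running[pos]), pos


def preranked_gsea(
    ranked_genes: pd.Series,
    gene_sets: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
    seed: int | None = None,
) -> list[GSEAResult]:
    """Preranked GSEA over a collection of gene sets.

    ``ranked_genes`` maps gene -> ranking metric (e.g. a moderated t); genes
    are sorted descending. The null distribution comes from random hit masks
    of the same size (gene-label permutation); the nominal p uses same-sign
    null values with an add-one correction, NES is ES over the mean |null ES|
    of the same sign, and FDR q follows the pooled positive/negative null
    procedure.
    """
    metric = ranked_genes.to_numpy(dtype=float)
    if not np.isfinite(metric).all():
        raise ValueError("ranking metric must be finite")
    order = np.argsort(-metric, kind="stable")
    genes_sorted = np.asarray(ranked_genes.index)[order]
    scores_sorted = metric[order]
    gene_pos = {g: i for i, g in enumerate(genes_sorted)}
    n = len(genes_sorted)
    rng = np.random.default_rng(seed)

    surviving = []
    for name in gene_sets:
        members = [g for g in gene_sets[name] if g in gene_pos]
        if min_size <= len(members) <= max_size:
            surviving.append((name, members))
    if not surviving:
        logger.warning("no gene set survives the size filter")
        return []

    observed = []
    nulls: dict[int, np.ndarray] = {}
    for name, members in surviving:
        hit = np.zeros(n, dtype=bool)
        hit[[gene_pos[g] for g in members]] = True
        es, pos = _enrichment_score(order, scores_sorted, hit, weight)
        if es >= 0:
            leading = [g for g in genes_sorted[: pos + 1] if hit[gene_pos[g]]]
        else:
            leading = [g for g in genes_sorted[pos:] if hit[gene_pos[g]]]
        size = len(members)
        if size not in nulls:
            null_es = np.empty(n_perm)
            for b in range(n_perm):
                perm_hit = np.zeros(n, dtype=bool)
                perm_hit[rng.choice(n, size=size, replace=False)] = True
                null_es[b], _ = _enrichment_score(
                    order, scores_sorted, perm_hit, weight
                )
            nulls[size] = null_es
        observed.append((name, es, size, leading))

    # NES for observed and pooled null, then nominal p and FDR q
    results = []
    null_nes_pool = []
    obs_nes = []
    for name, es, size, leading in observed:
        null = nulls[size]
        pos_mean = null[null > 0].mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        nes = es / pos_mean if es >= 0 else es / neg_mean
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same_sign):
            extreme = int((np.abs(same_sign) >= abs(es)).sum())
            p = (1 + extreme) / (1 + len(same_sign))
        else:
            p = 1.0 / (1 + n_perm)
        obs_nes.append(nes)
        null_nes = np.where(null >= 0, null / pos_mean, null / neg_mean)
        null_nes_pool.append(null_nes[np.isfinite(null_nes)])
        results.append((name, es, nes, p, size, leading))

    pool = np.concatenate(null_nes_pool)
    obs_nes_arr = np.asarray(obs_nes)
    out = []
    for (name, es, nes, p, size, leading), _ in zip(results, obs_nes_arr):
        if nes >= 0:
            null_frac = (pool >= nes).sum() / max((pool >= 0).sum(), 1)
            obs_frac = (obs_nes_arr >= nes).sum() / max((obs_nes_arr >= 0).sum(), 1)
        else:
            null_frac = (pool <= nes).sum() / max((pool < 0).sum(), 1)
            obs_frac = (obs_nes_arr <= nes).sum() / max((obs_nes_arr < 0).sum(), 1)
        q = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
        out.append(
            GSEAResult(
                name=name, es=es, nes=float(nes), p=float(p), fdr_q=float(q),
                size=size, leading_edge=leading,
            )
        )
    return out


def hypergeometric_ora(
    query_genes: list[str],
    gene_sets: GeneSetCollection,
    universe: list[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a query gene list.

    p = P(overlap >= k) for each set (restricted to the universe), with BH
    adjustment across sets.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    query = set(query_genes)
    if not query <= uni:
        raise ValueError("query genes must be a subset of the universe")
    n_uni, n_query = len(uni), len(query)
    rows = []
    for name in gene_sets:
        members = set(gene_sets[name]) & uni
        k = len(query & members)
        # P(X >= k), X ~ Hypergeom(N=n_uni, K=|set|, n=n_query)
        p = float(stats.hypergeom.sf(k - 1, n_uni, len(members), n_query))
        rows.append({"set": name, "set_size": len(members), "overlap": k, "p": p})
    df = pd.DataFrame(rows).set_index("set")
    df["q_bh"] = bh_adjust(df["p"].to_numpy())
    return df
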