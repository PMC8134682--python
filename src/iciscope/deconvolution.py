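"""Bulk immune-cell deconvolution and immune/stromal scoring.

Two complementary views of the tumor microenvironment from bulk expression:

* :func:`svr_deconvolve` — support-vector regression of each bulk sample
  against a cell-type signature matrix (the CIBERSORT algorithm): nu-SVR with
  a linear kernel over a small nu grid, best fit chosen by reconstruction
  RMSE, negative coefficients clipped and renormalized to fractions.
* :func:`ssgsea_score` / :func:`estimate_scores` — single-sample gene-set
  enrichment (rank-weighted running-sum, integrated in/out ECDF difference),
  the statistic underlying ESTIMATE immune and stromal scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.svm import NuSVR

from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

DEFAULT_NU_GRID = (0.25, 0.5, 0.75)


@dataclass
class CellFractionTable:
    """Samples x cell-type fraction estimates with per-sample fit diagnostics.

    Rows are convex (non-negative, sum to 1) unless a sample's fit was
    degenerate (all coefficients clipped to zero), in which case the row is
    all zeros and flagged in ``diagnostics['degenerate']``.
    """

    data: pd.DataFrame  # samples x cell types
    diagnostics: pd.DataFrame | None = None  # rmse, corr, p_value, degenerate

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if (values < -1e-9).any():
            raise ValueError("cell fractions must be non-negative")
        sums = values.sum(axis=1)
        degenerate = np.zeros(len(sums), dtype=bool)
        if self.diagnostics is not None and "degenerate" in self.diagnostics:
            degenerate = self.diagnostics["degenerate"].to_numpy(dtype=bool)
        ok = degenerate | np.isclose(sums, 1.0, atol=1e-6) | np.isclose(sums, 0.0)
        if not ok.all():
            raise ValueError("non-degenerate fraction rows must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class StromaImmuneScores:
    """Per-sample immune and stromal ssGSEA scores; their sum is the
    ESTIMATE-style combined score."""

    data: pd.DataFrame  # columns: immune_score, stromal_score, estimate_score

    def __post_init__(self) -> None:
        expected = self.data["immune_score"] + self.data["stromal_score"]
        if not np.allclose(expected, self.data["estimate_score"]):
            raise ValueError("estimate_score must equal immune + stromal")


def _quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization across columns (mean of sorted rows)."""
    ranks = df.rank(method="average", axis=0)
    sorted_mean = np.sort(df.to_numpy(), axis=0).mean(axis=1)
    # interpolate mean quantiles at (possibly fractional) average ranks
    grid = np.arange(1, len(df) + 1, dtype=float)
    out = {
        c: np.interp(ranks[c].to_numpy(), grid, sorted_mean) for c in df.columns
    }
    return pd.DataFrame(out, index=df.index)


def _fit_sample(X: np.ndarray, y: np.ndarray, nu_grid: Sequence[float]):
    """Fit the nu grid for one standardized sample; return (w, rmse, corr).

    Follows the CIBERSORT model-selection rule: per nu, fit a linear nu-SVR,
    clip negative coefficients, renormalize, and keep the nu whose clipped
    reconstruction has the lowest RMSE against the standardized bulk vector.
    """
    best = None
    for nu in nu_grid:
        model = NuSVR(kernel="linear", nu=nu, C=1.0)
        model.fit(X, y)
        w = model.coef_.ravel().copy()
        w[w < 0] = 0.0
        total = w.sum()
        if total > 0:
            w = w / total
            recon = X @ w
            rmse = float(np.sqrt(np.mean((recon - y) ** 2)))
            with np.errstate(invalid="ignore"):
                corr = float(np.corrcoef(recon, y)[0, 1])
        else:
            rmse, corr = np.inf, np.nan
        if best is None or rmse < best[1]:
            best = (w, rmse, corr)
    return best


def svr_deconvolve(
    bulk: ExpressionMatrix,
    sig: ExpressionMatrix,
    nu_grid: Sequence[float] = DEFAULT_NU_GRID,
    n_permutations: int = 0,
    seed: int | None = None,
    quantile_normalize: bool = False,
) -> CellFractionTable:
    """Estimate per-sample immune-cell fractions by nu-SVR deconvolution.

    Both matrices must be on the linear scale. Only genes shared between the
    bulk matrix and the signature matrix are used; the signature matrix is
    standardized globally (single mean/sd over all entries) and each bulk
    column is standardized per sample, so fractions are invariant to positive
    rescaling of a bulk column.

    ``n_permutations`` > 0 adds a per-sample permutation p-value: the fraction
    of gene-shuffled bulk vectors whose best-fit reconstruction correlation
    reaches the observed one (seeded; 0 disables, p reported as NaN).
    """
    if bulk.scale != "linear" or sig.scale != "linear":
        raise ValueError("deconvolution requires linear-scale matrices")
    shared = [g for g in sig.gene_ids if g in set(bulk.gene_ids)]
    if not shared:
        raise ValueError("no genes shared between bulk and signature matrices")
    if len(shared) < 0.5 * len(sig.gene_ids):
        logger.warning(
            "only %d/%d signature genes found in bulk matrix",
            len(shared),
            len(sig.gene_ids),
        )
    X_raw = sig.data.loc[shared]
    if np.linalg.matrix_rank(X_raw.to_numpy()) < X_raw.shape[1]:
        logger.warning("signature matrix is rank-deficient on shared genes")
    X = (X_raw - X_raw.to_numpy().mean()) / X_raw.to_numpy().std()
    X = X.to_numpy()

    bulk_data = bulk.data.loc[shared]
    if quantile_normalize:
        bulk_data = _quantile_normalize(bulk_data)

    rng = np.random.default_rng(seed)
    rows, diags = [], []
    for sample in bulk_data.columns:
        y_raw = bulk_data[sample].to_numpy(dtype=float)
        sd = y_raw.std()
        if sd == 0:
            rows.append(np.zeros(X.shape[1]))
            diags.append((np.nan, np.nan, np.nan, True))
            continue
        y = (y_raw - y_raw.mean()) / sd
        w, rmse, corr = _fit_sample(X, y, nu_grid)
        degenerate = not np.isfinite(rmse)
        p_value = np.nan
        if n_permutations > 0 and not degenerate:
            hits = 0
            for _ in range(n_permutations):
                y_perm = rng.permutation(y)
                _, _, corr_perm = _fit_sample(X, y_perm, nu_grid)
                if np.isfinite(corr_perm) and corr_perm >= corr:
                    hits += 1
            p_value = hits / n_permutations
        rows.append(w)
        diags.append((rmse, corr, p_value, degenerate))

    fractions = pd.DataFrame(rows, index=bulk_data.columns, columns=X_raw.columns)
    diagnostics = pd.DataFrame(
        diags, index=bulk_data.columns, columns=["rmse", "corr", "p_value", "degenerate"]
    )
    return CellFractionTable(fractions, diagnostics)


def ssgsea_score(
    m: ExpressionMatrix, gene_set: Sequence[str], alpha: float = 0.25
) -> pd.Series:
    """Single-sample gene-set enrichment score per sample.

    Genes are ranked by expression within each sample (highest expression gets
    the largest rank, ties averaged); walking the ranked list, in-set genes
    increment a weighted ECDF with weight rank**alpha and out-of-set genes
    increment the unweighted out ECDF. The score is the sum of
    (ECDF_in - ECDF_out) over all positions — the integrated-difference form
    — so it is invariant to any strictly monotone transform of expression.
    """
    members = set(gene_set) & set(m.gene_ids)
    if len(members) < 2:
        raise ValueError("need at least 2 gene-set members present in the matrix")
    n_genes = m.shape[0]
    in_set = np.array([g in members for g in m.gene_ids])
    n_out = n_genes - in_set.sum()
    scores = {}
    for sample in m.sample_ids:
        expr = m.data[sample].to_numpy(dtype=float)
        if n_out == 0:
            scores[sample] = 0.0
            continue
        ranks = rankdata(expr)  # ascending: highest expression -> rank n
        order = np.argsort(-expr, kind="stable")  # walk from highest expression
        hit = in_set[order]
        weights = np.where(hit, np.abs(ranks[order]) ** alpha, 0.0)
        ecdf_in = np.cumsum(weights) / weights.sum()
        ecdf_out = np.cumsum(~hit) / n_out
        scores[sample] = float(np.sum(ecdf_in - ecdf_out))
    return pd.Series(scores, name="ssgsea")


def estimate_scores(
    m: ExpressionMatrix,
    immune_set: Sequence[str],
    stromal_set: Sequence[str],
    alpha: float = 0.25,
) -> StromaImmuneScores:
    """ESTIMATE-style immune, stromal and combined scores per sample."""
    immune = ssgsea_score(m, immune_set, alpha=alpha)
    stromal = ssgsea_score(m, stromal_set, alpha=alpha)
    data = pd.DataFrame(
        {
            "immune_score": immune,
            "stromal_score": stromal,
            "estimate_score": immune + stromal,
        }
    )
    return StromaImmuneScores(data)


def scores_from_gmt(
    m: ExpressionMatrix,
    collection: GeneSetCollection,
    immune_name: str = "IMMUNE",
    stromal_name: str = "STROMAL",
) -> StromaImmuneScores:
    return estimate_scores(m, collection[immune_name], collection[stromal_name])
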