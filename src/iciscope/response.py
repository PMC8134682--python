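"""ICI score as a predictor of immunotherapy response: ROC and rate tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

#: RECIST response categories, worst to best.
RESPONSE_ORDER = ("PD", "SD", "PR", "CR")

#: RECIST convention: objective responders are CR/PR.
RESPONDER_CATEGORIES = frozenset({"CR", "PR"})


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")


def dichotomize_response(labels: pd.Series) -> pd.Series:
    """Collapse CR/PR/SD/PD to responder (1) vs non-responder (0)."""
    unknown = set(labels.unique()) - set(RESPONSE_ORDER)
    if unknown:
        raise ValueError(f"unknown response categories: {sorted(unknown)}")
    return labels.isin(RESPONDER_CATEGORIES).astype(int)


def roc_auc(scores, binary_outcome) -> ROCResult:
    """ROC curve and AUC (rank / Mann-Whitney formulation, tie-corrected)."""
    y = np.asarray(binary_outcome, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    fpr, tpr, thresholds = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    return ROCResult(
        thresholds=thresholds, sensitivity=tpr, specificity=1.0 - fpr, auc=auc
    )


def response_rate_table(
    response_labels: pd.Series, ici_groups: pd.Series
) -> tuple[pd.DataFrame, float, float]:
    """Per-ICI-group response-category proportions with a 2xk chi-square.

    Returns (proportions frame, chi2, p). The test is the plain Pearson
    chi-square on the counts table (no continuity correction for df > 1);
    categories absent from both groups are dropped.
    """
    groups = ici_groups.loc[response_labels.index]
    if groups.value_counts().min() == 0 or groups.nunique() < 2:
        raise ValueError("both ICI groups must be non-empty")
    counts = pd.crosstab(groups, response_labels)
    counts.index.name = "group"
    order = [c for c in RESPONSE_ORDER if c in counts.columns]
    counts = counts[order + [c for c in counts.columns if c not in order]]
    correction = counts.shape == (2, 2)
    chi2, p, _, _ = stats.chi2_contingency(counts.to_numpy(), correction=correction)
    props = counts.div(counts.sum(axis=1), axis=0)
    return props, float(chi2), float(p)
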