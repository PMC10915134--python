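"""ROC/AUC stage discrimination, Youden-optimal cutoffs and the
MGUS-to-myeloma progression analysis.

The AUC is the tie-corrected Mann-Whitney probability (risk ties count
1/2), which equals the trapezoidal area under the empirical ROC curve.
Cutoff candidates are midpoints between adjacent distinct scores, so a
sample never sits exactly on a cutoff and strict-versus-weak inequalities
are immaterial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .stats import fisher_exact

logger = logging.getLogger(__name__)


@dataclass
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    scores: np.ndarray
    labels: np.ndarray
    optimal_cutoff: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None


def roc_auc(scores, binary_labels) -> ROCResult:
    """Empirical ROC curve and AUC of a score for a binary outcome."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(binary_labels, dtype=int)
    if scores.size != labels.size:
        raise ValueError("scores and labels length mismatch")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(roc_auc_score(labels, scores))
    return ROCResult(auc=auc, fpr=fpr, tpr=tpr, thresholds=thr, scores=scores, labels=labels)


def _sens_spec(scores, labels, cutoff):
    pos = labels == 1
    sens = float(np.mean(scores[pos] > cutoff))
    spec = float(np.mean(scores[~pos] <= cutoff))
    return sens, spec


def optimal_cutoff(roc: ROCResult) -> ROCResult:
    """Youden-optimal operating point.

    Candidates are midpoints between adjacent distinct sorted scores; ties
    in J = sensitivity + specificity - 1 break toward the smallest cutoff.
    Returns the same ROCResult with cutoff, sensitivity and specificity set.
    """
    distinct = np.unique(roc.scores)
    if distinct.size < 2:
        raise ValueError("all scores identical; no cutoff candidates")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best_j, best = -np.inf, None
    for c in candidates:
        sens, spec = _sens_spec(roc.scores, roc.labels, c)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best = j, (c, sens, spec)
    roc.optimal_cutoff, roc.sensitivity, roc.specificity = best
    return roc


def stage_discrimination(scores: pd.Series, stage_labels: pd.Series) -> pd.DataFrame:
    """Pairwise AUCs between ordered disease stages.

    For each ordered pair (earlier, later) the AUC treats the later stage
    as the positive class; a stage with < 2 samples yields NaN for its
    pairs (logged).  Row = earlier stage, column = later stage.
    """
    scores = pd.Series(scores, dtype=float)
    stage_labels = pd.Series(stage_labels)
    if not scores.index.equals(stage_labels.index):
        stage_labels = stage_labels.loc[scores.index]
    if isinstance(stage_labels.dtype, pd.CategoricalDtype):
        order = [s for s in stage_labels.cat.categories if (stage_labels == s).any()]
    else:
        order = list(pd.unique(stage_labels.dropna()))
    if len(order) < 2:
        raise ValueError("need >= 2 stages present")
    out = pd.DataFrame(np.nan, index=order, columns=order)
    for i, early in enumerate(order):
        for late in order[i + 1 :]:
            e_mask = stage_labels == early
            l_mask = stage_labels == late
            if e_mask.sum() < 2 or l_mask.sum() < 2:
                logger.warning("stage pair (%s, %s) has < 2 samples; skipped", early, late)
                continue
            s = np.concatenate([scores[e_mask], scores[l_mask]])
            y = np.concatenate([np.zeros(e_mask.sum()), np.ones(l_mask.sum())])
            out.loc[early, late] = roc_auc(s, y).auc
    return out


@dataclass
class ProgressionResult:
    roc: ROCResult
    table: np.ndarray  # rows high/low, cols progressed/not
    fisher_p: float
    rate_high: float
    rate_low: float
    rate_ratio: float


def progression_eval(scores, progressed) -> ProgressionResult:
    """Progression-risk evaluation: ROC + Youden cutoff, then a 2x2
    high/low-by-progressed table with Fisher's exact p and the progression
    rate ratio (high over low)."""
    scores = np.asarray(scores, dtype=float)
    progressed = np.asarray(progressed, dtype=int)
    roc = optimal_cutoff(roc_auc(scores, progressed))
    high = scores > roc.optimal_cutoff
    table = np.array(
        [
            [int(np.sum(high & (progressed == 1))), int(np.sum(high & (progressed == 0)))],
            [int(np.sum(~high & (progressed == 1))), int(np.sum(~high & (progressed == 0)))],
        ]
    )
    fisher_p = fisher_exact(table).p_value
    rate_high = table[0, 0] / table[0].sum() if table[0].sum() else np.nan
    rate_low = table[1, 0] / table[1].sum() if table[1].sum() else np.nan
    ratio = rate_high / rate_low if rate_low > 0 else np.inf
    return ProgressionResult(
        roc=roc,
        table=table,
        fisher_p=fisher_p,
        rate_high=rate_high,
        rate_low=rate_low,
        rate_ratio=ratio,
    )
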