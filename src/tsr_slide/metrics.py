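"""Evaluation statistics for the patch classifier and the TSR estimates.

Classifier quality is summarized the standard way (confusion matrix,
accuracy, per-class precision/recall/F1). TSR estimates are compared with a
pathologist's visual scores, which live on the discrete grid
{10%, 20%, ..., 90%}: the comparison reports per-category mean, median,
standard deviation and SEE, the overall Pearson correlation and SEE, and
Cohen's kappa of the stroma-high/low dichotomization.

SEE — the standard error of the estimate — is the root-mean-square deviation
of the predicted TSR from the visually assigned category value,
``sqrt(mean((pred - true)**2))`` (denominator n). This is the definition
consistent with the identity ``SEE**2 = std**2 + bias**2`` that per-category
summaries obey up to rounding; a flag switches the standard deviation between
the n-1 (default) and n denominators.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from sklearn import metrics as _skm

from tsr_slide.datatypes import CLASS_NAMES, ClassReport
from tsr_slide.tsr import dichotomize

logger = logging.getLogger(__name__)

TSR_CATEGORY_GRID = tuple(range(10, 100, 10))


def classification_report(true_labels, pred_labels) -> ClassReport:
    """3-class report over the fixed class order (tumor, stroma, other).

    A class with no predicted (or no true) instances gets precision (recall)
    0 and is listed in ``flags`` — an explicit marker, never a NaN.
    """
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(pred_labels)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("label vectors must be nonempty and equal length")
    labels = np.arange(len(CLASS_NAMES))
    confusion = _skm.confusion_matrix(y_true, y_pred, labels=labels)
    precision, recall, f1, _ = _skm.precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    flags = [
        CLASS_NAMES[i]
        for i in labels
        if confusion[:, i].sum() == 0 or confusion[i, :].sum() == 0
    ]
    return ClassReport(
        confusion=confusion,
        accuracy=float(np.trace(confusion) / confusion.sum()),
        precision=precision,
        recall=recall,
        f1=f1,
        flags=flags,
    )


def pearson_r(pred, true) -> float:
    """Product-moment correlation; zero variance is an error, not a NaN."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape or pred.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.std(pred) == 0 or np.std(true) == 0:
        raise ValueError("Pearson r undefined for a zero-variance vector")
    return float(_sstats.pearsonr(pred, true).statistic)


def see(pred, true) -> float:
    """Standard error of the estimate: RMS deviation of pred from true."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("need two nonempty equal-length vectors")
    return float(np.sqrt(np.mean((pred - true) ** 2)))


def cohens_kappa(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two binary raters.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with the expected agreement from the
    marginal products. If both raters are constant and identical the
    expected agreement is 1 and kappa is defined as 1 by convention.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("need two nonempty equal-length label vectors")
    if len(np.unique(a)) == 1 and np.array_equal(a, b):
        logger.info("cohens_kappa: both raters constant and equal; kappa = 1")
        return 1.0
    return float(_skm.cohen_kappa_score(a, b))


def tsr_eval_table(
    pred_tsr,
    true_tsr,
    cutoff: float = 50.0,
    std_ddof: int = 1,
) -> dict:
    """Per-category and overall comparison of predicted vs visual TSR.

    Parameters
    ----------
    pred_tsr, true_tsr:
        Percent-scale vectors; every true value must sit on the visual
        scoring grid {10, 20, ..., 90}.
    cutoff:
        Stroma-high/low dichotomization cutoff in percent.
    std_ddof:
        1 for the sample standard deviation (default), 0 for population.

    Returns a dict with ``per_category`` (DataFrame indexed by true category:
    mean, median, see, std, n), ``pearson_r``, ``see`` (overall), ``kappa``
    and ``n``.
    """
    pred = np.asarray(pred_tsr, dtype=float)
    true = np.asarray(true_tsr, dtype=float)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("need two nonempty equal-length vectors")
    off = ~np.isin(true, TSR_CATEGORY_GRID)
    if off.any():
        bad = true[off][0]
        raise ValueError(
            f"true TSR value {bad} is off the visual grid {TSR_CATEGORY_GRID}"
        )

    rows = {}
    for cat in TSR_CATEGORY_GRID:
        sel = true == cat
        n = int(sel.sum())
        if n == 0:
            continue
        p = pred[sel]
        rows[cat] = {
            "mean": float(p.mean()),
            "median": float(np.median(p)),
            "see": see(p, np.full(n, float(cat))),
            "std": float(p.std(ddof=std_ddof)) if n > std_ddof else 0.0,
            "n": n,
        }
    per_category = pd.DataFrame.from_dict(rows, orient="index")
    per_category.index.name = "true_tsr"

    pred_cls = [dichotomize(v, cutoff) for v in pred]
    true_cls = [dichotomize(v, cutoff) for v in true]
    return {
        "per_category": per_category,
        "pearson_r": pearson_r(pred, true),
        "see": see(pred, true),
        "kappa": cohens_kappa(true_cls, pred_cls),
        "cutoff": cutoff,
        "n": int(pred.size),
    }
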