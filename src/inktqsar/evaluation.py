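"""Model evaluation: strong/weak classification, ROC curves, recovery metrics.

An analogue is a *strong* polarizer on an axis when its D-value strictly
exceeds the reference compound's D on that axis (the reference itself is
weak by definition).  A model's ability to rank strong above weak is
summarised by the ROC curve of its predicted D-values and the area under
it, computed by the rank-sum (Mann–Whitney) formulation with mid-rank
handling of ties.  For synthetic runs with a known data-generating model,
recovery metrics compare the selected descriptors and coefficient signs
against the ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from sklearn.metrics import roc_curve

__all__ = ["ROCResult", "classify_strength", "roc_auc",
           "parameter_recovery_report"]


def classify_strength(D_values: pd.Series, reference_D: float) -> pd.Series:
    """Binary strong/weak labels at the reference-compound cutoff.

    Strong ⇔ D > reference_D (strict).  Missing D-values are excluded from
    the result; an all-missing input yields an empty label set with a
    warning.
    """
    if not 0.1 <= reference_D <= 0.9:
        raise ValueError(f"reference_D {reference_D} outside the desirability range")
    D = pd.Series(D_values).astype(float)
    labels = (D > reference_D)[D.notna()]
    if labels.empty:
        warnings.warn("no non-missing D-values to classify", stacklevel=2)
    return labels


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "fpr": self.fpr,
                             "tpr": self.tpr})


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC of scores against binary labels.

    AUC by the Mann–Whitney rank formula (ties count half); the curve is a
    threshold sweep over the unique scores, anchored at (0,0) and (1,1).
    Requires at least one positive and one negative.
    """
    s = np.asarray(list(scores), dtype=float)
    lab = np.asarray(list(labels), dtype=bool)
    if s.shape != lab.shape:
        raise ValueError("scores and labels must be paired")
    n_pos, n_neg = int(lab.sum()), int((~lab).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    ranks = rankdata(s)  # mid-ranks
    auc = (ranks[lab].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(lab.astype(int), s, drop_intermediate=False)
    return ROCResult(thresholds=thr, tpr=tpr, fpr=fpr, auc=float(auc),
                     n_pos=n_pos, n_neg=n_neg)


def parameter_recovery_report(truth_coefficients: pd.Series, model) -> dict:
    """Compare a fitted model's descriptors against the generating truth.

    ``truth_coefficients`` is a descriptor-indexed vector (zeros for
    uninformative descriptors).  Reports descriptor-selection sensitivity,
    false-inclusion count, sign agreement among true positives, and the
    Spearman correlation between |fitted| and |true| coefficients over the
    full descriptor vocabulary.
    """
    truth = pd.Series(truth_coefficients).astype(float)
    fitted = pd.Series(model.coefficients, dtype=float)
    unknown = [c for c in fitted.index if c not in truth.index]
    if unknown:
        raise ValueError(f"model descriptors absent from truth vocabulary: {unknown}")
    informative = set(truth.index[truth != 0])
    selected = set(fitted.index[fitted != 0])
    true_pos = informative & selected
    sensitivity = len(true_pos) / len(informative) if informative else float("nan")
    false_inclusions = len(selected - informative)
    sign_ok = sum(1 for c in true_pos
                  if np.sign(fitted[c]) == np.sign(truth[c]))
    sign_agreement = sign_ok / len(true_pos) if true_pos else float("nan")
    full_fitted = fitted.reindex(truth.index).fillna(0.0)
    if truth.abs().nunique() > 1 and full_fitted.abs().nunique() > 1:
        rho = float(spearmanr(truth.abs(), full_fitted.abs()).statistic)
    else:
        rho = float("nan")
    return {
        "n_informative": len(informative),
        "n_selected": len(selected),
        "n_true_positive": len(true_pos),
        "sensitivity": sensitivity,
        "false_inclusions": false_inclusions,
        "sign_agreement": sign_agreement,
        "coefficient_rank_correlation": rho,
    }
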