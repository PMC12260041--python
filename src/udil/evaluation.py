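"""Metrics, forgetting scores and uncertainty-based OOD detection.

The positive class for precision/recall/F1 is the case class m (the
clinical minority); specificity is the true-negative rate on the control
class h. All zero-denominator metrics are 0 by convention. Forgetting of an
earlier domain is the drop, in percentage points, between its F1 at its own
training stage and at the final stage; negative forgetting is backward
transfer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .synthetic import DomainDataset, NEGATIVE_LABEL, POSITIVE_LABEL


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    pre: float
    rec: float
    spe: float
    f1: float
    macro_f1: float
    bal_acc: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """Counts and derived metrics from label vectors in {0 (h), 1 (m)}."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors have different lengths")
    for name, v in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.isin(v, (POSITIVE_LABEL, NEGATIVE_LABEL)).all():
            raise ValueError(f"{name} contains labels outside {{0,1}}")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    n = tp + fp + tn + fn
    pre = _safe_div(tp, tp + fp)
    rec = _safe_div(tp, tp + fn)
    spe = _safe_div(tn, tn + fp)
    f1 = _safe_div(2 * pre * rec, pre + rec)
    # F1 of the negative class, for macro averaging
    pre_h = _safe_div(tn, tn + fn)
    f1_h = _safe_div(2 * pre_h * spe, pre_h + spe)
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        acc=_safe_div(tp + tn, n), pre=pre, rec=rec, spe=spe, f1=f1,
        macro_f1=0.5 * (f1 + f1_h), bal_acc=0.5 * (rec + spe),
    )


@dataclass
class ForgettingReport:
    """Per earlier domain: F1 at its own stage vs the final stage.

    ``forgetting`` is in percentage points; only domains trained before the
    final stage appear, so a single-stage run yields an empty report.
    """

    domain_names: list[str]
    f1_at_own_stage: list[float]
    f1_at_final_stage: list[float]
    forgetting: list[float]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.domain_names, self.forgetting))


def forgetting_scores(
    f1_matrix: np.ndarray, domain_names: list[str] | None = None
) -> ForgettingReport:
    """Forgetting from a stage x domain F1 matrix (diagonal = own stage)."""
    mat = np.asarray(f1_matrix, dtype=float)
    n_stages = mat.shape[0]
    if n_stages <= 1:
        return ForgettingReport([], [], [], [])
    names = domain_names or [f"domain{j + 1}" for j in range(mat.shape[1])]
    own, final, forg, kept = [], [], [], []
    for j in range(n_stages - 1):
        own.append(float(mat[j, j]))
        final.append(float(mat[-1, j]))
        forg.append(100.0 * (mat[j, j] - mat[-1, j]))
        kept.append(names[j])
    return ForgettingReport(kept, own, final, forg)


def ranking_metrics(scores: np.ndarray, is_positive: np.ndarray) -> tuple[float, float]:
    """AUROC and AUPR with ``scores`` ranking the positive group high.

    AUROC is the tie-corrected rank statistic (a tied pair counts 1/2);
    AUPR uses step interpolation of precision at each positive threshold.
    """
    scores = np.asarray(scores, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    if scores.shape != is_positive.shape:
        raise ValueError("scores and labels have different lengths")
    if is_positive.all() or not is_positive.any():
        raise ValueError("both groups must be present for ranking metrics")
    auroc = float(roc_auc_score(is_positive, scores))
    aupr = float(average_precision_score(is_positive, scores))
    return auroc, aupr


@dataclass
class OODReport:
    mean_u_in: float
    std_u_in: float
    mean_u_ood: float
    std_u_ood: float
    auroc: float
    aupr: float


def ood_report(model, in_domains: list[DomainDataset], ood: DomainDataset) -> OODReport:
    """Uncertainty statistics and OOD detection scores for a trained model.

    ``model`` is anything with a ``predict(features) -> DirichletOutput``
    method. The OOD group is the positive class of the ranking problem and
    predictive uncertainty u is the score.
    """
    if not in_domains or len(ood) == 0:
        raise ValueError("need non-empty in-distribution and OOD datasets")
    u_in = np.concatenate([model.predict(d.features).uncertainty for d in in_domains])
    u_ood = model.predict(ood.features).uncertainty
    scores = np.concatenate([u_in, u_ood])
    labels = np.concatenate([np.zeros(u_in.size, bool), np.ones(u_ood.size, bool)])
    auroc, aupr = ranking_metrics(scores, labels)
    return OODReport(
        mean_u_in=float(u_in.mean()), std_u_in=float(u_in.std()),
        mean_u_ood=float(u_ood.mean()), std_u_ood=float(u_ood.std()),
        auroc=auroc, aupr=aupr,
    )
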