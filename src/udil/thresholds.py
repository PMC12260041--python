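"""Uncertainty-guided adaptive class-specific threshold learning.

For every training sample the divergence between the current model's
predictive distribution and the historical one (same classifier applied to
the frozen previous-domain extractor's embeddings) measures how far the
representation has drifted for that sample. Per class, a threshold

    tau_c = mu_c - sens_c * sigma_c

over those divergences (population standard deviation, statistics taken
over *reliable* records only) selects the low-divergence, high-agreement
portion of the class. Reliability gates on predictive uncertainty: a record
is reliable iff its uncertainty is strictly below a class-wise quantile cut
(or an absolute cutoff when configured).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .evidential import DirichletOutput
from .synthetic import NEGATIVE_LABEL, POSITIVE_LABEL

DIVERGENCE_KINDS = ("sym_kl", "js_mixture")


@dataclass
class DivergenceRecord:
    sample_index: int
    label: int  # POSITIVE_LABEL (m) or NEGATIVE_LABEL (h)
    divergence: float
    uncertainty_current: float
    reliable: bool


@dataclass
class ClassThresholds:
    """Per-class divergence statistics and the resulting thresholds.

    ``sens_*`` are the sensitivity coefficients multiplying sigma (the
    class-specific hyperparameters of the threshold rule; they are unrelated
    to the Dirichlet concentration).
    """

    mu_m: float
    sigma_m: float
    sens_m: float
    tau_m: float
    mu_h: float
    sigma_h: float
    sens_h: float
    tau_h: float

    def tau_for(self, label: int) -> float:
        return self.tau_m if label == POSITIVE_LABEL else self.tau_h


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    return float(np.sum(p * (np.log(p) - np.log(q))))


def predictive_divergence(
    p_current: np.ndarray,
    p_historical: np.ndarray,
    epsilon: float = 1e-8,
    kind: str = "sym_kl",
) -> float:
    """Divergence between two K-class predictive distributions.

    ``sym_kl`` (default) is the symmetrized KL, ½[KL(p‖q) + KL(q‖p)],
    computed on epsilon-clipped, renormalized distributions; it is symmetric,
    non-negative and zero iff the clipped distributions coincide, but
    unbounded — hence the clipping. ``js_mixture`` is the bounded
    mixture-based Jensen–Shannon divergence, offered for comparison.
    """
    if kind not in DIVERGENCE_KINDS:
        raise ValueError(f"unknown divergence kind {kind!r}")
    p = np.asarray(p_current, dtype=float)
    q = np.asarray(p_historical, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("expected two probability vectors of equal length")
    for name, vec in (("p_current", p), ("p_historical", q)):
        if (vec < 0).any() or abs(vec.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} is not a probability vector")
    p = np.clip(p, epsilon, None)
    p /= p.sum()
    q = np.clip(q, epsilon, None)
    q /= q.sum()
    if kind == "sym_kl":
        return 0.5 * (_kl(p, q) + _kl(q, p))
    m = 0.5 * (p + q)
    return 0.5 * (_kl(p, m) + _kl(q, m))


def batch_divergences(
    current: DirichletOutput,
    historical: DirichletOutput,
    labels: Sequence[int],
    reliability_quantile: float = 0.9,
    u_max: float | None = None,
    epsilon: float = 1e-8,
    kind: str = "sym_kl",
) -> list[DivergenceRecord]:
    """One divergence record per sample, comparing expected probabilities.

    The reliability flag is set class-wise: u < u_max if an absolute cutoff
    is given, else u < the class-wise ``reliability_quantile`` quantile of
    current uncertainty.
    """
    labels = np.asarray(labels, dtype=int)
    q = current.prob.shape[0]
    if historical.prob.shape != current.prob.shape or labels.shape != (q,):
        raise ValueError("current/historical/label shapes disagree")
    divs = np.array(
        [
            predictive_divergence(current.prob[j], historical.prob[j], epsilon=epsilon, kind=kind)
            for j in range(q)
        ]
    )
    u = current.uncertainty
    cutoffs = {}
    for label in (POSITIVE_LABEL, NEGATIVE_LABEL):
        mask = labels == label
        if u_max is not None:
            cutoffs[label] = u_max
        elif mask.any():
            cutoffs[label] = float(np.quantile(u[mask], reliability_quantile))
        else:
            cutoffs[label] = np.inf
    return [
        DivergenceRecord(
            sample_index=j,
            label=int(labels[j]),
            divergence=float(divs[j]),
            uncertainty_current=float(u[j]),
            reliable=bool(u[j] < cutoffs[int(labels[j])]),
        )
        for j in range(q)
    ]


def _class_stats(divs: np.ndarray) -> tuple[float, float]:
    mu = float(divs.mean())
    sigma = float(divs.std()) if divs.size >= 2 else 0.0  # population std
    return mu, sigma


def learn_thresholds(
    records: Sequence[DivergenceRecord],
    sens_m: float = 0.5,
    sens_h: float = 0.5,
    pooled: bool = False,
) -> ClassThresholds:
    """Thresholds tau_c = mu_c - sens_c * sigma_c from divergence records.

    Statistics use reliable records of each class; a class with no reliable
    records falls back to all its records (the reliability filter is
    waived), and a class with fewer than two contributing records gets
    sigma = 0 hence tau = mu. ``pooled=True`` computes one global
    mean/sigma over all classes' records (the class-agnostic ablation
    variant) and applies it to both classes.
    """
    if not records:
        raise ValueError("no divergence records")
    per_class: dict[int, np.ndarray] = {}
    for label in (POSITIVE_LABEL, NEGATIVE_LABEL):
        recs = [r for r in records if r.label == label]
        if not recs:
            name = "m" if label == POSITIVE_LABEL else "h"
            raise ValueError(f"class {name!r} absent from divergence records")
        reliable = [r.divergence for r in recs if r.reliable]
        per_class[label] = np.array(reliable if reliable else [r.divergence for r in recs])
    if pooled:
        all_divs = np.concatenate(list(per_class.values()))
        mu, sigma = _class_stats(all_divs)
        return ClassThresholds(
            mu_m=mu, sigma_m=sigma, sens_m=sens_m, tau_m=mu - sens_m * sigma,
            mu_h=mu, sigma_h=sigma, sens_h=sens_h, tau_h=mu - sens_h * sigma,
        )
    mu_m, sigma_m = _class_stats(per_class[POSITIVE_LABEL])
    mu_h, sigma_h = _class_stats(per_class[NEGATIVE_LABEL])
    return ClassThresholds(
        mu_m=mu_m, sigma_m=sigma_m, sens_m=sens_m, tau_m=mu_m - sens_m * sigma_m,
        mu_h=mu_h, sigma_h=sigma_h, sens_h=sens_h, tau_h=mu_h - sens_h * sigma_h,
    )


def fixed_thresholds(tau: float) -> ClassThresholds:
    """Class-agnostic fixed threshold (the fixed-tau ablation variants)."""
    return ClassThresholds(
        mu_m=tau, sigma_m=0.0, sens_m=0.0, tau_m=tau,
        mu_h=tau, sigma_h=0.0, sens_h=0.0, tau_h=tau,
    )
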