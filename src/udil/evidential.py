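"""Evidential (Dirichlet) classification head: evidence algebra and losses.

A classifier produces per-class non-negative evidence ``e``; the Dirichlet
concentration is ``alpha = e + 1``, the expected class probabilities are
``alpha / S`` with ``S = sum(alpha)``, and predictive uncertainty is
``u = K / S``: zero evidence means a uniform Dirichlet and maximal
uncertainty ``u = 1``.

Training minimizes the expected cross-entropy under the Dirichlet (the
"adaptive evidential cross-entropy", a digamma expression) plus an annealed
KL regularizer pulling the concentration towards the uniform prior
``Dir(1)``, which discourages confident evidence early in training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, polygamma

KL_FORMS = ("standard", "as_printed")


@dataclass
class DirichletOutput:
    """Per-sample evidential quantities for a batch of Q samples, K classes."""

    evidence: np.ndarray  # (Q, K), >= 0
    alpha: np.ndarray  # (Q, K), = evidence + 1
    total_evidence: np.ndarray  # (Q,), S = sum_k alpha_k
    prob: np.ndarray  # (Q, K), expected probabilities alpha / S
    uncertainty: np.ndarray  # (Q,), u = K / S in (0, 1]

    @property
    def n_classes(self) -> int:
        return self.alpha.shape[1]

    def predicted_labels(self) -> np.ndarray:
        """Arg-max of the expected probabilities; ties resolve to class 0 (h).

        For K = 2 the positive class m is column 1, so a sample is called
        positive only when p(m) strictly exceeds p(h) — conservative
        screening behaviour.
        """
        p = self.prob
        best = p.max(axis=1, keepdims=True)
        is_best = np.isclose(p, best)
        # first True per row wins -> lowest class index on ties
        return np.argmax(is_best, axis=1)


def logits_to_evidence(logits: np.ndarray) -> np.ndarray:
    """Map raw scores to non-negative evidence via a stabilized softplus."""
    logits = np.asarray(logits, dtype=float)
    if not np.isfinite(logits).all():
        raise ValueError("non-finite logits")
    return np.logaddexp(0.0, logits)


def evidence_to_output(evidence: np.ndarray) -> DirichletOutput:
    """Build the full Dirichlet summary from an evidence matrix."""
    evidence = np.atleast_2d(np.asarray(evidence, dtype=float))
    if (evidence < 0).any():
        raise ValueError("evidence must be non-negative")
    alpha = evidence + 1.0
    total = alpha.sum(axis=1)
    prob = alpha / total[:, None]
    uncertainty = alpha.shape[1] / total
    return DirichletOutput(
        evidence=evidence, alpha=alpha, total_evidence=total, prob=prob, uncertainty=uncertainty
    )


def _check_alpha(alpha: np.ndarray) -> np.ndarray:
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    if (alpha < 1.0 - 1e-12).any():
        raise ValueError("alpha must be >= 1 (alpha = evidence + 1)")
    return alpha


def _check_onehot(onehot: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    onehot = np.atleast_2d(np.asarray(onehot, dtype=float))
    if onehot.shape != shape:
        raise ValueError(f"one-hot shape {onehot.shape} != alpha shape {shape}")
    if not np.allclose(onehot.sum(axis=1), 1.0) or not np.isin(onehot, (0.0, 1.0)).all():
        raise ValueError("rows must be one-hot")
    return onehot


def ace_loss(alpha: np.ndarray, onehot: np.ndarray) -> tuple[np.ndarray, float]:
    """Adaptive evidential cross-entropy: sum_k y_k [psi(S) - psi(alpha_k)].

    The Dirichlet-expected negative log-likelihood of the true class;
    strictly positive for finite evidence and decreasing in the true-class
    evidence (psi(S) - psi(alpha_true) ~ 1/alpha_true for large alpha_true).
    """
    alpha = _check_alpha(alpha)
    onehot = _check_onehot(onehot, alpha.shape)
    s = alpha.sum(axis=1)
    per_sample = (onehot * (digamma(s)[:, None] - digamma(alpha))).sum(axis=1)
    return per_sample, float(per_sample.mean())


def kl_to_uniform(alpha: np.ndarray, form: str = "standard") -> tuple[np.ndarray, float]:
    """KL(Dir(alpha) || Dir(1)) per sample.

    form="standard" is the closed form
        logGamma(S) - sum_k logGamma(alpha_k) - logGamma(K)
        + sum_k (alpha_k - 1)(psi(alpha_k) - psi(S)),
    which is >= 0 with equality iff alpha = 1. form="as_printed" keeps an
    alternative published rendering that drops the -sum logGamma(alpha_k)
    term and negates the trailing sum; it is retained for auditability only
    and is not guaranteed non-negative.
    """
    if form not in KL_FORMS:
        raise ValueError(f"unknown kl form {form!r}; expected one of {KL_FORMS}")
    alpha = _check_alpha(alpha)
    k = alpha.shape[1]
    s = alpha.sum(axis=1)
    trailing = ((alpha - 1.0) * (digamma(alpha) - digamma(s)[:, None])).sum(axis=1)
    if form == "standard":
        per_sample = gammaln(s) - gammaln(alpha).sum(axis=1) - gammaln(k) + trailing
    else:
        per_sample = gammaln(s) - gammaln(k) - trailing
    return per_sample, float(per_sample.mean())


def anneal_coefficient(epoch: int, anneal_epochs: int) -> float:
    """Annealing weight min(1, t/E) for the KL regularizer."""
    if anneal_epochs < 1:
        raise ValueError(f"anneal_epochs must be >= 1, got {anneal_epochs}")
    if epoch < 0:
        raise ValueError(f"epoch must be >= 0, got {epoch}")
    return min(1.0, epoch / anneal_epochs)


@dataclass(frozen=True)
class AnnealState:
    epoch: int
    anneal_epochs: int

    @property
    def coefficient(self) -> float:
        return anneal_coefficient(self.epoch, self.anneal_epochs)


def masked_alpha(alpha: np.ndarray, onehot: np.ndarray) -> np.ndarray:
    """Remove the true-class evidence before the KL: alpha~ = y + (1-y)*alpha.

    The KL regularizer then shrinks only *misleading* evidence, leaving the
    true class free to accumulate confidence — the convention of the
    original evidential-learning literature. Without the mask the KL pins
    the true-class concentration near 2 (uncertainty near 2/3 for K = 2)
    regardless of the data, erasing the in- vs out-of-distribution
    uncertainty contrast the method relies on.
    """
    return onehot + (1.0 - onehot) * alpha


def edl_loss(
    alpha: np.ndarray,
    onehot: np.ndarray,
    anneal: AnnealState,
    kl_form: str = "standard",
    kl_mask_true_class: bool = True,
) -> float:
    """Mean evidential loss: ACE + lambda_t * KL-to-uniform."""
    _, ace = ace_loss(alpha, onehot)
    lam = anneal.coefficient
    if lam == 0.0:
        return ace
    onehot = _check_onehot(onehot, np.atleast_2d(alpha).shape)
    kl_alpha = masked_alpha(np.atleast_2d(alpha), onehot) if kl_mask_true_class else alpha
    _, kl = kl_to_uniform(kl_alpha, form=kl_form)
    return ace + lam * kl


def _kl_grad_alpha(alpha: np.ndarray, kl_form: str) -> np.ndarray:
    s = alpha.sum(axis=1)
    k = alpha.shape[1]
    psi1_s = polygamma(1, s)[:, None]
    psi1_a = polygamma(1, alpha)
    if kl_form == "standard":
        return (alpha - 1.0) * psi1_a - (s - k)[:, None] * psi1_s
    # as_printed: d/da_j [logG(S) - logG(K) - trailing]
    psi_s = digamma(s)[:, None]
    return (
        psi_s
        - (digamma(alpha) - psi_s)
        - (alpha - 1.0) * psi1_a
        + (s - k)[:, None] * psi1_s
    )


def edl_loss_grad_alpha(
    alpha: np.ndarray,
    onehot: np.ndarray,
    anneal: AnnealState,
    kl_form: str = "standard",
    kl_mask_true_class: bool = True,
) -> np.ndarray:
    """Gradient of the mean EDL loss with respect to alpha, shape (Q, K).

    ACE term: d/dalpha_j = psi1(S) - y_j psi1(alpha_j).
    Standard KL: d/dalpha_j = (alpha_j - 1) psi1(alpha_j) - (S - K) psi1(S),
    evaluated at the masked alpha~ (true-class entries carry no KL gradient)
    when the mask is on.
    """
    alpha = _check_alpha(alpha)
    onehot = _check_onehot(onehot, alpha.shape)
    q = alpha.shape[0]
    s = alpha.sum(axis=1)
    psi1_s = polygamma(1, s)[:, None]
    psi1_a = polygamma(1, alpha)
    grad = psi1_s - onehot * psi1_a
    lam = anneal.coefficient
    if lam > 0.0:
        if kl_mask_true_class:
            grad_kl = (1.0 - onehot) * _kl_grad_alpha(masked_alpha(alpha, onehot), kl_form)
        else:
            grad_kl = _kl_grad_alpha(alpha, kl_form)
        grad = grad + lam * grad_kl
    return grad / q


def cross_entropy_loss(prob: np.ndarray, onehot: np.ndarray, eps: float = 1e-12) -> float:
    """Plain cross-entropy on expected probabilities; diagnostic alternative
    to the evidential loss, not used by the default training objective."""
    prob = np.atleast_2d(np.asarray(prob, dtype=float))
    onehot = _check_onehot(onehot, prob.shape)
    return float(-(onehot * np.log(np.clip(prob, eps, 1.0))).sum(axis=1).mean())
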