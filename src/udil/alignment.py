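"""Data-free domain alignment: sample partitioning and the MMD penalty.

Samples whose current-vs-historical predictive divergence falls below the
class threshold (and which pass the reliability gate) form the
domain-similar set; the rest are domain-dissimilar. The squared maximum mean
discrepancy between the two sets' embeddings, under a Gaussian RBF kernel,
is the alignment loss: shrinking it keeps the representation of drifting
samples close to the representation that still agrees with the previous
domain's extractor, approximating the historical feature distribution
without any historical data.

The MMD^2 estimator is the V-statistic (self-pairs included); an unbiased
U-statistic is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .synthetic import NEGATIVE_LABEL, POSITIVE_LABEL
from .thresholds import ClassThresholds, DivergenceRecord


@dataclass
class Partition:
    """Disjoint, exhaustive index sets per class plus their pooled unions."""

    similar_m: np.ndarray
    dissimilar_m: np.ndarray
    similar_h: np.ndarray
    dissimilar_h: np.ndarray

    def __post_init__(self) -> None:
        for name in ("similar_m", "dissimilar_m", "similar_h", "dissimilar_h"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))

    @property
    def similar_all(self) -> np.ndarray:
        return np.sort(np.concatenate([self.similar_m, self.similar_h]))

    @property
    def dissimilar_all(self) -> np.ndarray:
        return np.sort(np.concatenate([self.dissimilar_m, self.dissimilar_h]))


@dataclass(frozen=True)
class KernelConfig:
    bandwidth_mode: str = "median_heuristic"  # or "fixed"
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.bandwidth_mode not in ("median_heuristic", "fixed"):
            raise ValueError(f"unknown bandwidth_mode {self.bandwidth_mode!r}")
        if self.bandwidth_mode == "fixed" and (self.sigma is None or self.sigma <= 0):
            raise ValueError("fixed bandwidth requires sigma > 0")


def partition_samples(
    records: Sequence[DivergenceRecord], thresholds: ClassThresholds
) -> Partition:
    """Split samples into domain-similar / domain-dissimilar sets per class.

    A sample is similar iff its divergence is strictly below its class
    threshold AND it is reliable; everything else is dissimilar. Empty sets
    are legal outcomes.
    """
    sets: dict[tuple[int, bool], list[int]] = {
        (POSITIVE_LABEL, True): [], (POSITIVE_LABEL, False): [],
        (NEGATIVE_LABEL, True): [], (NEGATIVE_LABEL, False): [],
    }
    for r in records:
        similar = r.reliable and r.divergence < thresholds.tau_for(r.label)
        sets[(r.label, similar)].append(r.sample_index)
    return Partition(
        similar_m=sets[(POSITIVE_LABEL, True)],
        dissimilar_m=sets[(POSITIVE_LABEL, False)],
        similar_h=sets[(NEGATIVE_LABEL, True)],
        dissimilar_h=sets[(NEGATIVE_LABEL, False)],
    )


def rbf_kernel(a: np.ndarray, b: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian RBF Gram matrix: exp(-||a_i - b_j||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature dimensions disagree")
    sq = cdist(a, b, metric="sqeuclidean")
    return np.exp(-sq / (2.0 * sigma**2))


def median_bandwidth(x: np.ndarray) -> float:
    """Median heuristic: sigma^2 = median nonzero pairwise sq. distance / 2.

    Falls back to 1.0 when every pairwise distance is zero.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] < 2:
        raise ValueError("median bandwidth needs at least 2 rows")
    sq = pdist(x, metric="sqeuclidean")
    nonzero = sq[sq > 0]
    if nonzero.size == 0:
        return 1.0
    return float(np.sqrt(np.median(nonzero) / 2.0))


def mmd2(xs: np.ndarray, xd: np.ndarray, sigma: float, unbiased: bool = False) -> float:
    """Squared MMD between two sample sets under the RBF kernel.

    Default is the V-statistic (all pairs, self-pairs included), which is
    non-negative for a characteristic kernel and exactly zero for identical
    sets. ``unbiased=True`` drops self-pairs in the within-set terms
    (U-statistic; can go slightly negative).
    """
    xs = np.atleast_2d(np.asarray(xs, dtype=float))
    xd = np.atleast_2d(np.asarray(xd, dtype=float))
    n, m = xs.shape[0], xd.shape[0]
    if n == 0 or m == 0:
        raise ValueError("mmd2 requires two non-empty sets")
    kss = rbf_kernel(xs, xs, sigma)
    kdd = rbf_kernel(xd, xd, sigma)
    ksd = rbf_kernel(xs, xd, sigma)
    if unbiased:
        if n < 2 or m < 2:
            raise ValueError("unbiased estimator needs >= 2 samples per set")
        term_ss = (kss.sum() - np.trace(kss)) / (n * (n - 1))
        term_dd = (kdd.sum() - np.trace(kdd)) / (m * (m - 1))
    else:
        term_ss = kss.sum() / n**2
        term_dd = kdd.sum() / m**2
    return float(term_ss + term_dd - 2.0 * ksd.sum() / (n * m))


def mmd2_grad(
    xs: np.ndarray, xd: np.ndarray, sigma: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """V-statistic MMD^2 and its gradients with respect to both sample sets.

    The bandwidth is treated as a constant (no gradient through a median
    heuristic). For the RBF kernel, d k(x,z)/dx = -k(x,z)(x - z)/sigma^2.
    """
    xs = np.atleast_2d(np.asarray(xs, dtype=float))
    xd = np.atleast_2d(np.asarray(xd, dtype=float))
    n, m = xs.shape[0], xd.shape[0]
    kss = rbf_kernel(xs, xs, sigma)
    kdd = rbf_kernel(xd, xd, sigma)
    ksd = rbf_kernel(xs, xd, sigma)
    value = float(kss.sum() / n**2 + kdd.sum() / m**2 - 2.0 * ksd.sum() / (n * m))
    inv = 1.0 / sigma**2
    # within-set terms: x_a appears as both kernel arguments -> factor 2
    grad_s = -(2.0 / n**2) * inv * (kss.sum(axis=1)[:, None] * xs - kss @ xs)
    grad_s += (2.0 / (n * m)) * inv * (ksd.sum(axis=1)[:, None] * xs - ksd @ xd)
    grad_d = -(2.0 / m**2) * inv * (kdd.sum(axis=1)[:, None] * xd - kdd @ xd)
    grad_d += (2.0 / (n * m)) * inv * (ksd.sum(axis=0)[:, None] * xd - ksd.T @ xs)
    return value, grad_s, grad_d


def alignment_loss(
    embeddings: np.ndarray,
    partition: Partition,
    kernel: KernelConfig = KernelConfig(),
    min_set_size: int = 2,
) -> tuple[float, bool]:
    """MMD^2 between similar and dissimilar embeddings; (value, skipped).

    Degrades to (0.0, skipped=True) when either set has fewer than
    ``min_set_size`` members — zero-variance kernel statistics are never
    computed.
    """
    value, _, skipped, _ = alignment_loss_grad(embeddings, partition, kernel, min_set_size)
    return value, skipped


def alignment_loss_grad(
    embeddings: np.ndarray,
    partition: Partition,
    kernel: KernelConfig = KernelConfig(),
    min_set_size: int = 2,
) -> tuple[float, np.ndarray, bool, float | None]:
    """Alignment loss with gradient wrt the full embedding matrix.

    Returns (value, grad (Q x p), skipped, sigma_used). The median-heuristic
    bandwidth is computed on the union of the two sets and held constant in
    the gradient.
    """
    embeddings = np.atleast_2d(np.asarray(embeddings, dtype=float))
    grad = np.zeros_like(embeddings)
    sim, dis = partition.similar_all, partition.dissimilar_all
    if sim.size < min_set_size or dis.size < min_set_size:
        return 0.0, grad, True, None
    xs, xd = embeddings[sim], embeddings[dis]
    if kernel.bandwidth_mode == "fixed":
        sigma = float(kernel.sigma)
    else:
        sigma = median_bandwidth(np.vstack([xs, xd]))
    value, grad_s, grad_d = mmd2_grad(xs, xd, sigma)
    np.add.at(grad, sim, grad_s)
    np.add.at(grad, dis, grad_d)
    return value, grad, False, sigma
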