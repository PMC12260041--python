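"""Sequential training over a domain stream.

The first domain is trained with the evidential loss alone. Every later
domain starts from the previous model: the extractor of the finished stage
is frozen as a snapshot, and each epoch (i) computes current and historical
predictions for the whole training split in no-gradient mode, (ii) learns
class-specific thresholds from the divergence records and partitions the
samples into domain-similar/dissimilar sets, and (iii) takes gradient steps
on   mean EDL loss + lambda * MMD^2(similar, dissimilar)   with the
partition fixed for the epoch. By default the similar side of the MMD is
represented by the frozen snapshot's embeddings, anchoring the drifting
samples to the historical feature distribution. A single classifier is
carried across domains and is shared by the current and historical
prediction paths.

Two baselines bracket the method: naive sequential fine-tuning (no
snapshot, no alignment) and joint training on the pooled stream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
import numpy as np

from ._nets import MLP, Adam
from .alignment import (
    KernelConfig,
    Partition,
    median_bandwidth,
    mmd2_grad,
    partition_samples,
)
from .evidential import (
    AnnealState,
    DirichletOutput,
    edl_loss,
    edl_loss_grad_alpha,
    evidence_to_output,
    logits_to_evidence,
)
from .evaluation import MetricsReport, confusion_metrics
from .synthetic import DomainDataset, StreamData, StreamSpec, make_stream
from .thresholds import batch_divergences, fixed_thresholds, learn_thresholds

N_CLASSES = 2

THRESHOLD_MODES = ("class", "global", "fixed")
OBJECTIVES = ("edl", "cross_entropy")


@dataclass(frozen=True)
class TrainConfig:
    """All tunable knobs of the incremental trainer.

    ``lambda_align`` trades current-domain fit against alignment (0.5 by
    default, the sweet spot of the inverted-U sensitivity pattern);
    ``sens_m``/``sens_h`` are the per-class threshold sensitivity
    coefficients; ``reliability_quantile`` sets the class-wise uncertainty
    cut for the reliability gate.
    """

    lambda_align: float = 0.5
    anneal_epochs: int = 10
    epochs_per_domain: int = 50
    learning_rate: float = 1e-3
    weight_decay: float = 3.0
    batch_size: int = 32
    sens_m: float = 0.5
    sens_h: float = 0.5
    reliability_quantile: float = 0.9
    u_max: float | None = None
    kernel: KernelConfig = field(default_factory=KernelConfig)
    divergence: str = "sym_kl"
    kl_form: str = "standard"
    kl_mask_true_class: bool = True
    threshold_mode: str = "class"
    fixed_tau: float = 0.4
    align_target: str = "historical"
    classwise_mmd: bool = True
    min_set_size: int = 2
    epsilon: float = 1e-8
    hidden_dims: tuple[int, ...] = (64, 32)
    objective: str = "edl"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_align < 0:
            raise ValueError("lambda_align must be >= 0")
        if self.anneal_epochs < 1:
            raise ValueError("anneal_epochs must be >= 1")
        if self.epochs_per_domain < 1:
            raise ValueError("epochs_per_domain must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.reliability_quantile <= 1.0:
            raise ValueError("reliability_quantile must lie in (0, 1]")
        if self.threshold_mode not in THRESHOLD_MODES:
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.align_target not in ("historical", "current"):
            raise ValueError(f"unknown align_target {self.align_target!r}")
        if self.objective not in OBJECTIVES:
            raise ValueError(f"unknown objective {self.objective!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kernel"] = {"bandwidth_mode": self.kernel.bandwidth_mode, "sigma": self.kernel.sigma}
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ModelState:
    """Feature extractor F (d -> p) plus evidential classifier C (p -> K)."""

    extractor: MLP
    classifier: MLP
    domain_index: int

    @property
    def embedding_dim(self) -> int:
        return self.extractor.dims[-1]

    def predict(self, features: np.ndarray) -> DirichletOutput:
        logits = self.classifier(self.extractor(np.asarray(features, dtype=float)))
        return evidence_to_output(logits_to_evidence(logits))

    def predicted_labels(self, features: np.ndarray) -> np.ndarray:
        return self.predict(features).predicted_labels()


@dataclass
class ExtractorSnapshot:
    """Frozen copy of a previous stage's extractor (the historical model).

    Receives no gradient updates; produces identical outputs for identical
    inputs for as long as it lives.
    """

    _mlp: MLP

    @classmethod
    def of(cls, state: ModelState) -> "ExtractorSnapshot":
        return cls(_mlp=state.extractor.clone())

    @property
    def embedding_dim(self) -> int:
        return self._mlp.dims[-1]

    def transform(self, features: np.ndarray) -> np.ndarray:
        return self._mlp(np.asarray(features, dtype=float))


@dataclass
class SequenceResult:
    """Stage x domain metric matrix plus the final model and training logs."""

    domain_names: list[str]
    metrics: list[dict[str, MetricsReport]]  # one dict per training stage
    final_state: ModelState
    logs: list[list[dict]]  # per-stage list of per-epoch/step records
    seed: int
    config_hash: str

    @property
    def n_stages(self) -> int:
        return len(self.metrics)

    def f1_matrix(self) -> np.ndarray:
        return np.array(
            [[self.metrics[s][name].f1 for name in self.domain_names]
             for s in range(self.n_stages)]
        )

    def metric_matrix(self, metric: str) -> np.ndarray:
        return np.array(
            [[getattr(self.metrics[s][name], metric) for name in self.domain_names]
             for s in range(self.n_stages)]
        )


def _onehot(labels: np.ndarray) -> np.ndarray:
    return np.eye(N_CLASSES)[np.asarray(labels, dtype=int)]


def _init_state(dim: int, config: TrainConfig) -> ModelState:
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xA11CE)))
    extractor = MLP([dim, *config.hidden_dims], rng, activate_last=True)
    classifier = MLP([config.hidden_dims[-1], N_CLASSES], rng)
    # zero-initialized evidential head: the model starts from "no evidence
    # anywhere" (u = 1), and evidence readout directions exist only where
    # training carves them out — off-manifold inputs inherit near-zero
    # evidence instead of the random readout of a random init
    for w in classifier.weights:
        w[:] = 0.0
    for b in classifier.biases:
        b[:] = 0.0
    return ModelState(extractor=extractor, classifier=classifier, domain_index=0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _classification_grad_step(
    state: ModelState,
    xb: np.ndarray,
    yb: np.ndarray,
    anneal: AnnealState,
    config: TrainConfig,
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Loss value plus gradients for the classification objective on a batch."""
    emb, cache_e = state.extractor.forward(xb)
    logits, cache_c = state.classifier.forward(emb)
    onehot = _onehot(yb)
    if config.objective == "edl":
        evidence = logits_to_evidence(logits)
        alpha = evidence + 1.0
        loss = edl_loss(alpha, onehot, anneal, kl_form=config.kl_form,
                        kl_mask_true_class=config.kl_mask_true_class)
        dalpha = edl_loss_grad_alpha(alpha, onehot, anneal, kl_form=config.kl_form,
                                     kl_mask_true_class=config.kl_mask_true_class)
        dlogits = dalpha * _sigmoid(logits)  # softplus' = sigmoid
    else:
        prob = _softmax(logits)
        loss = float(-(onehot * np.log(np.clip(prob, 1e-12, 1.0))).sum(axis=1).mean())
        dlogits = (prob - onehot) / xb.shape[0]
    demb, grads_c = state.classifier.backward(cache_c, dlogits)
    _, grads_e = state.extractor.backward(cache_e, demb)
    # gradient list order must match MLP.params(): weights first, then biases
    flat_e = [pair[0] for pair in grads_e] + [pair[1] for pair in grads_e]
    flat_c = [pair[0] for pair in grads_c] + [pair[1] for pair in grads_c]
    return float(loss), flat_e, flat_c


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _alignment_grad(
    state: ModelState,
    snapshot: ExtractorSnapshot | None,
    features: np.ndarray,
    partition: Partition,
    config: TrainConfig,
) -> tuple[float, list[np.ndarray] | None, bool, float | None]:
    """Alignment loss over full-domain embeddings and its extractor gradient.

    With ``align_target="historical"`` (default) the domain-similar set is
    represented by the frozen previous-stage extractor's embeddings — the
    surrogate for the prior domain's feature distribution — and only the
    current embeddings of the dissimilar set receive gradient, pulling the
    drifting samples back toward the historical representation. With
    ``"current"`` both sets use the current extractor, matching the printed
    form of the alignment loss.

    ``classwise_mmd`` aligns similar/dissimilar within each class and
    averages; the pooled union alternative couples class composition and,
    under imbalance, attracts the minority cluster toward the majority.
    """
    emb, cache = state.extractor.forward(features)
    anchored = config.align_target == "historical" and snapshot is not None
    if config.classwise_mmd:
        pairs = [
            (partition.similar_m, partition.dissimilar_m),
            (partition.similar_h, partition.dissimilar_h),
        ]
    else:
        pairs = [(partition.similar_all, partition.dissimilar_all)]
    hist = snapshot.transform(features) if anchored else None
    values: list[float] = []
    sigmas: list[float] = []
    grad_emb = np.zeros_like(emb)
    for sim, dis in pairs:
        if sim.size < config.min_set_size or dis.size < config.min_set_size:
            continue
        xs = hist[sim] if anchored else emb[sim]
        xd = emb[dis]
        if config.kernel.bandwidth_mode == "fixed":
            sigma = float(config.kernel.sigma)
        else:
            sigma = median_bandwidth(np.vstack([xs, xd]))
        value, grad_s, grad_d = mmd2_grad(xs, xd, sigma)
        if not anchored:
            np.add.at(grad_emb, sim, grad_s)
        np.add.at(grad_emb, dis, grad_d)
        values.append(value)
        sigmas.append(sigma)
    if not values:
        return 0.0, None, True, None
    value = float(np.mean(values))
    grad_emb /= len(values)
    _, grads_e = state.extractor.backward(cache, grad_emb)
    flat = [pair[0] for pair in grads_e] + [pair[1] for pair in grads_e]
    return value, flat, False, sigmas[0]


def _minibatches(
    n: int, batch_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i: i + batch_size] for i in range(0, n, batch_size)]


def _epoch_partition(
    state: ModelState,
    snapshot: ExtractorSnapshot,
    data: DomainDataset,
    config: TrainConfig,
) -> tuple[Partition, dict]:
    """No-gradient threshold/partition pass over the full training split."""
    current = state.predict(data.features)
    hist_logits = state.classifier(snapshot.transform(data.features))
    historical = evidence_to_output(logits_to_evidence(hist_logits))
    records = batch_divergences(
        current, historical, data.labels,
        reliability_quantile=config.reliability_quantile,
        u_max=config.u_max, epsilon=config.epsilon, kind=config.divergence,
    )
    if config.threshold_mode == "fixed":
        thr = fixed_thresholds(config.fixed_tau)
    else:
        thr = learn_thresholds(
            records, sens_m=config.sens_m, sens_h=config.sens_h,
            pooled=config.threshold_mode == "global",
        )
    partition = partition_samples(records, thr)
    diag = {
        "tau_m": thr.tau_m, "tau_h": thr.tau_h,
        "mu_m": thr.mu_m, "mu_h": thr.mu_h,
        "sigma_m": thr.sigma_m, "sigma_h": thr.sigma_h,
        "n_similar": int(partition.similar_all.size),
        "n_dissimilar": int(partition.dissimilar_all.size),
        "n_similar_m": int(partition.similar_m.size),
        "n_similar_h": int(partition.similar_h.size),
        "reliable_fraction": float(np.mean([r.reliable for r in records])),
    }
    return partition, diag


def _check_two_classes(data: DomainDataset) -> None:
    if data.n_positive == 0 or data.n_negative == 0:
        raise ValueError(f"domain {data.name!r} must contain both classes for training")


def _train_stage(
    state: ModelState,
    data: DomainDataset,
    config: TrainConfig,
    snapshot: ExtractorSnapshot | None,
    align: bool,
    log: list[dict],
    stage_seed: int,
) -> ModelState:
    _check_two_classes(data)
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x57A6E, stage_seed)))
    opt = Adam(state.extractor.params() + state.classifier.params(), lr=config.learning_rate)
    lam = config.lambda_align if align else 0.0
    for epoch in range(config.epochs_per_domain):
        anneal = AnnealState(epoch=epoch, anneal_epochs=config.anneal_epochs)
        partition: Partition | None = None
        if snapshot is not None and align:
            partition, diag = _epoch_partition(state, snapshot, data, config)
            log.append({"kind": "thresholds", "stage": state.domain_index + 1,
                        "epoch": epoch, **diag})
        epoch_losses = []
        for step, idx in enumerate(_minibatches(len(data), config.batch_size, rng)):
            cls_loss, grads_e, grads_c = _classification_grad_step(
                state, data.features[idx], data.labels[idx], anneal, config
            )
            mmd_value = 0.0
            if partition is not None and lam > 0:
                mmd_value, align_grads, skipped, sigma = _alignment_grad(
                    state, snapshot, data.features, partition, config
                )
                if not skipped:
                    grads_e = [ge + lam * ga for ge, ga in zip(grads_e, align_grads)]
            total = cls_loss + lam * mmd_value
            opt.step(grads_e + grads_c)
            if config.weight_decay > 0:
                # decoupled decay on the evidential head only: readout
                # directions without sustained data support shrink away,
                # so unfamiliar embeddings read out little evidence
                shrink = 1.0 - config.learning_rate * config.weight_decay
                for w in state.classifier.weights:
                    w *= shrink
            epoch_losses.append((cls_loss, mmd_value, total))
            log.append({"kind": "step", "stage": state.domain_index + 1, "epoch": epoch,
                        "step": step, "edl": cls_loss, "mmd": mmd_value,
                        "lambda": lam, "total": total})
        mean_edl = float(np.mean([e for e, _, _ in epoch_losses]))
        log.append({"kind": "epoch", "stage": state.domain_index + 1, "epoch": epoch,
                    "mean_edl": mean_edl,
                    "mean_mmd": float(np.mean([m for _, m, _ in epoch_losses]))})
    state.domain_index += 1
    return state


def train_first_domain(data: DomainDataset, config: TrainConfig,
                       log: list[dict] | None = None) -> ModelState:
    """Train F and C from scratch on the first domain with the EDL loss."""
    state = _init_state(data.features.shape[1], config)
    return _train_stage(state, data, config, snapshot=None, align=False,
                        log=log if log is not None else [], stage_seed=0)


def train_incremental_domain(
    state: ModelState,
    snapshot: ExtractorSnapshot,
    data: DomainDataset,
    config: TrainConfig,
    log: list[dict] | None = None,
) -> ModelState:
    """Continue training on a later domain with thresholds + alignment.

    The snapshot must come from ``state`` before any domain-i updates; the
    classifier is carried over and keeps training (one classifier serves
    both the current and historical prediction paths).
    """
    if snapshot.embedding_dim != state.embedding_dim:
        raise ValueError(
            f"snapshot embedding width {snapshot.embedding_dim} != "
            f"state embedding width {state.embedding_dim}"
        )
    return _train_stage(state, data, config, snapshot=snapshot, align=True,
                        log=log if log is not None else [],
                        stage_seed=state.domain_index)


def _evaluate_all(state: ModelState, stream: StreamData) -> dict[str, MetricsReport]:
    out = {}
    for test in stream.test:
        preds = state.predicted_labels(test.features)
        out[test.name] = confusion_metrics(test.labels, preds)
    return out


def _resolve_stream(stream: StreamSpec | StreamData) -> StreamData:
    return make_stream(stream) if isinstance(stream, StreamSpec) else stream


def run_sequence(stream: StreamSpec | StreamData, config: TrainConfig) -> SequenceResult:
    """Full incremental protocol: after every stage, evaluate on all domains."""
    data = _resolve_stream(stream)
    logs: list[list[dict]] = []
    metrics: list[dict[str, MetricsReport]] = []
    stage_log: list[dict] = []
    state = train_first_domain(data.train[0], config, log=stage_log)
    logs.append(stage_log)
    metrics.append(_evaluate_all(state, data))
    for domain in data.train[1:]:
        snapshot = ExtractorSnapshot.of(state)
        stage_log = []
        state = train_incremental_domain(state, snapshot, domain, config, log=stage_log)
        logs.append(stage_log)
        metrics.append(_evaluate_all(state, data))
    return SequenceResult(
        domain_names=data.names, metrics=metrics, final_state=state, logs=logs,
        seed=config.seed, config_hash=config.content_hash(),
    )


def baseline_finetune(stream: StreamSpec | StreamData, config: TrainConfig) -> SequenceResult:
    """Naive sequential fine-tuning: no snapshot, thresholds or alignment."""
    data = _resolve_stream(stream)
    logs: list[list[dict]] = []
    metrics: list[dict[str, MetricsReport]] = []
    stage_log: list[dict] = []
    state = train_first_domain(data.train[0], config, log=stage_log)
    logs.append(stage_log)
    metrics.append(_evaluate_all(state, data))
    for k, domain in enumerate(data.train[1:], start=1):
        stage_log = []
        state = _train_stage(state, domain, config, snapshot=None, align=False,
                             log=stage_log, stage_seed=k)
        logs.append(stage_log)
        metrics.append(_evaluate_all(state, data))
    return SequenceResult(
        domain_names=data.names, metrics=metrics, final_state=state, logs=logs,
        seed=config.seed, config_hash=config.content_hash(),
    )


def baseline_joint(stream: StreamSpec | StreamData, config: TrainConfig) -> SequenceResult:
    """Joint training on the pooled stream; one stage row, per-domain metrics."""
    data = _resolve_stream(stream)
    pooled = DomainDataset(
        name="pooled",
        features=np.vstack([d.features for d in data.train]),
        labels=np.concatenate([d.labels for d in data.train]),
        sample_ids=[sid for d in data.train for sid in d.sample_ids],
    )
    stage_log: list[dict] = []
    state = train_first_domain(pooled, config, log=stage_log)
    return SequenceResult(
        domain_names=data.names, metrics=[_evaluate_all(state, data)],
        final_state=state, logs=[stage_log],
        seed=config.seed, config_hash=config.content_hash(),
    )
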