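"""Incremental trainer: determinism, snapshot integrity, baselines, logging."""

import numpy as np
import pytest

from udil.synthetic import DomainDataset, DomainSpec, make_domain, make_stream
from udil.training import (
    ExtractorSnapshot,
    TrainConfig,
    baseline_finetune,
    baseline_joint,
    run_sequence,
    train_first_domain,
    train_incremental_domain,
)
from udil.evaluation import confusion_metrics

FAST = dict(epochs_per_domain=5, anneal_epochs=3)


def test_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(lambda_align=-0.1)
    with pytest.raises(ValueError):
        TrainConfig(anneal_epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(reliability_quantile=0.0)
    with pytest.raises(ValueError):
        TrainConfig(threshold_mode="nope")
    with pytest.raises(ValueError):
        TrainConfig(align_target="sideways")


def test_first_domain_requires_both_classes():
    data = DomainDataset("x", np.random.default_rng(0).standard_normal((10, 3)),
                         np.ones(10, int), [str(i) for i in range(10)])
    with pytest.raises(ValueError, match="both classes"):
        train_first_domain(data, TrainConfig(**FAST))


def test_first_domain_fits_separable_data():
    """Training F1 >= 0.95 on a well-separated domain, several seeds."""
    for seed in range(5):
        spec = DomainSpec(name="d", n_positive=40, n_negative=120, dim=16,
                          class_separation=4.0)
        data = make_domain(spec, seed)
        state = train_first_domain(data, TrainConfig(epochs_per_domain=50, seed=seed))
        m = confusion_metrics(data.labels, state.predicted_labels(data.features))
        assert m.f1 >= 0.95


def test_first_domain_deterministic_and_descending():
    spec = DomainSpec(name="d", n_positive=20, n_negative=40, dim=6,
                      class_separation=2.5)
    data = make_domain(spec, 0)
    logs = []
    config = TrainConfig(seed=4, epochs_per_domain=12, anneal_epochs=1)
    for _ in range(2):
        log = []
        state = train_first_domain(data, config, log=log)
        logs.append((state, log))
    a, b = logs
    for pa, pb in zip(a[0].extractor.params() + a[0].classifier.params(),
                      b[0].extractor.params() + b[0].classifier.params()):
        assert np.array_equal(pa, pb)
    # compare epochs trained under the same (saturated) annealing weight
    epochs = [r for r in a[1] if r["kind"] == "epoch"]
    assert epochs[-1]["mean_edl"] < epochs[1]["mean_edl"]


def test_snapshot_is_frozen_during_incremental_training(tiny_stream):
    data = make_stream(tiny_stream)
    config = TrainConfig(seed=1, **FAST)
    state = train_first_domain(data.train[0], config)
    snapshot = ExtractorSnapshot.of(state)
    probe = data.train[1].features[:8]
    before = snapshot.transform(probe).copy()
    train_incremental_domain(state, snapshot, data.train[1], config)
    after = snapshot.transform(probe)
    assert after.tobytes() == before.tobytes()
    # the live extractor did move
    assert not np.allclose(state.extractor(probe), before)


def test_snapshot_width_mismatch_rejected(tiny_stream):
    data = make_stream(tiny_stream)
    config = TrainConfig(seed=1, **FAST)
    state = train_first_domain(data.train[0], config)
    other = train_first_domain(data.train[0],
                               TrainConfig(seed=1, hidden_dims=(16, 8), **FAST))
    with pytest.raises(ValueError, match="width"):
        train_incremental_domain(state, ExtractorSnapshot.of(other),
                                 data.train[1], config)


def test_loss_ledger_identity(tiny_stream):
    """Logged total equals EDL + lambda x MMD at every recorded step."""
    result = run_sequence(make_stream(tiny_stream), TrainConfig(seed=2, **FAST))
    steps = [r for log in result.logs for r in log if r["kind"] == "step"]
    assert steps
    for r in steps:
        assert r["total"] == pytest.approx(r["edl"] + r["lambda"] * r["mmd"], abs=1e-12)


def test_run_sequence_matrix_shape_and_determinism(tiny_stream):
    config = TrainConfig(seed=3, **FAST)
    data = make_stream(tiny_stream)
    r1 = run_sequence(data, config)
    assert r1.n_stages == 3
    mat = r1.f1_matrix()
    assert mat.shape == (3, 3)
    per_cell = r1.metrics[1][r1.domain_names[0]]
    assert 0.0 <= per_cell.acc <= 1.0
    r2 = run_sequence(data, config)
    assert np.allclose(r1.f1_matrix(), r2.f1_matrix(), atol=1e-6)
    assert r1.config_hash == r2.config_hash


def test_incremental_diagnostics_logged(tiny_stream):
    result = run_sequence(make_stream(tiny_stream), TrainConfig(seed=5, **FAST))
    thr_records = [r for r in result.logs[1] if r["kind"] == "thresholds"]
    assert len(thr_records) == FAST["epochs_per_domain"]
    for key in ("tau_m", "tau_h", "n_similar", "n_dissimilar", "reliable_fraction"):
        assert key in thr_records[0]


def test_lambda_zero_equals_finetune(tiny_stream):
    """With lambda = 0 the alignment term is exactly absent."""
    data = make_stream(tiny_stream)
    config = TrainConfig(seed=6, lambda_align=0.0, **FAST)
    seq = run_sequence(data, config)
    ft = baseline_finetune(data, config)
    assert np.allclose(seq.f1_matrix(), ft.f1_matrix(), atol=1e-12)
    for log in seq.logs:
        for r in log:
            if r["kind"] == "step":
                assert r["mmd"] == 0.0


def test_baseline_joint_single_stage(tiny_stream):
    data = make_stream(tiny_stream)
    result = baseline_joint(data, TrainConfig(seed=7, **FAST))
    assert result.n_stages == 1
    assert forget_is_empty(result)
    again = baseline_joint(data, TrainConfig(seed=7, **FAST))
    assert np.allclose(result.f1_matrix(), again.f1_matrix(), atol=1e-12)


def forget_is_empty(result):
    from udil.evaluation import forgetting_scores

    return forgetting_scores(result.f1_matrix()).forgetting == []


def test_single_classifier_shared_between_paths(tiny_stream):
    data = make_stream(tiny_stream)
    config = TrainConfig(seed=8, **FAST)
    state = train_first_domain(data.train[0], config)
    snapshot = ExtractorSnapshot.of(state)
    state = train_incremental_domain(state, snapshot, data.train[1], config)
    # one classifier parameter set; historical path reuses it on snapshot features
    x = data.train[1].features[:4]
    hist_logits = state.classifier(snapshot.transform(x))
    cur_logits = state.classifier(state.extractor(x))
    assert hist_logits.shape == cur_logits.shape == (4, 2)


def test_threshold_mode_variants_run(tiny_stream):
    data = make_stream(tiny_stream)
    for mode, extra in (("fixed", dict(fixed_tau=0.4)), ("global", {})):
        config = TrainConfig(seed=9, threshold_mode=mode, **extra, **FAST)
        result = run_sequence(data, config)
        assert result.f1_matrix().shape == (3, 3)


def test_align_target_current_runs(tiny_stream):
    data = make_stream(tiny_stream)
    config = TrainConfig(seed=10, align_target="current", classwise_mmd=False, **FAST)
    result = run_sequence(data, config)
    assert result.f1_matrix().shape == (3, 3)


def test_cross_entropy_objective_trains(tiny_stream):
    data = make_stream(tiny_stream)
    result = run_sequence(make_stream(tiny_stream),
                          TrainConfig(seed=11, objective="cross_entropy", **FAST))
    assert result.f1_matrix().shape == (3, 3)
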