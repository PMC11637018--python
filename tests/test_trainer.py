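"""Mean-teacher loop: EMA updates, batch composition, checkpoints, reduction
to plain supervised training."""

import numpy as np
import pytest

from uamt3d.backbone import NetworkSpec, build_network
from uamt3d.errors import ConfigurationError
from uamt3d.objectives import LossConfig, supervised_loss
from uamt3d.phantoms import PhantomSpec, generate_case
from uamt3d.trainer import (SGD, Dataset, TrainerConfig, ema_update,
                            load_checkpoint, make_batch, save_checkpoint,
                            train, _rng_streams)
from uamt3d.uncertainty import NoiseSpec


def _params(values):
    from uamt3d.autograd import Tensor
    return {k: Tensor(np.array(v, dtype=np.float64), requires_grad=True)
            for k, v in values.items()}


def test_ema_transfers_one_percent():
    teacher = _params({"w": [0.0]})
    student = _params({"w": [1.0]})
    ema_update(teacher, student, decay=0.99)
    assert teacher["w"].data[0] == pytest.approx(0.01, abs=1e-12)


def test_ema_decay_one_freezes_teacher():
    teacher = _params({"w": [3.0]})
    student = _params({"w": [-1.0]})
    ema_update(teacher, student, decay=1.0)
    assert teacher["w"].data[0] == 3.0


def test_ema_geometric_closed_form_vs_loop():
    t0, s, eps, k = 2.0, 5.0, 0.9, 17
    teacher = _params({"w": [t0]})
    student = _params({"w": [s]})
    for _ in range(k):
        ema_update(teacher, student, eps)
    closed = t0 * eps ** k + s * (1 - eps ** k)
    assert teacher["w"].data[0] == pytest.approx(closed, rel=1e-12)


def test_ema_rejects_incongruent_parameter_sets():
    with pytest.raises(ConfigurationError):
        ema_update(_params({"a": [1.0]}), _params({"b": [1.0]}), 0.99)


def _tiny_dataset(n_labeled=2, n_unlabeled=4, n_test=0, shape=(16, 16, 8), seed=0):
    spec = PhantomSpec(volume_shape=shape, n_cases=n_labeled + n_unlabeled + n_test,
                       labeled_fraction=n_labeled / (n_labeled + n_unlabeled + n_test),
                       test_fraction=n_test / (n_labeled + n_unlabeled + n_test),
                       seed=seed)
    cases = [generate_case(spec, i) for i in range(spec.n_cases)]
    return Dataset.from_cases(cases, spec)


def test_batch_composition_one_labeled_one_unlabeled():
    ds = _tiny_dataset()
    rng = np.random.default_rng(0)
    for _ in range(10):
        x_l, y_l, x_u = make_batch(ds, rng)
        assert x_l.shape == y_l.shape == x_u.shape
        assert set(np.unique(y_l)) <= {0, 1}


def test_batch_sequence_deterministic_for_fixed_seed():
    ds = _tiny_dataset()
    a = [make_batch(ds, np.random.default_rng(5))[0] for _ in range(5)]
    b = [make_batch(ds, np.random.default_rng(5))[0] for _ in range(5)]
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)


def test_labeled_modality_ratio_matches_five_to_three():
    """Over many draws the clean fraction approaches 5/8 = 0.625."""
    ds = _tiny_dataset()
    # distinguish renderings by fingerprint
    clean_ids = {rec["clean"].tobytes() for rec in ds.labeled}
    rng = np.random.default_rng(123)
    hits = 0
    n = 8000
    from uamt3d.io_inference import normalize_intensity
    normed = {normalize_intensity(rec[k]).tobytes(): k
              for rec in ds.labeled for k in ("clean", "degraded")}
    for _ in range(n):
        x_l, _, _ = make_batch(ds, rng)
        if normed[x_l.tobytes()] == "clean":
            hits += 1
    assert hits / n == pytest.approx(0.625, abs=0.03)


def test_empty_labeled_pool_rejected():
    ds = Dataset()
    with pytest.raises(ConfigurationError):
        make_batch(ds, np.random.default_rng(0))


def test_teacher_receives_no_gradients_and_copy_init():
    ds = _tiny_dataset()
    spec = NetworkSpec(levels=2, base_channels=2, sam_kernel=3)
    student, teacher, state = train(ds, spec, TrainerConfig(epochs=1, seed=3),
                                    LossConfig(lambda_max=0.1, rampup_length=10))
    assert all(p.grad is None for p in teacher.parameters().values())
    assert state.step == len(ds.unlabeled)


def test_two_step_ema_matches_hand_tracked_snapshots():
    ds = _tiny_dataset(n_unlabeled=2)
    spec = NetworkSpec(levels=2, base_channels=2, use_residual=False,
                       use_cbam=False)
    rows = []
    student, teacher, _ = train(ds, spec, TrainerConfig(epochs=1, seed=4),
                                LossConfig(lambda_max=0.0), log_rows=rows)
    # replay: teacher = EMA of student snapshots from an identical run
    student2, _, _ = train(ds, spec, TrainerConfig(epochs=1, seed=4),
                           LossConfig(lambda_max=0.0))
    np.testing.assert_array_equal(
        student.parameters()["head.weight"].data,
        student2.parameters()["head.weight"].data)


def test_checkpoint_round_trip_preserves_both_networks(tmp_path, rng):
    ds = _tiny_dataset(n_unlabeled=2)
    spec = NetworkSpec(levels=2, base_channels=2, sam_kernel=3)
    student, teacher, state = train(ds, spec, TrainerConfig(epochs=1, seed=1),
                                    LossConfig(lambda_max=0.05, rampup_length=5))
    path = tmp_path / "ck.zip"
    save_checkpoint(path, student, teacher, state)
    s2, t2, spec2, state2 = load_checkpoint(path)
    assert spec2 == spec and state2.step == state.step
    x = rng.standard_normal((1, 16, 16, 8)).astype(np.float32)
    np.testing.assert_array_equal(student.forward(x).data, s2.forward(x).data)
    np.testing.assert_array_equal(teacher.forward(x).data, t2.forward(x).data)


def test_framework_reduces_to_supervised_loop_exactly():
    """Noise off, dropout off, lambda=0: losses equal a hand-rolled supervised
    loop with the same seed, step for step."""
    ds = _tiny_dataset(n_labeled=2, n_unlabeled=0, shape=(16, 16, 8))
    assert not ds.unlabeled
    spec = NetworkSpec(levels=2, base_channels=2, sam_kernel=3)
    cfg = TrainerConfig(epochs=2, seed=9, lr=0.01)
    rows = []
    train(ds, spec, cfg, LossConfig(lambda_max=0.0), use_dropout=False,
          use_noise=False, log_rows=rows)

    # reference loop
    rngs = _rng_streams(cfg.seed)
    net = build_network(spec, seed=cfg.seed)
    opt = SGD(net.parameters(), cfg.lr, cfg.momentum, cfg.weight_decay)
    ref = []
    for _ in range(len(rows)):
        x_l, y_l, _ = make_batch(ds, rngs["batch"])
        loss = supervised_loss(net.forward(x_l[None]), y_l)
        ref.append(float(loss.item()))
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert [r["sup"] for r in rows] == ref


def test_consistency_loss_engages_after_rampup():
    ds = _tiny_dataset(n_labeled=1, n_unlabeled=3)
    spec = NetworkSpec(levels=2, base_channels=2, sam_kernel=3)
    rows = []
    train(ds, spec, TrainerConfig(epochs=2, seed=2),
          LossConfig(lambda_max=0.1, rampup_length=3), log_rows=rows)
    assert all(np.isfinite(r["total"]) for r in rows)
    assert rows[-1]["lambda"] == pytest.approx(0.1)
    assert any(r["con"] > 0 for r in rows)


def test_noise_spec_clips_and_is_zero_mean():
    noise = NoiseSpec(sigma=0.5, clip=0.2)
    base = np.zeros((32, 32, 32), dtype=np.float32)
    out = noise.apply(base, np.random.default_rng(0))
    assert np.abs(out).max() <= 0.2
    assert abs(out.mean()) < 0.01
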