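import numpy as np
import pytest

from snetseg.io_ct import SliceSample
from snetseg.nn import Tensor
from snetseg.preprocess import PreprocessConfig
from snetseg.snet import AttentionConfig, ModelConfig, build_model
from snetseg.training import (PlateauScheduler, TrainConfig, dice_loss,
                              predict_volume, prepare_samples, train)


def test_dice_loss_extremes():
    t = np.zeros((1, 4, 4), dtype=np.float32)
    t[0, :2] = 1.0
    perfect = dice_loss(Tensor(t.copy()), t)
    assert float(perfect.data) == pytest.approx(0.0, abs=1e-5)
    disjoint = dice_loss(Tensor(1.0 - t), t)
    assert float(disjoint.data) == pytest.approx(1.0, abs=1e-5)


def test_dice_loss_half_confidence():
    # p = 0.5 everywhere on an all-ones target:
    # 1 - 2(0.5 n)/(0.5 n + n) = 1/3
    t = np.ones((1, 4, 4), dtype=np.float32)
    loss = dice_loss(Tensor(np.full_like(t, 0.5)), t)
    assert float(loss.data) == pytest.approx(1.0 / 3.0, abs=1e-6)


def test_dice_loss_shape_mismatch():
    with pytest.raises(ValueError):
        dice_loss(Tensor(np.zeros((1, 4, 4))), np.zeros((1, 5, 5)))


def test_plateau_scheduler_drops_after_exactly_three():
    sched = PlateauScheduler(0.01, patience=3, factor=0.1)
    assert sched.step(1.0) == 0.01        # first epoch improves on inf
    assert sched.step(1.0) == 0.01        # stagnant x1
    assert sched.step(1.0) == 0.01        # stagnant x2
    assert sched.step(1.0) == pytest.approx(0.001)  # stagnant x3 -> drop
    # improvement resets the counter
    assert sched.step(0.5) == pytest.approx(0.001)
    assert sched.step(0.5) == pytest.approx(0.001)


def _toy_samples(rng, n, size=16, case_id="c0"):
    out = []
    for i in range(n):
        tumor = np.zeros((size, size), bool)
        r, c = rng.integers(3, size - 5, size=2)
        tumor[r:r + 4, c:c + 4] = True
        liver = np.ones((size, size), bool)
        img = np.where(tumor, 0.9, 0.2) + rng.normal(0, 0.02, (size, size))
        out.append(SliceSample(image=np.clip(img, 0, 1), liver_mask=liver,
                               tumor_mask=tumor, case_id=case_id, slice_index=i))
    return out


def _tiny_model(seed=0):
    return build_model(ModelConfig(depth=2, base_channels=8, convs_per_block=1,
                                   attention=AttentionConfig(reduction=1),
                                   seed=seed))


def test_overfit_one_batch_halves_loss(rng):
    from snetseg.nn import SGD

    model = _tiny_model(seed=1)
    samples = _toy_samples(rng, 4)
    imgs = np.stack([s.image for s in samples]).astype(np.float32)
    targets = np.stack([s.tumor_mask for s in samples]).astype(np.float32)
    opt = SGD(model.parameters(), lr=0.01, momentum=0.9)
    first = None
    for _ in range(50):
        probs = model(Tensor(imgs))
        loss = dice_loss(probs.reshape(4, 16, 16), targets)
        if first is None:
            first = float(loss.data)
        opt.zero_grad()
        loss.backward()
        opt.step()
    assert float(loss.data) <= 0.5 * first


def test_train_loop_checkpoints_best(rng):
    model = _tiny_model(seed=2)
    train_s = _toy_samples(rng, 8, case_id="tr")
    val_s = _toy_samples(rng, 4, case_id="va")
    cfg = TrainConfig(max_epochs=2, batch_size=4, seed=0, augment=False)
    ckpt, hist = train(model, train_s, val_s, cfg, PreprocessConfig())
    assert len(hist.train_loss) == 2
    assert ckpt["best_epoch"] == hist.best_epoch
    assert ckpt["best_val_dice"] == max(hist.val_dice)
    assert set(ckpt["state"]) == set(model.state_dict())


def test_train_empty_set_raises(rng):
    with pytest.raises(ValueError):
        train(_tiny_model(), [], _toy_samples(rng, 2), TrainConfig())


def test_predict_volume_masked_to_liver(rng):
    from snetseg.phantom import PhantomConfig, generate_case

    case = generate_case(PhantomConfig(image_size=32, n_slices=6,
                                       tumor_radius_range=(2, 3)), seed=5)
    model = _tiny_model()
    pre = PreprocessConfig()
    pred = predict_volume(model, case, pre)
    assert pred.shape == case.volume.data.shape
    assert not (pred & ~case.liver_mask).any()


def test_predict_volume_config_mismatch(rng):
    from snetseg.phantom import PhantomConfig, generate_case
    import dataclasses

    case = generate_case(PhantomConfig(image_size=32, n_slices=6,
                                       tumor_radius_range=(2, 3)), seed=5)
    trained = dataclasses.asdict(PreprocessConfig(hu_window=(-100.0, 300.0)))
    with pytest.raises(ValueError, match="config"):
        predict_volume(_tiny_model(), case, PreprocessConfig(),
                       trained_preprocess=trained)
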