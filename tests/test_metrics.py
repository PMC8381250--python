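import numpy as np
import pytest

from snetseg import metrics


def test_dice_basic():
    a = np.zeros((4, 4), bool)
    b = np.zeros((4, 4), bool)
    a[:2] = True
    b[1:3] = True
    # |A|=8, |B|=8, inter=4 -> 2*4/16
    assert metrics.dice(a, b) == pytest.approx(0.5)


def test_dice_empty_conventions():
    e = np.zeros((3, 3), bool)
    f = np.ones((3, 3), bool)
    assert metrics.dice(e, e) == 1.0
    assert metrics.dice(e, f) == 0.0
    assert metrics.dice(f, e) == 0.0


def test_voe_conventions():
    e = np.zeros((3, 3), bool)
    f = np.ones((3, 3), bool)
    assert metrics.voe(e, e) == 0.0
    assert metrics.voe(f, f) == 0.0
    assert metrics.voe(e, f) == 1.0


def test_shape_mismatch_raises():
    with pytest.raises(ValueError, match="shapes"):
        metrics.dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


def test_dice_per_case_vs_global():
    big = np.ones((10, 10), bool)
    small_a = np.zeros((10, 10), bool)
    small_b = np.zeros((10, 10), bool)
    small_a[0, 0] = True
    small_b[5, 5] = True
    pairs = [(big, big), (small_a, small_b)]
    assert metrics.dice_per_case(pairs) == pytest.approx(0.5)
    # pooled: inter 100, total 202
    assert metrics.dice_global(pairs) == pytest.approx(200 / 202)


def test_surface_distances_known_value():
    a = np.zeros((5, 5, 5), bool)
    b = np.zeros((5, 5, 5), bool)
    a[2, 2, 2] = True
    b[3, 2, 2] = True
    assd, rmsd = metrics.surface_distances(a, b, spacing=(2.0, 1.0, 1.0))
    assert assd == pytest.approx(2.0)
    assert rmsd == pytest.approx(2.0)


def test_surface_distances_identical_masks_zero(rng):
    m = rng.random((6, 6, 4)) < 0.4
    m[0, 0, 0] = True
    assd, rmsd = metrics.surface_distances(m, m, (1.0, 1.0, 2.5))
    assert assd == 0.0 and rmsd == 0.0


def test_surface_distances_empty_raises():
    e = np.zeros((3, 3, 3), bool)
    f = np.ones((3, 3, 3), bool)
    with pytest.raises(ValueError, match="nonempty"):
        metrics.surface_distances(e, f, (1, 1, 1))


def test_stratify_cutoff_and_tie():
    # max 100 -> cutoff 20; the count exactly at the cutoff is "large"
    labels = metrics.stratify_by_size([10, 20, 100], threshold=0.2)
    assert labels == ["small", "large", "large"]
    labels_abs = metrics.stratify_by_size([10, 20, 100], threshold=15,
                                          absolute=True)
    assert labels_abs == ["small", "large", "large"]


def test_stratify_empty_cohort_raises():
    with pytest.raises(ValueError):
        metrics.stratify_by_size([0, 0])


def test_evaluate_cohort_report(rng):
    refs, preds = {}, {}
    for i in range(4):
        m = rng.random((8, 8, 4)) < 0.3
        m[0, 0, 0] = True
        refs[f"c{i}"] = m
        p = m.copy()
        p[1, 1, 1] ^= True
        preds[f"c{i}"] = p
    rep = metrics.evaluate_cohort(preds, refs, spacing=(1, 1, 2.5))
    assert set(rep.per_case.columns) >= {"case_id", "DC", "VOE", "ASSD_mm",
                                         "RMSD_mm", "size_stratum"}
    assert len(rep.per_case) == 4
    assert 0 <= rep.cohort["DC"] <= 1
    assert rep.cohort["DG"] == pytest.approx(
        metrics.dice_global([(preds[c], refs[c]) for c in sorted(preds)]))


def test_evaluate_cohort_id_mismatch_raises():
    m = np.ones((2, 2, 2), bool)
    with pytest.raises(ValueError, match="case ids"):
        metrics.evaluate_cohort({"a": m}, {"b": m})
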