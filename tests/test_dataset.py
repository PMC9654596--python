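"""Label binarization, feature extension, splitting, tensor reshaping."""

import numpy as np
import pytest

from eegemotion.dataset import (
    ExtensionMode, LabelSpec, SplitSpec, binarize_rating, extend_features,
    one_hot, split_indices, to_model_tensors,
)
from eegemotion.io import Recording
from eegemotion.spectral import extract_features, standardize


@pytest.fixture()
def small_features():
    rng = np.random.default_rng(4)
    rec = Recording(data=rng.standard_normal((3, 40, 600)),
                    ratings=np.array([[2.0, 7.0, 4.0, 6.0],
                                      [8.0, 3.0, 5.0, 1.5],
                                      [4.9, 5.0, 9.0, 1.0]]))
    return extract_features(rec, window_size=128, step=64)


# -------------------------------------------------------------- binarization

@pytest.mark.parametrize("rating,label", [
    (4.9, 0), (5.0, 1), (1.0, 0), (9.0, 1), (4.999, 0),
])
def test_binarize_boundary(rating, label):
    assert binarize_rating(rating) == label


def test_binarize_rejects_out_of_scale():
    with pytest.raises(ValueError):
        binarize_rating(0.5)
    with pytest.raises(ValueError):
        binarize_rating(np.array([5.0, 9.5]))


def test_one_hot_rows_sum_to_one():
    y = one_hot([0, 1, 1, 0])
    np.testing.assert_array_equal(y.sum(axis=1), 1.0)
    np.testing.assert_array_equal(y.argmax(axis=1), [0, 1, 1, 0])
    # re-encoding the argmax is idempotent
    np.testing.assert_array_equal(one_hot(y.argmax(axis=1)), y)


# ----------------------------------------------------------------- extension

@pytest.mark.parametrize("mode,target,appended", [
    ("none", "valence", ()),
    ("fe-l", "valence", ("liking",)),
    ("fe-l-d", "valence", ("liking", "dominance")),
    ("fe-3", "valence", ("arousal", "dominance", "liking")),
    ("fe-3", "arousal", ("valence", "dominance", "liking")),
])
def test_extension_modes_append_documented_columns(small_features, mode,
                                                   target, appended):
    ext = extend_features(small_features, ExtensionMode(mode, target))
    assert ext.n_features == 70 + len(appended)
    assert ext.extension == appended
    assert target not in appended
    for i, name in enumerate(appended):
        np.testing.assert_array_equal(
            ext.values[:, 70 + i], small_features.rating(name))
        assert ext.feature_names[70 + i] == f"rating_{name}"


def test_double_extension_rejected(small_features):
    ext = extend_features(small_features, ExtensionMode("fe-l", "valence"))
    with pytest.raises(ValueError, match="already"):
        extend_features(ext, ExtensionMode("fe-l", "valence"))


def test_invalid_mode_and_target_rejected():
    with pytest.raises(ValueError):
        ExtensionMode("fe-9", "valence")
    with pytest.raises(ValueError):
        ExtensionMode("fe-3", "liking")


# ----------------------------------------------------------------- splitting

@pytest.mark.parametrize("n,frac,train,test", [
    (624_640, 0.75, 468_480, 156_160),
    (624_640, 0.80, 499_712, 124_928),
    (100, 0.5, 50, 50),
])
def test_split_sizes_exact(n, frac, train, test):
    tr, te = split_indices(n, SplitSpec(frac, seed=0))
    assert (len(tr), len(te)) == (train, test)
    assert len(np.intersect1d(tr, te)) == 0
    assert len(np.union1d(tr, te)) == n


def test_split_seed_determinism():
    a1, _ = split_indices(1000, SplitSpec(0.75, seed=5))
    a2, _ = split_indices(1000, SplitSpec(0.75, seed=5))
    b, _ = split_indices(1000, SplitSpec(0.75, seed=6))
    np.testing.assert_array_equal(a1, a2)
    assert not np.array_equal(a1, b)
    assert len(a1) == len(b)


def test_trial_unit_split_keeps_trials_whole(small_features):
    key = small_features.trial_index
    tr, te = split_indices(small_features.n_windows,
                           SplitSpec(0.5, seed=1, unit="trial"), trial_key=key)
    assert set(key[tr]) & set(key[te]) == set()
    assert len(tr) + len(te) == small_features.n_windows


def test_invalid_fraction_rejected():
    with pytest.raises(ValueError):
        SplitSpec(train_fraction=1.0)
    with pytest.raises(ValueError):
        SplitSpec(train_fraction=0.0)


# ------------------------------------------------------------------- tensors

def test_to_model_tensors_shapes_and_labels(small_features):
    ext = extend_features(small_features, ExtensionMode("fe-3", "valence"))
    z, _ = standardize(ext)
    x, y = to_model_tensors(z, LabelSpec("valence"))
    assert x.shape == (z.n_windows, 73, 1)
    np.testing.assert_array_equal(x[..., 0], z.values)   # squeeze round-trip
    assert y.shape == (z.n_windows, 2)
    np.testing.assert_array_equal(y.sum(axis=1), 1.0)
    # trial valences 2.0 / 8.0 / 4.9 -> classes 0, 1, 0
    labels = y.argmax(axis=1)
    for trial, expected in [(0, 0), (1, 1), (2, 0)]:
        assert np.all(labels[z.trial_index == trial] == expected)


def test_unstandardized_tensors_need_explicit_flag(small_features):
    with pytest.raises(ValueError, match="standardize"):
        to_model_tensors(small_features, LabelSpec("valence"))
    x, _ = to_model_tensors(small_features, LabelSpec("valence"), allow_raw=True)
    assert x.shape[-1] == 1


def test_nan_inputs_rejected(small_features):
    from dataclasses import replace

    values = small_features.values.copy()
    values[0, 0] = np.nan
    bad = replace(small_features, values=values)
    with pytest.raises(ValueError, match="NaN"):
        to_model_tensors(bad, LabelSpec("valence"), allow_raw=True)
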