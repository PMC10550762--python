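"""Tiling, bag-of-codewords histograms, AdaBoost, and tile removal."""

import numpy as np
import pytest

from hescrub.codebook import Codebook, build_codebook
from hescrub.denoiser import (NON_NUCLEI, NUCLEI, classify_tiles, encode_tile,
                              encode_tiles, label_tiles, remove_background,
                              tile_image, train_denoiser, _best_stump)
from hescrub.exceptions import ParameterError


@pytest.fixture
def book(rng):
    feats = np.vstack([rng.normal(0, 0.3, (30, 8)), rng.normal(5, 0.3, (30, 8))])
    return build_codebook(feats, 4, seed=0, patch_size=2)


# --- tiling -----------------------------------------------------------------

@pytest.mark.parametrize("shape,t,n_tiles,remainder", [
    ((1000, 1000), 12, 6889, (4, 4)),
    ((24, 24), 12, 4, (0, 0)),
    ((25, 30), 12, 4, (1, 6)),
])
def test_tile_counts_and_remainder(shape, t, n_tiles, remainder):
    grid = tile_image(np.zeros(shape), t)
    assert grid.n_tiles == n_tiles
    assert grid.remainder == remainder


def test_tile_too_large_rejected():
    with pytest.raises(ParameterError):
        tile_image(np.zeros((10, 10)), 12)


def test_tile_slices_are_row_major():
    grid = tile_image(np.zeros((24, 36)), 12)
    assert grid.tile_slices(0) == (slice(0, 12), slice(0, 12))
    assert grid.tile_slices(1) == (slice(0, 12), slice(12, 24))
    assert grid.tile_slices(3) == (slice(12, 24), slice(0, 12))


# --- histograms -------------------------------------------------------------

def test_histogram_mass_conservation(book, rng):
    tile = rng.uniform(0, 5, (12, 12))
    hist = encode_tile(tile, book)
    assert hist.sum() == (12 // 2) ** 2
    assert hist.shape == (book.n_codes,)


def test_constant_tile_single_bin(book):
    hist = encode_tile(np.full((12, 12), 2.0), book)
    assert (hist > 0).sum() == 1
    assert hist.max() == 36


def test_patch_must_divide_tile(rng):
    feats = rng.standard_normal((20, 128))
    big = build_codebook(feats, 2, seed=0, patch_size=8)
    with pytest.raises(ParameterError):
        encode_tile(np.zeros((12, 12)), big)


def test_whole_image_encoding_matches_per_tile(book, rng):
    img = rng.uniform(0, 5, (36, 48))
    grid = tile_image(img, 12)
    hists = encode_tiles(img, grid, book)
    for idx in range(grid.n_tiles):
        np.testing.assert_array_equal(
            hists[idx], encode_tile(img[grid.tile_slices(idx)], book))


# --- labels -----------------------------------------------------------------

def test_tile_labels_follow_overlap_rule():
    grid = tile_image(np.zeros((24, 24)), 12)
    mask = np.zeros((24, 24), bool)
    mask[:12, :12] = True          # tile 0 fully nuclear
    mask[:12, 12 + 8:] = True      # tile 1 at 4/12 column overlap = 33%
    labels = label_tiles(grid, mask, overlap_threshold=0.5)
    assert labels[0] == NUCLEI
    assert labels[1] == NON_NUCLEI   # 30%-ish overlap below threshold
    assert labels[2] == NON_NUCLEI   # zero overlap
    labels_low = label_tiles(grid, mask, overlap_threshold=0.25)
    assert labels_low[1] == NUCLEI


def test_label_shape_mismatch():
    grid = tile_image(np.zeros((24, 24)), 12)
    with pytest.raises(ParameterError):
        label_tiles(grid, np.zeros((23, 24), bool))


# --- AdaBoost ---------------------------------------------------------------

def separable_data(rng, n=60):
    """Bin 2 perfectly splits the classes."""
    x = rng.integers(0, 4, (n, 5)).astype(float)
    y = np.where(rng.uniform(size=n) < 0.5, NUCLEI, NON_NUCLEI)
    x[:, 2] = np.where(y == NUCLEI, 10.0, 0.0) + rng.uniform(0, 1, n)
    return x, y


def test_separable_data_perfect_after_one_round(rng):
    x, y = separable_data(rng)
    model = train_denoiser(x, y, n_rounds=10)
    assert model.n_rounds == 1    # zero-error stump halts training
    pred, _ = classify_tiles(model, x)
    np.testing.assert_array_equal(pred, y)


def test_single_class_rejected(rng):
    x = rng.uniform(size=(10, 3))
    with pytest.raises(ParameterError):
        train_denoiser(x, np.full(10, NUCLEI))
    with pytest.raises(ParameterError):
        train_denoiser(x, np.full(10, NUCLEI), n_rounds=0)


def test_contradictory_labels_bounded_error():
    x = np.tile(np.array([[1.0, 2.0]]), (10, 1))
    y = np.array([NUCLEI] * 4 + [NON_NUCLEI] * 6)
    model = train_denoiser(x, y, n_rounds=5)
    pred, _ = classify_tiles(model, x)
    err = (pred != y).mean()
    assert 0.4 <= err <= 0.6    # irreducible: at best the minority fraction


def test_best_stump_never_worse_than_sklearn_tree(rng):
    """The exhaustive stump minimizes weighted error, so it can be no worse
    than a depth-1 decision tree (which is also a stump, chosen by Gini)."""
    from sklearn.tree import DecisionTreeClassifier
    x = rng.normal(0, 1, (80, 4))
    y = np.where(x[:, 1] + 0.3 * rng.standard_normal(80) > 0, 1.0, -1.0)
    w = rng.uniform(0.5, 1.5, 80)
    w /= w.sum()
    (feat, thr, pol), err = _best_stump(x, y, w)
    pred = np.where(pol * (x[:, feat] - thr) > 0, 1.0, -1.0)
    assert abs(err - np.sum(w * (pred != y))) < 1e-12  # reported = realized
    tree = DecisionTreeClassifier(max_depth=1).fit(x, y, sample_weight=w)
    tree_err = np.sum(w * (tree.predict(x) != y))
    assert err <= tree_err + 1e-9
    assert feat == 1


def test_boosting_drives_training_error_down(rng):
    x = rng.normal(0, 1, (200, 6))
    y = np.where(x[:, 0] + x[:, 3] + 0.5 * rng.standard_normal(200) > 0,
                 NUCLEI, NON_NUCLEI)
    m1 = train_denoiser(x, y, n_rounds=1)
    m20 = train_denoiser(x, y, n_rounds=20)
    e1 = (classify_tiles(m1, x)[0] != y).mean()
    e20 = (classify_tiles(m20, x)[0] != y).mean()
    assert e20 <= e1
    assert all(w > 0 for w in m20.stump_weights)


def test_classify_empty_input(rng):
    x, y = separable_data(rng)
    model = train_denoiser(x, y)
    pred, score = classify_tiles(model, np.empty((0, 5)))
    assert pred.size == 0 and score.size == 0


def test_single_stump_model_equals_rule():
    from hescrub.denoiser import DenoiserModel
    model = DenoiserModel(stumps=((0, 1.5, 1.0),), stump_weights=(1.0,),
                          n_rounds=1)
    pred, _ = classify_tiles(model, np.array([[2.0], [1.0]]))
    assert pred[0] == NUCLEI and pred[1] == NON_NUCLEI


def test_model_json_round_trip(tmp_path, rng):
    from hescrub.denoiser import DenoiserModel
    x, y = separable_data(rng)
    model = train_denoiser(x, y, n_rounds=3)
    path = tmp_path / "model.json"
    model.to_json(path)
    loaded = DenoiserModel.from_json(path)
    np.testing.assert_array_equal(classify_tiles(loaded, x)[0],
                                  classify_tiles(model, x)[0])


# --- removal ----------------------------------------------------------------

def test_remove_background_keeps_nuclei_bit_exact(rng):
    img = rng.integers(0, 255, (24, 24, 3)).astype(np.uint8)
    grid = tile_image(img, 12)
    labels = np.array([NUCLEI, NON_NUCLEI, NON_NUCLEI, NUCLEI])
    out = remove_background(img, grid, labels)
    np.testing.assert_array_equal(out[:12, :12], img[:12, :12])
    np.testing.assert_array_equal(out[12:, 12:], img[12:, 12:])
    assert (out[:12, 12:] == 255).all() and (out[12:, :12] == 255).all()


def test_remove_all_and_none(rng):
    img = rng.uniform(0, 1, (24, 24))
    grid = tile_image(img, 12)
    same = remove_background(img, grid, np.full(4, NUCLEI))
    np.testing.assert_array_equal(same, img)
    gone = remove_background(img, grid, np.full(4, NON_NUCLEI))
    assert (gone == 0).all()


def test_checkerboard_changes_half_and_spares_remainder(rng):
    img = rng.uniform(1, 2, (25, 25))   # 1-px remainder per axis
    grid = tile_image(img, 12)
    labels = np.array([NUCLEI, NON_NUCLEI, NON_NUCLEI, NUCLEI])
    out = remove_background(img, grid, labels, fill_value=0)
    assert (out == 0).sum() == 2 * 144
    np.testing.assert_array_equal(out[24:, :], img[24:, :])
    np.testing.assert_array_equal(out[:, 24:], img[:, 24:])


def test_misaligned_labels_rejected(rng):
    img = rng.uniform(size=(24, 24))
    grid = tile_image(img, 12)
    with pytest.raises(ParameterError):
        remove_background(img, grid, np.zeros(3))
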