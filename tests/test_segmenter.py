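"""Radial-symmetry markers, marker-controlled watershed, shape filtering."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from hescrub.exceptions import ParameterError
from hescrub.metrics import match_nuclei
from hescrub.segmenter import (SegmentationResult, SegmenterParams,
                               detect_markers, fast_radial_symmetry,
                               filter_regions, marker_watershed,
                               segment_nuclei)
from hescrub.synthetic import SyntheticParams, generate_sample


def dark_disk_image(shape=(96, 96), centers=((48, 48),), radius=8):
    img = np.full(shape, 1.0)
    for c in centers:
        rr, cc = draw_disk(c, radius, shape=shape)
        img[rr, cc] = 0.2
    return img


def test_uniform_image_has_zero_response():
    sym = fast_radial_symmetry(np.full((64, 64), 3.0), [6, 8, 10])
    assert not sym.any()


def test_single_dark_disk_peak_at_center():
    sym = fast_radial_symmetry(dark_disk_image(), [6, 8, 10])
    peak = np.unravel_index(sym.argmax(), sym.shape)
    assert np.hypot(peak[0] - 48, peak[1] - 48) <= 2


def test_two_disks_two_maxima():
    img = dark_disk_image(centers=((30, 30), (70, 66)))
    sym = fast_radial_symmetry(img, [6, 8, 10])
    marks = detect_markers(sym, min_distance=10, rel_threshold=0.3)
    assert len(marks) == 2
    dists = [min(np.hypot(r - a, c - b) for (r, c) in marks)
             for a, b in ((30, 30), (70, 66))]
    assert max(dists) <= 2


def test_empty_radii_rejected():
    with pytest.raises(ParameterError):
        fast_radial_symmetry(np.zeros((8, 8)), [])


def test_markers_single_peak_and_zero_map():
    m = np.zeros((32, 32))
    assert detect_markers(m).shape == (0, 2)
    m[10, 20] = 1.0
    marks = detect_markers(m)
    np.testing.assert_array_equal(marks, [[10, 20]])


def test_close_peaks_suppressed():
    m = np.zeros((32, 32))
    m[10, 10] = 1.0
    m[10, 15] = 0.9
    assert len(detect_markers(m, min_distance=10)) == 1
    assert len(detect_markers(m, min_distance=3)) == 2


def test_marker_out_of_bounds_rejected():
    with pytest.raises(ParameterError):
        marker_watershed(np.zeros((16, 16)), np.array([[20, 3]]))


def test_no_markers_empty_segmentation():
    seg = marker_watershed(np.random.default_rng(0).uniform(size=(16, 16)),
                           np.empty((0, 2)))
    assert seg.n_regions == 0


def hema_blob(shape, centers, radius):
    """Soft-edged bright blobs on a zero background (hematoxylin-like)."""
    img = np.zeros(shape)
    yy, xx = np.indices(shape, dtype=float)
    for r0, c0 in centers:
        rho = np.hypot(yy - r0, xx - c0) / radius
        img += np.clip((1.05 - rho) / 0.15, 0, 1)
    return np.clip(img, 0, 1)


def test_watershed_covers_single_nucleus():
    img = hema_blob((96, 96), [(48, 48)], 15)
    seg = marker_watershed(img, np.array([[48, 48]]))
    assert seg.n_regions == 1
    truth = img > 0.5
    covered = np.logical_and(seg.labels == 1, truth).sum() / truth.sum()
    assert covered >= 0.7


def test_watershed_separates_two_nuclei():
    img = hema_blob((96, 96), [(30, 30), (66, 66)], 13)
    seg = marker_watershed(img, np.array([[30, 30], [66, 66]]))
    assert seg.n_regions == 2
    # at most one region per marker, disjoint by construction of labels
    assert set(np.unique(seg.labels)) == {0, 1, 2}


def test_filter_small_regions_removed():
    labels = np.zeros((64, 64), int)
    labels[2:5, 2:5] = 1                        # 9 px, below area min
    rr, cc = draw_disk((40, 40), 15, shape=labels.shape)
    labels[rr, cc] = 2                           # proper disk
    seg = SegmentationResult.from_labels(labels)
    kept = filter_regions(seg, area_range=(314, 4900))
    assert kept.n_regions == 1
    row = kept.stats.iloc[0]
    assert row.roundness > 0.8 and row.solidity > 0.9


def test_filter_removes_thin_line():
    labels = np.zeros((64, 512), int)
    labels[30, 50:450] = 1                       # 400 px of 1-px-wide line
    seg = SegmentationResult.from_labels(labels)
    # closed form: area 400, perimeter ~2*400 -> roundness ~ 4*pi*400/800^2 << 0.4
    assert seg.stats.iloc[0].roundness < 0.05
    assert filter_regions(seg, area_range=(314, 4900)).n_regions == 0


def test_filter_is_idempotent(clean_sample):
    seg = segment_nuclei(clean_sample.image)
    again = filter_regions(seg, SegmenterParams().area_range)
    np.testing.assert_array_equal(seg.labels, again.labels)


def test_filter_bad_area_range():
    seg = SegmentationResult.from_labels(np.zeros((8, 8), int))
    with pytest.raises(ParameterError):
        filter_regions(seg, area_range=(100, 10))


def test_clean_image_perfect_detection(clean_sample):
    """Well-separated nuclei on a clean background are all found, no extras."""
    seg = segment_nuclei(clean_sample.image)
    gt = SegmentationResult.from_labels(clean_sample.nuclei_mask)
    rep = match_nuclei(seg, gt)
    assert rep.f1 == 1.0
    n = clean_sample.n_nuclei
    assert abs(seg.n_regions - n) / n <= 0.1


def test_pure_background_zero_detections():
    blank = generate_sample(SyntheticParams(
        image_size=(128, 128), n_nuclei=0, background_preset="flat",
        noise_amplitude=0.0, seed=1))
    seg = segment_nuclei(blank.image)
    assert seg.n_regions == 0


def test_segmentation_deterministic(clean_sample):
    a = segment_nuclei(clean_sample.image)
    b = segment_nuclei(clean_sample.image)
    np.testing.assert_array_equal(a.labels, b.labels)


def test_centroids_inside_bounding_boxes(clean_sample):
    seg = segment_nuclei(clean_sample.image)
    for _, row in seg.stats.iterrows():
        mask = seg.labels == row.label
        rows, cols = np.nonzero(mask)
        assert rows.min() <= row.row <= rows.max()
        assert cols.min() <= row.col <= cols.max()
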