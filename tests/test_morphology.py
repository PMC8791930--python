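"""Tile QC, stain unmixing, segmentation and feature arithmetic."""

import numpy as np
import pytest

from mitonuclear.morphology import (
    RUIFROK_HE_MATRIX,
    aggregate_subject,
    contour_perimeter,
    deconvolve_hematoxylin,
    extract_features,
    foreground_mask,
    MorphologyFeatures,
    percent_increase,
    process_tile,
    qc_tile,
    segment_nuclei,
)
from mitonuclear.simulate import generate_tiles


def _disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


@pytest.mark.parametrize(
    "value, keep",
    [(0, False), (255, False), (128, True), (14, False), (241, False), (16, True)],
)
def test_qc_tile_brightness_rules(value, keep):
    tile = np.full((32, 32, 3), value, dtype=np.uint8)
    assert qc_tile(tile) is keep


def test_qc_tile_rejects_empty():
    with pytest.raises(ValueError):
        qc_tile(np.zeros((0, 0, 3), dtype=np.uint8))


def test_deconvolution_white_tile_is_zero():
    white = np.full((16, 16, 3), 255, dtype=np.uint8)
    chan = deconvolve_hematoxylin(white)
    assert np.all(chan < 2.0)  # only the +1 log guard remains


def test_deconvolution_unmixing_identity():
    """A tile painted with the pure hematoxylin colour unmixes to a high
    hematoxylin channel and a near-zero eosin channel."""
    h_vec = RUIFROK_HE_MATRIX[0]
    rgb = np.round(255.0 * 10.0 ** (-0.8 * h_vec)).astype(np.uint8)
    tile = np.tile(rgb, (8, 8, 1))
    conc = deconvolve_hematoxylin(tile, return_all=True)
    assert conc[..., 0].mean() > 150  # ~0.8 concentration * 255
    assert conc[..., 1].mean() < 10


def test_deconvolution_roundtrip_on_synthetic_tile():
    tile = generate_tiles(1, 8, radius_mean=12, seed=5)[0]
    recovered = deconvolve_hematoxylin(tile.pixels) / 255.0
    r = np.corrcoef(recovered.ravel(), tile.hematoxylin_truth.ravel())[0, 1]
    assert r > 0.99


def test_deconvolution_rejects_non_rgb():
    with pytest.raises(ValueError):
        deconvolve_hematoxylin(np.zeros((8, 8)))


def test_foreground_mask_threshold_is_half_mean():
    chan = np.zeros((10, 10))
    chan[:5] = 100.0  # mean 50, threshold 25
    mask = foreground_mask(chan)
    assert mask[:5].all() and not mask[5:].any()
    assert foreground_mask(np.full((4, 4), 7.0)).all()


@pytest.mark.parametrize(
    "radius, expected",
    [(12, 1), (5, 0)],
)
def test_segmentation_radius_filter(radius, expected):
    chan = np.where(_disk_mask((64, 64), (32, 32), radius), 200.0, 0.0)
    labels = segment_nuclei(foreground_mask(chan), chan)
    assert labels.max() == expected


def test_segmentation_splits_two_disks():
    chan = np.zeros((128, 128))
    chan[_disk_mask((128, 128), (40, 40), 12)] = 200.0
    chan[_disk_mask((128, 128), (40, 80), 12)] = 200.0
    labels = segment_nuclei(foreground_mask(chan), chan)
    assert labels.max() == 2


def test_segmentation_shape_mismatch():
    with pytest.raises(ValueError):
        segment_nuclei(np.zeros((4, 4)), np.zeros((5, 5)))


def test_square_circularity_closed_form():
    """Filled square, side s: border-centre contour has length 4(s-1)."""
    s = 100
    labels = np.zeros((s + 20, s + 20), dtype=int)
    labels[10:10 + s, 10:10 + s] = 1
    feats = extract_features(labels, np.ones_like(labels, dtype=float))
    assert feats.circularity == pytest.approx(
        4 * np.pi * s**2 / (4 * (s - 1)) ** 2, abs=1e-9
    )


def test_rectangle_size_area():
    labels = np.zeros((40, 40), dtype=int)
    labels[5:15, 10:30] = 1  # 10 x 20
    feats = extract_features(labels, np.full((40, 40), 3.0))
    assert feats.size_area == 200
    assert feats.intensity == pytest.approx(3.0)


def test_disk_circularity_near_one():
    labels = _disk_mask((201, 201), (100, 100), 50).astype(int)
    feats = extract_features(labels, np.ones((201, 201)))
    assert 0.90 <= feats.circularity <= 1.15


def test_perimeter_matches_bruteforce_boundary_walk():
    """Independent oracle: the traced contour length equals the summed
    step lengths of a border-pixel adjacency cycle computed by brute
    force for a convex digital disk."""
    m = _disk_mask((81, 81), (40, 40), 18)
    # border pixels: object pixels 4-adjacent to background
    from scipy import ndimage

    eroded = ndimage.binary_erosion(m, structure=ndimage.generate_binary_structure(2, 1))
    border = m & ~eroded
    pts = np.argwhere(border)
    # greedy nearest-neighbour cycle through the border centres
    used = np.zeros(len(pts), bool)
    order = [0]
    used[0] = True
    for _ in range(len(pts) - 1):
        cur = pts[order[-1]]
        d2 = np.sum((pts - cur) ** 2, axis=1).astype(float)
        d2[used] = np.inf
        nxt = int(np.argmin(d2))
        used[nxt] = True
        order.append(nxt)
    cycle = pts[order + [0]]
    oracle = float(np.sum(np.hypot(*np.diff(cycle, axis=0).T)))
    assert contour_perimeter(m) == pytest.approx(oracle, rel=0.02)


def test_zero_objects_reported_missing():
    feats = extract_features(np.zeros((8, 8), int), np.zeros((8, 8)))
    assert feats.n_nuclei == 0
    assert np.isnan(feats.intensity) and np.isnan(feats.circularity)


def test_aggregate_subject_arithmetic():
    tiles = [MorphologyFeatures("a", 10, 800.0, 5.0, 0.9),
             MorphologyFeatures("b", 10, 1200.0, 5.0, 0.9)]
    ph = aggregate_subject(tiles, "s1")
    assert ph.log2_size_per_nucleus == pytest.approx(np.log2(100), abs=1e-12)

    k, n = 5, 7
    one = [MorphologyFeatures("c", n, float(2**k * n), 1.0, 1.0)]
    assert aggregate_subject(one).log2_size_per_nucleus == pytest.approx(k)


def test_aggregate_zero_nuclei_missing():
    ph = aggregate_subject([MorphologyFeatures("a", 0, np.nan, np.nan, np.nan)])
    assert np.isnan(ph.log2_size_per_nucleus)
    assert ph.mean_n_nuclei == 0


def test_percent_increase_matches_reported_arithmetic():
    """Per-nuclei Size Area 4.7 vs 3.6 is ~23% larger relative to itself."""
    assert percent_increase(4.7, 3.6) == pytest.approx(23.4, abs=0.05)
    assert percent_increase(26.90, 13.03) == pytest.approx(51.6, abs=0.05)


def test_roundtrip_recovers_planted_disks():
    for k, seed in [(0, 1), (5, 2), (12, 3)]:
        tile = generate_tiles(1, k, radius_mean=12, seed=seed)[0]
        feats = process_tile(tile.pixels, tile.tile_id)
        assert feats.n_nuclei == k
        if k:
            planted = np.pi * 12**2 * k
            assert abs(feats.size_area - planted) / planted < 0.10


def test_translation_invariance_of_features():
    base = np.zeros((128, 128))
    base[_disk_mask((128, 128), (40, 40), 12)] = 200.0
    shifted = np.roll(np.roll(base, 25, axis=0), 30, axis=1)
    f1 = extract_features(segment_nuclei(foreground_mask(base), base), base)
    f2 = extract_features(segment_nuclei(foreground_mask(shifted), shifted), shifted)
    assert f1.n_nuclei == f2.n_nuclei
    assert f1.size_area == f2.size_area
    assert f1.circularity == pytest.approx(f2.circularity, abs=1e-9)


def test_size_area_monotone_in_radius():
    areas = []
    for r in (10, 12, 14, 16):
        chan = np.where(_disk_mask((96, 96), (48, 48), r), 200.0, 0.0)
        labels = segment_nuclei(foreground_mask(chan), chan)
        areas.append(extract_features(labels, chan).size_area)
    assert all(a < b for a, b in zip(areas, areas[1:]))
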