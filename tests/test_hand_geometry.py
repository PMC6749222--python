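"""Contour tracing, hull, landmarks and the 62-entry feature vector."""

import itertools

import numpy as np
import pytest

from handvein import (
    FEATURE_COUNT, HandDetectionError, ParameterError, SegmentationError,
    convex_hull, convexity_defects, finger_base, measure_hand, trace_contour,
)
from handvein.hand_geometry import (
    HandFeatures, _extent, _hull_indices, estimate_orientation,
    locate_landmarks,
)
from handvein.synthetic import ZERO_NOISE, render_capture


# ---------------------------------------------------------------------------
# contour
# ---------------------------------------------------------------------------

def test_contour_of_solid_square_is_boundary_cycle():
    mask = np.zeros((5, 5), bool)
    mask[1:4, 1:4] = True
    contour = trace_contour(mask)
    expected = {(1, 1), (1, 2), (1, 3), (2, 3), (3, 3),
                (3, 2), (3, 1), (2, 1)}
    assert len(contour) == 8
    assert set(map(tuple, contour.tolist())) == expected
    # consecutive points 8-adjacent, closed
    closed = np.vstack([contour, contour[:1]])
    steps = np.abs(np.diff(closed, axis=0)).max(axis=1)
    assert (steps == 1).all()


def test_contour_single_pixel():
    mask = np.zeros((4, 4), bool)
    mask[2, 1] = True
    contour = trace_contour(mask)
    assert contour.shape == (1, 2) and tuple(contour[0]) == (2, 1)


def test_contour_traces_largest_component_only():
    mask = np.zeros((12, 12), bool)
    mask[1:3, 1:3] = True          # 4 px blob
    mask[5:11, 5:11] = True        # 36 px blob
    contour = trace_contour(mask)
    assert contour[:, 0].min() >= 5 and contour[:, 1].min() >= 5


def test_contour_empty_mask_raises():
    with pytest.raises(SegmentationError):
        trace_contour(np.zeros((5, 5), bool))


# ---------------------------------------------------------------------------
# convex hull and defects
# ---------------------------------------------------------------------------

def test_hull_of_square_with_interior_points():
    pts = np.array([[0, 0], [0, 10], [10, 0], [10, 10],
                    [5, 5], [3, 7], [9, 1]])
    hull = convex_hull(pts)
    assert set(map(tuple, hull.tolist())) == {(0, 0), (0, 10), (10, 0), (10, 10)}


def test_hull_idempotent(rng):
    pts = rng.integers(0, 50, (50, 2))
    hull = convex_hull(pts)
    assert set(map(tuple, convex_hull(hull).tolist())) == set(map(tuple, hull.tolist()))


def test_hull_matches_exhaustive_oracle(rng):
    pts = rng.random((50, 2)) * 40
    hull = set(map(tuple, convex_hull(pts).tolist()))

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    # O(n^3) oracle: a point is a hull vertex iff some line through it and
    # another point keeps all remaining points on one side
    oracle = set()
    for i, j in itertools.permutations(range(len(pts)), 2):
        signs = [cross(pts[i], pts[j], pts[k])
                 for k in range(len(pts)) if k not in (i, j)]
        if all(s >= -1e-9 for s in signs) or all(s <= 1e-9 for s in signs):
            oracle.add(tuple(pts[i]))
            oracle.add(tuple(pts[j]))
    assert hull <= oracle


def test_hull_degenerate_collinear_raises():
    pts = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float)
    with pytest.raises(ParameterError):
        convex_hull(pts)


def test_convex_shape_has_no_defects():
    mask = np.zeros((30, 30), bool)
    rr, cc = np.ogrid[:30, :30]
    mask[(rr - 15) ** 2 + (cc - 15) ** 2 <= 100] = True
    contour = trace_contour(mask)
    hull = contour[_hull_indices(contour)]
    assert convexity_defects(contour, hull, 2.0) == []


def test_u_shape_single_defect_of_known_depth():
    # U of depth 20: walls rows 5..25, floor at row 25
    mask = np.zeros((30, 30), bool)
    mask[5:26, 5:10] = True
    mask[5:26, 20:25] = True
    mask[25:29, 5:25] = True
    contour = trace_contour(mask)
    hull = contour[_hull_indices(contour)]
    defects = convexity_defects(contour, hull, 10.0)
    assert len(defects) == 1
    assert defects[0]["depth"] == pytest.approx(20.0, abs=1.5)
    assert defects[0]["point"][0] == pytest.approx(25, abs=1)


# ---------------------------------------------------------------------------
# landmarks on the synthetic hand
# ---------------------------------------------------------------------------

def test_zero_noise_fingertips_within_two_px(clean_capture, clean_result):
    _, gt = clean_capture
    err = np.hypot(*(gt.fingertips - clean_result.landmarks.fingertips).T)
    assert (err <= 2.0).all(), err


def test_exactly_four_valleys_between_fingers(clean_result):
    assert clean_result.landmarks.valleys.shape == (4, 2)


def test_fingerless_disk_raises_hand_detection_error():
    mask = np.zeros((200, 200), bool)
    rr, cc = np.ogrid[:200, :200]
    mask[(rr - 100) ** 2 + (cc - 100) ** 2 <= 70 ** 2] = True
    with pytest.raises(HandDetectionError):
        locate_landmarks(mask)


def test_rotated_capture_tips_within_three_px(subject, config):
    from handvein import extract_capture
    noise = dict(ZERO_NOISE)
    noise["rotation_deg"] = 9.0  # pose drawn within ±9°
    img, gt = render_capture(subject, 3, noise)
    res = extract_capture(img, config)
    err = np.hypot(*(gt.fingertips - res.landmarks.fingertips).T)
    assert (err <= 3.0).all(), err


def test_orientation_estimate_tracks_pose(subject):
    noise = dict(ZERO_NOISE)
    noise["rotation_deg"] = 8.0
    img, gt = render_capture(subject, 2, noise)
    from handvein.pipeline import segment_hand
    up = estimate_orientation(segment_hand(img))
    # the raw PCA estimate carries a few degrees of anatomy bias; the
    # landmark stage refines it from the finger axes afterwards
    assert up @ gt.up >= np.cos(np.radians(10.0))


# ---------------------------------------------------------------------------
# finger base rule
# ---------------------------------------------------------------------------

def test_finger_base_midpoint_rule():
    base = finger_base(np.array([[100.0, 40.0], [100.0, 60.0]]))
    assert base == pytest.approx([100.0, 50.0])


def test_finger_base_reflection_is_projection_onto_axis():
    # single valley reflected across a vertical axis through the tip
    base = finger_base(np.array([[100.0, 47.0]]), tip=np.array([20.0, 40.0]),
                       axis=np.array([-1.0, 0.0]))
    assert base == pytest.approx([100.0, 40.0])


def test_finger_base_needs_axis_for_single_valley():
    with pytest.raises(ParameterError):
        finger_base(np.array([[1.0, 2.0]]))


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def test_capsule_extent_recovers_width():
    # standalone capsule, length 120 width 30
    mask = np.zeros((160, 60), bool)
    rr, cc = np.ogrid[:160, :60]
    center_r = np.clip(rr, 35, 140)
    mask[np.hypot(rr - center_r, cc - 30) <= 15] = True
    # interior samples perpendicular to the vertical axis
    for r in (50, 70, 90, 110, 130):
        w = _extent(mask, np.array([float(r), 30.0]), np.array([0.0, 1.0]))
        assert w == pytest.approx(30.0, abs=2.0)


def test_feature_vector_has_fixed_length(clean_result):
    vec = clean_result.features.vector()
    assert vec.shape == (FEATURE_COUNT,)
    assert (vec >= 0).all()
    rt = HandFeatures.from_vector(vec)
    assert np.allclose(rt.vector(), vec)


def test_measurement_translation_invariance(clean_capture, config):
    from handvein import extract_capture
    img, _ = clean_capture
    shifted = np.roll(img, (6, -9), axis=(0, 1))
    a = extract_capture(img, config).features.vector()
    b = extract_capture(shifted, config).features.vector()
    assert np.allclose(a, b, atol=1e-6)


def test_scale_equivariance_of_measurements(clean_capture, config):
    from scipy import ndimage as ndi
    from handvein.pipeline import segment_hand
    img, _ = clean_capture
    mask = segment_hand(img, config)
    lm = locate_landmarks(mask, min_depth=config.min_depth,
                          curvature_k=config.curvature_k,
                          cluster_gap=config.cluster_gap)
    f1 = measure_hand(mask, lm).vector()
    big = ndi.zoom(mask.astype(float), 2.0, order=1) >= 0.5
    lm2 = locate_landmarks(big, min_depth=2 * config.min_depth,
                           curvature_k=config.curvature_k,
                           cluster_gap=2 * config.cluster_gap)
    f2 = measure_hand(big, lm2).vector()
    assert np.allclose(f2, 2.0 * f1, rtol=0.04, atol=2.5)
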