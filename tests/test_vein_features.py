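"""ROI geometry, vein segmentation, Zhang–Suen thinning, crossing numbers,
pruning and minutiae extraction."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from handvein import (
    MinutiaeSet, ParameterError, connection_number, connection_number_map,
    extract_minutiae, extract_roi, prune_skeleton, segment_veins,
    zhang_suen_thin,
)
from handvein.hand_geometry import HandLandmarks
from tests.conftest import random_blob


def _landmarks_for_valleys(v2, v4):
    valleys = np.array([[0.0, -40.0], v2, [(v2[0] + v4[0]) / 2,
                                           (v2[1] + v4[1]) / 2], v4])
    return HandLandmarks(fingertips=np.zeros((5, 2)), valleys=valleys,
                         palm_center=np.array([200.0, 300.0]),
                         finger_bases=np.zeros((5, 2)),
                         up=np.array([-1.0, 0.0]))


# ---------------------------------------------------------------------------
# ROI
# ---------------------------------------------------------------------------

def test_roi_dimensions_follow_valley_span():
    img = np.full((480, 640), 120, np.uint8)
    lm = _landmarks_for_valleys([100.0, 250.0], [100.0, 350.0])
    roi, spec = extract_roi(img, lm, seat_px=0.0)
    assert (spec.width, spec.height) == (100, 140)  # 1.4 × width
    assert roi.shape == (140, 100)
    assert spec.rotation == pytest.approx(0.0, abs=1e-6)


def test_roi_axis_aligned_crop_equals_slice():
    rng = np.random.default_rng(3)
    img = rng.integers(0, 256, (480, 640)).astype(np.uint8)
    lm = _landmarks_for_valleys([100.0, 250.0], [100.0, 300.0])
    roi, spec = extract_roi(img, lm, seat_px=0.0)
    assert np.array_equal(roi, img[100:170, 250:300])


def test_roi_roundtrip_transform():
    img = np.full((480, 640), 90, np.uint8)
    lm = _landmarks_for_valleys([102.0, 250.0], [96.0, 348.0])  # tilted
    _, spec = extract_roi(img, lm)
    pts = np.array([[10.0, 20.0], [50.0, 5.0]])
    back = spec.image_to_roi(spec.roi_to_image(pts))
    assert np.allclose(back, pts, atol=1e-9)


def test_rotated_capture_roi_registers_with_upright(subject, config):
    """The derotated ROI of a rotated capture matches the upright capture."""
    from handvein import extract_capture
    from handvein.synthetic import ZERO_NOISE, render_capture
    up_img, _ = render_capture(subject, 0, ZERO_NOISE)
    noise = dict(ZERO_NOISE)
    noise["rotation_deg"] = 10.0
    rot_img, _ = render_capture(subject, 0, noise)  # same jitter stream
    r1 = extract_capture(up_img, config)
    r2 = extract_capture(rot_img, config)
    a = r1.minutiae.branchings
    b = r2.minutiae.branchings
    assert len(a) == len(b) > 0
    d = np.hypot(*(a[:, None, :] - b[None, :, :]).T).T
    assert d.min(axis=1).max() <= 3.0


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def test_constant_roi_gives_empty_vein_mask():
    roi = np.full((80, 60), 150, np.uint8)
    assert not segment_veins(roi).any()


def test_straight_dark_band_segments_as_single_component():
    # tissue-like ROI: smooth shading plus sensor noise, one dark band
    rng = np.random.default_rng(5)
    roi = np.full((100, 70), 180.0)
    shading = ndi.gaussian_filter(rng.standard_normal(roi.shape), 18.0)
    roi += shading * (5.0 / shading.std())
    cc = np.arange(70)
    band = np.clip(3.5 + 0.5 - np.abs(cc - 35), 0, 1)  # 7 px vertical band
    roi -= 30 * band[None, :]
    roi += rng.normal(0, 4, roi.shape)
    mask = segment_veins(np.clip(roi, 0, 255).astype(np.uint8))
    labels, n = ndi.label(mask, structure=np.ones((3, 3)))
    sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
    main = labels == (1 + int(np.argmax(sizes)))
    band_true = np.abs(cc - 35) <= 3
    assert main[:, band_true].mean() >= 0.95   # one component covers the band
    assert np.sort(sizes)[:-1].sum() <= 100    # residue is negligible


def test_salt_and_pepper_noise_leaves_no_large_components():
    rng = np.random.default_rng(6)
    roi = np.full((90, 70), 170, np.uint8)
    idx = rng.integers(0, roi.size, 300)
    roi.ravel()[idx] = rng.choice([0, 255], 300)
    mask = segment_veins(roi)
    labels, n = ndi.label(mask, structure=np.ones((3, 3)))
    if n:
        sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
        assert sizes.max() < 5


# ---------------------------------------------------------------------------
# thinning
# ---------------------------------------------------------------------------

def _naive_zhang_suen(mask):
    """Direct per-pixel transcription of the two sub-iterations."""
    img = mask.astype(np.uint8).copy()
    h, w = img.shape

    def nb(r, c):
        out = []
        for dr, dc in ((-1, 0), (-1, 1), (0, 1), (1, 1),
                       (1, 0), (1, -1), (0, -1), (-1, -1)):
            rr, cc = r + dr, c + dc
            out.append(int(img[rr, cc]) if 0 <= rr < h and 0 <= cc < w else 0)
        return out

    while True:
        changed = False
        for step in (0, 1):
            to_del = []
            for r in range(h):
                for c in range(w):
                    if not img[r, c]:
                        continue
                    p = nb(r, c)
                    b = sum(p)
                    a = sum(1 for i in range(8) if p[i] == 0 and p[(i + 1) % 8] == 1)
                    if not (2 <= b <= 6 and a == 1):
                        continue
                    if step == 0:
                        ok = p[0] * p[2] * p[4] == 0 and p[2] * p[4] * p[6] == 0
                    else:
                        ok = p[0] * p[2] * p[6] == 0 and p[0] * p[4] * p[6] == 0
                    if ok:
                        to_del.append((r, c))
            # same component protection as documented for the implementation
            comp, n = ndi.label(img, structure=np.ones((3, 3)))
            dset = set(to_del)
            for lab in range(1, n + 1):
                pix = [tuple(p) for p in np.argwhere(comp == lab)]
                if pix and all(p in dset for p in pix):
                    dset.discard(pix[0])
            for rc in dset:
                img[rc] = 0
                changed = True
        if not changed:
            return img.astype(bool)


def test_thinning_matches_naive_reference(rng):
    for _ in range(5):
        mask = random_blob(rng, (24, 24), smooth=2.0)
        assert np.array_equal(zhang_suen_thin(mask), _naive_zhang_suen(mask))


def test_thinning_empty_and_idempotent(rng):
    assert not zhang_suen_thin(np.zeros((8, 8), bool)).any()
    skel = zhang_suen_thin(random_blob(rng, (30, 30)))
    assert np.array_equal(zhang_suen_thin(skel), skel)


def test_thinning_bar_becomes_line():
    mask = np.zeros((9, 30), bool)
    mask[3:6, 2:28] = True
    skel = zhang_suen_thin(mask)
    rows, cols = np.nonzero(skel)
    assert len(np.unique(rows)) == 1
    assert cols.min() <= 4 and cols.max() >= 25  # same extent ±2 px


def test_thinning_preserves_component_count(rng):
    for _ in range(5):
        mask = random_blob(rng, (32, 32), smooth=2.5, frac=0.3)
        _, n0 = ndi.label(mask, structure=np.ones((3, 3)))
        _, n1 = ndi.label(zhang_suen_thin(mask), structure=np.ones((3, 3)))
        assert n0 == n1


# ---------------------------------------------------------------------------
# crossing number
# ---------------------------------------------------------------------------

def test_connection_number_examples():
    iso = np.zeros((5, 5), bool)
    iso[2, 2] = True
    assert connection_number(iso, (2, 2)) == 0

    line = np.zeros((5, 7), bool)
    line[2, 1:6] = True
    assert connection_number(line, (2, 1)) == 1
    assert connection_number(line, (2, 3)) == 2

    tee = np.zeros((5, 5), bool)
    tee[2, :] = True
    tee[3:, 2] = True
    assert connection_number(tee, (2, 2)) == 3


def test_connection_number_rejects_background():
    with pytest.raises(ParameterError):
        connection_number(np.zeros((3, 3), bool), (1, 1))


def test_connection_number_map_matches_exhaustive_patterns():
    """All 256 neighbourhood patterns against direct transition counting."""
    offsets = [(-1, 0), (-1, 1), (0, 1), (1, 1),
               (1, 0), (1, -1), (0, -1), (-1, -1)]
    for pattern in range(256):
        img = np.zeros((3, 3), bool)
        img[1, 1] = True
        bits = [(pattern >> i) & 1 for i in range(8)]
        for bit, (dr, dc) in zip(bits, offsets):
            img[1 + dr, 1 + dc] = bool(bit)
        expect = sum(abs(bits[(i + 1) % 8] - bits[i]) for i in range(8)) // 2
        assert connection_number(img, (1, 1)) == expect
        assert connection_number_map(img)[1, 1] == expect


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def _line_with_spur(spur_len):
    skel = np.zeros((26, 40), bool)
    skel[20, 2:38] = True
    for i in range(1, spur_len + 1):
        skel[20 - i, 20] = True
    return skel


def test_short_spur_removed_line_intact():
    skel = _line_with_spur(3)
    out = prune_skeleton(skel, max_spur=10, border_band=0)
    assert not out[:20, 20].any()
    assert out[20, 5:35].all()


def test_long_spur_kept():
    skel = _line_with_spur(14)
    out = prune_skeleton(skel, max_spur=10, border_band=0)
    assert out[:20, 20].sum() >= 12


def test_isolated_pixels_removed():
    skel = np.zeros((10, 10), bool)
    skel[2, 2] = skel[7, 5] = True
    assert not prune_skeleton(skel, max_spur=5, border_band=0).any()


def test_border_touching_end_is_protected():
    skel = np.zeros((20, 20), bool)
    skel[0:6, 10] = True  # short line reaching the top edge
    out = prune_skeleton(skel, max_spur=10, border_band=3)
    assert out[:6, 10].sum() >= 5


# ---------------------------------------------------------------------------
# minutiae
# ---------------------------------------------------------------------------

def test_y_skeleton_minutiae():
    skel = np.zeros((20, 21), bool)
    skel[8:18, 10] = True                 # stem, interior end at row 17
    for i in range(1, 9):
        skel[8 - i, 10 - i] = True        # arm to top-left edge
        skel[8 - i, 10 + i] = True        # arm to top-right edge
    ms = extract_minutiae(skel, border_band=3, edges="top")
    br = ms.branchings
    assert len(br) == 1
    assert np.hypot(br[0, 0] - 8, br[0, 1] - 10) <= 2.0
    assert len(ms.endings) == 2           # only the arms reach the top band
    assert (ms.endings[:, 0] <= 2).all()


def test_interior_line_yields_empty_set():
    skel = np.zeros((20, 20), bool)
    skel[10, 5:15] = True
    ms = extract_minutiae(skel, border_band=3)
    assert len(ms) == 0


def test_minutiae_translation_equivariance():
    skel = np.zeros((40, 40), bool)
    skel[10:30, 20] = True
    skel[20, 20:35] = True
    a = extract_minutiae(skel, border_band=0)
    b = extract_minutiae(np.roll(skel, (3, 4), (0, 1)), border_band=0)
    assert np.allclose(np.sort(a.branchings, 0) + [3, 4],
                       np.sort(b.branchings, 0))


def test_minutiae_json_roundtrip():
    ms = MinutiaeSet(points=np.array([[1.5, 2.0], [3.0, 4.0]]),
                     kinds=["branching", "ending"], frame=(50, 40))
    rt = MinutiaeSet.loads(ms.dumps())
    assert rt.frame == (50, 40)
    assert rt.kinds == ms.kinds
    assert np.allclose(rt.points, ms.points)


def test_zero_noise_branch_minutiae_recall(clean_capture, clean_result):
    """Every generated branch node is matched by a branching minutia."""
    _, gt = clean_capture
    br_gt = clean_result.roi_spec.image_to_roi(gt.true_minutiae.branchings)
    est = clean_result.minutiae.branchings
    assert len(est) > 0
    d = np.hypot(*(br_gt[:, None, :] - est[None, :, :]).T).T
    assert d.min(axis=1).max() <= 3.0
    assert d.min(axis=0).max() <= 3.0
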