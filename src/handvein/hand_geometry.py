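"""Hand-contour biometric features.

From a segmented hand silhouette (fingers roughly upward, any in-plane
rotation within ~±10°) this module extracts a fixed 62-entry feature
vector:

====================  =====  =========================================
finger_lengths        5      fingertip to finger-base distance, thumb→pinky
finger_widths         5×10   silhouette extent perpendicular to the finger
                             axis at 10 centred fractions (5%…95%) of the
                             tip→base segment
tip_distances         3      adjacent fingertip gaps, thumb–index excluded
valley_distances      3      adjacent finger-valley gaps
palm_width            1      extent through the palm centre perpendicular
                             to the middle-finger axis
====================  =====  =========================================

All measurements are Euclidean distances in pixels and are computed in the
original image frame: instead of resampling the image to a canonical pose,
the hand's principal axis is estimated and every directional measurement is
taken along pose-aware rays, so translation invariance is exact and
rotation never costs interpolation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError

from .errors import HandDetectionError, MeasurementError, ParameterError, SegmentationError

__all__ = [
    "Contour", "HandLandmarks", "HandFeatures", "FEATURE_COUNT",
    "trace_contour", "convex_hull", "convexity_defects",
    "detect_fingertips", "detect_valleys", "finger_base",
    "estimate_orientation", "locate_landmarks", "measure_hand",
]

FEATURE_COUNT = 62

#: clockwise Moore neighbourhood, starting north
_MOORE = np.array([(-1, 0), (-1, 1), (0, 1), (1, 1),
                   (1, 0), (1, -1), (0, -1), (-1, -1)])

Contour = np.ndarray  # (n, 2) int array of (row, col), cyclic, 8-connected


# ---------------------------------------------------------------------------
# contour and hull
# ---------------------------------------------------------------------------

def trace_contour(mask: np.ndarray) -> Contour:
    """Moore boundary trace (clockwise) of the largest 8-connected component."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndi.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        raise SegmentationError("empty mask: nothing to trace")
    sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
    obj = labels == (1 + int(np.argmax(sizes)))

    rows, cols = np.nonzero(obj)
    first = np.lexsort((cols, rows))[0]  # topmost, then leftmost
    start = (int(rows[first]), int(cols[first]))

    h, w = obj.shape

    def at(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and obj[r, c]

    points = [start]
    # backtrack direction: the neighbour we "came from"; west of the start
    # pixel is guaranteed background because start is row-minimal/col-minimal
    backtrack = 6  # index of (0, -1) in _MOORE
    cur = start
    first_move: tuple | None = None
    while True:
        found = False
        for k in range(1, 9):
            d = (backtrack + k) % 8
            r, c = cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1]
            if at(r, c):
                nxt = (r, c)
                # new backtrack: the previously inspected (background) cell
                prev = (backtrack + k - 1) % 8
                back_cell = (cur[0] + _MOORE[prev][0], cur[1] + _MOORE[prev][1])
                dr, dc = back_cell[0] - nxt[0], back_cell[1] - nxt[1]
                backtrack = int(np.argmax(np.all(_MOORE == (dr, dc), axis=1)))
                found = True
                break
        if not found:  # isolated pixel
            break
        move = (cur, nxt)
        if first_move is None:
            first_move = move
        elif move == first_move:  # Jacob's stopping criterion
            break
        cur = nxt
        points.append(cur)
    if len(points) > 1 and points[-1] == start:
        points.pop()
    return np.asarray(points, dtype=int)


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Vertices of the convex polygon containing all points.

    Returned counterclockwise with respect to standard (x=col, y=-row)
    axes; use :func:`_hull_indices` when the indices into the input are
    needed as well.
    """
    return points[_hull_indices(points)]


def _hull_indices(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ParameterError("convex hull needs at least 3 points")
    try:
        hull = ConvexHull(pts[:, ::-1])  # (x, y) ordering for qhull
    except QhullError as exc:
        raise ParameterError(f"degenerate point set: {exc}") from exc
    return hull.vertices


def convexity_defects(contour: Contour, hull: np.ndarray,
                      min_depth: float) -> list[dict]:
    """Deepest contour point under each hull edge, filtered by depth.

    ``hull`` must consist of points of ``contour``.  Returns a list of
    ``{"point", "depth", "index"}`` dicts ordered by contour position.
    """
    contour = np.asarray(contour)
    lookup: dict[tuple, int] = {}
    for i, p in enumerate(map(tuple, contour.tolist())):
        lookup.setdefault(p, i)
    try:
        hull_idx = sorted(lookup[tuple(p)] for p in np.asarray(hull).tolist())
    except KeyError as exc:
        raise ParameterError("hull vertex not found on contour") from exc

    n = len(contour)
    defects = []
    for a, b in zip(hull_idx, hull_idx[1:] + [hull_idx[0] + n]):
        if b - a < 2:
            continue
        seg_idx = np.arange(a + 1, b) % n
        seg = contour[seg_idx].astype(float)
        pa, pb = contour[a % n].astype(float), contour[b % n].astype(float)
        chord = pb - pa
        norm = np.hypot(*chord)
        if norm == 0:
            dist = np.hypot(*(seg - pa).T)
        else:
            rel = seg - pa
            dist = np.abs(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / norm
        k = int(np.argmax(dist))
        if dist[k] >= min_depth:
            defects.append({"point": seg[k], "depth": float(dist[k]),
                            "index": int(seg_idx[k])})
    defects.sort(key=lambda d: d["index"])
    return defects


# ---------------------------------------------------------------------------
# orientation and landmarks
# ---------------------------------------------------------------------------

def estimate_orientation(mask: np.ndarray) -> np.ndarray:
    """Unit vector along the hand's principal axis, pointing at the fingers.

    The sign is resolved by comparing silhouette density at the two ends of
    the axis: the finger side carries less area per unit length than the
    palm side.
    """
    coords = np.argwhere(mask).astype(float)
    if len(coords) < 2:
        raise SegmentationError("mask too small to orient")
    centred = coords - coords.mean(axis=0)
    cov = np.cov(centred.T)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, int(np.argmax(evals))]
    t = centred @ axis
    hi, lo = np.quantile(t, [0.75, 0.25])
    dens_pos = np.count_nonzero(t > hi) / max(t.max() - hi, 1e-9)
    dens_neg = np.count_nonzero(t < lo) / max(lo - t.min(), 1e-9)
    up = axis if dens_pos < dens_neg else -axis
    return up / np.hypot(*up)


def _right_of(up: np.ndarray) -> np.ndarray:
    """Unit vector 90° clockwise from ``up`` in (row, col) image coords."""
    return np.array([up[1], -up[0]])


def detect_fingertips(contour: Contour, hull_idx: np.ndarray,
                      palm_center: np.ndarray, up: np.ndarray,
                      cluster_gap: float = 16.0, k: int = 15):
    """Locate the five fingertips on the contour.

    Hull vertices are clustered by gap, clusters on the finger side of the
    palm centre are ranked by distance, and within each of the five winning
    clusters the tip is refined to the contour point of maximal curvature
    (minimal angle between the two direction vectors ±``k`` points away).

    Returns ``(tips (5,2) float array, tip_contour_indices (5,) int array)``
    ordered thumb→pinky.
    """
    contour = np.asarray(contour)
    n = len(contour)
    pts = contour[hull_idx].astype(float)

    # cluster consecutive hull vertices (hull order is cyclic)
    clusters: list[list[int]] = [[0]]
    for i in range(1, len(pts)):
        if np.hypot(*(pts[i] - pts[clusters[-1][-1]])) <= cluster_gap:
            clusters[-1].append(i)
        else:
            clusters.append([i])
    if len(clusters) > 1 and np.hypot(*(pts[0] - pts[clusters[-1][-1]])) <= cluster_gap:
        clusters[0] = clusters.pop() + clusters[0]

    up = np.asarray(up, dtype=float)
    candidates = []
    for cl in clusters:
        centroid = pts[cl].mean(axis=0)
        rel = centroid - palm_center
        dist = float(np.hypot(*rel))
        # keep clusters inside a cone around the hand axis (the axis
        # estimate can be several degrees off, so a plain half-plane test
        # is not enough to reject palm corners), then rank by distance
        if dist == 0 or rel @ up <= 0.3 * dist:
            continue
        candidates.append((dist, cl, centroid))
    if len(candidates) < 5:
        raise HandDetectionError(
            f"found {len(candidates)} fingertip candidates, need 5")
    candidates.sort(key=lambda c: -c[0])
    chosen = candidates[:5]

    tips, tip_idx = [], []
    for _, cl, _ in chosen:
        idxs = np.sort(hull_idx[cl])
        lo, hi = int(idxs[0]), int(idxs[-1])
        if hi - lo > n // 2:  # cluster wraps around the contour start
            lo, hi = hi, lo + n
        window = np.arange(lo - k, hi + k + 1) % n
        angles = np.full(len(window), np.inf)
        for j, i in enumerate(window):
            p = contour[i].astype(float)
            v1 = contour[(i - k) % n] - p
            v2 = contour[(i + k) % n] - p
            d1, d2 = np.hypot(*v1), np.hypot(*v2)
            if d1 == 0 or d2 == 0:
                continue
            angles[j] = np.arccos(np.clip((v1 @ v2) / (d1 * d2), -1.0, 1.0))
        # the angle is near-constant along a circular cap (its minimum is a
        # noisy plateau); take the plateau's extremal points along the hand
        # axis and report their centroid
        near = window[angles <= angles.min() + 0.35]
        heights = contour[near].astype(float) @ up
        top = heights >= heights.max() - 0.75
        apex_pts = contour[near[top]].astype(float)
        # sub-pixel apex from circle geometry: for a cap of radius r the
        # half-span at depth d below the apex is sqrt(2 r d), so the spans
        # of the top two pixel rows give the apex offset d1 = s1²/(s2²−s1²)
        second = (~top) & (heights >= heights.max() - 1.75)
        d1 = 0.5
        if second.any():
            right = _right_of(up)
            s1 = float(np.ptp(apex_pts @ right)) + 1.0
            s2 = float(np.ptp(contour[near[second]].astype(float) @ right)) + 1.0
            if s2 > s1 + 0.5:
                d1 = float(np.clip(s1 * s1 / (s2 * s2 - s1 * s1), 0.05, 0.95))
        tip = apex_pts.mean(axis=0) + d1 * up
        best = int(near[np.argmin(np.hypot(*(contour[near] - tip).T))])
        tips.append(tip)
        tip_idx.append(best)

    right = _right_of(up)
    order = np.argsort([(t - palm_center) @ right for t in tips])
    tips_arr = np.asarray(tips)[order]
    idx_arr = np.asarray(tip_idx)[order]
    return tips_arr, idx_arr


def detect_valleys(contour: Contour, hull_idx: np.ndarray,
                   tip_indices: np.ndarray, min_depth: float,
                   up: np.ndarray | None = None, floor_band: float = 1.5):
    """The four finger valleys between adjacent fingertips.

    A valley must show up as a convexity defect of depth ≥ ``min_depth``
    on the contour arc between the two tips.  Because the defect of a
    flat-bottomed gap is ambiguous along the floor, the reported valley
    point is the centroid of the arc points within ``floor_band`` px of
    the arc's lowest point along ``up`` (the deepest defect pixel is used
    unrefined when ``up`` is not given).

    Returns ``(valleys (4,2) float array, valley_contour_indices)`` ordered
    thumb side → pinky side.
    """
    contour = np.asarray(contour)
    n = len(contour)
    defects = convexity_defects(contour, contour[hull_idx], min_depth)
    if not defects:
        raise HandDetectionError("no convexity defects above the depth filter")
    tip_set = sorted(int(i) for i in tip_indices)

    def between(idx: int, a: int, b: int) -> bool:
        span = (b - a) % n
        return 0 < (idx - a) % n < span

    valleys, valley_idx = [], []
    for a, b in zip(tip_indices[:-1], tip_indices[1:]):
        a, b = int(a), int(b)
        # choose the contour arc a→b (either direction) free of other tips
        others = [t for t in tip_set if t not in (a, b)]
        if any(between(t, a, b) for t in others):
            a, b = b, a
        best = None
        for d in defects:
            if between(d["index"], a, b):
                if best is None or d["depth"] > best["depth"]:
                    best = d
        if best is None:
            raise HandDetectionError("missing valley between adjacent fingers")
        if up is None:
            valleys.append(best["point"])
        else:
            arc = np.arange(a + 1, a + 1 + (b - a) % n - 1) % n
            pts = contour[arc].astype(float)
            upv = np.asarray(up, dtype=float)
            depth_coord = -(pts @ upv)
            floor = pts[depth_coord >= depth_coord.max() - floor_band]
            # pixel centres sit inside the object; the web edge is half a
            # pixel above them
            valleys.append(floor.mean(axis=0) + 0.5 * upv)
        valley_idx.append(best["index"])
    return np.asarray(valleys, dtype=float), np.asarray(valley_idx)


def finger_base(valleys: np.ndarray, tip: np.ndarray | None = None,
                axis: np.ndarray | None = None) -> np.ndarray:
    """Base point of a finger from its adjacent valley point(s).

    Two valleys → their midpoint (middle and ring fingers).  One valley →
    midpoint of the valley and its reflection across the finger axis
    (thumb, index, pinky), i.e. the orthogonal projection of the valley
    onto the axis line through ``tip`` with direction ``axis``.
    """
    valleys = np.atleast_2d(np.asarray(valleys, dtype=float))
    if len(valleys) == 2:
        return valleys.mean(axis=0)
    if len(valleys) == 1:
        if tip is None or axis is None:
            raise ParameterError("single-valley base needs tip and axis")
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.hypot(*axis)
        rel = valleys[0] - np.asarray(tip, dtype=float)
        return np.asarray(tip, dtype=float) + (rel @ axis) * axis
    raise ParameterError("finger_base expects 1 or 2 valley points")


@dataclass
class HandLandmarks:
    """Geometric landmarks of a segmented hand."""
    fingertips: np.ndarray        # (5, 2) thumb→pinky
    valleys: np.ndarray           # (4, 2) thumb side→pinky side
    palm_center: np.ndarray       # (2,)
    finger_bases: np.ndarray      # (5, 2)
    up: np.ndarray                # (2,) unit vector toward the fingers
    contour: Contour | None = None


def locate_landmarks(mask: np.ndarray, min_depth: float = 20.0,
                     curvature_k: int = 15,
                     cluster_gap: float = 16.0) -> HandLandmarks:
    """Full landmark chain: contour → hull → tips → valleys → bases."""
    mask = np.asarray(mask, dtype=bool)
    contour = trace_contour(mask)
    if len(contour) < 3:
        raise HandDetectionError("contour too short for landmark detection")
    hull_idx = _hull_indices(contour)
    palm_center = np.argwhere(mask).mean(axis=0)
    up = estimate_orientation(mask)
    tips, tip_idx = detect_fingertips(contour, hull_idx, palm_center, up,
                                      cluster_gap=cluster_gap, k=curvature_k)
    valleys, _ = detect_valleys(contour, hull_idx, tip_idx, min_depth, up=up)

    # the principal-axis estimate is biased by the asymmetric thumb mass;
    # refine the axis from the middle/ring finger axes and redo the
    # orientation-sensitive steps once
    ax2 = tips[2] - (valleys[1] + valleys[2]) / 2
    ax3 = tips[3] - (valleys[2] + valleys[3]) / 2
    refined = ax2 / np.hypot(*ax2) + ax3 / np.hypot(*ax3)
    refined = refined / np.hypot(*refined)
    if refined @ up > np.cos(np.radians(25.0)):
        up = refined
        tips, tip_idx = detect_fingertips(contour, hull_idx, palm_center, up,
                                          cluster_gap=cluster_gap,
                                          k=curvature_k)
        valleys, _ = detect_valleys(contour, hull_idx, tip_idx, min_depth,
                                    up=up)

    bases = np.empty((5, 2))
    bases[0] = finger_base(valleys[[0]], tip=tips[0], axis=up)
    bases[1] = finger_base(valleys[[1]], tip=tips[1], axis=up)
    bases[2] = finger_base(valleys[[1, 2]])
    bases[3] = finger_base(valleys[[2, 3]])
    bases[4] = finger_base(valleys[[3]], tip=tips[4], axis=up)
    return HandLandmarks(fingertips=tips, valleys=valleys,
                         palm_center=palm_center, finger_bases=bases,
                         up=up, contour=contour)


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

@dataclass
class HandFeatures:
    """The 62-entry hand-geometry feature vector."""
    finger_lengths: np.ndarray    # (5,)
    finger_widths: np.ndarray     # (5, 10)
    tip_distances: np.ndarray     # (3,)
    valley_distances: np.ndarray  # (3,)
    palm_width: float

    def vector(self) -> np.ndarray:
        return np.concatenate([
            np.asarray(self.finger_lengths, float).ravel(),
            np.asarray(self.finger_widths, float).ravel(),
            np.asarray(self.tip_distances, float).ravel(),
            np.asarray(self.valley_distances, float).ravel(),
            [float(self.palm_width)],
        ])

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "HandFeatures":
        vec = np.asarray(vec, dtype=float).ravel()
        if vec.size != FEATURE_COUNT:
            raise ParameterError(f"feature vector must have {FEATURE_COUNT} entries")
        n_w = 5 * 10
        return cls(finger_lengths=vec[:5].copy(),
                   finger_widths=vec[5:5 + n_w].reshape(5, 10).copy(),
                   tip_distances=vec[55:58].copy(),
                   valley_distances=vec[58:61].copy(),
                   palm_width=float(vec[61]))

    #: indices of the entries that are direct anatomy (lengths, widths,
    #: tip gaps, palm width); valley gaps depend on the pixel-level valley
    #: localisation convention and are excluded from anatomy-recovery checks
    ANATOMY_SLICE = np.r_[np.arange(0, 58), [61]]


def _extent(mask: np.ndarray, point: np.ndarray, direction: np.ndarray,
            step: float = 0.25, max_extent: float = 400.0) -> float:
    """Length of the contiguous silhouette run through ``point`` along
    ``direction`` (both ways), by sub-pixel ray marching with bilinear
    silhouette sampling."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.hypot(*direction)
    n_steps = int(max_extent / step)
    ts = np.arange(1, n_steps) * step
    maskf = mask.astype(np.float32)

    def march(sign: float) -> float:
        coords = point[:, None] + sign * direction[:, None] * ts[None, :]
        vals = ndi.map_coordinates(maskf, coords, order=1, mode="constant")
        off = np.nonzero(vals < 0.5)[0]
        return float(ts[off[0]] - step / 2) if len(off) else float(ts[-1])

    centre = ndi.map_coordinates(maskf, point[:, None], order=1,
                                 mode="constant")[0]
    if centre < 0.5:
        raise MeasurementError("measurement axis leaves the silhouette")
    return march(1.0) + march(-1.0)


def measure_hand(mask: np.ndarray, landmarks: HandLandmarks,
                 n_width_samples: int = 10) -> HandFeatures:
    """Measure the feature vector from a silhouette and its landmarks."""
    mask = np.asarray(mask, dtype=bool)
    tips = landmarks.fingertips
    bases = landmarks.finger_bases
    valleys = landmarks.valleys

    lengths = np.hypot(*(tips - bases).T)
    widths = np.empty((5, n_width_samples))
    fractions = (np.arange(n_width_samples) + 0.5) / n_width_samples
    for i in range(5):
        axis = bases[i] - tips[i]
        norm = np.hypot(*axis)
        if norm == 0:
            raise MeasurementError(f"degenerate axis for finger {i}")
        axis = axis / norm
        perp = np.array([-axis[1], axis[0]])
        for j, f in enumerate(fractions):
            p = tips[i] + f * lengths[i] * axis
            widths[i, j] = _extent(mask, p, perp)

    tip_d = np.hypot(*(tips[1:-1] - tips[2:]).T)          # pairs 2-3, 3-4, 4-5
    valley_d = np.hypot(*(valleys[:-1] - valleys[1:]).T)  # 3 adjacent gaps

    middle_axis = bases[2] - tips[2]
    middle_axis = middle_axis / np.hypot(*middle_axis)
    palm_perp = np.array([-middle_axis[1], middle_axis[0]])
    palm_width = _extent(mask, landmarks.palm_center, palm_perp)

    return HandFeatures(finger_lengths=lengths, finger_widths=widths,
                        tip_distances=tip_d, valley_distances=valley_d,
                        palm_width=palm_width)
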