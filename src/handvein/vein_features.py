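"""Dorsal-vein minutiae extraction.

Pipeline: rectangular region of interest (ROI) on the hand dorsum spanning
finger valleys 2 and 4 with height 1.4× its width, resampled so the veins
run along the long (vertical) axis → median smoothing → histogram
equalization → adaptive thresholding of the inverted ROI (veins are darker
than surrounding tissue under near-infrared light) → cleanup → Zhang–Suen
thinning → crossing-number spur pruning → minutiae.

A *minutia* is either a vein branching (skeleton pixel with crossing
number ≥ 3) or a vein ending (crossing number 1 within a narrow band of
the frame edge, i.e. a vessel leaving the ROI).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from . import imaging
from .errors import ParameterError
from .hand_geometry import HandLandmarks

log = logging.getLogger("handvein")

__all__ = [
    "RoiSpec", "MinutiaeSet", "extract_roi", "segment_veins",
    "zhang_suen_thin", "connection_number", "connection_number_map",
    "prune_skeleton", "extract_minutiae",
]

BRANCHING = "branching"
ENDING = "ending"


# ---------------------------------------------------------------------------
# region of interest
# ---------------------------------------------------------------------------

@dataclass
class RoiSpec:
    """Placement of the vein ROI in the source image.

    ROI coordinates map to image coordinates as
    ``image = origin + col * e1 + row * e2`` where ``e1`` runs along the
    valley-2 → valley-4 top edge and ``e2`` points toward the wrist.
    """
    origin: np.ndarray          # (2,) image coords of the ROI (0, 0) corner
    e1: np.ndarray              # (2,) unit vector along the top edge
    e2: np.ndarray              # (2,) unit vector down the long side
    width: int
    height: int
    rotation: float             # degrees of e1 against the image col axis
    clipped: bool = False       # ROI exceeded the image bounds

    def roi_to_image(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.origin + pts[:, 1:2] * self.e1 + pts[:, 0:1] * self.e2

    def image_to_roi(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.origin
        return np.column_stack([pts @ self.e2, pts @ self.e1])


def extract_roi(img: np.ndarray, landmarks: HandLandmarks,
                factor: float = 1.4, seat_px: float = 4.0
                ) -> tuple[np.ndarray, RoiSpec]:
    """Cut and derotate the vein ROI.

    The top edge spans valleys 2 and 4 (numbered 1–4 from the thumb side),
    the width equals that span and the height is ``factor`` × width,
    extending toward the wrist.  The rectangle is seated ``seat_px`` below
    the web line so the crop never samples inter-finger background (valley
    localisation is only pixel-accurate); the seating is recorded in the
    returned frame origin.  The crop is resampled bilinearly so the output
    rows run down the hand and the veins are vertical.
    """
    img = np.asarray(img)
    v2, v4 = landmarks.valleys[1], landmarks.valleys[3]
    edge = v4 - v2
    width_f = float(np.hypot(*edge))
    if width_f < 2:
        raise ParameterError("valleys 2 and 4 coincide; ROI undefined")
    e1 = edge / width_f
    normal = np.array([-e1[1], e1[0]])
    if normal @ (-landmarks.up) < 0:   # must point away from the fingers
        normal = -normal
    width = int(round(width_f))
    height = int(round(factor * width_f))
    v2 = v2 + seat_px * normal

    rows = np.arange(height)
    cols = np.arange(width)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    coords = (v2[:, None, None]
              + cc[None] * e1[:, None, None]
              + rr[None] * normal[:, None, None])
    clipped = bool((coords[0].min() < 0) or (coords[1].min() < 0)
                   or (coords[0].max() > img.shape[0] - 1)
                   or (coords[1].max() > img.shape[1] - 1))
    if clipped:
        log.warning("vein ROI exceeds image bounds; clipped")
    roi = ndi.map_coordinates(img.astype(np.float64), coords.reshape(2, -1),
                              order=1, mode="nearest").reshape(height, width)
    spec = RoiSpec(origin=v2.astype(float), e1=e1, e2=normal,
                   width=width, height=height,
                   rotation=float(np.degrees(np.arctan2(e1[0], e1[1]))),
                   clipped=clipped)
    return np.clip(np.round(roi), 0, 255).astype(np.uint8), spec


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_veins(roi: np.ndarray, median_large: int = 11,
                  median_small: int = 3, surrounding: int = 15,
                  t_g: float = -14.0, closing_radius: int = 1,
                  fill_hole_area: int = 40,
                  min_component_area: int = 60) -> np.ndarray:
    """Binary vein mask from a grayscale ROI.

    Median(``median_large``) smoothing removes skin texture while retaining
    the vein bands; equalization stretches the vein/tissue contrast; the
    ROI is inverted so the dark veins satisfy the ≥ inequality of the
    adaptive threshold; a small median plus a dilation+erosion closing
    removes fragments and reconnects vessels broken by noise.  Enclosed
    pockets below ``fill_hole_area`` px are filled so a bifurcation can
    never thin into a spurious loop, and components below
    ``min_component_area`` px are dropped (a real vessel run is wider and
    longer than any noise blob the smoothing can produce).
    """
    roi = np.asarray(roi, dtype=np.uint8)
    if roi.size == 0:
        log.warning("empty ROI; returning empty vein mask")
        return np.zeros_like(roi, dtype=bool)
    smooth = imaging.median_filter(roi, median_large)
    if smooth.min() == smooth.max():
        log.warning("featureless ROI; returning empty vein mask")
        return np.zeros_like(roi, dtype=bool)
    eq = imaging.equalize_histogram(smooth)
    inverted = (255 - eq).astype(np.uint8)
    mask = imaging.local_threshold(inverted, surrounding, t_g)
    mask = imaging.median_filter(mask.astype(np.uint8), median_small).astype(bool)
    if closing_radius > 0:
        mask = imaging.erode(imaging.dilate(mask, closing_radius), closing_radius)
    if fill_hole_area > 0:
        holes, n = ndi.label(~mask)
        if n:
            sizes = ndi.sum_labels(~mask, holes, index=np.arange(1, n + 1))
            border = np.zeros_like(mask)
            border[0, :] = border[-1, :] = True
            border[:, 0] = border[:, -1] = True
            touches = np.unique(holes[border & ~mask])
            for lab in range(1, n + 1):
                if sizes[lab - 1] < fill_hole_area and lab not in touches:
                    mask[holes == lab] = True
    if min_component_area > 0:
        comp, n = ndi.label(mask, structure=np.ones((3, 3)))
        if n:
            sizes = ndi.sum_labels(mask, comp, index=np.arange(1, n + 1))
            small = np.nonzero(sizes < min_component_area)[0] + 1
            if len(small):
                mask[np.isin(comp, small)] = False
    return mask


# ---------------------------------------------------------------------------
# thinning and crossing numbers
# ---------------------------------------------------------------------------

def _neighbours(img: np.ndarray):
    """The 8 neighbour planes P2..P9 (N, NE, E, SE, S, SW, W, NW) of a
    zero-padded binary array."""
    p = np.pad(img, 1)
    return (p[:-2, 1:-1], p[:-2, 2:], p[1:-1, 2:], p[2:, 2:],
            p[2:, 1:-1], p[2:, :-2], p[1:-1, :-2], p[:-2, :-2])


def zhang_suen_thin(mask: np.ndarray) -> np.ndarray:
    """Two-subiteration thinning to a 1-px-wide 8-connected skeleton.

    Each pass deletes boundary pixels with 2–6 object neighbours and
    exactly one 0→1 transition around the neighbourhood cycle, subject to
    the directional products of the two sub-passes; iteration stops when a
    full double pass deletes nothing.  The parallel formulation can erase a
    2×2 component outright in one sub-pass; one pixel of any component
    that would vanish is retained so connected-component count is
    preserved exactly.
    """
    img = np.ascontiguousarray(np.asarray(mask, dtype=bool)).astype(np.uint8)
    eight = np.ones((3, 3))
    while True:
        changed = False
        for step in (0, 1):
            p2, p3, p4, p5, p6, p7, p8, p9 = _neighbours(img)
            cycle = (p2, p3, p4, p5, p6, p7, p8, p9, p2)
            b = sum(cycle[:-1])
            a = sum((cycle[i] == 0) & (cycle[i + 1] == 1) for i in range(8))
            if step == 0:
                cond = (p2 * p4 * p6 == 0) & (p4 * p6 * p8 == 0)
            else:
                cond = (p2 * p4 * p8 == 0) & (p2 * p6 * p8 == 0)
            delete = (img == 1) & (b >= 2) & (b <= 6) & (a == 1) & cond
            if delete.any():
                comp, n = ndi.label(img, structure=eight)
                survivors = ndi.sum_labels(img.astype(bool) & ~delete, comp,
                                           index=np.arange(1, n + 1))
                for lab in np.nonzero(survivors == 0)[0] + 1:
                    r, c = np.argwhere(comp == lab)[0]
                    delete[r, c] = False
                img[delete] = 0
                changed = True
        if not changed:
            break
    return img.astype(bool)


def connection_number_map(skel: np.ndarray) -> np.ndarray:
    """Crossing number of every pixel: half the sum of absolute differences
    around the ordered 8-neighbourhood cycle.  Background pixels get -1."""
    img = np.asarray(skel, dtype=bool).astype(np.int8)
    nb = _neighbours(img)
    cycle = list(nb) + [nb[0]]
    cn = sum(np.abs(cycle[i + 1].astype(np.int8) - cycle[i].astype(np.int8))
             for i in range(8)) // 2
    out = np.where(img.astype(bool), cn, -1)
    return out.astype(np.int8)


def connection_number(skel: np.ndarray, p: tuple[int, int]) -> int:
    """Crossing number of the object pixel ``p`` (0 isolated, 1 line end,
    2 interior, ≥3 branching)."""
    skel = np.asarray(skel, dtype=bool)
    r, c = p
    if not skel[r, c]:
        raise ParameterError(f"pixel {p} is not an object pixel")
    offsets = [(-1, 0), (-1, 1), (0, 1), (1, 1),
               (1, 0), (1, -1), (0, -1), (-1, -1)]
    h, w = skel.shape
    vals = [int(skel[r + dr, c + dc]) if 0 <= r + dr < h and 0 <= c + dc < w
            else 0 for dr, dc in offsets]
    return sum(abs(vals[(i + 1) % 8] - vals[i]) for i in range(8)) // 2


def _border_mask(shape: tuple[int, int], band: int,
                 edges: str = "all") -> np.ndarray:
    """Band of pixels along the frame edges: "top", "top_bottom" (the
    anatomically meaningful vessel exits of a vertically oriented ROI) or
    "all" four edges."""
    out = np.zeros(shape, dtype=bool)
    if band <= 0:
        return out
    out[:band, :] = True
    if edges in ("all", "top_bottom"):
        out[-band:, :] = True
    if edges == "all":
        out[:, :band] = True
        out[:, -band:] = True
    return out


def prune_skeleton(skel: np.ndarray, max_spur: int = 10,
                   border_band: int = 3, edges: str = "all") -> np.ndarray:
    """Remove isolated pixels and short spurs, keeping border exits.

    A spur is the path from a line end (crossing number 1) to the first
    branching pixel; spurs shorter than ``max_spur`` are deleted whole.
    Ends inside the ``border_band`` are genuine vessel exits and are never
    treated as spur tips.  Whole fragments (end-to-end paths) shorter than
    ``max_spur`` with no border contact are deleted too.  The skeleton is
    re-thinned afterwards so the junction neighbourhoods stay 1 px wide.
    """
    out = np.asarray(skel, dtype=bool).copy()
    border = _border_mask(out.shape, border_band, edges)
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]

    def neighbours_of(r, c, img):
        h, w = img.shape
        return [(r + dr, c + dc) for dr, dc in offsets
                if 0 <= r + dr < h and 0 <= c + dc < w and img[r + dr, c + dc]]

    for _ in range(64):  # passes until stable (bounded)
        cn = connection_number_map(out)
        out[cn == 0] = False
        cn = connection_number_map(out)
        ends = [tuple(p) for p in np.argwhere(cn == 1)
                if not border[tuple(p)]]
        removed_any = False
        for end in ends:
            if not out[end]:
                continue
            path = [end]
            prev, cur = None, end
            status = "long"
            while len(path) < max_spur:
                nbrs = [n for n in neighbours_of(*cur, out) if n != prev]
                if prev is not None and len(nbrs) > 1:
                    # ignore diagonal shortcuts back past the previous pixel
                    direct = [n for n in nbrs
                              if max(abs(n[0] - prev[0]), abs(n[1] - prev[1])) > 1]
                    if direct:
                        nbrs = direct
                if not nbrs:
                    status = "fragment"
                    break
                if len(nbrs) > 1 or cn[nbrs[0]] >= 3:
                    status = "junction"  # spur root reached; keep the junction
                    break
                prev, cur = cur, nbrs[0]
                path.append(cur)
                if cn[cur] == 1:
                    status = "fragment"
                    break
            if status == "junction":
                for p in path:
                    out[p] = False
                removed_any = True
            elif status == "fragment" and not any(border[p] for p in path):
                for p in path:
                    out[p] = False
                removed_any = True
        if not removed_any:
            break
    out = zhang_suen_thin(out)
    cn = connection_number_map(out)
    out[cn == 0] = False
    return out


# ---------------------------------------------------------------------------
# minutiae
# ---------------------------------------------------------------------------

@dataclass
class MinutiaeSet:
    """Point set of vein branchings and endings within an ROI frame."""
    points: np.ndarray                  # (n, 2) float (row, col)
    kinds: list[str]                    # BRANCHING or ENDING per point
    frame: tuple[int, int]              # (height, width)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) != len(self.kinds):
            raise ParameterError("points and kinds length mismatch")

    def __len__(self) -> int:
        return len(self.points)

    def of_kind(self, kind: str) -> np.ndarray:
        sel = [i for i, k in enumerate(self.kinds) if k == kind]
        return self.points[sel]

    @property
    def branchings(self) -> np.ndarray:
        return self.of_kind(BRANCHING)

    @property
    def endings(self) -> np.ndarray:
        return self.of_kind(ENDING)

    def to_json(self) -> dict:
        return {"frame": {"h": int(self.frame[0]), "w": int(self.frame[1])},
                "points": [{"r": float(r), "c": float(c), "kind": k}
                           for (r, c), k in zip(self.points, self.kinds)]}

    @classmethod
    def from_json(cls, data: dict) -> "MinutiaeSet":
        pts = [(p["r"], p["c"]) for p in data["points"]]
        kinds = [p["kind"] for p in data["points"]]
        return cls(points=np.asarray(pts, dtype=float).reshape(-1, 2),
                   kinds=kinds,
                   frame=(data["frame"]["h"], data["frame"]["w"]))

    def dumps(self) -> str:
        return json.dumps(self.to_json())

    @classmethod
    def loads(cls, text: str) -> "MinutiaeSet":
        return cls.from_json(json.loads(text))


def _merge_close(points: np.ndarray, radius: float) -> np.ndarray:
    """Union-find clustering of points within ``radius``; cluster centroids."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(points[i] - points[j])) <= radius:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return np.asarray([points[idx].mean(axis=0) for idx in clusters.values()])


def extract_minutiae(skel: np.ndarray, border_band: int = 3,
                     branch_min_cn: int = 3, merge_radius: float = 3.0,
                     edges: str = "all") -> MinutiaeSet:
    """Branching and ending minutiae of a pruned skeleton.

    Branchings: pixels with crossing number ≥ ``branch_min_cn``; adjacent
    branch pixels within ``merge_radius`` collapse to their centroid (one
    anatomical bifurcation can thin to several high-crossing pixels).
    Endings: crossing-number-1 pixels within ``border_band`` of the frame
    edge (vessels leaving the ROI).
    """
    skel = np.asarray(skel, dtype=bool)
    cn = connection_number_map(skel)
    branch_pts = np.argwhere(cn >= branch_min_cn).astype(float)
    if len(branch_pts):
        branch_pts = _merge_close(branch_pts, merge_radius)
    border = _border_mask(skel.shape, border_band, edges)
    end_pts = np.argwhere((cn == 1) & border).astype(float)

    points = (np.vstack([branch_pts, end_pts])
              if len(branch_pts) or len(end_pts) else np.empty((0, 2)))
    kinds = [BRANCHING] * len(branch_pts) + [ENDING] * len(end_pts)
    return MinutiaeSet(points=points, kinds=kinds, frame=skel.shape)
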