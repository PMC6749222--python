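"""Synthetic dorsal-hand capture generator with exact ground truth.

The generator emulates the statistical structure the verification pipeline
assumes: a bright hand silhouette against a dark matte background at
640×480 / 8 bit, five separated fingers, and a branching vein network —
darker than the surrounding tissue, as under near-infrared light — inside
the dorsum region of interest (the rectangle spanning finger valleys 2–4
with height 1.4× its width).  Each subject carries a persistent anatomy
(finger lengths/widths, palm size, vein-tree topology); captures of the
same subject differ by small anatomical jitter, in-plane pose, blur and
sensor noise.

Geometry of the phantom: the palm is an axis-aligned rectangle with a flat
top edge, and all five fingers are parallel vertical capsules (rectangles
with semicircular tips) standing on that edge, the thumb shorter and
separated by a wider gap.  This keeps every measured quantity of the
feature extractor analytically equal to the generator parameter — the
fingertip is the capsule apex, each finger valley lies on the flat top
edge, so the valley-projection base point coincides with the capsule base
and the measured length equals the drawn length exactly.  Whole-hand
rotation (default up to ±8°) still exercises pose normalization.

Coordinates: the *canonical* frame has the palm top edge at row 0 and the
palm centred on column 0; rendering maps canonical to image coordinates
through the per-capture pose (rotation + translation).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage as ndi

from .errors import ParameterError, RenderError
from .hand_geometry import HandFeatures
from .vein_features import BRANCHING, ENDING, MinutiaeSet

log = logging.getLogger("handvein")

__all__ = [
    "SubjectModel", "VeinTree", "CaptureGroundTruth",
    "DEFAULT_COHORT", "DEFAULT_NOISE", "ZERO_NOISE",
    "generate_subject", "render_capture", "generate_dataset",
    "analytic_features",
]

FRAME = (480, 640)
BACKGROUND_LEVEL = 18
HAND_LEVEL = 185
VEIN_DEPTH = 30.0          # intensity drop of a vein below the tissue

#: cohort anatomy: mean/spread per dimension (px), thumb→pinky ordering
DEFAULT_COHORT: dict = {
    # the tip-height profile is kept strictly concave across the hand so
    # every fingertip pokes above the hull chord of its neighbours
    "finger_length_mean": (50.0, 114.0, 132.0, 120.0, 80.0),
    "finger_length_sd": (2.5, 2.5, 2.5, 2.5, 2.5),
    "finger_width_mean": (24.0, 26.0, 27.0, 26.0, 22.0),
    "finger_width_sd": (1.5, 1.5, 1.5, 1.5, 1.5),
    "finger_gap_mean": (24.0, 12.0, 12.0, 12.0),   # thumb gap wider
    "finger_gap_sd": (2.0, 1.2, 1.2, 1.2),
    "palm_width_mean": 210.0, "palm_width_sd": 8.0,
    "palm_height_mean": 170.0, "palm_height_sd": 6.0,
    # the thumb capsule roots this far below the palm top edge, so its tip
    # sits clearly lower than the finger tips, as on a real dorsum
    "thumb_drop": 20.0,
    "vein_branchings": (2, 4),       # inclusive range of branch-node count
    "vein_width": (6.0, 7.2),        # rendered band width range (px)
    "jitter_scale": 0.02,            # intra-subject relative variation
}

#: per-capture nuisance defaults (the study conditions)
DEFAULT_NOISE: dict = {
    "jitter": None,          # None → use the subject's jitter_scale
    "blur_sigma": 0.7,       # px, Gaussian optics blur
    "noise_sigma": 5.0,      # grey levels, additive sensor noise
    "rotation_deg": 8.0,     # in-plane pose range (uniform ±)
    "translation_px": 10.0,  # pose translation range (uniform ±, both axes)
    # smooth skin-shading field on the hand surface (grey levels); its
    # correlation length exceeds the adaptive-threshold window so the local
    # mean removes it, while it keeps the ROI histogram broad enough for
    # histogram equalization to behave as on real tissue
    "texture_sigma": 5.0,
    "texture_scale": 18.0,   # px correlation length of the shading field
    "seed": 0,               # extra entropy mixed into the capture stream
}

ZERO_NOISE: dict = {"jitter": 0.0, "blur_sigma": 0.0, "noise_sigma": 0.0,
                    "rotation_deg": 0.0, "translation_px": 0.0,
                    "texture_sigma": 0.0, "texture_scale": 18.0, "seed": 0}


# ---------------------------------------------------------------------------
# subject model
# ---------------------------------------------------------------------------

@dataclass
class VeinTree:
    """Rooted planar tree in canonical coordinates.

    ``nodes[i]`` connects to ``nodes[parents[i]]`` with a band of width
    ``widths[i]``; the root has parent −1.  Bend nodes (degree 2) shape the
    curvature, branch nodes (≥2 children) are the anatomical bifurcations.
    """
    nodes: np.ndarray      # (n, 2) float (row, col)
    parents: np.ndarray    # (n,) int
    widths: np.ndarray     # (n,) float, width of the edge to the parent

    def children_count(self) -> np.ndarray:
        counts = np.zeros(len(self.nodes), dtype=int)
        for p in self.parents:
            if p >= 0:
                counts[p] += 1
        return counts

    @property
    def branch_nodes(self) -> np.ndarray:
        return self.nodes[self.children_count() >= 2]

    @property
    def leaf_nodes(self) -> np.ndarray:
        return self.nodes[self.children_count() == 0]

    def edges(self):
        for i, p in enumerate(self.parents):
            if p >= 0:
                yield self.nodes[p], self.nodes[i], self.widths[i]


@dataclass
class SubjectModel:
    """Persistent anatomy of one synthetic subject."""
    subject_id: str
    finger_lengths: np.ndarray      # (5,) thumb→pinky
    finger_base_widths: np.ndarray  # (5,)
    finger_gaps: np.ndarray         # (4,) gaps between adjacent fingers
    palm_width: float
    palm_height: float
    thumb_drop: float               # thumb root depth below the palm top edge
    palm_center: np.ndarray         # (2,) image coords of the palm centre
    vein_tree: VeinTree
    jitter_scale: float
    seed: int

    def __post_init__(self) -> None:
        for name in ("finger_lengths", "finger_base_widths", "finger_gaps"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if np.any(arr <= 0):
                raise ParameterError(f"{name} must be strictly positive")
        if self.palm_width <= 0 or self.palm_height <= 0:
            raise ParameterError("palm dimensions must be strictly positive")
        if not 0.0 <= self.jitter_scale < 0.1:
            raise ParameterError("jitter_scale must lie in [0, 0.1)")
        if len(self.vein_tree.branch_nodes) < 1 or len(self.vein_tree.leaf_nodes) < 2:
            raise ParameterError("vein tree needs ≥1 branching and ≥2 leaves")

    # -- derived canonical geometry ---------------------------------------

    def finger_centers(self) -> np.ndarray:
        w, g = self.finger_base_widths, self.finger_gaps
        span = w.sum() + g.sum()
        c = np.empty(5)
        c[0] = -span / 2 + w[0] / 2
        for k in range(4):
            c[k + 1] = c[k] + w[k] / 2 + g[k] + w[k + 1] / 2
        return c

    def valley_points(self) -> np.ndarray:
        """Canonical mid-gap valley points on the palm top edge."""
        c, w = self.finger_centers(), self.finger_base_widths
        cols = [(c[k] + w[k] / 2 + c[k + 1] - w[k + 1] / 2) / 2 for k in range(4)]
        return np.column_stack([np.zeros(4), cols])

    def roi_box(self) -> tuple[float, float, float]:
        """(left col, right col, height) of the canonical vein ROI."""
        v = self.valley_points()
        left, right = v[1, 1], v[3, 1]
        return left, right, 1.4 * (right - left)


def _trunc_normal(rng: np.random.Generator, mean, sd, size=None) -> np.ndarray:
    """Normal draw truncated at ±3 spread (by clipping the deviate)."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd <= 0):
        raise ParameterError("spread parameters must be strictly positive")
    z = np.clip(rng.standard_normal(size if size is not None else mean.shape),
                -3.0, 3.0)
    return mean + sd * z


def _grow_vein_tree(rng: np.random.Generator, left: float, right: float,
                    height: float, n_branch: int,
                    width_range: tuple[float, float]) -> VeinTree:
    """Planned top-down growth of a planar vein tree.

    ``k`` vessels exit through the ROI top edge at columns spaced at least
    17 px apart (closer parallel runs shade the tissue between them under
    the median filter); adjacent vessels merge pairwise at well-separated
    rows until a single trunk leaves through the bottom, which realises
    exactly ``k-1`` bifurcations.  Every join is a wide V (the tributary
    departs steeply), which keeps the skeleton junction of the rendered
    band within ~2 px of the node.  Exit columns, merge rows and merge
    order all vary between subjects and carry the vein identity.
    """
    inner_top, inner_bottom = 16.0, height - 26.0
    lo, hi = left + 9.0, right - 9.0
    spacing = 17.0
    k_max = int((hi - lo) // spacing) + 1
    k = int(np.clip(n_branch + 1, 2, k_max))

    merge_lo = max(inner_top + 12.0, 0.25 * height)
    while k > 2 and (inner_bottom - merge_lo) < 13.0 * (k - 2):
        k -= 1
    n_merge = k - 1

    # exit columns: minimal spacing plus randomly shared slack
    slack = (hi - lo) - spacing * (k - 1)
    shares = rng.dirichlet(np.ones(k + 1)) * slack
    cols = lo + shares[:k].cumsum() + spacing * np.arange(k)

    # merge rows: ascending, separated by >= 16 px
    row_slack = (inner_bottom - merge_lo) - 13.0 * (n_merge - 1)
    row_shares = rng.dirichlet(np.ones(n_merge + 1)) * max(row_slack, 0.0)
    merge_rows = (merge_lo + row_shares[:n_merge].cumsum()
                  + 13.0 * np.arange(n_merge))

    # plan the topology: at each merge row join a random adjacent pair
    groups: list[dict] = [{"col": float(c), "children": None} for c in cols]
    for m in merge_rows:
        i = int(rng.integers(len(groups) - 1))
        gl, gr = groups[i], groups[i + 1]
        mid = (gl["col"] + gr["col"]) / 2 + float(rng.uniform(-2.0, 2.0))
        groups[i:i + 2] = [{"col": mid, "children": (gl, gr, float(m))}]
    plan = groups[0]

    nodes: list[np.ndarray] = []
    parents: list[int] = []
    widths: list[float] = []

    def add(pos, parent):
        nodes.append(np.asarray(pos, dtype=float))
        parents.append(parent)
        widths.append(float(rng.uniform(*width_range)))
        return len(nodes) - 1

    def emit(node_plan: dict, parent: int, bottom_row: float) -> None:
        col = node_plan["col"]
        if node_plan["children"] is None:
            # vessel running out through the top edge, with a gentle bend
            mid = add((max(bottom_row / 2.0, 4.0),
                       col + rng.uniform(-1.5, 1.5)), parent)
            add((-6.0, col), mid)
            return
        gl, gr, m = node_plan["children"]
        b = parent
        if bottom_row - m > 30.0:  # long stem: slight curvature
            b = add(((bottom_row + m) / 2.0, col + rng.uniform(-1.5, 1.5)),
                    parent)
        b = add((m, col), b)
        for child in (gl, gr):
            rise = rng.uniform(5.0, 7.0)
            arm = add((m - rise, child["col"]), b)
            emit(child, arm, m - rise)

    root = add((height + 22.0, plan["col"]), -1)
    emit(plan, root, height + 22.0)
    return VeinTree(nodes=np.asarray(nodes), parents=np.asarray(parents),
                    widths=np.asarray(widths))


def generate_subject(seed: int, cohort_params: dict | None = None) -> SubjectModel:
    """Draw one subject's anatomy from the cohort distributions.

    Dimensions are independent normals truncated at ±3 spread; the vein
    tree is grown by recursive branching (default 2–4 branchings) inside
    the dorsum region.  Deterministic for a fixed seed.
    """
    p = {**DEFAULT_COHORT, **(cohort_params or {})}
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    lengths = _trunc_normal(rng, p["finger_length_mean"], p["finger_length_sd"])
    widths = _trunc_normal(rng, p["finger_width_mean"], p["finger_width_sd"])
    gaps = _trunc_normal(rng, p["finger_gap_mean"], p["finger_gap_sd"])
    palm_w = float(_trunc_normal(rng, np.float64(p["palm_width_mean"]),
                                 np.float64(p["palm_width_sd"])))
    palm_h = float(_trunc_normal(rng, np.float64(p["palm_height_mean"]),
                                 np.float64(p["palm_height_sd"])))
    span = widths.sum() + gaps.sum()
    palm_w = max(palm_w, span + 8.0)

    c = _finger_centers(widths, gaps)
    left = (c[1] + widths[1] / 2 + c[2] - widths[2] / 2) / 2
    right = (c[3] + widths[3] / 2 + c[4] - widths[4] / 2) / 2
    height = 1.4 * (right - left)
    b_lo, b_hi = p["vein_branchings"]
    n_branch = int(rng.integers(b_lo, b_hi + 1))
    tree = _grow_vein_tree(rng, left, right, height, n_branch,
                           tuple(p["vein_width"]))
    return SubjectModel(
        subject_id=f"S{int(seed):08d}", finger_lengths=lengths,
        finger_base_widths=widths, finger_gaps=gaps, palm_width=palm_w,
        palm_height=palm_h, thumb_drop=float(p["thumb_drop"]),
        palm_center=np.array([330.0, 320.0]),
        vein_tree=tree, jitter_scale=float(p["jitter_scale"]), seed=int(seed))


# ---------------------------------------------------------------------------
# capture rendering
# ---------------------------------------------------------------------------

@dataclass
class CaptureGroundTruth:
    """What the pipeline should recover from one capture."""
    true_features: HandFeatures
    true_minutiae: MinutiaeSet        # image coordinates, branchings+endings
    silhouette: np.ndarray            # analytic hand mask (bool)
    fingertips: np.ndarray            # (5, 2) image coords thumb→pinky
    valleys: np.ndarray               # (4, 2) image coords
    palm_center: np.ndarray           # (2,) image coords of the palm centre
    up: np.ndarray                    # (2,) unit vector toward the fingers
    anatomy: dict = field(default_factory=dict)  # jittered scalar dimensions


def _jittered_dims(subject: SubjectModel, rng: np.random.Generator,
                   jitter: float) -> dict:
    def jit(arr):
        arr = np.asarray(arr, dtype=float)
        return arr * (1.0 + jitter * np.clip(rng.standard_normal(arr.shape),
                                             -2.0, 2.0))
    dims = {
        "lengths": jit(subject.finger_lengths),
        "widths": jit(subject.finger_base_widths),
        "gaps": jit(subject.finger_gaps),
        "palm_width": float(jit(subject.palm_width)),
        "palm_height": float(jit(subject.palm_height)),
        "thumb_drop": float(subject.thumb_drop),
    }
    nodes = subject.vein_tree.nodes + rng.normal(
        0.0, jitter * 30.0 + 1e-12, subject.vein_tree.nodes.shape).clip(-3, 3)
    dims["vein_nodes"] = nodes
    return dims


def _finger_centers(widths: np.ndarray, gaps: np.ndarray) -> np.ndarray:
    span = widths.sum() + gaps.sum()
    c = np.empty(5)
    c[0] = -span / 2 + widths[0] / 2
    for k in range(4):
        c[k + 1] = c[k] + widths[k] / 2 + gaps[k] + widths[k + 1] / 2
    return c


def _analytic_feature_set(dims: dict) -> HandFeatures:
    """Feature vector implied by the (jittered) anatomy, using the same
    measurement conventions as the extractor."""
    L, w = dims["lengths"], dims["widths"]
    c = _finger_centers(w, dims["gaps"])
    fractions = (np.arange(10) + 0.5) / 10.0
    widths = np.empty((5, 10))
    for k in range(5):
        r = w[k] / 2.0
        d = fractions * L[k]
        cap = 2.0 * np.sqrt(np.maximum(2.0 * r * d - d * d, 0.0))
        widths[k] = np.where(d < r, cap, w[k])
    tips = np.column_stack([-L, c])
    tip_d = np.hypot(*(tips[1:-1] - tips[2:]).T)
    vcols = np.array([(c[k] + w[k] / 2 + c[k + 1] - w[k + 1] / 2) / 2
                      for k in range(4)])
    valley_d = np.abs(np.diff(vcols))
    return HandFeatures(finger_lengths=L.copy(), finger_widths=widths,
                        tip_distances=tip_d, valley_distances=valley_d,
                        palm_width=float(dims["palm_width"]))


def analytic_features(subject: SubjectModel, capture_index: int,
                      noise: dict | None = None) -> HandFeatures:
    """Ground-truth feature vector of a capture without rendering it."""
    n = {**DEFAULT_NOISE, **(noise or {})}
    jitter = subject.jitter_scale if n["jitter"] is None else float(n["jitter"])
    rng = np.random.default_rng([subject.seed & 0x7FFFFFFF,
                                 int(capture_index), int(n["seed"])])
    return _analytic_feature_set(_jittered_dims(subject, rng, jitter))


def _pose_transform(dims: dict, subject: SubjectModel,
                    theta_deg: float, translation: np.ndarray):
    """canonical → image affine; canonical palm centre maps near
    ``subject.palm_center``."""
    th = np.radians(theta_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    anchor_canon = np.array([dims["palm_height"] / 2.0, 0.0])
    A = np.asarray(subject.palm_center, dtype=float) + translation

    def to_image(pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - anchor_canon) @ R.T + A

    def to_canon(pts):
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (pts - A) @ R + anchor_canon

    return to_image, to_canon, R


def _hand_sdf(pr: np.ndarray, pc: np.ndarray, dims: dict) -> np.ndarray:
    """Signed distance to the hand silhouette in canonical coords."""
    pw, ph = dims["palm_width"], dims["palm_height"]
    dx = np.abs(pc) - pw / 2.0
    dy = np.maximum(-pr, pr - ph)
    outside = np.hypot(np.maximum(dx, 0.0), np.maximum(dy, 0.0))
    inside = np.minimum(np.maximum(dx, dy), 0.0)
    sdf = outside + inside

    c = _finger_centers(dims["widths"], dims["gaps"])
    for k in range(5):
        r = dims["widths"][k] / 2.0
        top = -(dims["lengths"][k] - r)
        bottom = dims["thumb_drop"] if k == 0 else 0.0
        near_r = np.clip(pr, top, bottom)
        d = np.hypot(pr - near_r, pc - c[k]) - r
        sdf = np.minimum(sdf, d)
    return sdf


def render_capture(subject: SubjectModel, capture_index: int,
                   noise: dict | None = None
                   ) -> tuple[np.ndarray, CaptureGroundTruth]:
    """Render one 640×480 8-bit capture plus its ground truth.

    The noise map controls the per-capture nuisances (see
    ``DEFAULT_NOISE``); ground truth is returned in image coordinates
    after jitter and pose.
    """
    n = {**DEFAULT_NOISE, **(noise or {})}
    jitter = subject.jitter_scale if n["jitter"] is None else float(n["jitter"])
    rng = np.random.default_rng([subject.seed & 0x7FFFFFFF,
                                 int(capture_index), int(n["seed"])])
    dims = _jittered_dims(subject, rng, jitter)
    theta = float(rng.uniform(-n["rotation_deg"], n["rotation_deg"])) \
        if n["rotation_deg"] else 0.0
    trans = (rng.uniform(-n["translation_px"], n["translation_px"], 2)
             if n["translation_px"] else np.zeros(2))
    to_image, to_canon, R = _pose_transform(dims, subject, theta, trans)
    dims["pose_theta_deg"] = theta
    dims["pose_translation"] = np.asarray(trans, dtype=float)

    # frame check: extremes of the canonical bounding box
    max_len = float(dims["lengths"].max())
    bbox = np.array([[-max_len - 2, -dims["palm_width"] / 2 - 2],
                     [-max_len - 2, dims["palm_width"] / 2 + 2],
                     [dims["palm_height"] + 2, -dims["palm_width"] / 2 - 2],
                     [dims["palm_height"] + 2, dims["palm_width"] / 2 + 2]])
    corners = to_image(bbox)
    if (corners.min() < 0 or corners[:, 0].max() > FRAME[0] - 1
            or corners[:, 1].max() > FRAME[1] - 1):
        raise RenderError("hand placed partially out of frame")

    rr, cc = np.meshgrid(np.arange(FRAME[0], dtype=np.float64),
                         np.arange(FRAME[1], dtype=np.float64), indexing="ij")
    canon = to_canon(np.column_stack([rr.ravel(), cc.ravel()]))
    pr = canon[:, 0].reshape(FRAME)
    pc = canon[:, 1].reshape(FRAME)

    sdf = _hand_sdf(pr, pc, dims)
    coverage = np.clip(0.5 - sdf, 0.0, 1.0)

    # vein darkness field, canonical coords, restricted to the tree bbox
    tree = VeinTree(nodes=dims["vein_nodes"], parents=subject.vein_tree.parents,
                    widths=subject.vein_tree.widths)
    vein = np.zeros(FRAME)
    lo_r = tree.nodes[:, 0].min() - 8
    hi_r = tree.nodes[:, 0].max() + 8
    lo_c = tree.nodes[:, 1].min() - 8
    hi_c = tree.nodes[:, 1].max() + 8
    sel = (pr >= lo_r) & (pr <= hi_r) & (pc >= lo_c) & (pc <= hi_c)
    spr, spc = pr[sel], pc[sel]
    band = np.zeros_like(spr)
    for a, b, w in tree.edges():
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip(((spr - a[0]) * ab[0] + (spc - a[1]) * ab[1]) / denom,
                    0.0, 1.0) if denom > 0 else 0.0
        d = np.hypot(spr - (a[0] + t * ab[0]), spc - (a[1] + t * ab[1]))
        band = np.maximum(band, np.clip(w / 2.0 + 0.5 - d, 0.0, 1.0))
    vein[sel] = band

    img = (BACKGROUND_LEVEL
           + (HAND_LEVEL - BACKGROUND_LEVEL) * coverage
           - VEIN_DEPTH * vein * coverage)
    if n.get("texture_sigma", 0.0):
        field = ndi.gaussian_filter(rng.standard_normal(FRAME),
                                    n.get("texture_scale", 18.0))
        field *= n["texture_sigma"] / max(field.std(), 1e-9)
        img = img + field * coverage
    if n["blur_sigma"]:
        img = ndi.gaussian_filter(img, n["blur_sigma"])
    if n["noise_sigma"]:
        img = img + rng.normal(0.0, n["noise_sigma"], img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    # ------------------------------------------------------------------ gt
    silhouette = sdf <= 0.0
    features = _analytic_feature_set(dims)
    c = _finger_centers(dims["widths"], dims["gaps"])
    tips_img = to_image(np.column_stack([-dims["lengths"], c]))
    vcols = np.array([(c[k] + dims["widths"][k] / 2
                       + c[k + 1] - dims["widths"][k + 1] / 2) / 2
                      for k in range(4)])
    valleys_img = to_image(np.column_stack([np.zeros(4), vcols]))
    palm_center_img = to_image([[dims["palm_height"] / 2.0, 0.0]])[0]
    up_img = R @ np.array([-1.0, 0.0])

    pts, kinds = [], []
    for p in tree.branch_nodes:
        pts.append(p)
        kinds.append(BRANCHING)
    roi_h = 1.4 * (vcols[3] - vcols[1])
    for a, b, _ in tree.edges():
        for edge_row in (0.0, roi_h):  # exits through the ROI top/bottom edge
            lo_e, hi_e = sorted((a[0], b[0]))
            if lo_e < edge_row < hi_e:
                t = (edge_row - a[0]) / (b[0] - a[0])
                pts.append(np.array([edge_row, a[1] + t * (b[1] - a[1])]))
                kinds.append(ENDING)
    minutiae = MinutiaeSet(points=to_image(np.asarray(pts)) if pts
                           else np.empty((0, 2)),
                           kinds=kinds, frame=FRAME)

    gt = CaptureGroundTruth(true_features=features, true_minutiae=minutiae,
                            silhouette=silhouette, fingertips=tips_img,
                            valleys=valleys_img, palm_center=palm_center_img,
                            up=up_img, anatomy=dims)
    return img, gt


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

def generate_dataset(n_subjects: int = 40, captures_per_subject: int = 7,
                     seed: int = 0, out_dir: str | Path = ".",
                     n_enroll: int = 2, cohort_params: dict | None = None,
                     noise: dict | None = None) -> pd.DataFrame:
    """Write a labeled synthetic dataset and return its manifest.

    Default mirrors the study protocol: 40 subjects × 7 captures with the
    first 2 captures per subject flagged for enrollment.  Images are 8-bit
    single-channel PNG; ground truth goes to one JSON per capture; the
    manifest CSV holds (subject_id, capture_idx, path, is_enrollment,
    gt_path).  Byte-identical for a fixed seed.
    """
    if n_subjects < 2:
        raise ParameterError("need at least 2 subjects")
    if captures_per_subject < 3:
        raise ParameterError("need at least 3 captures per subject")
    if not 2 <= n_enroll < captures_per_subject:
        raise ParameterError("n_enroll must be >=2 and < captures_per_subject")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(int(seed))
    subject_seeds = [int(s) & 0x7FFFFFFF for s in ss.generate_state(n_subjects)]
    rows = []
    for i, sseed in enumerate(subject_seeds):
        subject = generate_subject(sseed, cohort_params)
        sid = f"subj{i:03d}"
        for ci in range(captures_per_subject):
            img, gt = render_capture(subject, ci, noise)
            img_path = out / f"{sid}_c{ci}.png"
            gt_path = out / f"{sid}_c{ci}_gt.json"
            Image.fromarray(img, mode="L").save(img_path)
            gt_payload = {
                "features": [round(float(v), 6) for v in gt.true_features.vector()],
                "minutiae": gt.true_minutiae.to_json(),
                "fingertips": np.round(gt.fingertips, 4).tolist(),
                "valleys": np.round(gt.valleys, 4).tolist(),
                "palm_center": np.round(gt.palm_center, 4).tolist(),
            }
            gt_path.write_text(json.dumps(gt_payload))
            rows.append({"subject_id": sid, "capture_idx": ci,
                         "path": img_path.name,
                         "is_enrollment": ci < n_enroll,
                         "gt_path": gt_path.name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    log.info("wrote %d captures for %d subjects to %s",
             len(manifest), n_subjects, out)
    return manifest
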