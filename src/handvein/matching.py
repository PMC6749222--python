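"""Score computation, normalization, fusion and the accept/reject decision.

All four metrics are *dissimilarities*: zero on identical inputs, larger
for worse matches.  The geometry modality compares 62-entry feature
vectors against a per-subject template (mean and RMS spread per feature
over the enrollment captures); the vein modality compares minutiae point
sets with Hausdorff-type distances.  Per-metric scores are min-max
normalized over a comparison batch, fused by arithmetic mean, and the
claim is accepted when the fused score does not exceed the threshold
(default 0.5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateBatchError, EmptySetError, EnrollmentError, ParameterError
from .hand_geometry import FEATURE_COUNT, HandFeatures
from .vein_features import MinutiaeSet

__all__ = [
    "Template", "ScorePair", "build_template",
    "euclidean_distance", "hamming_distance",
    "hausdorff_oriented", "hausdorff", "mhv",
    "minutiae_score", "min_max_normalize", "fuse_and_decide",
]


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

@dataclass
class Template:
    """Per-subject enrollment record."""
    subject_id: str
    feature_means: np.ndarray       # (62,)
    feature_sigmas: np.ndarray      # (62,) strictly positive (floored)
    reference_minutiae: MinutiaeSet
    n_enroll: int

    def to_json(self) -> dict:
        return {"subject_id": self.subject_id,
                "feature_means": [float(v) for v in self.feature_means],
                "feature_sigmas": [float(v) for v in self.feature_sigmas],
                "reference_minutiae": self.reference_minutiae.to_json(),
                "n_enroll": int(self.n_enroll)}

    @classmethod
    def from_json(cls, data: dict) -> "Template":
        return cls(subject_id=data["subject_id"],
                   feature_means=np.asarray(data["feature_means"], float),
                   feature_sigmas=np.asarray(data["feature_sigmas"], float),
                   reference_minutiae=MinutiaeSet.from_json(
                       data["reference_minutiae"]),
                   n_enroll=int(data["n_enroll"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Template":
        return cls.from_json(json.loads(Path(path).read_text()))


@dataclass
class ScorePair:
    """Raw, normalized and fused scores of one comparison."""
    geometry_raw: float
    vein_raw: float
    geometry_norm: float
    vein_norm: float
    fused: float


def _vector(x) -> np.ndarray:
    if isinstance(x, HandFeatures):
        return x.vector()
    return np.asarray(x, dtype=float).ravel()


def build_template(features, minutiae, subject_id: str = "",
                   sigma_floor: float = 0.5) -> Template:
    """Template from ≥2 enrollment captures.

    Per-feature mean and RMS deviation from the mean (floored at
    ``sigma_floor`` so coinciding captures cannot produce a zero spread);
    the first capture's minutiae set becomes the vein reference.
    """
    vectors = [_vector(f) for f in features]
    if len(vectors) < 2:
        raise EnrollmentError("template needs at least 2 enrollment captures")
    if len(minutiae) != len(vectors):
        raise EnrollmentError("features and minutiae sequences differ in length")
    X = np.vstack(vectors)
    if X.shape[1] != FEATURE_COUNT:
        raise ParameterError(f"feature vectors must have {FEATURE_COUNT} entries")
    means = X.mean(axis=0)
    sigmas = np.sqrt(np.mean((X - means) ** 2, axis=0))
    sigmas = np.maximum(sigmas, sigma_floor)
    return Template(subject_id=subject_id, feature_means=means,
                    feature_sigmas=sigmas, reference_minutiae=minutiae[0],
                    n_enroll=len(vectors))


# ---------------------------------------------------------------------------
# geometry metrics
# ---------------------------------------------------------------------------

def euclidean_distance(x, t) -> float:
    """√Σ(xᵢ−tᵢ)² between a probe vector and the template means."""
    x, t = _vector(x), _vector(t)
    if x.shape != t.shape:
        raise ParameterError("feature vectors differ in length")
    return float(np.sqrt(np.sum((x - t) ** 2)))


def hamming_distance(x, template: Template) -> int:
    """Number of features deviating from the template mean by more than
    the template's RMS spread (strict inequality)."""
    x = _vector(x)
    means, sigmas = template.feature_means, template.feature_sigmas
    if x.shape != means.shape:
        raise ParameterError("feature vector length does not match template")
    return int(np.count_nonzero(np.abs(x - means) > sigmas))


# ---------------------------------------------------------------------------
# point-set metrics
# ---------------------------------------------------------------------------

def _points(A) -> np.ndarray:
    pts = A.points if isinstance(A, MinutiaeSet) else np.asarray(A, dtype=float)
    pts = pts.reshape(-1, 2).astype(float)
    if len(pts) == 0:
        raise EmptySetError("point-set distance undefined for an empty set")
    return pts


def hausdorff_oriented(A, B) -> float:
    """Directed Hausdorff distance max_{x∈A} min_{y∈B} ‖x−y‖ (asymmetric)."""
    a, b = _points(A), _points(B)
    return float(cdist(a, b).min(axis=1).max())


def hausdorff(A, B) -> float:
    """Symmetric Hausdorff distance: the larger of the two directed ones."""
    a, b = _points(A), _points(B)
    d = cdist(a, b)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def mhv(A, B) -> float:
    """Modified Hausdorff distance.

    The directed term averages the nearest-neighbour distances,
    d(A,B) = (1/|A|) Σ_{x∈A} min_{y∈B} ‖x−y‖, which suppresses the
    influence of single outliers; the returned score symmetrizes by the
    maximum of the two directions.
    """
    a, b = _points(A), _points(B)
    d = cdist(a, b)
    return float(max(d.min(axis=1).mean(), d.min(axis=0).mean()))


_METRICS = {"hv": hausdorff, "mhv": mhv, "oriented": hausdorff_oriented}


def minutiae_score(A: MinutiaeSet, B: MinutiaeSet, metric: str = "mhv",
                   align: bool = True, kind_match: bool = False) -> float:
    """Vein dissimilarity between two minutiae sets.

    With ``align`` the sets are translation-registered by centroid before
    the distance is taken (the scanner pose is not fixed, so the ROI can
    shift by a few pixels between captures).  With ``kind_match`` the
    metric is averaged over per-kind comparisons when both sets carry both
    kinds, so branchings only ever match branchings.
    """
    fn = _METRICS[metric]
    a_pts, b_pts = _points(A), _points(B)
    if align:
        a_pts = a_pts - a_pts.mean(axis=0)
        b_pts = b_pts - b_pts.mean(axis=0)
    if not kind_match or not isinstance(A, MinutiaeSet):
        return fn(a_pts, b_pts)
    scores = []
    for kind in ("branching", "ending"):
        sa = [i for i, k in enumerate(A.kinds) if k == kind]
        sb = [i for i, k in enumerate(B.kinds) if k == kind]
        if sa and sb:
            scores.append(fn(a_pts[sa], b_pts[sb]))
    if not scores:
        return fn(a_pts, b_pts)
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# normalization, fusion, decision
# ---------------------------------------------------------------------------

def min_max_normalize(scores) -> np.ndarray:
    """Map a raw score batch onto [0, 1] by (o − min)/(max − min)."""
    scores = np.asarray(scores, dtype=float).ravel()
    if scores.size < 2:
        raise DegenerateBatchError("normalization needs at least 2 scores")
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        raise DegenerateBatchError("all scores identical; min-max undefined")
    return (scores - lo) / (hi - lo)


def fuse_and_decide(geometry_norm: float, vein_norm: float,
                    threshold: float = 0.5) -> tuple[float, bool]:
    """Arithmetic-mean fusion and the accept decision.

    Scores are dissimilarities, so the claim is accepted when the fused
    score is ≤ ``threshold`` (boundary inclusive).
    """
    for name, v in (("geometry_norm", geometry_norm), ("vein_norm", vein_norm)):
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"{name}={v} outside [0, 1]")
    fused = (float(geometry_norm) + float(vein_norm)) / 2.0
    return fused, fused <= threshold
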