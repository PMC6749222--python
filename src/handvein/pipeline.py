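"""Per-capture processing chain: image → features + minutiae.

Binds the primitives in the order the system runs: preprocessing,
segmentation, landmark extraction, geometry measurement, vein ROI,
vein segmentation, thinning, pruning, minutiae.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from . import imaging, vein_features
from .config import PipelineConfig
from .errors import SegmentationError
from .hand_geometry import HandFeatures, HandLandmarks, locate_landmarks, measure_hand
from .vein_features import MinutiaeSet, RoiSpec

log = logging.getLogger("handvein")

__all__ = ["CaptureResult", "segment_hand", "extract_capture"]


@dataclass
class CaptureResult:
    features: HandFeatures
    minutiae: MinutiaeSet
    landmarks: HandLandmarks
    roi_spec: RoiSpec
    mask: np.ndarray
    skeleton: np.ndarray


def segment_hand(img: np.ndarray, config: PipelineConfig | None = None) -> np.ndarray:
    """Hand silhouette: averaging filter, global mean-offset threshold,
    largest 8-connected component, hole filling."""
    config = config or PipelineConfig()
    log.debug("stage=preprocessing core=%d", config.mean_core)
    smooth = imaging.mean_filter(img, config.mean_core)
    log.debug("stage=segmentation t_g=%s", config.hand_tg)
    binary = imaging.global_threshold(smooth, config.hand_tg)
    labels, n = ndi.label(binary, structure=np.ones((3, 3)))
    if n == 0:
        raise SegmentationError("global threshold produced an empty mask")
    sizes = ndi.sum_labels(binary, labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    return ndi.binary_fill_holes(mask)


def extract_capture(img: np.ndarray,
                    config: PipelineConfig | None = None) -> CaptureResult:
    """Run the full dual-modality extraction on one grayscale capture."""
    config = config or PipelineConfig()
    img = np.asarray(img)
    mask = segment_hand(img, config)

    log.debug("stage=extraction modality=geometry")
    landmarks = locate_landmarks(mask, min_depth=config.min_depth,
                                 curvature_k=config.curvature_k,
                                 cluster_gap=config.cluster_gap)
    features = measure_hand(mask, landmarks,
                            n_width_samples=config.n_width_samples)

    log.debug("stage=extraction modality=vein")
    roi, spec = vein_features.extract_roi(img, landmarks,
                                          factor=config.roi_factor,
                                          seat_px=config.roi_seat)
    vein_mask = vein_features.segment_veins(
        roi, median_large=config.vein_median_large,
        median_small=config.vein_median_small,
        surrounding=config.vein_surrounding, t_g=config.vein_tg,
        closing_radius=config.closing_radius)
    # thin on an edge-replicated canvas so vessels crossing the frame keep
    # their centerline up to the border (thinning otherwise erodes the
    # blunt band end a few pixels inward, making border endings flicker)
    pad = 8
    padded = np.pad(vein_mask, pad, mode="edge")
    skel = vein_features.zhang_suen_thin(padded)[pad:-pad, pad:-pad]
    skel = vein_features.prune_skeleton(skel, max_spur=config.max_spur,
                                        border_band=config.border_band,
                                        edges=config.ending_edges)
    minutiae = vein_features.extract_minutiae(
        skel, border_band=config.border_band,
        branch_min_cn=config.branch_min_cn,
        merge_radius=config.merge_radius, edges=config.ending_edges)
    return CaptureResult(features=features, minutiae=minutiae,
                         landmarks=landmarks, roi_spec=spec,
                         mask=mask, skeleton=skel)
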