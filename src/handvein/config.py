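"""Pipeline configuration.

Every tunable of the verification pipeline lives here with its default and
documented range.  Values can be overridden from a YAML mapping (``load``)
or keyword arguments; each field is validated on construction.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ParameterError

log = logging.getLogger("handvein")


@dataclass
class PipelineConfig:
    # -- hand segmentation ------------------------------------------------
    #: size of the averaging core applied before global thresholding
    mean_core: int = 3
    #: global threshold constant; threshold = image mean - hand_tg.  Negative
    #: values put the threshold *above* the mean, which suits a dark
    #: background covering most of the frame.
    hand_tg: float = -40.0

    # -- hand landmark detection ------------------------------------------
    #: minimal convexity-defect depth (px) for a finger valley
    min_depth: float = 20.0
    #: half-window (contour points) of the fingertip curvature test
    curvature_k: int = 15
    #: hull-vertex clusters closer than this gap (px) merge into one fingertip
    cluster_gap: float = 16.0
    #: number of width samples per finger
    n_width_samples: int = 10

    # -- vein ROI and segmentation -----------------------------------------
    #: ROI height as a multiple of its width
    roi_factor: float = 1.4
    #: the ROI is seated this many px below the valley line so the crop
    #: never samples inter-finger background
    roi_seat: float = 4.0
    #: window of the large smoothing median inside the ROI
    vein_median_large: int = 11
    #: window of the small post-threshold median
    vein_median_small: int = 3
    #: local-mean window of the adaptive threshold
    vein_surrounding: int = 15
    #: T_g of the adaptive threshold applied to the *inverted* ROI; negative
    #: so that only pixels exceeding the local mean by |T_g| become object
    vein_tg: float = -14.0
    #: disk radius of the dilation+erosion closing
    closing_radius: int = 1

    # -- skeleton / minutiae -----------------------------------------------
    #: spurs shorter than this (px) are pruned from the skeleton
    max_spur: int = 10
    #: distance (px) from the frame edge within which line ends count as
    #: ending minutiae
    border_band: int = 3
    #: which frame edges carry ending minutiae: "top_bottom" (the vessel
    #: exits of a vertically oriented ROI; side contacts are clipping
    #: artifacts), "top" only, or "all" four edges
    ending_edges: str = "top_bottom"
    #: minimal crossing number of a branching minutia (3 = standard
    #: crossing-number practice; 4 = literal strict reading)
    branch_min_cn: int = 3
    #: branch pixels within this radius (px) merge into one minutia
    merge_radius: float = 3.0

    # -- matching and decision ----------------------------------------------
    #: lower bound on per-feature RMS spread (px)
    sigma_floor: float = 0.5
    #: translation-register minutiae sets (centroid alignment) before
    #: Hausdorff-type matching
    align_minutiae: bool = True
    #: restrict nearest-neighbour search to minutiae of the same kind
    kind_match: bool = False
    #: accept when the fused dissimilarity is <= this value
    accept_threshold: float = 0.5
    #: threshold grid step of the FMR/FNMR sweep
    grid_step: float = 0.005

    def __post_init__(self) -> None:
        for name in ("mean_core", "vein_median_large", "vein_median_small",
                     "vein_surrounding"):
            v = getattr(self, name)
            if v < 3 or v % 2 == 0:
                raise ParameterError(f"{name} must be an odd integer >= 3, got {v}")
        if self.roi_factor <= 0:
            raise ParameterError("roi_factor must be positive")
        if not 0.0 <= self.accept_threshold <= 1.0:
            raise ParameterError("accept_threshold must lie in [0, 1]")
        if not 0.0 < self.grid_step <= 0.5:
            raise ParameterError("grid_step must lie in (0, 0.5]")
        if self.sigma_floor <= 0:
            raise ParameterError("sigma_floor must be positive")
        if self.branch_min_cn not in (3, 4):
            raise ParameterError("branch_min_cn must be 3 or 4")
        if self.ending_edges not in ("all", "top", "top_bottom"):
            raise ParameterError(
                "ending_edges must be 'all', 'top' or 'top_bottom'")
        for name in ("min_depth", "curvature_k", "cluster_gap", "max_spur",
                     "border_band", "merge_radius", "closing_radius",
                     "n_width_samples"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "PipelineConfig":
        """Build a config from an optional YAML file plus keyword overrides."""
        values: dict = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
            if not isinstance(data, dict):
                raise ParameterError("config file must hold a key-value mapping")
            values.update(data)
        values.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**values)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
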