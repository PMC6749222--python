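"""Verification-error evaluation: FMR/FNMR threshold sweep and the EER.

With dissimilarity scores the accept rule is ``score ≤ t``, so the false
match rate (FMR, impostors accepted) grows with the threshold while the
false non-match rate (FNMR, genuines rejected) shrinks; the equal error
rate (EER) is the value at their crossing, linearly interpolated between
grid points.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import matching
from .config import PipelineConfig
from .errors import EvaluationError
from .pipeline import extract_capture

log = logging.getLogger("handvein")

__all__ = ["ErrorCurves", "sweep_errors", "compute_eer",
           "score_dataset", "evaluate_dataset", "write_results",
           "FUSED_METRICS"]

#: the two best single-modality metrics feeding the fused score
FUSED_METRICS = ("geometry_hamming", "vein_mhv")

ALL_METRICS = ("geometry_euclidean", "geometry_hamming", "vein_hv", "vein_mhv")


@dataclass
class ErrorCurves:
    thresholds: np.ndarray
    fmr: np.ndarray
    fnmr: np.ndarray
    eer: float = float("nan")
    eer_threshold: float = float("nan")


def sweep_errors(scores, genuine, thresholds=None,
                 grid_step: float = 0.005) -> ErrorCurves:
    """FMR/FNMR over an ascending threshold grid (default 0→1, step 0.005).

    ``scores`` are normalized dissimilarities, ``genuine`` the same-subject
    flags.  FMR(t) = fraction of impostor scores ≤ t; FNMR(t) = fraction of
    genuine scores > t.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    genuine = np.asarray(genuine, dtype=bool).ravel()
    if scores.shape != genuine.shape:
        raise EvaluationError("scores and genuine flags differ in length")
    gen = np.sort(scores[genuine])
    imp = np.sort(scores[~genuine])
    if len(gen) == 0 or len(imp) == 0:
        raise EvaluationError("need at least one genuine and one impostor score")
    if thresholds is None:
        n = int(round(1.0 / grid_step))
        thresholds = np.linspace(0.0, 1.0, n + 1)
    thresholds = np.asarray(thresholds, dtype=float)

    fmr = np.searchsorted(imp, thresholds, side="right") / len(imp)
    fnmr = 1.0 - np.searchsorted(gen, thresholds, side="right") / len(gen)
    if np.any(np.diff(fmr) < 0) or np.any(np.diff(fnmr) > 0):
        raise EvaluationError("error curves violate monotonicity")  # defensive
    curves = ErrorCurves(thresholds=thresholds, fmr=fmr, fnmr=fnmr)
    curves.eer, curves.eer_threshold = compute_eer(curves)
    return curves


def compute_eer(curves: ErrorCurves) -> tuple[float, float]:
    """EER at the FMR/FNMR crossing, linearly interpolated between grid
    points; if the curves touch over an interval the midpoint threshold is
    reported."""
    t, fmr, fnmr = curves.thresholds, curves.fmr, curves.fnmr
    d = fmr - fnmr
    cross = np.nonzero(d >= 0)[0]
    if len(cross) == 0:          # curves never cross inside the grid
        return float((fmr[-1] + fnmr[-1]) / 2), float(t[-1])
    i = int(cross[0])
    if d[i] == 0:
        j = i
        while j + 1 < len(d) and d[j + 1] == 0:
            j += 1
        mid = (t[i] + t[j]) / 2
        return float(fmr[i]), float(mid)
    if i == 0:
        return float((fmr[0] + fnmr[0]) / 2), float(t[0])
    alpha = -d[i - 1] / (d[i] - d[i - 1])
    eer = fmr[i - 1] + alpha * (fmr[i] - fmr[i - 1])
    return float(eer), float(t[i - 1] + alpha * (t[i] - t[i - 1]))


# ---------------------------------------------------------------------------
# dataset-level evaluation
# ---------------------------------------------------------------------------

def _load_manifest(manifest) -> pd.DataFrame:
    if isinstance(manifest, (str, Path)):
        df = pd.read_csv(manifest)
        base = Path(manifest).parent
        df["path"] = [str(base / p) if not Path(p).is_absolute() else p
                      for p in df["path"]]
    else:
        df = manifest.copy()
    if df.empty:
        raise EvaluationError("empty manifest")
    required = {"subject_id", "capture_idx", "path", "is_enrollment"}
    missing = required - set(df.columns)
    if missing:
        raise EvaluationError(f"manifest missing columns: {sorted(missing)}")
    return df


def _extract_all(df: pd.DataFrame, config: PipelineConfig) -> dict:
    out = {}
    for row in df.itertuples():
        try:
            img = np.asarray(Image.open(row.path).convert("L"))
            res = extract_capture(img, config)
            out[(row.subject_id, row.capture_idx)] = res
        except Exception as exc:  # noqa: BLE001 - keep evaluating the rest
            log.warning("capture %s/%s failed: %s",
                        row.subject_id, row.capture_idx, exc)
    return out


def score_dataset(manifest, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Score every non-enrollment capture against every subject template.

    Returns the comparison table with raw and min-max-normalized scores
    per metric plus the fused score and the genuine flag.
    """
    config = config or PipelineConfig()
    df = _load_manifest(manifest).sort_values(
        ["subject_id", "capture_idx"], kind="mergesort")
    extracted = _extract_all(df, config)

    templates = {}
    for sid, grp in df[df["is_enrollment"].astype(bool)].groupby("subject_id"):
        keys = [(sid, ci) for ci in grp["capture_idx"]]
        avail = [extracted[k] for k in keys if k in extracted]
        if len(avail) < 2:
            log.warning("subject %s: fewer than 2 usable enrollment captures; "
                        "skipped", sid)
            continue
        templates[sid] = matching.build_template(
            [r.features for r in avail], [r.minutiae for r in avail],
            subject_id=str(sid), sigma_floor=config.sigma_floor)
    if not templates:
        raise EvaluationError("no subject could be enrolled")

    probes = df[~df["is_enrollment"].astype(bool)]
    rows = []
    for row in probes.itertuples():
        key = (row.subject_id, row.capture_idx)
        if key not in extracted:
            continue
        res = extracted[key]
        for sid, tmpl in templates.items():
            rows.append({
                "probe_id": row.subject_id,
                "probe_capture": row.capture_idx,
                "gallery_id": sid,
                "genuine": row.subject_id == sid,
                "geometry_euclidean": matching.euclidean_distance(
                    res.features, tmpl.feature_means),
                "geometry_hamming": matching.hamming_distance(
                    res.features, tmpl),
                "vein_hv": matching.minutiae_score(
                    res.minutiae, tmpl.reference_minutiae, "hv",
                    align=config.align_minutiae, kind_match=config.kind_match),
                "vein_mhv": matching.minutiae_score(
                    res.minutiae, tmpl.reference_minutiae, "mhv",
                    align=config.align_minutiae, kind_match=config.kind_match),
            })
    scores = pd.DataFrame(rows)
    if scores.empty or scores["genuine"].all() or not scores["genuine"].any():
        raise EvaluationError("comparison table lacks a genuine or impostor class")
    for metric in ALL_METRICS:
        scores[metric + "_norm"] = matching.min_max_normalize(scores[metric])
    scores["fused"] = (scores[FUSED_METRICS[0] + "_norm"]
                       + scores[FUSED_METRICS[1] + "_norm"]) / 2.0
    return scores


def evaluate_dataset(manifest, config: PipelineConfig | None = None):
    """Error curves for each single-modality metric and the fused score.

    Returns ``(curves, scores)`` where ``curves`` maps
    geometry_euclidean / geometry_hamming / vein_hv / vein_mhv / fused to
    :class:`ErrorCurves`.
    """
    config = config or PipelineConfig()
    scores = score_dataset(manifest, config)
    genuine = scores["genuine"].to_numpy()
    curves = {}
    for metric in ALL_METRICS:
        curves[metric] = sweep_errors(scores[metric + "_norm"], genuine,
                                      grid_step=config.grid_step)
    curves["fused"] = sweep_errors(scores["fused"], genuine,
                                   grid_step=config.grid_step)
    return curves, scores


def write_results(curves: dict, scores: pd.DataFrame, out_dir,
                  plot: bool = False) -> dict:
    """Write DET data CSV, the comparison table and a summary JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    det = pd.DataFrame({"threshold": next(iter(curves.values())).thresholds})
    for name, c in curves.items():
        det[f"fmr_{name}"] = c.fmr
        det[f"fnmr_{name}"] = c.fnmr
    det.to_csv(out / "det_curves.csv", index=False, float_format="%.6f")
    scores.to_csv(out / "scores.csv", index=False, float_format="%.6f")
    summary = {name: {"eer": c.eer, "eer_threshold": c.eer_threshold}
               for name, c in curves.items()}
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    if plot:  # pragma: no cover - optional dependency
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 4))
        for name, c in curves.items():
            ax.plot(c.thresholds, c.fmr, label=f"FMR {name}", alpha=0.7)
            ax.plot(c.thresholds, c.fnmr, "--", label=f"FNMR {name}", alpha=0.7)
        ax.set_xlabel("accept threshold")
        ax.set_ylabel("error rate")
        ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(out / "error_curves.png", dpi=120)
        plt.close(fig)
    return summary
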