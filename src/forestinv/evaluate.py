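"""Scoring pipeline output against synthetic-stand ground truth.

Detected trees are matched to true trees by nearest xy within 0.5 m; the
metrics mirror how stem-map validation campaigns score tree extraction:
detection rate, height RMSE over detected trees, and mean absolute DBH
error over all true trees (missed trees count as having no estimate and
are excluded from the DBH mean, but reduce the detection rate).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .pipeline import PipelineResult
from .synthetic import GroundTruth

MATCH_TOLERANCE = 0.5  # m


def evaluate_against_truth(result: PipelineResult, truth: GroundTruth) -> dict:
    """Score a pipeline run against the generator's per-tree truth."""
    tt = truth.trees
    txy = tt[["x", "y"]].to_numpy()
    th = tt["height_m"].to_numpy()
    td = tt["dbh_cm"].to_numpy()

    tl = result.tree_list.frame
    if len(tl) == 0:
        return {
            "n_true": len(tt),
            "n_detected": 0,
            "detection_rate": 0.0,
            "height_rmse_m": float("nan"),
            "mean_abs_dbh_error_cm": float("nan"),
            "stem_false_positive_rate": 0.0,
            "n_dbh_extracted": 0,
        }
    ltree = cKDTree(tl[["x", "y"]].to_numpy())
    dist, idx = ltree.query(txy)
    found = dist < MATCH_TOLERANCE

    h_est = tl["height_m"].to_numpy()[idx[found]]
    d_est = tl["dbh_cm"].to_numpy()[idx[found]]
    height_rmse = float(np.sqrt(np.mean((h_est - th[found]) ** 2))) if found.any() else float("nan")
    dbh_mae = float(np.mean(np.abs(d_est - td[found]))) if found.any() else float("nan")

    if result.stems:
        sxy = np.array([[s.x, s.y] for s in result.stems])
        sd, _ = cKDTree(txy).query(sxy)
        fp_rate = float((sd >= MATCH_TOLERANCE).mean())
    else:
        fp_rate = 0.0

    return {
        "n_true": int(len(tt)),
        "n_detected": int(found.sum()),
        "detection_rate": float(found.mean()),
        "height_rmse_m": height_rmse,
        "mean_abs_dbh_error_cm": dbh_mae,
        "stem_false_positive_rate": fp_rate,
        "n_dbh_extracted": int((tl["dbh_source"] == "extracted").sum()),
    }
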