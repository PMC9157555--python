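"""Spatially match extracted DBHs to detected tree tops, filter against the
regional allometry, fit the site model, and fill missing diameters.

A stem circle and a tree top are candidates for pairing when they lie
within 4 m of each other; among candidates, the pairing cost is how far
the extracted DBH sits from the diameter the regional model predicts for
that top's height.  Accepting the globally cheapest pair first makes the
result independent of input ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allometry import PowerModel, fit_power_model, predict_dbh, within_bounds
from .io_formats import TreeList
from .stems import StemRecord
from .treetops import TreeTop

logger = logging.getLogger(__name__)

DEFAULT_MATCH_RADIUS = 4.0  # m

__all__ = [
    "MatchedPair",
    "match_dbh_to_heights",
    "filter_matches",
    "complete_tree_list",
    "pairs_to_frame",
]


@dataclass
class MatchedPair:
    tree_id: int
    stem_id: int
    height: float          # m
    dbh_extracted: float   # cm
    dbh_regional: float    # cm, regional prediction for this height
    distance: float        # m, stem-to-top separation
    cost: float            # cm, |dbh_extracted - dbh_regional|
    passed_filter: bool = False


def match_dbh_to_heights(
    tops: list[TreeTop],
    stems: list[StemRecord],
    regional: PowerModel,
    radius: float = DEFAULT_MATCH_RADIUS,
) -> list[MatchedPair]:
    """Greedy one-to-one matching of stems to tops under the allometric cost.

    All (stem, top) pairs within ``radius`` are ranked by
    |extracted DBH - regional DBH(top height)|; the globally cheapest
    remaining pair is accepted repeatedly, removing both members.  Ties
    break by smaller separation, then lower stem id, then lower tree id.
    Stems with no candidate top are discarded; unmatched tops pass
    through for later DBH modeling.
    """
    if not stems or not tops:
        return []
    tx = np.array([t.x for t in tops])
    ty = np.array([t.y for t in tops])
    th = np.array([t.height for t in tops])
    reg = predict_dbh(regional, th)

    candidates: list[tuple[float, float, int, int, int, int]] = []
    for si, stem in enumerate(stems):
        dist = np.hypot(tx - stem.x, ty - stem.y)
        for ti in np.nonzero(dist <= radius)[0]:
            cost = abs(stem.dbh - reg[ti])
            candidates.append(
                (cost, float(dist[ti]), stem.stem_id, tops[ti].tree_id, si, int(ti))
            )
    candidates.sort(key=lambda c: c[:4])

    used_stems: set[int] = set()
    used_tops: set[int] = set()
    pairs: list[MatchedPair] = []
    for cost, dist, _sid, _tid, si, ti in candidates:
        if si in used_stems or ti in used_tops:
            continue
        used_stems.add(si)
        used_tops.add(ti)
        pairs.append(
            MatchedPair(
                tree_id=tops[ti].tree_id,
                stem_id=stems[si].stem_id,
                height=float(th[ti]),
                dbh_extracted=stems[si].dbh,
                dbh_regional=float(reg[ti]),
                distance=dist,
                cost=cost,
            )
        )
    n_dropped = len(stems) - len(pairs)
    if n_dropped:
        logger.info("match_dbh_to_heights: %d stems had no top within %.1f m or lost out",
                    n_dropped, radius)
    return pairs


def filter_matches(pairs: list[MatchedPair], regional: PowerModel) -> list[MatchedPair]:
    """Flag pairs whose extracted DBH falls inside the regional 90% residual
    band; return only the passing pairs (the input objects are annotated)."""
    passed = []
    for p in pairs:
        p.passed_filter = within_bounds(regional, p.height, p.dbh_extracted)
        if p.passed_filter:
            passed.append(p)
    logger.info("filter_matches: %d / %d pairs inside regional bounds", len(passed), len(pairs))
    return passed


def complete_tree_list(
    tops: list[TreeTop],
    passed: list[MatchedPair],
    regional: PowerModel | None = None,
) -> tuple[TreeList, PowerModel]:
    """Fill every detected top with a DBH: extracted where a filtered match
    exists, otherwise predicted by the site model fit to the passing pairs.

    With fewer than 3 passing pairs the site model cannot be fit; the
    regional model then predicts all missing diameters (a prominent
    warning is logged).  Returns the completed tree list and the model
    used for prediction.
    """
    if len(passed) >= 3:
        model = fit_power_model(
            np.array([p.height for p in passed]),
            np.array([p.dbh_extracted for p in passed]),
        )
    else:
        if regional is None:
            raise ValueError("fewer than 3 passing pairs and no regional fallback model")
        logger.warning(
            "complete_tree_list: only %d passing pairs; falling back to the REGIONAL "
            "height-DBH model for all missing DBHs",
            len(passed),
        )
        model = regional

    by_tree = {p.tree_id: p for p in passed}
    rows = []
    for t in tops:
        p = by_tree.get(t.tree_id)
        if p is not None:
            rows.append((t.tree_id, t.x, t.y, t.height, p.dbh_extracted, "extracted"))
        else:
            rows.append(
                (t.tree_id, t.x, t.y, t.height, float(predict_dbh(model, t.height)), "modeled")
            )
    frame = pd.DataFrame(rows, columns=list(TreeList.COLUMNS))
    return TreeList(frame), model


def pairs_to_frame(pairs: list[MatchedPair]) -> pd.DataFrame:
    """Diagnostics table for matched pairs (written as matched_pairs.csv)."""
    return pd.DataFrame(
        [
            {
                "tree_id": p.tree_id,
                "stem_id": p.stem_id,
                "height_m": p.height,
                "dbh_extracted_cm": p.dbh_extracted,
                "dbh_regional_cm": p.dbh_regional,
                "distance_m": p.distance,
                "cost_cm": p.cost,
                "passed_filter": p.passed_filter,
            }
            for p in pairs
        ],
        columns=[
            "tree_id",
            "stem_id",
            "height_m",
            "dbh_extracted_cm",
            "dbh_regional_cm",
            "distance_m",
            "cost_cm",
            "passed_filter",
        ],
    )
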