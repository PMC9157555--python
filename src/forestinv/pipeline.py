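"""End-to-end workflow: tree metric extraction, spatial matching, regional
filtering, and site-model prediction of missing DBHs."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .allometry import PowerModel, RegionalInventory, filter_regional_plots, fit_power_model
from .chm import DEFAULT_CELL_SIZE, HeightRaster, rasterize_chm, write_chm_geotiff
from .io_formats import PointCloud, TreeList, write_point_cloud, write_tree_list
from .matching import (
    DEFAULT_MATCH_RADIUS,
    MatchedPair,
    complete_tree_list,
    filter_matches,
    match_dbh_to_heights,
    pairs_to_frame,
)
from .stems import (
    StemParams,
    StemRecord,
    assign_tree_points,
    classify_stem_points,
    fit_dbh,
    map_stems_hough,
    slice_cloud,
)
from .terrain import GroundParams, NormalizeParams, classify_ground, normalize_heights
from .treetops import DetectParams, TreeTop, detect_treetops

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters plus the site descriptors and the RNG seed."""

    ground: GroundParams = field(default_factory=GroundParams)
    normalize: NormalizeParams = field(default_factory=NormalizeParams)
    chm_cell_size: float = DEFAULT_CELL_SIZE
    detect: DetectParams = field(default_factory=DetectParams)
    stems: StemParams = field(default_factory=StemParams)
    match_radius: float = DEFAULT_MATCH_RADIUS
    site_index: float = 20.0
    dominant_species: str = "PIPO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        if "ground" in raw:
            cfg.ground = GroundParams(**raw["ground"])
        if "normalize" in raw:
            cfg.normalize = NormalizeParams(**raw["normalize"])
        if "detect" in raw:
            cfg.detect = DetectParams(**raw["detect"])
        if "stems" in raw:
            cfg.stems = StemParams(**raw["stems"])
        for key in ("chm_cell_size", "match_radius", "site_index", "dominant_species", "seed"):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    tree_list: TreeList
    chm: HeightRaster
    tops: list[TreeTop]
    stems: list[StemRecord]
    pairs: list[MatchedPair]
    regional_model: PowerModel
    site_model: PowerModel
    normalized_cloud: PointCloud


def run_pipeline(
    cloud: PointCloud,
    inventory: RegionalInventory,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full workflow on a raw point cloud and a regional inventory.

    Stages: ground classification -> height normalization -> CHM ->
    treetop detection, in parallel with stem-zone slicing -> Hough stem
    mapping -> tree-ID attribution -> stem-point classification -> RANSAC
    DBH fitting; then regional plot filtering -> regional power model ->
    greedy matching -> percentile filtering -> site model -> completed
    tree list.  If ``outdir`` is given, the CHM GeoTIFF, stem CSV,
    matched-pairs CSV, tree-list CSV, stem-point LAS and a run log of all
    effective parameters are written there.
    """
    config = config or PipelineConfig()

    classified = classify_ground(cloud, config.ground)
    normalized = normalize_heights(classified, config.normalize)
    logger.info("pipeline: normalized %d points", len(normalized))

    chm = rasterize_chm(normalized, config.chm_cell_size)
    tops = detect_treetops(chm, config.detect)
    logger.info("pipeline: detected %d tree tops", len(tops))

    slab = slice_cloud(normalized, config.stems.slice_zmin, config.stems.slice_zmax)
    centers = map_stems_hough(slab, config.stems)
    logger.info("pipeline: mapped %d candidate stems", len(centers))
    labeled = assign_tree_points(slab, centers)
    stem_cloud = classify_stem_points(labeled, config.stems)
    stems = fit_dbh(stem_cloud, config.stems, seed=config.seed)
    logger.info("pipeline: fitted DBH for %d stems", len(stems))

    regional_trees = filter_regional_plots(inventory, config.site_index, config.dominant_species)
    regional = fit_power_model(
        regional_trees.trees["height_m"].to_numpy(),
        regional_trees.trees["dbh_cm"].to_numpy(),
    )
    pairs = match_dbh_to_heights(tops, stems, regional, config.match_radius)
    passed = filter_matches(pairs, regional)
    logger.info("pipeline: %d matches, %d passed the regional filter", len(pairs), len(passed))
    tree_list, site_model = complete_tree_list(tops, passed, regional)

    result = PipelineResult(
        tree_list, chm, tops, stems, pairs, regional, site_model, normalized
    )
    if outdir is not None:
        _write_artifacts(result, config, Path(outdir))
    return result


def _write_artifacts(result: PipelineResult, config: PipelineConfig, outdir: Path) -> None:
    import pandas as pd

    outdir.mkdir(parents=True, exist_ok=True)
    write_chm_geotiff(result.chm, outdir / "chm.tif")
    pd.DataFrame(
        [
            {
                "stem_id": s.stem_id,
                "x": s.x,
                "y": s.y,
                "dbh_cm": s.dbh,
                "n_inliers": s.n_inliers,
                "rmse_cm": s.rmse,
            }
            for s in result.stems
        ],
        columns=["stem_id", "x", "y", "dbh_cm", "n_inliers", "rmse_cm"],
    ).to_csv(outdir / "stems.csv", index=False, float_format="%.4f")
    pairs_to_frame(result.pairs).to_csv(
        outdir / "matched_pairs.csv", index=False, float_format="%.4f"
    )
    write_tree_list(result.tree_list, outdir / "tree_list.csv")
    write_point_cloud(result.normalized_cloud, outdir / "normalized.las")
    result.site_model.to_json(outdir / "site_model.json")
    result.regional_model.to_json(outdir / "regional_model.json")
    (outdir / "run_log.yaml").write_text(
        yaml.safe_dump(
            {
                "parameters": config.to_dict(),
                "counts": {
                    "tops_detected": len(result.tops),
                    "stems_fitted": len(result.stems),
                    "pairs_matched": len(result.pairs),
                    "pairs_passed_filter": int(
                        sum(p.passed_filter for p in result.pairs)
                    ),
                    "trees_in_list": len(result.tree_list),
                },
            },
            sort_keys=False,
        )
    )
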