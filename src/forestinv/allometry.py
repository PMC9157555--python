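"""Height-diameter allometry: regional plot filtering, power-model fits,
prediction, and residual percentile bounds.

The central object is the power model DBH = a * H^b (DBH in cm, H in m),
the standard height-diameter form for even-aged conifers.  Residual
bounds are the 5th/95th percentiles of the additive residuals, so the
band brackets the central 90% of the training data and serves as the
outlier filter for point-cloud-extracted diameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import EmptySelectionError, InsufficientInputError

logger = logging.getLogger(__name__)

__all__ = [
    "RegionalInventory",
    "PowerModel",
    "filter_regional_plots",
    "fit_power_model",
    "predict_dbh",
    "within_bounds",
]


@dataclass
class RegionalInventory:
    """Regional plot network extract: plot metadata plus height/DBH pairs.

    ``plots``: columns plot_id, site_index_m, species, ba_share (per-plot
    basal-area share per species; shares of a plot sum to 1).
    ``trees``: columns plot_id, species, height_m, dbh_cm.
    """

    plots: pd.DataFrame
    trees: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("plot_id", "site_index_m", "species", "ba_share"):
            if col not in self.plots.columns:
                raise ValueError(f"plots table missing column {col}")
        for col in ("plot_id", "species", "height_m", "dbh_cm"):
            if col not in self.trees.columns:
                raise ValueError(f"trees table missing column {col}")
        if len(self.plots):
            sums = self.plots.groupby("plot_id")["ba_share"].sum()
            if not np.allclose(sums, 1.0, atol=0.01):
                raise ValueError("basal-area shares must sum to 1 per plot")
        if len(self.trees):
            if not ((self.trees["height_m"] > 0) & (self.trees["dbh_cm"] > 0)).all():
                raise ValueError("heights and DBHs must be positive")

    @classmethod
    def from_csv(cls, plots_path: str | Path, trees_path: str | Path) -> "RegionalInventory":
        return cls(pd.read_csv(plots_path), pd.read_csv(trees_path))

    def to_csv(self, plots_path: str | Path, trees_path: str | Path) -> None:
        self.plots.to_csv(plots_path, index=False)
        self.trees.to_csv(trees_path, index=False)


@dataclass
class PowerModel:
    """DBH = a * height^b with residual percentile bounds (cm offsets)."""

    a: float
    b: float
    residual_lo: float = 0.0
    residual_hi: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("coefficient a must be > 0")
        if not self.residual_lo <= 0 <= self.residual_hi:
            raise ValueError("residual bounds must bracket 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "a": self.a,
                    "b": self.b,
                    "residual_lo": self.residual_lo,
                    "residual_hi": self.residual_hi,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PowerModel":
        return cls(**json.loads(Path(path).read_text()))


def filter_regional_plots(
    inv: RegionalInventory, site_index: float, dominant_species: str
) -> RegionalInventory:
    """Keep plots comparable to the study site.

    A plot survives when its site index is within +/-2 m of the site's
    and strictly more than 70% of its basal area belongs to the site's
    dominant species.  Returns the surviving plots and their tree rows.
    """
    if len(inv.plots) == 0:
        raise EmptySelectionError("regional inventory has no plots")
    si = inv.plots.groupby("plot_id")["site_index_m"].first()
    share = (
        inv.plots[inv.plots["species"] == dominant_species]
        .groupby("plot_id")["ba_share"]
        .sum()
        .reindex(si.index, fill_value=0.0)
    )
    keep = si.index[(np.abs(si - site_index) <= 2.0) & (share > 0.70)]
    if len(keep) == 0:
        raise EmptySelectionError(
            "no regional plots within +/-2 m site index and >70% dominant-species basal area"
        )
    plots = inv.plots[inv.plots["plot_id"].isin(keep)].reset_index(drop=True)
    trees = inv.trees[inv.trees["plot_id"].isin(keep)].reset_index(drop=True)
    logger.info("filter_regional_plots: kept %d of %d plots", len(keep), si.size)
    return RegionalInventory(plots, trees)


def _power(h: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * np.power(h, b)


def fit_power_model(heights: np.ndarray, dbhs: np.ndarray) -> PowerModel:
    """Fit DBH = a * H^b by nonlinear least squares.

    The fit is initialized from the log-log linear regression; if the
    nonlinear step fails to converge the log-log closed form is used with
    a warning.  Residual bounds are the 5th/95th percentiles of
    (observed - fitted), so ~90% of the training data lies inside them.
    """
    h = np.asarray(heights, float)
    d = np.asarray(dbhs, float)
    if h.size < 3:
        raise InsufficientInputError("need at least 3 height/DBH pairs")
    if not ((h > 0).all() and (d > 0).all()):
        raise ValueError("heights and DBHs must be positive")

    slope, intercept = np.polyfit(np.log(h), np.log(d), 1)
    a0, b0 = float(np.exp(intercept)), float(slope)
    try:
        (a, b), _ = curve_fit(_power, h, d, p0=(a0, b0), maxfev=10000)
        if a <= 0 or not np.isfinite([a, b]).all():
            raise RuntimeError("degenerate nonlinear fit")
    except RuntimeError:
        logger.warning("power fit did not converge; falling back to log-log fit")
        a, b = a0, b0

    resid = d - _power(h, a, b)
    lo, hi = np.percentile(resid, [5.0, 95.0])
    return PowerModel(float(a), float(b), min(float(lo), 0.0), max(float(hi), 0.0))


def predict_dbh(model: PowerModel, height: float | np.ndarray) -> float | np.ndarray:
    """Predicted DBH (cm) for a height (m) under the power model."""
    h = np.asarray(height, float)
    if np.any(h <= 0):
        raise ValueError("height must be > 0")
    out = model.a * np.power(h, model.b)
    return float(out) if np.isscalar(height) else out


def within_bounds(model: PowerModel, height: float, dbh: float) -> bool:
    """True when the residual sits inside the central-90% band (inclusive)."""
    resid = dbh - predict_dbh(model, float(height))
    return bool(model.residual_lo <= resid <= model.residual_hi)
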