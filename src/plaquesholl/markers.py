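"""Reporter-intensity statistics: intensity vs distance-to-plaque, and
percent-positive (stained) area of an intensity grid.

The intensity–distance analysis asks whether a per-cell reporter signal
(e.g. an EGFP reporter of a mitogenic receptor) is graded with distance
from amyloid plaques: each cell is paired with its distance to the nearest
plaque centre (or boundary), and both Pearson's r and Spearman's ρ are
reported — negative coefficients mean the signal falls with distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MarkerStatsError",
    "InsufficientDataError",
    "CorrelationReport",
    "intensity_distance_correlation",
    "distance_to_nearest_plaque",
    "percent_positive_area",
]


class MarkerStatsError(ValueError):
    pass


class InsufficientDataError(MarkerStatsError):
    pass


@dataclass(frozen=True)
class CorrelationReport:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int
    undefined: bool = False  # set when either variable has zero variance

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "n": self.n,
            "undefined": self.undefined,
        }


def distance_to_nearest_plaque(
    cells: pd.DataFrame, plaques: pd.DataFrame, to: str = "centre"
) -> np.ndarray:
    """Per-cell distance (µm) to the nearest plaque centre or boundary.

    ``to="boundary"`` subtracts the plaque radius and clips at 0 (a cell
    inside a plaque is at distance 0 from its boundary).
    """
    if to not in ("centre", "boundary"):
        raise MarkerStatsError(f"distance reference must be 'centre' or 'boundary', got {to!r}")
    if len(plaques) == 0:
        raise MarkerStatsError("at least one plaque is required")
    cx = cells["x_um"].to_numpy(float)[:, None]
    cy = cells["y_um"].to_numpy(float)[:, None]
    px = plaques["x_um"].to_numpy(float)[None, :]
    py = plaques["y_um"].to_numpy(float)[None, :]
    d = np.hypot(cx - px, cy - py)
    if to == "boundary":
        d = np.clip(d - plaques["radius_um"].to_numpy(float)[None, :], 0.0, None)
    return d.min(axis=1)


def intensity_distance_correlation(
    cells: pd.DataFrame, plaques: pd.DataFrame, distance_to: str = "centre"
) -> CorrelationReport:
    """Correlate per-cell reporter intensity with distance to the nearest plaque.

    Rows with missing intensity are dropped; at least 3 complete pairs are
    required. If either variable is constant the correlation is undefined
    and the report carries NaN coefficients with ``undefined=True``.
    """
    if "intensity" not in cells.columns:
        raise MarkerStatsError("cell table has no 'intensity' column")
    keep = cells[cells["intensity"].notna()]
    if len(keep) < 3:
        raise InsufficientDataError(
            f"need at least 3 cells with intensity, got {len(keep)}"
        )
    dist = distance_to_nearest_plaque(keep, plaques, to=distance_to)
    inten = keep["intensity"].to_numpy(float)
    n = len(keep)
    if np.ptp(dist) == 0 or np.ptp(inten) == 0:
        return CorrelationReport(np.nan, np.nan, np.nan, np.nan, n, undefined=True)
    pr = stats.pearsonr(dist, inten)
    sr = stats.spearmanr(dist, inten)
    return CorrelationReport(
        float(pr.statistic), float(pr.pvalue), float(sr.statistic), float(sr.pvalue), n
    )


def percent_positive_area(field: np.ndarray, threshold: float) -> float:
    """Percent of pixels at or above a threshold — the 'per cent stained area'.

    ``field`` is any 2-D (or flattenable) non-negative intensity grid; the
    threshold is in the same arbitrary units. Monotone non-increasing in the
    threshold.
    """
    if threshold < 0:
        raise MarkerStatsError("threshold must be >= 0")
    arr = np.asarray(field, dtype=float)
    if arr.size == 0:
        raise MarkerStatsError("empty intensity grid")
    return 100.0 * float(np.count_nonzero(arr >= threshold)) / arr.size
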