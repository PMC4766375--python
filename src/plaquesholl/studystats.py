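"""Expression, immunoassay and behaviour scoring rules used across the study.

* qPCR relative expression by the 2^-ΔΔCt method, normalised to the
  geometric mean of a housekeeping panel, with a quality screen that drops
  samples whose housekeeping Cts spread by more than a threshold (5 cycles
  by default).
* Antibody-array fold changes with limit-of-detection (LOD) censoring: an
  analyte detected in no more than half of all samples is reported N/D;
  otherwise censored values are substituted (LOD/2 by convention) and the
  fold change carries the ±fold sign convention (+fold = upregulated,
  −fold = downregulated, |fold| ≥ 1).
* Kendall's tau-b (tie-corrected) for correlating expression against an
  ordinal severity score such as Braak stage.
* T-maze spontaneous-alternation scoring: the mean of the 0/1 alternation
  scores over scored trials, with failed (no-move) trials excluded from
  both numerator and denominator.

Tables are tidy pandas DataFrames; schemas are documented per function and
in :mod:`plaquesholl.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StudyStatsError",
    "quality_screen_ct",
    "relative_expression",
    "lod_fold_change",
    "kendall_tau_b",
    "alternation_ratio",
    "AlternationScore",
    "TRIAL_OUTCOMES",
]

TRIAL_OUTCOMES = ("alternated", "repeated", "failed")


class StudyStatsError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise StudyStatsError(f"{what} table missing columns: {missing}")


def quality_screen_ct(
    ct: pd.DataFrame,
    housekeeping_genes: Sequence[str],
    max_spread: float = 5.0,
) -> tuple[list, pd.DataFrame]:
    """Screen samples on the spread of their housekeeping Cts.

    A sample is excluded when max − min of its housekeeping Ct values
    exceeds ``max_spread`` cycles (low RNA yield/quality), or when any
    housekeeping gene is unmeasured. Returns (retained sample ids,
    exclusion table with columns sample_id, reason, spread).

    ``ct`` is tidy: one row per (sample_id, gene) with columns
    ``sample_id, group, gene, ct``.
    """
    _require_columns(ct, ("sample_id", "gene", "ct"), "Ct")
    retained: list = []
    exclusions: list[dict] = []
    for sample_id, sub in ct.groupby("sample_id", sort=False):
        hk = sub[sub["gene"].isin(housekeeping_genes)]
        measured = hk.dropna(subset=["ct"])
        if set(measured["gene"]) != set(housekeeping_genes):
            exclusions.append(
                {"sample_id": sample_id, "reason": "missing-data", "spread": np.nan}
            )
            continue
        spread = float(measured["ct"].max() - measured["ct"].min())
        if spread > max_spread:
            exclusions.append(
                {"sample_id": sample_id, "reason": "housekeeping-spread", "spread": spread}
            )
        else:
            retained.append(sample_id)
    return retained, pd.DataFrame(exclusions, columns=["sample_id", "reason", "spread"])


def relative_expression(
    ct: pd.DataFrame,
    target_gene: str,
    housekeeping_genes: Sequence[str],
    control_group: str,
) -> pd.DataFrame:
    """Per-sample fold change of a target gene by the 2^-ΔΔCt method.

    The normalization factor is the geometric mean of the housekeeping Cts
    of each sample (a single housekeeping gene degenerates to that gene's
    Ct). ΔCt = Ct_target − NF; ΔΔCt = ΔCt − mean ΔCt of the control group;
    fold = 2^-ΔΔCt. By construction the geometric mean of the control
    group's fold changes is exactly 1.

    Returns one row per sample: sample_id, group, delta_ct, delta_delta_ct,
    fold_change.
    """
    _require_columns(ct, ("sample_id", "group", "gene", "ct"), "Ct")
    if not housekeeping_genes:
        raise StudyStatsError("at least one housekeeping gene is required")

    rows = []
    for sample_id, sub in ct.groupby("sample_id", sort=False):
        hk = sub[sub["gene"].isin(housekeeping_genes)].dropna(subset=["ct"])
        tgt = sub[sub["gene"] == target_gene].dropna(subset=["ct"])
        if set(hk["gene"]) != set(housekeeping_genes) or len(tgt) == 0:
            continue  # incomplete sample; screen with quality_screen_ct first
        nf = float(stats.gmean(hk["ct"].to_numpy(float)))
        rows.append(
            {
                "sample_id": sample_id,
                "group": sub["group"].iloc[0],
                "delta_ct": float(tgt["ct"].mean()) - nf,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty or not (out["group"] == control_group).any():
        raise StudyStatsError(f"control group {control_group!r} is empty")
    calibrator = out.loc[out["group"] == control_group, "delta_ct"].mean()
    out["delta_delta_ct"] = out["delta_ct"] - calibrator
    out["fold_change"] = 2.0 ** (-out["delta_delta_ct"])
    return out


def lod_fold_change(
    panel: pd.DataFrame,
    numerator_group: str,
    denominator_group: str,
    nd_fraction: float = 0.5,
    lod_substitute_factor: float = 0.5,
) -> pd.DataFrame:
    """Per-analyte signed fold change between two groups with LOD censoring.

    An analyte is reported N/D (not detectable) when more than
    ``nd_fraction`` of all its samples (pooled across groups) fall below
    the limit of detection. Otherwise censored values are substituted with
    ``lod_substitute_factor × LOD`` and fold = mean(numerator) /
    mean(denominator), reported on the signed-fold convention: ratios ≥ 1
    as +ratio, ratios < 1 as −1/ratio (so +fold = upregulation, −fold =
    downregulation, |fold| ≥ 1).

    ``panel`` is tidy with columns ``sample_id, group, analyte,
    concentration_pg_ml, below_lod, lod_pg_ml``. Returns one row per
    analyte: analyte, fold_change (NaN when N/D or undefined), n_d,
    undefined, n_below_lod, n_samples.
    """
    _require_columns(
        panel,
        ("sample_id", "group", "analyte", "concentration_pg_ml", "below_lod", "lod_pg_ml"),
        "analyte panel",
    )
    rows = []
    for analyte, sub in panel.groupby("analyte", sort=False):
        below = sub["below_lod"].astype(bool)
        n_below, n_all = int(below.sum()), len(sub)
        if n_below > nd_fraction * n_all:
            rows.append(
                {
                    "analyte": analyte,
                    "fold_change": np.nan,
                    "n_d": True,
                    "undefined": False,
                    "n_below_lod": n_below,
                    "n_samples": n_all,
                }
            )
            continue
        conc = sub["concentration_pg_ml"].to_numpy(float).copy()
        conc[below.to_numpy()] = (
            lod_substitute_factor * sub["lod_pg_ml"].to_numpy(float)[below.to_numpy()]
        )
        groups = sub["group"].to_numpy()
        num = conc[groups == numerator_group]
        den = conc[groups == denominator_group]
        if len(num) == 0 or len(den) == 0:
            raise StudyStatsError(f"empty group for analyte {analyte!r}")
        den_mean = den.mean()
        if den_mean == 0:
            rows.append(
                {
                    "analyte": analyte,
                    "fold_change": np.nan,
                    "n_d": False,
                    "undefined": True,
                    "n_below_lod": n_below,
                    "n_samples": n_all,
                }
            )
            continue
        ratio = num.mean() / den_mean
        fold = ratio if ratio >= 1.0 else -1.0 / ratio
        rows.append(
            {
                "analyte": analyte,
                "fold_change": float(fold),
                "n_d": False,
                "undefined": False,
                "n_below_lod": n_below,
                "n_samples": n_all,
            }
        )
    return pd.DataFrame(rows)


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall's tau-b rank correlation with tie correction in both variables.

    Suited to ordinal scores (e.g. Braak stage) against continuous values.
    Returns NaN when either variable is entirely tied (undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StudyStatsError("x and y must be 1-D and the same length")
    if len(x) < 3:
        raise StudyStatsError(f"need at least 3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    res = stats.kendalltau(x, y, variant="b")
    return float(res.statistic)


class AlternationScore(NamedTuple):
    ratio: float  # NaN when every trial failed
    n_scored: int
    n_failed: int
    failed_fraction: float


def alternation_ratio(outcomes: Sequence[str]) -> AlternationScore:
    """Spontaneous-alternation ratio over a T-maze trial sequence.

    Each outcome is ``"alternated"`` (score 1), ``"repeated"`` (score 0) or
    ``"failed"`` (no arm choice within the time limit — excluded from both
    numerator and denominator). The ratio is the mean score over scored
    trials; the failed-trial fraction is reported alongside. With every
    trial failed the ratio is undefined (NaN).
    """
    outcomes = list(outcomes)
    if not outcomes:
        raise StudyStatsError("empty trial sequence")
    bad = sorted({o for o in outcomes if o not in TRIAL_OUTCOMES})
    if bad:
        raise StudyStatsError(f"unknown trial outcomes: {bad}")
    n_failed = sum(o == "failed" for o in outcomes)
    scored = [1.0 if o == "alternated" else 0.0 for o in outcomes if o != "failed"]
    ratio = float(np.mean(scored)) if scored else math.nan
    return AlternationScore(
        ratio=ratio,
        n_scored=len(scored),
        n_failed=n_failed,
        failed_fraction=n_failed / len(outcomes),
    )
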