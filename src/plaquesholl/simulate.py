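"""Seeded synthetic-histology generator.

Generates 2-D tissue fields with the statistical structure the analyses in
this package assume, so every stage is testable without real tissue:

* plaques as a hard-core Poisson point process (candidate centres are
  thinned to enforce a minimum separation) at an intensity matching the
  plaque densities reported for 9-month APP/PS1 cortex (≈4.4 plaques/mm²),
  with normally distributed radii;
* microglia as an inhomogeneous Poisson process whose rate is elevated near
  plaques and relaxes exponentially to a background (wild-type) level:
  λ(p) = background · (1 + A·exp(−d_b(p)/τ)), with d_b the distance to the
  nearest plaque boundary (0 inside a plaque);
* a proliferation label assigned per cell with probability interpolating
  from ``pi_near`` at the plaque edge to ``pi_far`` in the far field on the
  same exponential scale;
* a per-cell reporter intensity decaying with distance to the nearest
  plaque *centre*: I = I₀·exp(−d_c/τ_I) + N(0, σ), clipped at 0.

The two distance conventions (boundary for density/labelling, centre for
intensity) mirror the two distances the analyses themselves use. Identical
configs produce byte-identical tables; one seeded generator per call, no
global state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "simulate_field", "simulate_ct_table", "CtSimulationConfig"]


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters for one synthetic field.

    Defaults emulate 9-month APP/PS1-like cortex: ~4.4 plaques/mm², a
    background microglial density of 300 cells/mm², and a 3-fold edge
    enrichment decaying over 40 µm — putting the first Sholl annulus at
    roughly 2–4× background.
    """

    seed: int = 0
    width_um: float = 1000.0
    height_um: float = 1000.0
    plaque_intensity_per_mm2: float = 4.41
    plaque_radius_mean_um: float = 15.0
    plaque_radius_sd_um: float = 4.0
    min_plaque_separation_um: float = 100.0
    background_density_per_mm2: float = 300.0
    enrichment_amplitude: float = 3.0
    decay_length_um: float = 40.0
    cell_radius_um: float = 5.0
    pi_near: float = 0.05
    pi_far: float = 0.01
    intensity_i0: float = 100.0
    intensity_decay_um: float = 50.0
    intensity_noise_sd: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "width_um",
            "height_um",
            "plaque_radius_mean_um",
            "decay_length_um",
            "cell_radius_um",
            "intensity_decay_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "plaque_intensity_per_mm2",
            "plaque_radius_sd_um",
            "min_plaque_separation_um",
            "background_density_per_mm2",
            "enrichment_amplitude",
            "intensity_i0",
            "intensity_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("pi_near", "pi_far"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def area_mm2(self) -> float:
        return self.width_um * self.height_um / 1e6


def _boundary_distance(x, y, plaques: pd.DataFrame) -> np.ndarray:
    """Distance to the nearest plaque boundary, 0 inside a plaque."""
    if len(plaques) == 0:
        return np.full(np.shape(x), np.inf)
    d = np.hypot(
        np.asarray(x)[:, None] - plaques["x_um"].to_numpy()[None, :],
        np.asarray(y)[:, None] - plaques["y_um"].to_numpy()[None, :],
    )
    return np.clip(d - plaques["radius_um"].to_numpy()[None, :], 0.0, None).min(axis=1)


def _centre_distance(x, y, plaques: pd.DataFrame) -> np.ndarray:
    if len(plaques) == 0:
        return np.full(np.shape(x), np.inf)
    d = np.hypot(
        np.asarray(x)[:, None] - plaques["x_um"].to_numpy()[None, :],
        np.asarray(y)[:, None] - plaques["y_um"].to_numpy()[None, :],
    )
    return d.min(axis=1)


def _place_plaques(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    diagonal = math.hypot(cfg.width_um, cfg.height_um)
    if cfg.plaque_intensity_per_mm2 > 0 and cfg.min_plaque_separation_um > diagonal:
        warnings.warn(
            "field too small to place any plaque at the requested separation; "
            "returning a plaque-free field",
            stacklevel=3,
        )
        return pd.DataFrame(columns=["id", "x_um", "y_um", "radius_um"])
    n_candidates = rng.poisson(cfg.plaque_intensity_per_mm2 * cfg.area_mm2)
    xs, ys = [], []
    for _ in range(n_candidates):
        x = rng.uniform(0.0, cfg.width_um)
        y = rng.uniform(0.0, cfg.height_um)
        ok = all(
            math.hypot(x - px, y - py) >= cfg.min_plaque_separation_um
            for px, py in zip(xs, ys)
        )
        if ok:
            xs.append(x)
            ys.append(y)
    radii = np.maximum(
        rng.normal(cfg.plaque_radius_mean_um, cfg.plaque_radius_sd_um, size=len(xs)),
        2.0,
    )
    return pd.DataFrame(
        {
            "id": [f"plaque_{i}" for i in range(len(xs))],
            "x_um": xs,
            "y_um": ys,
            "radius_um": radii,
        }
    )


def simulate_field(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one field; returns (plaque table, cell table).

    Tables conform to the CSV schemas the profiler reads (see
    :mod:`plaquesholl.io`). Microglia are drawn by thinning a homogeneous
    Poisson process at the rate maximum, which samples the inhomogeneous
    process exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    plaques = _place_plaques(cfg, rng)

    lam_max = cfg.background_density_per_mm2 * (1.0 + cfg.enrichment_amplitude)
    n_cand = rng.poisson(lam_max * cfg.area_mm2)
    x = rng.uniform(0.0, cfg.width_um, size=n_cand)
    y = rng.uniform(0.0, cfg.height_um, size=n_cand)
    d_b = _boundary_distance(x, y, plaques)
    profile = np.where(np.isinf(d_b), 0.0, np.exp(-np.where(np.isinf(d_b), 0.0, d_b) / cfg.decay_length_um))
    lam = cfg.background_density_per_mm2 * (1.0 + cfg.enrichment_amplitude * profile)
    keep = rng.uniform(0.0, 1.0, size=n_cand) < lam / lam_max
    x, y, profile = x[keep], y[keep], profile[keep]

    p_label = cfg.pi_far + (cfg.pi_near - cfg.pi_far) * profile
    is_proliferating = (rng.uniform(0.0, 1.0, size=len(x)) < p_label).astype(int)

    d_c = _centre_distance(x, y, plaques)
    base = np.where(np.isinf(d_c), 0.0, cfg.intensity_i0 * np.exp(-np.where(np.isinf(d_c), 0.0, d_c) / cfg.intensity_decay_um))
    intensity = np.clip(base + rng.normal(0.0, cfg.intensity_noise_sd, size=len(x)), 0.0, None)

    cells = pd.DataFrame(
        {
            "id": [f"cell_{i}" for i in range(len(x))],
            "x_um": x,
            "y_um": y,
            "radius_um": np.full(len(x), cfg.cell_radius_um),
            "is_microglia": np.ones(len(x), dtype=int),
            "is_proliferating": is_proliferating,
            "intensity": intensity,
        }
    )
    return plaques, cells


@dataclass(frozen=True)
class CtSimulationConfig:
    """Generative parameters for a synthetic qPCR Ct table.

    ``target_fold`` is the true expression fold of the target gene in the
    non-control group; its Ct tracks each sample's housekeeping
    normalization factor so that the fold is recoverable by the 2^-ΔΔCt
    method (exactly so at ``noise_sd_cycles = 0``).
    """

    seed: int = 0
    n_per_group: int = 12
    groups: tuple[str, str] = ("control", "disease")
    housekeeping_genes: tuple[str, ...] = ("GAPDH", "ACTB", "B2M", "GUSB")
    target_gene: str = "CSF1R"
    target_fold: float = 2.0
    hk_mean_ct: float = 20.0
    hk_sd_cycles: float = 0.5
    target_offset_cycles: float = 5.0
    noise_sd_cycles: float = 0.25

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.target_fold <= 0:
            raise ValueError("n_per_group must be >= 1 and target_fold > 0")
        if len(self.groups) != 2 or not self.housekeeping_genes:
            raise ValueError("need two groups and at least one housekeeping gene")


def simulate_ct_table(cfg: CtSimulationConfig) -> pd.DataFrame:
    """Simulate a tidy Ct table (sample_id, group, gene, ct).

    Housekeeping Cts are Normal(hk_mean, hk_sd) per gene and sample. The
    target Ct is the sample's normalization factor plus a fixed offset,
    shifted by −log2(target_fold) in the affected (second) group, plus
    Normal(0, noise_sd) measurement noise.
    """
    from scipy.stats import gmean

    rng = np.random.default_rng(cfg.seed)
    control, affected = cfg.groups
    rows = []
    for group in cfg.groups:
        for i in range(cfg.n_per_group):
            sample_id = f"{group}_{i}"
            hk_cts = rng.normal(cfg.hk_mean_ct, cfg.hk_sd_cycles, size=len(cfg.housekeeping_genes))
            for gene, ct in zip(cfg.housekeeping_genes, hk_cts):
                rows.append({"sample_id": sample_id, "group": group, "gene": gene, "ct": ct})
            nf = float(gmean(hk_cts))
            shift = -math.log2(cfg.target_fold) if group == affected else 0.0
            ct_t = nf + cfg.target_offset_cycles + shift + rng.normal(0.0, cfg.noise_sd_cycles)
            rows.append({"sample_id": sample_id, "group": group, "gene": cfg.target_gene, "ct": ct_t})
    return pd.DataFrame(rows)
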