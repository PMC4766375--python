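# plaquesholl

Plaque-centric quantification of microglia in 2-D histology: an adapted
Sholl analysis that profiles microglial density in concentric annuli around
amyloid-β plaques, proliferation-index and population-turnover arithmetic,
reporter-intensity–distance correlation, and the companion scoring rules
for qPCR expression, LOD-censored immunoassay panels, ordinal-severity
correlation and T-maze behaviour — plus a seeded synthetic-histology
generator so every stage can be exercised and validated without tissue
data.

It is written for quantitative neurobiologists and image analysts who
already have segmented object tables (plaque and cell centroids/radii from
ImageJ or similar) and want reproducible, scriptable downstream statistics.

## The core methods

**Radial profiling.** Around each plaque (a disk of radius r₀), concentric
circles are traced at r₀, r₀+Δ, r₀+2Δ, … with step Δ = 20 µm. Each
microglial soma (a disk, default radius 5 µm) is assigned to the single
annulus containing the majority (>50%) of its area — computed exactly from
the circle–circle lens formula, with 50/50 ties going inward — and density
is count / annulus area (cells/mm²). Profiling stops when the next circle
would contact a neighbouring plaque, when density returns to the wild-type
reference level ρ_ref (within a tolerance: ρ ≤ ρ_ref·(1+t), default
t = 0.1), when the circle would leave the tissue field, or at a safety cap.
Profiles are aggregated per distance-from-plaque bin as mean ± SEM, and an
exponential enrichment model ρ(d) = B·(1 + A·e^(−d/τ)) can be fitted to
recover the decay length τ.

**Turnover.** With a 1-day proliferation-label pulse, the proliferation
index PI = (lineage⁺ label⁺)/(lineage⁺) is a per-day rate; accumulated
linearly over a horizon H it gives the cumulative proliferating fraction
PI·H. Balanced against the observed population fold change f via
N_end = N_start·(1 + births − deaths), the implied compensatory death
fraction is births − (f − 1).

**Study statistics.** Relative expression by 2^−ΔΔCt against the geometric
mean of a housekeeping panel (samples with housekeeping-Ct spread > 5
cycles are screened out); immunoassay fold changes with below-LOD values
substituted at LOD/2 and analytes censored in more than half of all
samples reported N/D, on the signed ±fold convention; Kendall's tau-b for
ordinal severity scores; spontaneous-alternation ratios with failed trials
excluded.

## Worked example

```python
from plaquesholl import (SimulationConfig, simulate_field, Field,
                         profile_field, aggregate_profiles, summarize_turnover)

cfg = SimulationConfig(seed=1, width_um=1500, height_um=1500)
plaques, cells = simulate_field(cfg)
field = Field(cfg.width_um, cfg.height_um, cfg.background_density_per_mm2)
agg = aggregate_profiles(profile_field(plaques, cells, field))
print(agg[["offset_inner_um", "mean_density_per_mm2", "n_plaques"]].head(3))

s = summarize_turnover(19, 1000, label_window_days=1, extrapolation_days=28,
                       population_fold_change=1.0)
print(f"PI {s.pi:.1%}/day -> {s.cumulative_fraction:.0%} over 4 weeks; "
      f"implied death {s.implied_death_fraction:.0%}")
```

prints

```
   offset_inner_um  mean_density_per_mm2  n_plaques
0              0.0           1190.878537          8
1             20.0            947.296743          7
2             40.0            452.410129          7
PI 1.9%/day -> 53% over 4 weeks; implied death 53%
```

The first rows show microglial density falling from ~1190 cells/mm² in the
first 20 µm ring to ~450 by 40–60 µm (the simulated background is 300) —
the plaque-associated accumulation the profiler is built to measure. The
turnover lines are the package's worked calculation: a 1.9%/day index
means ~53% of microglia proliferate in a 4-week window, and a stable total
count implies the same fraction is lost to death.

The `examples/` directory has one short narrative script per capability;
a thin CLI (`plaquesholl simulate|profile|turnover|correlate|area|
expression|arrays|braak-corr|alternation`) wraps the same functions for
shell use.

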