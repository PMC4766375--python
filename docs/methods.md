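# Methods

This note documents the models and procedures the package implements, the
parameters that matter, and the design decisions taken where the
underlying quantification protocol leaves choices open.

## Geometry and cell assignment

All spatial reasoning is planar and continuous: coordinates are Cartesian
micrometres with the origin at the field's lower-left corner, distances
Euclidean. Plaques and cell somata are disks. The one primitive everything
rests on is the circle–circle intersection ("lens") area, computed in
closed form; the fraction of a soma inside an annulus is the difference of
two lens areas over the soma area, so fractions over any concentric
partition sum to 1 exactly. A Monte-Carlo point-sampling estimator of the
same fraction exists in the test suite purely as an independent oracle —
the analytic path is the implementation, for determinism and speed.

Cells are modelled as disks of configurable radius, default 5 µm, because
the majority-area assignment rule presupposes cells with spatial extent;
a 10 µm soma diameter is typical for microglia. The package takes the
delineation (soma outline vs nuclear footprint) as given by the input
table.

## Radial profiling

Concentric circles start at each plaque's own radius and advance in 20 µm
steps (both configurable). A soma is assigned to the region — plaque
interior, one annulus, or beyond the outermost circle — holding the
largest share of its area; an exact 50/50 split goes inward. For somata
smaller than the step (the default regime) this is precisely the
">50% of the cell" majority rule. Cells whose majority lies inside the
plaque disk are reported separately (`cells_inside_plaque`), not folded
into the first annulus: the circles are traced from the plaque boundary
outward and intra-plaque cells are a different population.

Stopping rules, applied to each candidate annulus in order:

1. **Neighbour contact** — the candidate's outer circle touches a
   neighbouring plaque (centre distance ≤ outer radius + neighbour
   radius). The circle, not the focal plaque, is what grows outward, so
   contact is judged on it. The touching annulus is excluded.
2. **Tissue border** — the outer circle is not fully inside the field
   rectangle. Full containment avoids deciding how to clip annulus areas
   at an edge. The crossing annulus is excluded.
3. **Background reached** — evaluated after counting: the first annulus
   whose density is ≤ ρ_ref·(1 + t) (tolerance t, default 0.1) is
   *included* and profiling stops. A reference density of 0 means no
   wild-type baseline is available and disables this rule.
4. **Maximum radius** — a safety cap (default 200 µm) preventing
   unbounded profiles on sparse fields.

Each plaque is profiled independently with all others as neighbours; a
cell may therefore appear in two plaques' profiles, bounded in practice by
the neighbour-contact stop.

Aggregation across plaques is per annulus index — i.e. distance from the
plaque *boundary* in multiples of the step — because plaque radii differ
and this is the only grid profiles share. Bins report mean ± SEM over the
profiles that reached them; no zero-imputation beyond a profile's stop
radius (SEM is 0 with `n_plaques = 1` flagging the bin).

### Enrichment decay fit

`fit_decay_length` fits ρ(d) = B·(1 + A·e^(−d/τ)) to the aggregate by
weighted least squares, with bin weights √n_plaques (the precision of a
bin mean grows with its contributing plaques; unweighted fits let sparse
deep bins destabilise B and hence τ). For parameter-recovery experiments
the profiles feeding the fit are built with the background stop disabled
and `max_radius` raised to 300 µm: the return-to-baseline rule truncates
profiles stochastically — conditionally on staying *above* threshold —
which both discards and upward-biases exactly the tail bins that pin the
background parameter.

## Turnover model

The proliferation index PI = double-positive / total is treated as a
per-window rate (window default 1 day, matching a label pulse given one
day before sacrifice) and accumulated **linearly**: cumulative = PI ×
horizon/window, capped at 1 with an explicit flag. Linear accumulation is
the model under which a 1.9%/day index yields 53% over 28 days
(compounding would give 41.6%); it assumes each day labels a fresh cohort
and ignores re-division of labelled cells, adequate far from saturation.
The death balance uses N_end = N_start·(1 + births − deaths), so
deaths = births − (fold − 1), clamped at 0 (with a flag) when observed
growth exceeds what births explain. Cell-cycle length, label dilution and
lineage structure are out of scope.

## Intensity statistics

Distance is measured to the nearest plaque **centre** by default (the
convention for reporter-gradient analyses), with boundary distance as an
option. Both Pearson's r and Spearman's ρ are reported; ρ is the more
defensible headline since reporter intensity units are arbitrary, but both
are affine-invariant in the intensity. Fewer than 3 complete pairs is an
error; a constant variable yields an `undefined` flag rather than a
coefficient. Percent-positive area is simply 100 × (pixels ≥ threshold) /
pixels, threshold user-supplied (acquisition settings, not the package,
determine comparability across images).

## Expression, arrays, behaviour

* **ΔΔCt**: the normalization factor is the geometric mean of each
  sample's housekeeping Cts; ΔCt = Ct_target − NF; the calibrator is the
  arithmetic mean ΔCt of the control group (rather than a single
  calibrator sample), which makes the control group's geometric-mean fold
  exactly 1. The quality screen drops samples whose housekeeping Ct
  spread (max − min over the panel) exceeds 5 cycles, or with missing
  housekeeping values. PCR-efficiency correction is out of scope.
* **LOD censoring**: an analyte below detection in more than half of all
  samples pooled (as array reports state the rule) is N/D; surviving
  censored values are substituted at LOD/2 (the common convention; the
  factor is configurable). Fold changes use the signed convention
  (+ratio if ≥ 1, else −1/ratio), antisymmetric under group swap away
  from 1.
* **Tau-b** delegates to the standard tie-corrected implementation; the
  test suite verifies it exactly against an exhaustive pair-classification
  oracle. All-tied input is undefined (NaN).
* **Alternation**: failed trials (no choice within the time limit) are
  excluded from numerator and denominator — the only reading consistent
  with "failed trials are not scored" — and the failed fraction is
  reported alongside.

## Synthetic tissue generator

The generator emulates the statistical structure of plaque-bearing cortex:

| parameter | default | meaning |
|---|---|---|
| `plaque_intensity_per_mm2` | 4.41 | plaque density typical of 9-month disease-model cortex |
| `plaque_radius_mean_um` / `sd` | 15 / 4 | congophilic plaque size (radii truncated ≥ 2 µm) |
| `min_plaque_separation_um` | 100 | hard-core centre separation |
| `background_density_per_mm2` | 300 | wild-type microglial density in sections |
| `enrichment_amplitude` | 3 | density at the plaque edge = 4× background |
| `decay_length_um` | 40 | e-folding of the enrichment with boundary distance |
| `cell_radius_um` | 5 | soma radius |
| `pi_near` / `pi_far` | 0.05 / 0.01 | labelling probability at plaque edge / far field |
| `intensity_i0`, `intensity_decay_um`, `intensity_noise_sd` | 100, 50, 10 | reporter gradient from plaque centres |

Plaques are a hard-core process: Poisson-many uniform candidates accepted
sequentially if ≥ `min_plaque_separation` from all accepted ones (simpler
and seed-deterministic compared with Matérn II thinning; the realised
intensity therefore runs a few percent below nominal). Microglia are an
inhomogeneous Poisson process, λ(p) = background·(1 + A·e^(−d_b/τ)) with
d_b the distance to the nearest plaque *boundary* (0 inside a plaque),
sampled exactly by thinning at λ_max. Labelling probability interpolates
pi_far → pi_near on the same exponential; with these defaults the
field-wide proliferation index comes out at roughly 1.4–1.6%/day, the
order of magnitude measured in disease-model tissue. Reporter intensity
decays from the nearest plaque *centre* (the two distance conventions
mirror the two used by the analyses) with additive Gaussian noise clipped
at 0. One seeded generator per call; identical configs give byte-identical
tables. The Ct-table generator ties the target gene's Ct to each sample's
housekeeping normalization factor so the generative fold is exactly
recoverable in the noise-free limit.

What the generator does **not** emulate: real plaque morphology (plaques
are disks), clustered or fractal plaque patterns, anisotropy, section
artefacts, segmentation error, monocyte influx, or plaque growth. Passing
tests therefore validate the estimators under the stated point-process
model, not the upstream imaging pipeline.

## Problem sizes and numerical notes

Validation experiments use 1–2.25 mm² fields, ~10 plaques and ~300–1200
cells per field, pooling 100+ plaques for parameter recovery — ample for
the estimators while keeping the full suite fast. Decay-length recovery on
these sizes is unbiased (mean ≈ 40 µm) with ~10% spread. Lens-area
evaluation clamps acos arguments to [−1, 1] and the Heron-style radicand
to ≥ 0 against rounding; the partial-overlap branch is evaluated on
(r_min, r_max) so the area is bit-identical under argument swap. Annulus
stopping comparisons use a 1 nm tolerance so exact-touch fixtures are
classified deterministically.

## Known limitations

* 2-D only; no clipping of annulus areas at tissue borders (profiles stop
  instead, matching the stated protocol).
* Double counting of cells between nearby plaques is bounded but not
  eliminated; profiles are per-plaque by design.
* The linear turnover extrapolation is a modelling convention, not a
  mechanistic cell-cycle model.
* The LOD/2 substitution is a convention; sensitivity to it should be
  checked when censoring is heavy.
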