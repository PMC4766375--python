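"""Radial profiler: annulus construction, stopping rules, cell assignment,
count conservation and cross-plaque aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

from plaquesholl import (
    AnnulusRecord,
    Disk,
    Field,
    IncompatibleProfilesError,
    Point2D,
    ProfilerError,
    RadialProfile,
    SimulationConfig,
    StopReason,
    aggregate_profiles,
    build_annuli,
    fit_decay_length,
    profile_field,
    profile_plaque,
    simulate_field,
)
from plaquesholl.geometry import lens_area

from conftest import make_cells, make_plaques


def plaque_at(x, y, r=10.0):
    return Disk(Point2D(x, y), r)


class TestBuildAnnuli:
    def test_unobstructed_plaque_runs_to_max_radius(self, square_field):
        rings, stop = build_annuli(
            plaque_at(500, 500), [], square_field, step=20, max_radius=110
        )
        assert rings == [(10, 30), (30, 50), (50, 70), (70, 90), (90, 110)]
        assert stop == StopReason.MAX_RADIUS

    def test_neighbour_contact_excludes_touching_ring(self, square_field):
        # neighbour 100 µm away, radius 10: ring [70,90) has outer circle
        # radius 90 and 90 + 10 >= 100, so it is excluded.
        rings, stop = build_annuli(
            plaque_at(400, 500), [plaque_at(500, 500)], square_field, step=20, max_radius=200
        )
        assert rings == [(10, 30), (30, 50), (50, 70)]
        assert stop == StopReason.NEIGHBOUR_CONTACT

    def test_tissue_border_stops_profile(self, square_field):
        # centre 45 µm from the left edge: [30,50) would cross the border
        rings, stop = build_annuli(plaque_at(45, 500), [], square_field, step=20, max_radius=200)
        assert rings == [(10, 30)]
        assert stop == StopReason.TISSUE_BORDER

    def test_no_valid_first_ring_gives_empty_profile(self, square_field):
        rings, stop = build_annuli(plaque_at(25, 500), [], square_field, step=20, max_radius=200)
        assert rings == []
        assert stop == StopReason.TISSUE_BORDER

    def test_plaque_outside_field_rejected(self, square_field):
        with pytest.raises(ProfilerError):
            build_annuli(plaque_at(-5, 500), [], square_field)

    def test_enlarging_max_radius_preserves_earlier_rings(self, square_field):
        """Monotone stopping: the cap only ever truncates, never reshapes."""
        short, _ = build_annuli(plaque_at(500, 500), [], square_field, step=20, max_radius=90)
        long, _ = build_annuli(plaque_at(500, 500), [], square_field, step=20, max_radius=210)
        assert long[: len(short)] == short


OPEN_FIELD = Field(1000.0, 1000.0, reference_density_per_mm2=0.0)  # background rule off


class TestCellAssignment:
    def test_fully_contained_cell_counted_once(self):
        cells = make_cells([525.0], [500.0])  # distance 25, radius 5: inside [10,30)
        prof = profile_plaque(
            plaque_at(500, 500), cells, [], OPEN_FIELD, step=20, max_radius=110,
            background_tolerance=0.0,
        )
        assert prof.annuli[0].cell_count == 1
        assert sum(a.cell_count for a in prof.annuli[1:]) == 0
        assert prof.cells_inside_plaque == 0

    def test_cell_on_ring_boundary_goes_inward(self):
        """A soma split exactly across a circle is assigned by majority area;
        the curved boundary puts slightly more than half outside, and an
        exact 50/50 split goes to the inner ring."""
        cells = make_cells([530.0], [500.0])  # centre exactly on the r=30 circle
        prof = profile_plaque(
            plaque_at(500, 500), cells, [], OPEN_FIELD, step=20, max_radius=110,
            background_tolerance=0.0,
        )
        # analytic check of where the majority lies
        inner_frac = (lens_area(30.0, 5.0, 30.0) - lens_area(10.0, 5.0, 30.0)) / (math.pi * 25)
        counts = [a.cell_count for a in prof.annuli]
        if inner_frac >= 0.5:
            assert counts[:2] == [1, 0]
        else:
            assert counts[:2] == [0, 1]

    def test_intra_plaque_cells_reported_separately(self):
        cells = make_cells([500.0, 525.0], [500.0, 500.0])
        prof = profile_plaque(
            plaque_at(500, 500), cells, [], OPEN_FIELD, step=20, max_radius=110,
            background_tolerance=0.0,
        )
        assert prof.cells_inside_plaque == 1
        assert prof.annuli[0].cell_count == 1

    def test_non_microglial_cells_ignored(self):
        cells = make_cells([525.0], [500.0], is_microglia=0)
        prof = profile_plaque(
            plaque_at(500, 500), cells, [], OPEN_FIELD, step=20, max_radius=110,
            background_tolerance=0.0,
        )
        assert prof.total_cells == 0

    def test_empty_cell_table_is_not_an_error(self):
        prof = profile_plaque(
            plaque_at(500, 500), make_cells([], []), [], OPEN_FIELD, step=20,
            max_radius=110, background_tolerance=0.0,
        )
        assert prof.total_cells == 0
        assert len(prof.annuli) >= 1

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ProfilerError):
            profile_plaque(
                plaque_at(500, 500), make_cells([], []), [], OPEN_FIELD,
                background_tolerance=-0.1,
            )


class TestBackgroundStop:
    def test_uniform_grid_at_reference_density_stops_immediately(self):
        """Density already at the wild-type level: rule (ii) fires on ring 1.

        Deterministic fixture: a 17×17 regular grid over 1 mm² (289
        cells/mm²) with the plaque centred on a grid point, so the first
        ring is empty and its density (0) is at/below reference."""
        s = 1000.0 / 17.0
        xs, ys = np.meshgrid((np.arange(17) + 0.5) * s, (np.arange(17) + 0.5) * s)
        cells = make_cells(xs.ravel(), ys.ravel())
        field = Field(1000.0, 1000.0, reference_density_per_mm2=289.0)
        prof = profile_plaque(
            plaque_at(8.5 * s, 8.5 * s), cells, [], field, step=20, max_radius=200,
            background_tolerance=0.1,
        )
        assert prof.stop_reason == StopReason.BACKGROUND_REACHED
        assert len(prof.annuli) == 1

    def test_background_ring_is_included(self, square_field):
        """The triggering annulus itself is reported, then profiling stops."""
        cfg = SimulationConfig(seed=7, width_um=1500, height_um=1500)
        plaques, cells = simulate_field(cfg)
        field = Field(1500, 1500, reference_density_per_mm2=cfg.background_density_per_mm2)
        for prof in profile_field(plaques, cells, field):
            if prof.stop_reason == StopReason.BACKGROUND_REACHED:
                threshold = field.reference_density_per_mm2 * 1.1
                assert prof.annuli[-1].density_per_mm2 <= threshold
                for a in prof.annuli[:-1]:
                    assert a.density_per_mm2 > threshold


class TestConservation:
    def test_counts_conserved_against_majority_rule(self, square_field):
        """Annulus counts + intra-plaque count must equal the number of
        microglia whose majority soma area lies within the final circle,
        re-derived here directly from lens areas."""
        for seed in range(5):
            cfg = SimulationConfig(seed=seed)
            plaques, cells = simulate_field(cfg)
            field = Field(cfg.width_um, cfg.height_um, cfg.background_density_per_mm2)
            for prof, row in zip(profile_field(plaques, cells, field), plaques.itertuples()):
                final_r = prof.final_outer_radius_um
                d = np.hypot(cells["x_um"] - row.x_um, cells["y_um"] - row.y_um)
                frac_inside = lens_area(
                    final_r, cells["radius_um"].to_numpy(), d.to_numpy()
                ) / (math.pi * cells["radius_um"].to_numpy() ** 2)
                expected = int(np.count_nonzero(frac_inside >= 0.5))
                assert prof.total_cells == expected


class TestAggregation:
    @staticmethod
    def _profile(densities, step=20.0, r0=10.0):
        annuli = [
            AnnulusRecord(r0 + k * step, r0 + (k + 1) * step, 0, 1.0, d)
            for k, d in enumerate(densities)
        ]
        return RadialProfile("p", r0, step, annuli, 0, StopReason.MAX_RADIUS)

    def test_single_profile_mean_with_zero_sem(self):
        agg = aggregate_profiles([self._profile([100.0, 50.0])])
        assert list(agg["mean_density_per_mm2"]) == [100.0, 50.0]
        assert list(agg["sem_density_per_mm2"]) == [0.0, 0.0]
        assert list(agg["n_plaques"]) == [1, 1]

    def test_two_profile_arithmetic(self):
        agg = aggregate_profiles([self._profile([100.0, 50.0]), self._profile([200.0, 150.0])])
        assert list(agg["mean_density_per_mm2"]) == [150.0, 100.0]
        assert list(agg["sem_density_per_mm2"]) == pytest.approx([50.0, 50.0])

    def test_short_profiles_do_not_zero_impute(self):
        agg = aggregate_profiles([self._profile([100.0]), self._profile([200.0, 150.0])])
        assert list(agg["n_plaques"]) == [2, 1]
        assert agg["mean_density_per_mm2"].iloc[1] == 150.0

    def test_mixed_steps_rejected(self):
        with pytest.raises(IncompatibleProfilesError):
            aggregate_profiles([self._profile([1.0], step=20), self._profile([1.0], step=25)])

    def test_first_ring_enriched_over_last_on_appps1_like_fields(self):
        """Microglia accumulate near plaques: the first annulus is denser
        than the furthest one in simulated disease-like fields."""
        enriched = 0
        total = 0
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, width_um=1500, height_um=1500)
            plaques, cells = simulate_field(cfg)
            if len(plaques) == 0:
                continue
            field = Field(1500, 1500, cfg.background_density_per_mm2)
            agg = aggregate_profiles(profile_field(plaques, cells, field))
            if len(agg) >= 2:
                total += 1
                if agg["mean_density_per_mm2"].iloc[0] > agg["mean_density_per_mm2"].iloc[-1]:
                    enriched += 1
        assert total >= 10
        assert enriched / total > 0.95


class TestDecayFit:
    def test_recovers_exact_exponential(self):
        step = 20.0
        d = np.arange(8) * step
        rho = 300.0 * (1.0 + 3.0 * np.exp(-(d + step / 2) / 40.0))
        profiles = [TestAggregation._profile(list(rho), step=step)]
        fit = fit_decay_length(aggregate_profiles(profiles))
        assert fit.decay_length_um == pytest.approx(40.0, rel=1e-6)
        assert fit.background_per_mm2 == pytest.approx(300.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(3.0, rel=1e-6)

    def test_needs_enough_bins(self):
        with pytest.raises(ProfilerError):
            fit_decay_length(aggregate_profiles([TestAggregation._profile([1.0, 2.0])]))
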