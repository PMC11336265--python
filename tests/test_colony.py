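"""Agent-based colony dynamics: growth, activation, noise, reproducibility."""

from dataclasses import replace

import numpy as np
import pytest

import metalsense as ms
from metalsense.errors import PlacementError


def run(config):
    return ms.run_scenario(config)


class TestInitColony:
    def test_growing_and_stationary_counts(self):
        growing = ms.init_colony(ms.get_scenario("arsenic_growing_threshold"))
        assert growing.n_live == 1000
        stationary = ms.init_colony(ms.get_scenario("arsenic_stationary_threshold"))
        assert stationary.n_live == 1999
        assert stationary.n_expressing == 0

    def test_growing_cells_seeded_in_central_disk(self):
        config = ms.get_scenario("arsenic_growing_threshold")
        colony = ms.init_colony(config)
        radii = np.hypot(*colony.positions.T)
        assert radii.max() <= config.colony_radius

    def test_same_seed_gives_identical_positions(self):
        config = ms.get_scenario("lead_stationary_zero", seed=42)
        a = ms.init_colony(config)
        b = ms.init_colony(config)
        assert np.array_equal(a.positions, b.positions)

    def test_overpacked_disk_rejected(self):
        config = replace(
            ms.get_scenario("arsenic_growing_threshold"), colony_radius=10.0
        )
        with pytest.raises(PlacementError):
            ms.init_colony(config)


class TestStepColony:
    def test_no_error_at_threshold_everyone_expresses_after_delay(
        self, quick_stationary
    ):
        config = replace(quick_stationary, error_rate=0.0)
        records, colony, _ = run(config)
        assert records[-1].expressing_count == records[-1].live_count
        # nothing is visible before the maturation delay has elapsed
        for record in records:
            if record.time < config.maturation_delay:
                assert record.expressing_count == 0

    def test_no_error_zero_metal_nothing_expresses(self, quick_stationary):
        config = replace(quick_stationary, error_rate=0.0, metal_conc=0.0)
        records, _, _ = run(config)
        assert all(r.expressing_count == 0 for r in records)

    def test_erroneous_on_count_matches_binomial_mean(self):
        """2000 cells at 0.1%/step must average ~2 erroneous ONs per step."""
        config = replace(
            ms.get_scenario("arsenic_stationary_zero", seed=7),
            initial_pop=2000, max_pop=2000, t_end=300.0,
        )
        _, colony, _ = run(config)
        n_steps = config.t_end / config.dt
        per_step = colony.error_on_events / n_steps
        assert per_step == pytest.approx(2.0, rel=0.25)

    def test_population_cap_never_exceeded(self, quick_growing):
        config = replace(quick_growing, max_pop=150)
        records, _, _ = run(config)
        counts = [r.live_count for r in records]
        assert max(counts) <= 150
        assert counts == sorted(counts)  # growing regime never loses cells
        assert counts[-1] == 150  # cap reached and held


class TestRunScenario:
    def test_bit_identical_rerun_at_fixed_seed(self, quick_stationary):
        first = run(quick_stationary)[0]
        second = run(quick_stationary)[0]
        assert [
            (r.time, r.live_count, r.expressing_count) for r in first
        ] == [(r.time, r.live_count, r.expressing_count) for r in second]

    def test_different_seeds_diverge(self, quick_stationary):
        config = replace(quick_stationary, metal_conc=0.0)
        a = run(config)[1]
        b = run(config.with_seed(99))[1]
        assert not np.array_equal(a.positions, b.positions)

    def test_monotone_activation_in_concentration(self, quick_stationary):
        """Raising the bath concentration never lowers the final ON fraction."""
        fractions = []
        for conc in (0.0, 5.0, 10.0, 20.0):
            config = replace(quick_stationary, metal_conc=conc, error_rate=0.0)
            records = run(config)[0]
            fractions.append(records[-1].expressing_count / records[-1].live_count)
        assert fractions == sorted(fractions)
        assert fractions[0] == 0.0 and fractions[-1] == 1.0

    def test_error_rate_recovery_within_binomial_ci(self):
        """Zero-metal run recovers the induced 0.1% error rate."""
        config = replace(
            ms.get_scenario("mercury_stationary_zero", seed=17), t_end=300.0
        )
        _, colony, _ = run(config)
        estimate = ms.estimated_error_rate(colony)
        p = config.error_rate
        half_width = 1.96 * np.sqrt(p * (1 - p) / colony.cell_steps)
        assert abs(estimate - p) <= half_width

    def test_growing_spatial_pattern_inner_on_outer_dark(self, quick_growing):
        _, colony, _ = run(quick_growing)
        assert colony.n_expressing > 0
        assert colony.n_live > colony.n_expressing
        assert ms.mean_radius(colony, True) < ms.mean_radius(colony, False)

    def test_cell_views_expose_state(self, quick_stationary):
        config = replace(quick_stationary, t_end=5.0, initial_pop=20, max_pop=20)
        _, colony, _ = run(config)
        cells = colony.cells
        assert len(cells) == 20
        assert all(c.alive for c in cells)
        assert all(c.expressing is False or c.alive for c in cells)
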