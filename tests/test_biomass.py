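"""Biomass distribution, logistic attraction and mass-conserving redistribution."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reefsim.biomass import (
    ScenarioParams,
    apply_attraction,
    attraction_fraction,
    density_ratio_at_zero,
    deploy,
    deploy_for_pelagics,
    deploy_for_residents,
    q0_from_q,
    q_from_q0,
    redistribute,
    resident_field,
    shape_param,
)
from reefsim.grid import GridSpec, build_grid, distance_field, place_reefs


class TestScalarRelations:
    def test_shape_param_halves_at_d_h(self):
        for d_h in (10, 20, 37.5):
            assert math.exp(-shape_param(d_h) * d_h) == pytest.approx(0.5)

    def test_shape_param_values(self):
        assert shape_param(10) == pytest.approx(0.069315, abs=1e-6)
        assert shape_param(20) == pytest.approx(0.034657, abs=1e-6)

    def test_shape_param_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            shape_param(0)

    @pytest.mark.parametrize("q,q0", [(2, 2 / 3), (1, 0.5), (5, 5 / 6)])
    def test_q0_from_q(self, q, q0):
        assert q0_from_q(q) == pytest.approx(q0)

    @given(st.floats(0.1, 50))
    def test_q_round_trip(self, q):
        assert q_from_q0(q0_from_q(q)) == pytest.approx(q)

    def test_density_ratio_at_zero_recovers_quality(self):
        # an AR of quality Q holds Q times the density of an adjacent NR
        assert density_ratio_at_zero(5) == pytest.approx(5.0)
        assert density_ratio_at_zero(2) == pytest.approx(2.0)

    def test_q0_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            q0_from_q(0)


class TestResidentField:
    def test_exponential_decay_milestones(self, small_grid):
        d = distance_field(small_grid, [(10, 10)])
        b = resident_field(d, d_h=20.0)
        assert b[10, 10] == 1.0
        assert b[10, 12] == pytest.approx(0.5)  # 20 m = D_h
        assert b[10, 14] == pytest.approx(0.25)  # 2 D_h

    def test_equals_max_over_per_cell_exponentials(self):
        # nearest-distance evaluation implements the non-additive max rule
        grid = GridSpec(21, 10.0)
        cells = [(3, 4), (10, 10), (10, 11), (17, 2)]
        b = resident_field(distance_field(grid, cells), d_h=15.0)
        per_cell = [resident_field(distance_field(grid, [c]), d_h=15.0) for c in cells]
        assert np.allclose(b, np.maximum.reduce(per_cell))


class TestAttractionFraction:
    def test_logistic_milestones(self):
        q0, d50, d99 = 0.7, 150.0, 300.0
        assert attraction_fraction(d50, q0, d50, d99) == pytest.approx(q0 / 2)
        assert attraction_fraction(0.0, q0, d50, d99) == pytest.approx(0.99 * q0)
        assert attraction_fraction(d99, q0, d50, d99) == pytest.approx(0.01 * q0)

    @settings(max_examples=50, deadline=None)
    @given(
        q0=st.floats(0.01, 0.99),
        d50=st.floats(10, 500),
        d1=st.floats(0, 1000),
        d2=st.floats(0, 1000),
    )
    def test_strictly_decreasing_in_distance(self, q0, d50, d1, d2):
        if abs(d1 - d2) < 1e-6:
            return
        lo, hi = sorted((d1, d2))
        f = lambda d: attraction_fraction(d, q0, d50, 2 * d50)
        assert f(lo) > f(hi)

    def test_bounded_on_attraction_span(self):
        q0, d50 = 0.5, 200.0
        d = np.linspace(0, 2 * d50, 101)
        f = attraction_fraction(d, q0, d50, 2 * d50)
        assert np.all(f <= 0.99 * q0 + 1e-12)
        assert np.all(f >= 0.01 * q0 - 1e-12)

    def test_far_distances_do_not_overflow(self):
        assert attraction_fraction(1e6, 0.5, 100, 200) == 0.0


class TestApplyAttraction:
    def test_zero_field_yields_zero_attraction(self, small_grid):
        d = distance_field(small_grid, [(10, 10)])
        remaining, total = apply_attraction(np.zeros(small_grid.shape), d, 0.5, 100, 200)
        assert total == 0.0
        assert not remaining.any()

    def test_small_q0_limit_leaves_field_unchanged(self, small_grid):
        field = np.random.default_rng(0).random(small_grid.shape)
        d = distance_field(small_grid, [(10, 10)])
        remaining, total = apply_attraction(field, d, 1e-12, 100, 200)
        assert np.allclose(remaining, field, atol=1e-9)
        assert total == pytest.approx(0.0, abs=1e-6)

    def test_uniform_3x3_matches_per_cell_oracle(self):
        # brute-force per-cell evaluation of the logistic on a 3x3 grid
        grid = GridSpec(3, 10.0)
        q0, d50, d99 = 0.5, 20.0, 40.0
        d = distance_field(grid, [(1, 1)])
        remaining, total = apply_attraction(np.ones(grid.shape), d, q0, d50, d99)
        expected = 0.0
        for r in range(3):
            for c in range(3):
                dist = 10.0 * math.hypot(r - 1, c - 1)
                expected += q0 / (1 + math.exp((math.log(99**2) / d99) * (dist - d50)))
        assert total == pytest.approx(expected, rel=1e-12)

    def test_grid_mismatch_rejected(self, small_grid):
        d = distance_field(small_grid, [(10, 10)])
        with pytest.raises(ValueError):
            apply_attraction(np.ones((3, 3)), d, 0.5, 100, 200)


class TestRedistribute:
    def test_zero_attracted_is_identity(self):
        remaining = np.random.default_rng(1).random((5, 5))
        w = np.random.default_rng(2).random((5, 5))
        assert np.array_equal(redistribute(remaining, 0.0, w), remaining)

    def test_uniform_weights_share_equally(self):
        remaining = np.zeros((4, 4))
        after = redistribute(remaining, 8.0, np.ones((4, 4)))
        assert np.allclose(after, 0.5)

    def test_conserves_total(self):
        rng = np.random.default_rng(3)
        remaining, w = rng.random((7, 7)), rng.random((7, 7))
        after = redistribute(remaining, 3.7, w)
        assert after.sum() == pytest.approx(remaining.sum() + 3.7, rel=1e-12)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            redistribute(np.ones((3, 3)), 1.0, np.zeros((3, 3)))

    def test_max_rule_keeps_larger_contribution(self):
        remaining = np.array([[1.0, 0.0], [0.0, 0.0]])
        w = np.array([[0.0, 1.0], [0.0, 0.0]])
        after = redistribute(remaining, 2.0, w, overlap_rule="max")
        assert after[0, 1] == 2.0 and after[0, 0] == 1.0


def random_params(rng, group=None):
    return ScenarioParams(
        group=group or rng.choice(["resident", "pelagic"]),
        s_r=int(rng.integers(1, 4)),
        q=float(rng.integers(1, 11)),
        d_r_step=int(rng.integers(1, 13)),
        d_50=float(rng.choice([100, 150, 200, 250, 300])),
        d_h=float(rng.choice([10, 15, 20, 25, 30, 35, 40])),
        p=int(rng.choice([2, 5, 10, 20, 50, 100])),
    )


class TestDeploy:
    def test_resident_mass_conserved_and_bounded(self, grid211):
        params = ScenarioParams(group="resident", s_r=2, q=5, d_r_step=3, d_h=10, d_50=300)
        layout = place_reefs(grid211, params.s_r, params.d_r_step)
        out = deploy_for_residents(layout, params)
        assert out.after.sum() == pytest.approx(out.before.sum(), rel=1e-9)
        assert np.all(out.remaining <= out.before + 1e-15)
        assert np.all(out.after >= 0)
        assert 0 <= out.attracted_fraction <= 1

    def test_resident_distant_mobile_limit_attracts_nothing(self, grid211):
        params = ScenarioParams(group="resident", s_r=1, q=5, d_r_step=12, d_h=10, d_50=300)
        layout = place_reefs(grid211, 1, 12)
        out = deploy_for_residents(layout, params)
        assert out.attracted_fraction < 0.05

    def test_resident_attraction_increases_with_quality(self, grid211):
        layout = place_reefs(grid211, 1, 3)
        fracs = [
            deploy_for_residents(
                layout, ScenarioParams(group="resident", q=q, d_r_step=3, d_h=10, d_50=300)
            ).attracted_fraction
            for q in (1, 3, 5, 10)
        ]
        assert fracs == sorted(fracs)

    def test_adjacent_reef_density_ratio_approaches_quality(self):
        # Q=2: an AR immediately adjacent to the NR ends up with ~twice the
        # NR's biomass density (attraction split f : 1-f with f -> 0.99*Q0
        # at zero distance, so the realized split at one cell's separation
        # sits just under the exact Q)
        from reefsim.grid import ReefLayout

        grid = build_grid(211, 10.0)
        layout = ReefLayout(
            grid=grid, natural_cells=((105, 105),), artificial_cells=((105, 106),),
            s_r=1, d_r=10.0,
        )
        params = ScenarioParams(group="resident", q=2, d_h=10, d_50=300)
        out = deploy_for_residents(layout, params)
        nr_remaining = out.remaining[105, 105]
        moved_off_nr = out.before[105, 105] - out.remaining[105, 105]
        split = moved_off_nr / nr_remaining
        assert split == pytest.approx(2.0, rel=0.05)
        assert split < 2.0  # the logistic never quite attains Q0
        # the exact identity holds in the zero-distance limit
        assert density_ratio_at_zero(2) == pytest.approx(2.0, rel=1e-12)

    def test_pelagic_two_stage_conserves_total(self, grid211):
        params = ScenarioParams(group="pelagic", s_r=3, q=7, d_r_step=3, d_h=10, d_50=200)
        layout = place_reefs(grid211, 3, 3)
        out = deploy_for_pelagics(layout, params)
        assert out.before.sum() == pytest.approx(grid211.n_cells, rel=1e-9)
        assert out.after.sum() == pytest.approx(out.before.sum(), rel=1e-9)

    def test_pelagic_stage1_depletion_profile(self, grid211):
        # Q_nr=1 -> Q0=0.5: cells beyond D_99 keep >=99% of uniform biomass,
        # cells adjacent to the NR lose ~49.5%
        params = ScenarioParams(group="pelagic", s_r=1, q=5, d_r_step=12, d_h=20, d_50=200)
        layout = place_reefs(grid211, 1, 12)
        dist_nr = distance_field(grid211, layout.natural_cells)
        from reefsim.biomass import q0_from_q as q0f

        uniform = np.ones(grid211.shape)
        remaining, _ = apply_attraction(uniform, dist_nr, q0f(1.0), 200, 400)
        far = dist_nr >= 400
        assert np.all(remaining[far] >= 0.99)
        nr_r, nr_c = layout.natural_cells[0]
        assert 1 - remaining[nr_r, nr_c + 1] == pytest.approx(0.495, abs=0.01)

    def test_pelagic_interior_minimum_over_separation(self, grid211):
        fracs = []
        for step in range(1, 13):
            params = ScenarioParams(
                group="pelagic", s_r=2, q=5, d_r_step=step, d_h=20, d_50=200
            )
            layout = place_reefs(grid211, 2, step)
            fracs.append(deploy_for_pelagics(layout, params).attracted_fraction)
        am = int(np.argmin(fracs))
        assert 0 < am < 11  # minimum strictly inside the separation ladder

    def test_group_dispatch_and_mismatch(self, grid211):
        layout = place_reefs(grid211, 1, 3)
        res = ScenarioParams(group="resident")
        pel = ScenarioParams(group="pelagic")
        with pytest.raises(ValueError):
            deploy_for_residents(layout, pel)
        with pytest.raises(ValueError):
            deploy_for_pelagics(layout, res)
        assert deploy(layout, res).before[105, 105] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_random_scenarios(self, seed):
        rng = np.random.default_rng(seed)
        params = random_params(rng)
        layout = place_reefs(params.grid, params.s_r, params.d_r_step)
        out = deploy(layout, params)
        assert out.after.sum() == pytest.approx(out.before.sum(), rel=1e-9)


class TestScenarioParams:
    def test_d99_derived_and_enforced(self):
        assert ScenarioParams(d_50=150).d_99 == 300
        with pytest.raises(ValueError, match="twice"):
            ScenarioParams(d_50=150, d_99=250)

    def test_with_updates_rederives_d99(self):
        p = ScenarioParams(d_50=300).with_updates(d_50=100)
        assert p.d_99 == 200

    @pytest.mark.parametrize(
        "kw",
        [dict(d_h=0), dict(q=0.5), dict(d_50=-1), dict(s_r=4), dict(p=0),
         dict(group="demersal"), dict(q_nr=0), dict(overlap_rule="mean")],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            ScenarioParams(**kw)
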