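"""Energy budget over distance and maximum dispersal distance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dispersalenergy import (
    AnimalProfile,
    basal_metabolic_rate,
    cost_per_metre,
    energy_budget,
    energy_cost,
    energy_storage,
    field_metabolic_rate,
    lambda_sweep,
    max_dispersal_distance,
    max_dispersal_distance_resting,
    relative_depletion,
    travel_speed,
)

MODES = ("flying", "running", "swimming")

animals = st.builds(
    AnimalProfile,
    st.floats(1e-3, 1e3),
    group=st.none(),
    mode=st.sampled_from(MODES),
)


class TestEnergyCost:
    def test_zero_distance_identity(self, each_group, params):
        o = energy_cost(each_group, 0.0, params)
        assert o.energy_cost == 0.0
        assert o.energy_remaining == energy_storage(each_group, params)
        assert o.travel_time == 0.0

    def test_published_cost_over_100km(self, params):
        # 58.82 J/m × 1e5 m for the 4.5 kg running mammal
        o = energy_cost(AnimalProfile.mammal(4.5), 1e5, params)
        assert o.energy_cost == pytest.approx(5.882e6, rel=1e-2)

    @settings(max_examples=30, derandomize=True)
    @given(animal=animals, distance=st.floats(0.0, 1e7))
    def test_energy_conservation(self, animal, distance):
        o = energy_cost(animal, distance)
        assert o.energy_remaining + o.energy_cost == pytest.approx(
            energy_storage(animal), rel=1e-9
        )

    @settings(max_examples=30, derandomize=True)
    @given(animal=animals, distance=st.floats(1.0, 1e6))
    def test_cost_linear_in_distance(self, animal, distance):
        assert energy_cost(animal, 2 * distance).energy_cost == pytest.approx(
            2 * energy_cost(animal, distance).energy_cost, rel=1e-9
        )

    def test_depletion_linear_second_differences_vanish(self, params):
        grid = np.linspace(0.0, 5e5, 11)
        er = np.array(
            [energy_cost(AnimalProfile.bird(0.5), d, params).energy_remaining for d in grid]
        )
        scale = abs(er).max()
        assert np.all(np.abs(np.diff(er, 2)) < 1e-9 * scale)

    def test_beyond_maximum_reports_infeasible_not_error(self, params):
        a = AnimalProfile.mammal(0.05)
        far = 10 * max_dispersal_distance(a, 0.1, params).d_max
        o = energy_cost(a, far, params)
        assert o.energy_remaining < 0 and not o.feasible

    def test_negative_distance_rejected(self, params):
        with pytest.raises(ValueError):
            energy_cost(AnimalProfile.fish(1.0), -1.0, params)


class TestCostPerMetre:
    def test_consistent_with_energy_cost(self, each_group, params):
        d = 12345.0
        assert cost_per_metre(each_group, params) * d == pytest.approx(
            energy_cost(each_group, d, params).energy_cost, rel=1e-12
        )

    def test_equals_fmr_over_speed(self, each_group, params):
        assert cost_per_metre(each_group, params) == pytest.approx(
            field_metabolic_rate(each_group, params) / travel_speed(each_group, params)
        )


class TestRelativeDepletion:
    def test_zero_at_origin_one_at_dmax(self, each_group, params):
        assert relative_depletion(each_group, 0.0, 0.1, params) == 0.0
        dmax = max_dispersal_distance(each_group, 0.1, params).d_max
        assert relative_depletion(each_group, dmax, 0.1, params) == pytest.approx(1.0)

    def test_published_seven_percent_for_giant_mammal(self, params):
        frac = relative_depletion(AnimalProfile.mammal(4000.0), 1e5, 0.1, params)
        assert round(100 * frac) == 7

    def test_larger_mammal_more_efficient_despite_higher_absolute_cost(self, params):
        small, big = AnimalProfile.mammal(4.5), AnimalProfile.mammal(4000.0)
        assert cost_per_metre(big, params) > cost_per_metre(small, params)
        assert relative_depletion(big, 1e5, 0.1, params) < relative_depletion(
            small, 1e5, 0.1, params
        )

    def test_lambda_one_rejected(self, params):
        with pytest.raises(ValueError):
            relative_depletion(AnimalProfile.fish(1.0), 10.0, 1.0, params)


class TestMaxDispersalDistance:
    def test_lambda_one_gives_zero(self, each_group, params):
        assert max_dispersal_distance(each_group, 1.0, params).d_max == 0.0

    def test_linear_in_one_minus_lambda(self, each_group, params):
        d0 = max_dispersal_distance(each_group, 0.0, params).d_max
        for lam in (0.1, 0.35, 0.8):
            assert max_dispersal_distance(each_group, lam, params).d_max == pytest.approx(
                (1 - lam) * d0, rel=1e-12
            )

    def test_mode_ordering_at_two_kg(self, params):
        fish = max_dispersal_distance(AnimalProfile.fish(2.0), 0.1, params).d_max
        bird = max_dispersal_distance(AnimalProfile.bird(2.0), 0.1, params).d_max
        mammal = max_dispersal_distance(AnimalProfile.mammal(2.0), 0.1, params).d_max
        assert fish > bird > mammal

    @pytest.mark.parametrize(
        "mode,lo,hi",
        [("flying", 0.0031, 8.44), ("running", 0.0076, 3940.0), ("swimming", 0.22, 550.0)],
    )
    def test_monotone_in_mass_over_empirical_ranges(self, mode, lo, hi, params):
        masses = np.logspace(np.log10(lo), np.log10(hi), 25)
        d = [
            max_dispersal_distance(AnimalProfile(m, mode=mode), 0.1, params).d_max
            for m in masses
        ]
        assert np.all(np.diff(d) > 0)

    def test_budget_consistency(self, each_group, params):
        res = max_dispersal_distance(each_group, 0.25, params)
        assert res.e_available == pytest.approx(
            energy_budget(each_group, 0.25, params).e_available
        )
        assert res.d_max == pytest.approx(res.speed * res.depletion_time)


class TestRestingExtension:
    def test_beta_zero_reduces_exactly(self, each_group, params):
        plain = max_dispersal_distance(each_group, 0.1, params)
        rest = max_dispersal_distance_resting(each_group, 0.1, 0.0, params)
        assert rest.d_max == plain.d_max
        assert rest.depletion_time == plain.depletion_time

    def test_beta_one_gives_zero(self, each_group, params):
        assert max_dispersal_distance_resting(each_group, 0.1, 1.0, params).d_max == 0.0

    def test_strictly_decreasing_in_beta(self, each_group, params):
        betas = np.linspace(0, 1, 11)
        d = [
            max_dispersal_distance_resting(each_group, 0.1, b, params).d_max for b in betas
        ]
        assert np.all(np.diff(d) < 0)

    def test_half_rest_matches_algebraic_oracle(self, each_group, params):
        # Dmaxβ = v·Eα / (FMRdis + (β/(1−β))·BMR), derived by eliminating t3
        beta = 0.5
        v = travel_speed(each_group, params)
        ea = energy_budget(each_group, 0.1, params).e_available
        oracle = v * ea / (
            field_metabolic_rate(each_group, params)
            + beta / (1 - beta) * basal_metabolic_rate(each_group, params)
        )
        assert max_dispersal_distance_resting(
            each_group, 0.1, beta, params
        ).d_max == pytest.approx(oracle, rel=1e-12)

    def test_beta_out_of_range_rejected(self, params):
        with pytest.raises(ValueError):
            max_dispersal_distance_resting(AnimalProfile.bird(1.0), 0.1, 1.5, params)


class TestLambdaSweep:
    def test_rows_and_linearity(self, params):
        a = AnimalProfile.fish(3.0)
        table = lambda_sweep(a, [0.0, 0.5, 1.0], params)
        assert list(table["lambda"]) == [0.0, 0.5, 1.0]
        d0 = table["d_max_m"].iloc[0]
        assert table["d_max_m"].iloc[1] == pytest.approx(0.5 * d0)
        assert table["d_max_m"].iloc[2] == 0.0

    def test_default_lambda_row_matches_direct_call(self, params):
        a = AnimalProfile.bird(0.1)
        table = lambda_sweep(a, [0.1], params)
        assert table["d_max_m"].iloc[0] == max_dispersal_distance(a, 0.1, params).d_max

    def test_pairwise_ratio_closed_form(self, params):
        a = AnimalProfile.mammal(10.0)
        table = lambda_sweep(a, [0.2, 0.6], params)
        assert table["d_max_m"].iloc[0] / table["d_max_m"].iloc[1] == pytest.approx(
            (1 - 0.2) / (1 - 0.6)
        )

    def test_empty_or_invalid_grid_rejected(self, params):
        with pytest.raises(ValueError):
            lambda_sweep(AnimalProfile.bird(1.0), [], params)
        with pytest.raises(ValueError):
            lambda_sweep(AnimalProfile.bird(1.0), [0.5, 1.2], params)
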