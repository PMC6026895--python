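"""Grid search, sensitivity, interaction regression and dosing procedures,
validated against analytic toy objectives and planted synthetic responses."""

import math

import numpy as np
import pytest

from phagecycle.economics import CycleEconomics
from phagecycle.experiments import (
    SearchParameter,
    SearchSpace,
    apply_operational_parameters,
    dosing_simulation,
    find_minimum_dose,
    interaction_scan,
    local_sensitivity,
    production_time,
    semi_exhaustive_search,
)


def five_param_space(levels=4):
    return SearchSpace(
        tuple(
            SearchParameter(name=n, lower=0.0, upper=10.0, levels=levels)
            for n in ("a", "b", "c", "d", "e")
        )
    )


CENTER = {"a": 6.3, "b": 2.2, "c": 8.1, "d": 4.4, "e": 5.5}


class TestSemiExhaustiveSearch:
    def test_two_round_evaluation_count(self):
        """4 levels ** 5 parameters, twice: exactly 2048 scheduled runs."""
        result = semi_exhaustive_search(
            five_param_space(), lambda p: sum(p.values()), rounds=2
        )
        assert result.n_evaluations == 2048
        assert (result.evaluations["round"] == 1).sum() == 1024
        assert (result.evaluations["round"] == 2).sum() == 1024

    def test_convex_toy_incumbent_near_true_minimum(self):
        objective = lambda p: sum((p[k] - CENTER[k]) ** 2 for k in p)  # noqa: E731
        result = semi_exhaustive_search(five_param_space(), objective, rounds=2)
        # round-2 grid spacing: (10/3) / 3 levels gaps ~ 1.11 per coordinate
        spacing = (10.0 / 3) / 3
        for name, true_val in CENTER.items():
            assert abs(result.incumbent[name] - true_val) <= spacing

    def test_incumbent_never_worsens_between_rounds(self):
        objective = lambda p: math.cos(p["a"]) * p["b"] - p["c"] + (p["d"] - p["e"]) ** 2  # noqa: E731
        result = semi_exhaustive_search(five_param_space(), objective, rounds=2)
        frame = result.evaluations
        best_r1 = frame[frame["round"] == 1]["objective"].min()
        assert result.incumbent_objective <= best_r1

    def test_single_parameter_single_round_argmin(self):
        space = SearchSpace((SearchParameter(name="x", lower=0.0, upper=3.0, levels=4),))
        result = semi_exhaustive_search(space, lambda p: (p["x"] - 1.1) ** 2, rounds=1)
        assert result.n_evaluations == 4
        assert result.incumbent["x"] == pytest.approx(1.0)

    def test_infeasible_points_rank_as_infinite(self):
        def objective(p):
            if p["x"] < 1.5:
                raise RuntimeError("simulation failed")
            return p["x"]

        space = SearchSpace((SearchParameter(name="x", lower=0.0, upper=3.0, levels=4),))
        result = semi_exhaustive_search(space, objective, rounds=1)
        assert result.incumbent["x"] == pytest.approx(2.0)
        assert np.isinf(result.evaluations["objective"]).sum() == 2

    def test_log_scale_grid_levels(self):
        par = SearchParameter(name="s", lower=1.0, upper=1000.0, scale="log", levels=4)
        np.testing.assert_allclose(par.grid(), [1.0, 10.0, 100.0, 1000.0])
        # refined range spans one decade centred on the incumbent, clipped
        lo, hi = par.refined_bounds(1000.0, shrink=3.0)
        np.testing.assert_allclose([lo, hi], [10 ** 2.5, 1000.0])
        refined = par.grid(lo, hi)
        assert refined[0] == pytest.approx(316.2, rel=1e-3)


class TestLocalSensitivity:
    def test_linear_objective_has_unit_elasticity(self):
        report = local_sensitivity(
            {"v": 2.0, "w": 5.0}, lambda p: {"C": 7.0 * p["v"]}, delta=0.01
        )
        assert report.sensitivities["C"]["v"] == pytest.approx(1.0)
        assert report.sensitivities["C"]["w"] == 0.0
        assert report.n_evaluations == 4

    def test_reciprocal_objective_elasticity(self):
        report = local_sensitivity({"v": 3.0}, lambda p: {"C": 1.0 / p["v"]}, delta=0.01)
        # averaged one-sided estimates of a 1/V map at +/-1%: -(1 + delta^2...)
        assert report.sensitivities["C"]["v"] == pytest.approx(-1.0, abs=2e-4)

    def test_power_law_elasticity_matches_exponent(self):
        report = local_sensitivity({"v": 1.7}, lambda p: {"C": 3.0 * p["v"] ** 2.5})
        assert report.sensitivities["C"]["v"] == pytest.approx(2.5, abs=2e-3)

    def test_five_parameters_schedule_ten_runs(self):
        calls = []

        def objective(p):
            calls.append(dict(p))
            return {"C": sum(p.values())}

        point = {k: float(i + 1) for i, k in enumerate("abcde")}
        report = local_sensitivity(point, objective)
        assert report.n_evaluations == 10
        assert len(calls) == 11  # mid-point evaluated once, shared by all

    def test_zero_baseline_flagged(self):
        report = local_sensitivity({"v": 1.0}, lambda p: {"C": 0.0})
        assert math.isnan(report.sensitivities["C"]["v"])
        assert report.flags


class TestInteractionScan:
    def test_factorial_count(self):
        point = {k: 10.0 for k in "abcde"}
        report = interaction_scan(point, lambda p: sum(p.values()))
        assert report.n_evaluations == 3125
        assert report.design.startswith("5-level full factorial")

    def test_planted_interaction_recovered(self, rng):
        """A response built as 2*x1*x2 plus tiny noise must yield the x1:x2
        product term with the right normalized coefficient and a
        Bonferroni-significant p-value, and no other significant terms."""
        point = {k: 10.0 for k in "abcde"}
        noise = iter(rng.normal(0.0, 0.01, size=4000))
        # unit-variance coded levels of the +/-2% design
        scale = float(np.std([-0.02, -0.01, 0.0, 0.01, 0.02]))

        def objective(p):
            x1 = (p["a"] - 10.0) / 10.0 / scale
            x2 = (p["b"] - 10.0) / 10.0 / scale
            return 2.0 * x1 * x2 + next(noise)

        report = interaction_scan(point, objective)
        row = report.table.set_index("term").loc["a:b"]
        # planted coefficient on the z-scored scale: unity (the product term
        # carries all the signal), recovered within 5%
        assert row["coefficient"] == pytest.approx(1.0, rel=0.05)
        assert row["p_adjusted"] < 1e-10
        others = report.table[report.table["term"] != "a:b"]
        assert (others["p_adjusted"] > 0.05).all()

    def test_additive_response_shows_no_interactions(self):
        point = {k: 5.0 for k in "abcde"}
        report = interaction_scan(point, lambda p: 3 * p["a"] - 2 * p["b"] + p["c"])
        assert len(report.significant()) == 0

    def test_bonferroni_is_raw_times_ten_capped(self, rng):
        point = {k: 5.0 for k in "abc"}
        noise = iter(rng.normal(0.0, 1.0, size=200))
        report = interaction_scan(
            point, lambda p: p["a"] + next(noise), deltas=(-0.02, 0.0, 0.02)
        )
        n_pairs = 3
        for _, row in report.table.iterrows():
            assert row["p_adjusted"] == pytest.approx(min(1.0, row["p_raw"] * n_pairs))


class TestDosing:
    def test_zero_dose_zero_eradication(self):
        assert dosing_simulation(1e6, 0.0) == 0.0

    def test_eradication_monotone_in_dose(self):
        doses = [1e5, 1e6, 1e7, 1e8]
        fractions = [dosing_simulation(1e6, d) for d in doses]
        assert all(b >= a for a, b in zip(fractions, fractions[1:]))
        assert 0.0 <= min(fractions) and max(fractions) <= 1.0

    def test_reference_dose_neutralizes_most_bacteria(self):
        """1e7 particles/mL against 1e6 cells/mL with Ki=1e-7 mL/h and a
        0.5 h latent period eradicates the large majority within an hour
        (the exact fraction depends on the assumed burst size)."""
        fraction = dosing_simulation(1e6, 1e7, ki=1e-7, latent=0.5, duration=1.0)
        assert 0.6 < fraction < 1.0
        dose, table = find_minimum_dose(1e6, target_fraction=0.9)
        assert dose in (1e7, 1e8)
        assert table["eradicated_fraction"].is_monotonic_increasing

    def test_invalid_duration(self):
        with pytest.raises(ValueError, match="duration"):
            dosing_simulation(1e6, 1e7, duration=0.0)


class TestProductionTime:
    @staticmethod
    def eco(phages_per_hour):
        return CycleEconomics(
            cost_per_cycle=850.0, cost_per_hour=309.0, cost_per_phage=4.4e-13,
            phages_per_cycle=phages_per_hour * 2.75, phages_per_hour=phages_per_hour,
        )

    def test_division(self):
        assert production_time(1e17, self.eco(7.0e14)) == pytest.approx(142.86, rel=1e-3)
        assert production_time(1e16, self.eco(7.0e14)) == pytest.approx(14.29, rel=1e-3)

    def test_one_hour_worth(self):
        assert production_time(7.0e14, self.eco(7.0e14)) == pytest.approx(1.0)

    def test_zero_productivity_rejected(self):
        with pytest.raises(ValueError, match="productivity"):
            production_time(1e17, self.eco(0.0))


class TestOperationalParameterMapping:
    def test_apply_parameters(self):
        from phagecycle.process import ProcessSpec, ReactorSpec

        spec = ProcessSpec(
            scf=ReactorSpec(hls=50.0, lls=11.6, influent_substrate=1000.0),
            sci=ReactorSpec(hls=50.0, lls=1.0, mls=40.0, influent_substrate=316.0),
            cycle_time=2.75,
        )
        new = apply_operational_parameters(
            spec, {"LLS_SCF": 12.0, "cycle_time": 3.0, "S_in_SCI": 100.0}
        )
        assert new.scf.lls == 12.0
        assert new.cycle_time == 3.0
        assert new.sci.influent_substrate == 100.0
        assert new.scf.influent_substrate == 1000.0  # untouched
        with pytest.raises(ValueError, match="unknown operational"):
            apply_operational_parameters(spec, {"bogus": 1.0})
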