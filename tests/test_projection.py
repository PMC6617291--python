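"""Posterior projection, burden summaries and the printed-table layout."""

import numpy as np
import pytest

from dmpop import (
    ParameterSet,
    PosteriorChains,
    percent_change,
    prevalence_percent,
    project_burden,
    simulate_disease,
    table1_layout,
    undiagnosed_share,
)
from dmpop.grids import N_AGES, HealthStateGrid
from dmpop.projection import ProjectionSummary


def degenerate_chains(params: ParameterSet, n_iter=40, n_chains=2):
    vec = params.to_vector()
    draws = np.broadcast_to(vec, (n_chains, n_iter, 31)).copy()
    return PosteriorChains(draws=draws, log_posts=np.zeros((n_chains, n_iter)),
                           burn_in=10, acceptance_rates=np.full(n_chains, 0.15),
                           free_names=ParameterSet.calibrated_names(),
                           seed=0, template=params,
                           free_mask=np.ones(31, dtype=bool))


def grid_with(h=0.0, u=0.0, d=0.0):
    counts = np.zeros((N_AGES, 2, 3))
    counts[40, 0] = [h, u, d]
    return HealthStateGrid(counts, 2015.0)


class TestScalarSummaries:
    def test_prevalence_all_healthy_zero(self):
        assert prevalence_percent(grid_with(h=1000.0)) == 0.0

    def test_prevalence_worked_example(self):
        # 3.7 million DM of 56.9 million people -> 6.50%
        grid = grid_with(h=56.9e6 - 3.7e6, u=0.673e6, d=3.7e6 - 0.673e6)
        assert prevalence_percent(grid) == pytest.approx(6.50, abs=0.01)

    def test_prevalence_all_statuses_is_100(self):
        grid = grid_with(h=10.0, u=5.0, d=5.0)
        assert prevalence_percent(grid, ("H", "U", "D")) == 100.0

    def test_prevalence_empty_population_undefined(self):
        with pytest.raises(ValueError):
            prevalence_percent(grid_with())

    def test_undiagnosed_share_worked_example(self):
        # 673,000 undiagnosed of 3.7 million total DM -> 18.2%
        assert undiagnosed_share(673e3, 3.7e6 - 673e3) == pytest.approx(18.2, abs=0.05)

    def test_undiagnosed_share_extremes(self):
        assert undiagnosed_share(grid_with(u=5.0)) == 100.0
        assert undiagnosed_share(grid_with(d=5.0)) == 0.0
        with pytest.raises(ValueError):
            undiagnosed_share(grid_with(h=10.0))

    def test_percent_change_worked_examples(self):
        assert round(percent_change(0.7, 1.3)) == 86
        assert round(percent_change(1.1, 1.8)) == 64
        assert percent_change(2.5, 2.5) == 0.0
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)


class TestProjectBurden:
    def test_degenerate_posterior_zero_width(self, noise_free_scenario):
        sc = noise_free_scenario
        chains = degenerate_chains(sc.true_params)
        summary = project_burden(chains, sc.initial_health, sc.schedule,
                                 sc.config, n_samples=5, seed=1,
                                 output_years=[2015.0, 2035.0])
        cells = summary.cells()
        piv = cells.pivot_table(index=["year", "sex", "age_group"],
                                columns="statistic", values="value")
        assert np.allclose(piv["lower"], piv["upper"])
        assert np.allclose(piv["lower"], piv["median"])

    def test_single_sample_equals_direct_simulation(self, noise_free_scenario):
        sc = noise_free_scenario
        chains = degenerate_chains(sc.true_params)
        summary = project_burden(chains, sc.initial_health, sc.schedule,
                                 sc.config, n_samples=1, seed=3,
                                 output_years=[2015.0])
        sim = simulate_disease(sc.initial_health, sc.true_params,
                               sc.schedule.hold_forward(2035.0), sc.config,
                               [2015.0])
        grid = sim.at(2015.0)
        lo, hi = sc.config.incidence_groups[3]
        direct = grid.counts[lo:hi + 1, :, 1:].sum(axis=(0, 2))
        assert summary.dm[0, 0, 0, 3] == pytest.approx(direct[0], rel=1e-9)
        assert summary.dm[0, 0, 1, 3] == pytest.approx(direct[1], rel=1e-9)

    def test_doubling_incidence_draws_increases_burden(self, noise_free_scenario):
        sc = noise_free_scenario
        base_chains = degenerate_chains(sc.true_params)
        doubled = ParameterSet(incidence=2 * sc.true_params.incidence,
                               screening=sc.true_params.screening,
                               excess_mortality_undx=sc.true_params.excess_mortality_undx,
                               reporting=sc.true_params.reporting)
        more_chains = degenerate_chains(doubled)
        kw = dict(n_samples=2, seed=0, output_years=[2035.0])
        a = project_burden(base_chains, sc.initial_health, sc.schedule,
                           sc.config, **kw)
        b = project_burden(more_chains, sc.initial_health, sc.schedule,
                           sc.config, **kw)
        assert b.total_dm(2035.0).mean() >= a.total_dm(2035.0).mean()

    def test_interval_nesting_50_in_95(self, noise_free_scenario):
        # jittered draws: the 50% interval must nest inside the 95% one
        sc = noise_free_scenario
        rng = np.random.default_rng(4)
        vec = sc.true_params.to_vector()
        draws = vec * np.exp(rng.normal(0, 0.05, size=(2, 30, 31)))
        draws[:, :, 28:] = np.clip(draws[:, :, 28:], 0, 1)
        chains = PosteriorChains(draws=draws, log_posts=np.zeros((2, 30)),
                                 burn_in=5, acceptance_rates=np.full(2, 0.15),
                                 free_names=ParameterSet.calibrated_names(),
                                 seed=0, template=sc.true_params,
                                 free_mask=np.ones(31, dtype=bool))
        summary = project_burden(chains, sc.initial_health, sc.schedule,
                                 sc.config, n_samples=20, seed=2,
                                 output_years=[2035.0])
        wide = summary.cells(credible=0.95).pivot_table(
            index=["year", "sex", "age_group"], columns="statistic", values="value")
        narrow = summary.cells(credible=0.50).pivot_table(
            index=["year", "sex", "age_group"], columns="statistic", values="value")
        assert (narrow["lower"] >= wide["lower"] - 1e-9).all()
        assert (narrow["upper"] <= wide["upper"] + 1e-9).all()

    def test_no_discontinuity_at_fit_boundary(self, noise_free_scenario):
        # projection output at the fit-window end must match the fitted
        # trajectory run only to that year
        sc = noise_free_scenario
        chains = degenerate_chains(sc.true_params)
        summary = project_burden(chains, sc.initial_health, sc.schedule,
                                 sc.config, n_samples=1, seed=0,
                                 output_years=[2015.0, 2035.0])
        fitted = sc.truth_sim.at(2015.0)
        total_fit = fitted.counts[:, :, 1:].sum()
        assert summary.total_dm(2015.0)[0] == pytest.approx(total_fit, rel=1e-6)

    def test_oversampling_pool_errors(self, noise_free_scenario):
        sc = noise_free_scenario
        chains = degenerate_chains(sc.true_params, n_iter=12)
        with pytest.raises(ValueError, match="pool"):
            project_burden(chains, sc.initial_health, sc.schedule, sc.config,
                           n_samples=1000, seed=0, output_years=[2015.0])


class TestTable1Layout:
    @staticmethod
    def summary_from_cells(cell_matrix, years, groups=("0-39", "40-49", "50-59", "60+")):
        """Build a degenerate one-sample summary carrying given counts
        (cell_matrix in persons, shape (n_years, 2, n_groups))."""
        arr = np.asarray(cell_matrix, dtype=float)[None, :, :, :]
        return ProjectionSummary(years=np.asarray(years, dtype=float),
                                 age_groups=groups, dm=arr,
                                 undx=np.zeros_like(arr),
                                 pop=np.full_like(arr, 1e9), seed=0)

    def test_printed_rows_sum_to_totals(self):
        # the published projection rows, in thousands (male, female per group)
        printed = {
            2015: [320, 130, 240, 210, 420, 590, 710, 1100],
            2035: [230, 100, 210, 210, 460, 620, 1300, 1800],
        }
        cells = np.zeros((2, 2, 4))
        for yi, year in enumerate(sorted(printed)):
            row = printed[year]
            for gi in range(4):
                cells[yi, 1, gi] = row[2 * gi] * 1000.0      # male
                cells[yi, 0, gi] = row[2 * gi + 1] * 1000.0  # female
        summary = self.summary_from_cells(cells, sorted(printed))
        frame, text = table1_layout(summary)
        assert frame.loc[frame.year == 2015, "total"].iloc[0] == 3720
        assert frame.loc[frame.year == 2035, "total"].iloc[0] == 4930
        cell_cols = [c for c in frame.columns if c not in ("year", "total")]
        assert (frame[cell_cols].sum(axis=1) == frame["total"]).all()

    def test_rounded_cells_always_sum_to_total(self):
        rng = np.random.default_rng(6)
        cells = rng.uniform(1e4, 2e6, size=(3, 2, 4))
        summary = self.summary_from_cells(cells, [2010, 2020, 2030])
        frame, _ = table1_layout(summary)
        cell_cols = [c for c in frame.columns if c not in ("year", "total")]
        assert (frame[cell_cols].sum(axis=1) == frame["total"]).all()

    def test_single_cell_table(self):
        cells = np.zeros((1, 2, 4))
        cells[0, 1, 0] = 250e3
        summary = self.summary_from_cells(cells, [2015])
        frame, _ = table1_layout(summary, years=[2015], age_groups=["0-39"])
        assert list(frame.columns) == ["year", "0-39_male", "0-39_female", "total"]
        assert frame["total"].iloc[0] == 250

    def test_missing_group_errors(self, noise_free_scenario):
        sc = noise_free_scenario
        chains = degenerate_chains(sc.true_params)
        summary = project_burden(chains, sc.initial_health, sc.schedule,
                                 sc.config, n_samples=1, seed=0,
                                 output_years=[2015.0])
        with pytest.raises(KeyError):
            table1_layout(summary, years=[2015], age_groups=["85+"])
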