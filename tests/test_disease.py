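"""Disease overlay: three-status chain, ledger, seeding, parameter I/O."""

import numpy as np
import pytest

from dmpop import (
    AgeSexGrid,
    HealthStateGrid,
    ModelConfig,
    ParameterSet,
    all_healthy,
    mean_time_to_diagnosis,
    seed_disease,
    simulate_disease,
    simulate_population,
)
from dmpop.disease import disease_derivative
from dmpop.grids import N_AGES

from _oracles import enumerate_demographic_flows, three_state_chain_solution
from conftest import make_schedule


def zero_params(**overrides):
    base = dict(incidence=np.zeros((4, 2)), screening=np.zeros((3, 2, 2)),
                excess_mortality_undx=np.zeros((4, 2)), reporting=np.zeros(3),
                cfr_diagnosed=0.0)
    base.update(overrides)
    return ParameterSet(**base)


def single_cell_state(age=50, sex=0, h=1000.0, u=0.0, d=0.0, t=2000.0):
    counts = np.zeros((N_AGES, 2, 3))
    counts[age, sex] = [h, u, d]
    return HealthStateGrid(counts, t)


class TestDerivative:
    def test_no_onset_no_dm_forever(self, zero_schedule, config):
        params = zero_params(screening=np.full((3, 2, 2), 0.5))
        initial = single_cell_state()
        sim = simulate_disease(initial, params, zero_schedule, config,
                               [2005.0, 2015.0], aging=False)
        for grid in sim.grids:
            assert grid.status("U").sum() == 0
            assert grid.status("D").sum() == 0

    def test_closed_cell_matches_matrix_exponential(self, zero_schedule, config):
        # H -> U -> D chain with lam=0.1, sigma=0.5, no deaths, 5 years
        lam, sigma = 0.1, 0.5
        params = zero_params(incidence=np.full((4, 2), lam),
                             screening=np.full((3, 2, 2), sigma))
        initial = single_cell_state(age=50, h=1000.0)
        sim = simulate_disease(initial, params, zero_schedule, config,
                               [2005.0], aging=False)
        got = sim.grids[-1].counts[50, 0]
        want = three_state_chain_solution(1000.0, 0.0, 0.0, lam, sigma,
                                          0.0, 0.0, 5.0)
        np.testing.assert_allclose(got, want, rtol=1e-8)

    def test_status_sum_equals_demographic_derivative_plus_excess(self, config):
        # flow-by-flow: summing the three statuses must reproduce the pure
        # demographic derivative minus status-specific excess deaths
        rng = np.random.default_rng(5)
        schedule = make_schedule(fertility_total=2.0, mortality=0.0, migration=3.0)
        schedule.mortality[0] = rng.uniform(0, 0.05, size=(N_AGES, 2))
        counts = rng.uniform(0, 100, size=(N_AGES, 2, 3))
        state = HealthStateGrid(counts, 2005.0)
        params = ParameterSet(incidence=rng.uniform(0, 0.05, (4, 2)),
                              screening=rng.uniform(0, 1.0, (3, 2, 2)),
                              excess_mortality_undx=rng.uniform(0, 0.5, (4, 2)),
                              reporting=np.array([0.8, 0.85, 0.9]),
                              cfr_diagnosed=0.0184)
        d = disease_derivative(state, params, schedule, config, 2005.0)
        status_sum = d.sum(axis=2)
        demog = enumerate_demographic_flows(
            counts.sum(axis=2), schedule.mortality_at(2005.0),
            schedule.fertility_at(2005.0), schedule.migration_at(2005.0),
            schedule.sex_ratio_at_birth)
        excess = (params.excess_mortality_by_age(config) * counts[:, :, 1]
                  + params.cfr_diagnosed * counts[:, :, 2])
        np.testing.assert_allclose(status_sum, demog - excess, rtol=1e-10,
                                   atol=1e-10)

    def test_no_diagnosis_below_screening_floor(self, zero_schedule, config):
        params = zero_params(incidence=np.full((4, 2), 0.05),
                             screening=np.full((3, 2, 2), 2.0))
        initial = single_cell_state(age=10, h=1000.0)
        sim = simulate_disease(initial, params, zero_schedule, config,
                               [2003.0], aging=False)
        assert sim.grids[-1].counts[10, 0, 2] == 0.0
        assert sim.grids[-1].counts[10, 0, 1] > 0.0


class TestSimulate:
    def test_no_screening_all_dm_undiagnosed(self, zero_schedule, config):
        params = zero_params(incidence=np.full((4, 2), 0.05))
        initial = single_cell_state()
        sim = simulate_disease(initial, params, zero_schedule, config,
                               [2010.0], aging=False)
        assert sim.grids[-1].status("D").sum() == 0
        assert sim.grids[-1].status("U").sum() > 0

    def test_doubling_screening_decreases_undiagnosed(self, noise_free_scenario):
        sc = noise_free_scenario
        params = sc.true_params
        doubled = ParameterSet(incidence=params.incidence,
                               screening=2 * params.screening,
                               excess_mortality_undx=params.excess_mortality_undx,
                               reporting=params.reporting,
                               cfr_diagnosed=params.cfr_diagnosed)
        years = [2005.0, 2010.0, 2015.0]
        base = simulate_disease(sc.initial_health, params, sc.schedule,
                                sc.config, years)
        more = simulate_disease(sc.initial_health, doubled, sc.schedule,
                                sc.config, years)
        for g_base, g_more in zip(base.grids, more.grids):
            assert g_more.status("U").sum() <= g_base.status("U").sum()
        assert (more.ledger["true_diagnoses"].sum()
                >= base.ledger["true_diagnoses"].sum())

    def test_ledger_matches_integral_of_diagnosis_flow(self, zero_schedule, config):
        # with sigma and U constant-free dynamics the ledger integral has a
        # closed form via the chain solution at year boundaries
        lam, sigma = 0.1, 0.5
        params = zero_params(incidence=np.full((4, 2), lam),
                             screening=np.full((3, 2, 2), sigma))
        initial = single_cell_state(age=50, h=1000.0)
        sim = simulate_disease(initial, params, zero_schedule, config,
                               [2003.0], aging=False)
        # cumulative D at year boundaries equals cumulative diagnoses (no deaths)
        led = sim.ledger
        row = led[(led.year == 2002) & (led.sex == "female")
                  & (led.age_group == "50-59")]
        d2 = three_state_chain_solution(1000, 0, 0, lam, sigma, 0, 0, 2.0)[2]
        d3 = three_state_chain_solution(1000, 0, 0, lam, sigma, 0, 0, 3.0)[2]
        assert row["true_diagnoses"].iloc[0] == pytest.approx(d3 - d2, rel=1e-7)

    def test_irreversibility_cumulative_flows_nondecreasing(self, noise_free_scenario):
        led = noise_free_scenario.truth_sim.ledger
        assert (led["onsets"] >= -1e-9).all()
        assert (led["true_diagnoses"] >= -1e-9).all()

    def test_status_conservation_vs_demography_only(self, noise_free_scenario):
        # with both excess hazards at zero the H+U+D marginal must follow the
        # demography-only model
        sc = noise_free_scenario
        params = ParameterSet(incidence=sc.true_params.incidence,
                              screening=sc.true_params.screening,
                              excess_mortality_undx=np.zeros((4, 2)),
                              reporting=sc.true_params.reporting,
                              cfr_diagnosed=0.0)
        years = [2005.0, 2015.0]
        disease = simulate_disease(sc.initial_health, params, sc.schedule,
                                   sc.config, years)
        demog = simulate_population(sc.initial_health.marginal(), sc.schedule,
                                    (2000.0, 2015.0), years)
        for g_dis, g_dem in zip(disease.grids, demog.grids):
            np.testing.assert_allclose(g_dis.marginal().counts, g_dem.counts,
                                       rtol=1e-6, atol=1e-8)

    def test_conservation_audit(self, noise_free_scenario):
        assert noise_free_scenario.truth_sim.conservation_residual() < 1e-6

    def test_mean_time_to_diagnosis_by_group(self, true_params):
        # male 60+, late period: sigma = 1.11/yr -> about 0.9 years
        assert mean_time_to_diagnosis(true_params, 2, 1, 1) == pytest.approx(
            1 / 1.11, rel=1e-12)
        # male 15-34, late period: sigma = 0.06/yr -> far over ten years
        assert mean_time_to_diagnosis(true_params, 0, 1, 1) > 10.0


class TestSeeding:
    def test_all_healthy_mode(self, noise_free_scenario, config, true_params):
        pop = noise_free_scenario.initial_health.marginal()
        grid = seed_disease(pop, true_params, config, mode="all_healthy")
        assert grid.status("U").sum() == 0
        assert grid.status("D").sum() == 0
        np.testing.assert_allclose(grid.status("H"), pop.counts)

    def test_equilibrium_split_matches_long_run_limit(self, config):
        # a frozen cell run to its quasi-stationary balance: the seeded U
        # fraction solves lam H = (sigma + mu + delta_u) U
        lam, sigma = 0.01, 0.5
        params = zero_params(incidence=np.full((4, 2), lam),
                             screening=np.full((3, 2, 2), sigma))
        counts = np.zeros((N_AGES, 2))
        counts[50, 0] = 1000.0
        grid = seed_disease(AgeSexGrid(counts, 2000.0), params, config,
                            prevalence_ceiling=1.0)
        u_frac = grid.counts[50, 0, 1] / counts[50, 0]
        # balance uses the seeding's nominal 0.02/yr background exit
        assert u_frac == pytest.approx(lam / (sigma + 0.02), rel=1e-9)

    def test_seeding_preserves_marginal(self, noise_free_scenario, config, true_params):
        pop = noise_free_scenario.initial_health.marginal()
        grid = seed_disease(pop, true_params, config)
        np.testing.assert_allclose(grid.marginal().counts, pop.counts,
                                   rtol=1e-12, atol=1e-9)


class TestParameterSet:
    def test_vector_round_trip(self, true_params):
        vec = true_params.to_vector()
        assert vec.shape == (31,)
        back = ParameterSet.from_vector(vec, true_params.cfr_diagnosed)
        np.testing.assert_allclose(back.to_vector(), vec)

    def test_csv_round_trip_is_32_rows(self, tmp_path, true_params, config):
        path = tmp_path / "params.csv"
        true_params.to_csv(path, config)
        import pandas as pd

        frame = pd.read_csv(path)
        assert len(frame) == 32  # 31 calibrated + fixed diagnosed case fatality
        back = ParameterSet.from_csv(path, config)
        np.testing.assert_allclose(back.to_vector(), true_params.to_vector())
        assert back.cfr_diagnosed == true_params.cfr_diagnosed

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            zero_params(reporting=np.array([0.5, 1.2, 0.5]))
        with pytest.raises(ValueError):
            zero_params(incidence=np.full((4, 2), -0.1))

    def test_calibrated_names_match_vector_order(self, true_params, config):
        names = ParameterSet.calibrated_names(config)
        assert len(names) == 31
        vec = true_params.to_vector()
        i = names.index("screening[60+,male,2010-2015]")
        assert vec[i] == true_params.screening[2, 1, 1]
        i = names.index("incidence[50-59,female]")
        assert vec[i] == true_params.incidence[2, 0]
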