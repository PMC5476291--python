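"""Batch simulation: conservation laws, diauxie, events, flux maps."""

import numpy as np
import pytest

from drumalg.kinetics import (
    CARBON_ATOMS,
    KineticParameters,
    M_CARBON,
    convert_units,
)
from drumalg.simulate import (
    Event,
    ExperimentCondition,
    SimulationError,
    apply_addition_event,
    butyrate_exhaustion_day,
    initial_state,
    ode_rhs,
    photosynthetic_quotient,
    reconstruct_fluxes,
    simulate,
    total_carbon,
)


class TestRHS:
    def test_no_biomass_means_no_flux(self, model, params):
        state = np.zeros(14)
        state[model.index("ACE")] = 1e-3
        assert np.allclose(ode_rhs(state, model, params, 136.0), 0.0)

    def test_dark_acetate_only_activates_mr1_alone(self, model, params):
        state = np.zeros(14)
        state[model.index("ACE")] = 1e-3
        state[model.index("B")] = 1e-4
        dx = ode_rhs(state, model, params, 0.0)
        alpha1 = params.k_mr1 * 1e-3 / (params.Ks_mr1 + 1e-3)
        assert dx[model.index("ACE")] == pytest.approx(-2 * alpha1 * 1e-4)
        assert dx[model.index("SUC")] == pytest.approx(alpha1 * 1e-4)
        assert dx[model.index("GAP")] == 0.0
        assert dx[model.index("Light")] == 0.0

    def test_carbon_weighted_derivative_is_zero(self, model, params):
        rng = np.random.default_rng(3)
        carbon = model.carbon_vector()
        for _ in range(25):
            state = rng.uniform(0, 1e-3, size=14)
            dx = ode_rhs(state, model, params, 136.0)
            assert abs(carbon @ dx) <= 1e-9

    def test_non_finite_state_rejected(self, model, params):
        state = np.zeros(14)
        state[0] = np.nan
        with pytest.raises(SimulationError):
            ode_rhs(state, model, params, 0.0)


class TestBatchSimulation:
    def test_acetate_batch_reaches_the_stoichiometric_yield(self, model, params):
        condition = ExperimentCondition(ace0=0.1, duration_days=15)
        traj = simulate(condition, model, params)
        assert traj.species("ACE")[-1] <= 1e-9
        assert traj.species("SUC")[-1] <= 1e-9
        b = traj.species("B")
        gained = (b[-1] - b[0]) * CARBON_ATOMS["B"] * M_CARBON
        assert gained == pytest.approx(0.514 * 0.1, rel=5e-3)

    def test_butyrate_inhibition_prevents_growth(self, model, params):
        # at 1 gC/L butyrate the substrate inhibition keeps growth below
        # 0.01 g/L over the whole batch -- flat at experimental scale,
        # whereas the same carbon as acetate yields ~0.9 g/L
        condition = ExperimentCondition(butyr0=1.0, duration_days=15)
        traj = simulate(condition, model, params)
        assert traj.X[-1] - traj.X[0] < 0.01
        reference = simulate(
            ExperimentCondition(ace0=1.0, duration_days=15), model, params)
        assert (reference.X[-1] - reference.X[0]) > 50 * (
            traj.X[-1] - traj.X[0])

    def test_diauxic_growth_is_sequential(self, model, params):
        condition = ExperimentCondition(ace0=0.25, butyr0=0.25)
        traj = simulate(condition, model, params)
        ace, butyr = traj.species("ACE"), traj.species("BUTYR")
        exhausted = np.nonzero(ace < 0.01 * ace[0])[0][0]
        consumed = (butyr[0] - butyr[exhausted]) / butyr[0]
        assert consumed < 0.01

    def test_removing_diauxic_repression_makes_uptake_simultaneous(
            self, model, params):
        relaxed = KineticParameters(**{**params.to_dict(), "k_D": 1.0})
        condition = ExperimentCondition(ace0=0.25, butyr0=0.25)

        def consumed_before_acetate_exhaustion(p):
            traj = simulate(condition, model, p)
            ace, butyr = traj.species("ACE"), traj.species("BUTYR")
            exhausted = np.nonzero(ace < 0.01 * ace[0])[0][0]
            return (butyr[0] - butyr[exhausted]) / butyr[0]

        assert consumed_before_acetate_exhaustion(relaxed) > (
            10 * consumed_before_acetate_exhaustion(params))

    def test_carbon_conservation_along_trajectories(self, model, params):
        for condition in [
            ExperimentCondition(ace0=0.5, duration_days=10),
            ExperimentCondition(ace0=0.3, butyr0=0.3,
                                incident_light=136, duration_days=10),
        ]:
            traj = simulate(condition, model, params)
            carbon = total_carbon(traj)
            assert np.max(np.abs(carbon - carbon[0])) <= 1e-6 * carbon[0]

    def test_mass_balance_defines_total_biomass(self, model, params):
        condition = ExperimentCondition(ace0=0.3, incident_light=136,
                                        duration_days=8)
        traj = simulate(condition, model, params)
        expected = (
            118.09 * traj.species("SUC")
            + 170.06 * traj.species("GAP")
            + 186.0 * np.maximum(traj.species("B"), 0.0)
        )
        assert np.allclose(traj.X, expected, rtol=1e-9, atol=1e-12)

    def test_biomass_nondecreasing_in_dark_growth(self, model, params):
        condition = ExperimentCondition(ace0=0.5, duration_days=12)
        traj = simulate(condition, model, params)
        assert np.all(np.diff(traj.X) >= -1e-9)

    def test_tolerance_refinement_leaves_trajectory_unchanged(
            self, model, params):
        condition = ExperimentCondition(ace0=0.25, butyr0=0.1,
                                        duration_days=8)
        times = np.linspace(0, 8 * 24.0, 50)
        a = simulate(condition, model, params, sample_times_h=times,
                     rtol=1e-8, atol=1e-12)
        b = simulate(condition, model, params, sample_times_h=times,
                     rtol=5e-9, atol=5e-13)
        scale = np.maximum(np.abs(a.X), 1e-9)
        assert np.max(np.abs(a.X - b.X) / scale) <= 1e-6


class TestEvents:
    def test_zero_volume_ratio_is_identity(self, model):
        state = np.arange(14, dtype=float)
        event = Event(1.0, "add_medium", added_ace=0.5, volume_ratio=0.0)
        assert np.allclose(apply_addition_event(state, event, model), state)

    def test_feed_mixing_mass_balance(self, model):
        state = np.zeros(14)
        state[model.index("B")] = 3e-4
        event = Event(5.0, "add_medium", added_ace=0.5, volume_ratio=0.5)
        new = apply_addition_event(state, event, model)
        ace = convert_units(new[model.index("ACE")], "M", "gC/L", "ACE")
        assert ace == pytest.approx(0.5 * 0.5 / 1.5)
        assert new[model.index("B")] == pytest.approx(3e-4 * 2 / 3)

    def test_event_conserves_total_carbon(self, model):
        rng = np.random.default_rng(11)
        state = rng.uniform(0, 1e-3, 14)
        event = Event(2.0, "add_medium", added_ace=0.4, added_butyr=0.2,
                      volume_ratio=0.5)
        carbon = model.carbon_vector()
        before = state @ carbon
        added = (
            convert_units(0.4, "gC/L", "M", "ACE") * 2
            + convert_units(0.2, "gC/L", "M", "BUTYR") * 4
        ) * 0.5
        after = apply_addition_event(state, event, model) @ carbon * 1.5
        assert after == pytest.approx(before + added, abs=1e-12)

    def test_light_switch_activates_photosynthesis(self, model, params):
        condition = ExperimentCondition(
            butyr0=0.5, duration_days=10,
            events=[Event(5.0, "set_light", new_light=136.0)],
        )
        traj = simulate(condition, model, params)
        before = traj.alpha[traj.times_h < 5 * 24.0, 2]
        after = traj.alpha[traj.times_h > 5 * 24.0 + 1, 2]
        assert np.allclose(before, 0.0)
        assert np.all(after > 0.0)


class TestFluxMaps:
    def test_dark_growth_has_silent_photosynthesis(
            self, pipeline_model, macroreactions, params, core_net):
        network, assignment, _ = core_net
        condition = ExperimentCondition(ace0=0.3, duration_days=5)
        traj = simulate(condition, pipeline_model, params)
        fmap = reconstruct_fluxes(traj, macroreactions, 24.0)
        for rid, tag in assignment.items():
            if tag == "photosynthesis":
                assert fmap.fluxes.get(rid, 0.0) == 0.0

    def test_internal_metabolites_have_zero_net_production(
            self, pipeline_model, macroreactions, params, core_net):
        from drumalg.network import split_subnetworks

        network, assignment, exchange = core_net
        condition = ExperimentCondition(ace0=0.3, incident_light=136,
                                        duration_days=5)
        traj = simulate(condition, pipeline_model, params)
        fmap = reconstruct_fluxes(traj, macroreactions, 48.0)
        S = network.stoichiometric_matrix()
        for sub in split_subnetworks(network, assignment, exchange):
            for met in sub.internal_metabolites:
                net = sum(
                    S.loc[met, rid] * fmap.fluxes.get(rid, 0.0)
                    for rid in sub.reaction_ids
                )
                assert abs(net) <= 1e-9

    def test_mixotrophic_acetate_growth_is_heterotrophy_dominated(
            self, pipeline_model, macroreactions, params, core_net):
        network, assignment, _ = core_net
        condition = ExperimentCondition(ace0=0.3, incident_light=136,
                                        duration_days=5)
        traj = simulate(condition, pipeline_model, params)
        fmap = reconstruct_fluxes(traj, macroreactions, 17.0)
        glyox = sum(abs(f) for rid, f in fmap.fluxes.items()
                    if assignment[rid] == "glyoxysome")
        photo = sum(abs(f) for rid, f in fmap.fluxes.items()
                    if assignment[rid] == "photosynthesis")
        assert glyox > photo

    def test_out_of_range_time_rejected(
            self, pipeline_model, macroreactions, params):
        condition = ExperimentCondition(ace0=0.1, duration_days=2)
        traj = simulate(condition, pipeline_model, params)
        with pytest.raises(ValueError):
            reconstruct_fluxes(traj, macroreactions, 100 * 24.0)


class TestPhotosyntheticQuotient:
    def test_dark_condition_is_undefined(self, model, params):
        condition = ExperimentCondition(ace0=0.2, duration_days=5)
        traj = simulate(condition, model, params)
        assert photosynthetic_quotient(traj, 24.0) is None

    def test_autotrophic_quotient_starts_at_unity(self, model, params):
        condition = ExperimentCondition(incident_light=136, duration_days=10)
        traj = simulate(condition, model, params)
        early = photosynthetic_quotient(traj, 0.5)
        assert early == pytest.approx(1.0, abs=0.01)


class TestScenarios:
    def test_interventions_unlock_butyrate_consumption(self, model, params):
        from drumalg.simulate import run_disinhibition_scenarios

        report = run_disinhibition_scenarios(model, params).set_index("scenario")
        assert np.isnan(report.loc["no_addition", "butyrate_exhaustion_day"])
        for scenario in ("acetate_feed", "light_136", "light_272"):
            assert np.isfinite(
                report.loc[scenario, "butyrate_exhaustion_day"])
        assert (report.loc["light_272", "butyrate_exhaustion_day"]
                < report.loc["light_136", "butyrate_exhaustion_day"])
        # feeding fermentative mix overcomes inhibition but is slower than
        # the same feed with illumination
        assert (report.loc["mix_feed_light", "final_butyrate_gC_L"]
                < report.loc["mix_feed_dark", "final_butyrate_gC_L"])
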