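"""VEGF-challenge binding kinetics, percent free VEGF, and design search."""

import numpy as np
import pytest

from ocuvegf.challenge import (
    BindingKineticsParams,
    drug_sites_at_day,
    find_design_window,
    kinetics_params_for_agent,
    percent_free_vegf,
    protection_timecourse,
    simulate_binding_kinetics,
)
from ocuvegf.errors import ConfigError
from ocuvegf.leakage import LeakageLogisticModel


@pytest.fixture(scope="module")
def model():
    return LeakageLogisticModel.from_points((46, 0.2), (94, 0.8))


@pytest.fixture(scope="module")
def afl_params(config):
    return kinetics_params_for_agent(config.agent("aflibercept"), config.design)


class TestKinetics:
    def test_params_satisfy_kd_identity(self, config):
        for agent in config.agents:
            p = kinetics_params_for_agent(agent, config.design)
            assert p.kd_molar == pytest.approx(agent.kd_body, rel=1e-12)

    def test_mass_balance_without_elimination(self, afl_params):
        tiny = 1e-12
        p = BindingKineticsParams(k_on=afl_params.k_on, k_off=afl_params.k_off,
                                  k_el_drug=tiny, k_el_vegf=tiny, k_el_complex=tiny)
        traj = simulate_binding_kinetics(10.0, 17.0, p, 2.0, mode="ode")
        d_tot = traj["drug_free"] + traj["complex"]
        v_tot = traj["vegf_free"] + traj["complex"]
        assert np.ptp(d_tot) / 10.0 < 1e-6
        assert np.ptp(v_tot) / 17.0 < 1e-6

    def test_vehicle_decays_exponentially(self, afl_params):
        traj = simulate_binding_kinetics(0.0, 17.0, afl_params, 2.0, mode="ode")
        expect = 17.0 * np.exp(-afl_params.k_el_vegf * traj["time"])
        np.testing.assert_allclose(traj["vegf_free"], expect, rtol=1e-6, atol=1e-9)

    @pytest.mark.parametrize("drug0", [0.5, 2.0, 5.0])
    def test_quasi_equilibrium_matches_full_ode(self, afl_params, drug0):
        """At diffusion-limited k_on the quasi-equilibrium trajectory agrees
        with the stiff ODE to within 1% of the free-VEGF AUC."""
        qe = simulate_binding_kinetics(drug0, 17.45, afl_params, 2.0,
                                       mode="quasi_equilibrium", n_grid=2001)
        od = simulate_binding_kinetics(drug0, 17.45, afl_params, 2.0,
                                       mode="ode", n_grid=2001)
        auc_qe = np.trapezoid(qe["vegf_free"], qe["time"])
        auc_od = np.trapezoid(od["vegf_free"], od["time"])
        assert auc_qe == pytest.approx(auc_od, rel=0.01)

    def test_nonnegative_trajectories(self, afl_params):
        for mode in ("quasi_equilibrium", "ode"):
            traj = simulate_binding_kinetics(50.0, 17.45, afl_params, 2.0, mode=mode)
            for col in ("drug_free", "vegf_free", "complex"):
                assert (traj[col] >= 0).all()

    def test_negative_initial_state_rejected(self, afl_params):
        with pytest.raises(ConfigError):
            simulate_binding_kinetics(-1.0, 10.0, afl_params, 1.0)


class TestPercentFreeVEGF:
    def test_vehicle_is_100_percent(self, config, afl_params):
        res = percent_free_vegf(config.agent("aflibercept"), 0.0, config.design,
                                afl_params, config.geometry)
        assert res.percent_free == pytest.approx(100.0, rel=1e-12)

    def test_large_drug_excess_captures_everything(self, config, afl_params):
        afl = config.agent("aflibercept")
        c0 = afl.initial_site_concentration_nm(config.geometry.vitreous_volume)
        res = percent_free_vegf(afl, c0, config.design, afl_params, config.geometry)
        assert res.percent_free < 0.1

    def test_tenfold_site_excess_below_ten_percent(self, config):
        """Ten-fold drug site excess with K_D far below the VEGF level must
        suppress free VEGF below 10% (equilibrium bound)."""
        afl = config.agent("aflibercept")
        params = kinetics_params_for_agent(afl, config.design)
        vegf0 = config.design.vegf_site_concentration_nm(config.geometry.vitreous_volume)
        res = percent_free_vegf(afl, 10 * vegf0, config.design, params,
                                config.geometry)
        assert res.percent_free < 10.0

    def test_monotone_decreasing_in_drug(self, config, afl_params):
        afl = config.agent("aflibercept")
        pf = [percent_free_vegf(afl, d, config.design, afl_params,
                                config.geometry).percent_free
              for d in (0.0, 1.0, 5.0, 20.0, 100.0)]
        assert all(a >= b for a, b in zip(pf, pf[1:]))

    def test_monotone_increasing_in_kd(self, config):
        afl = config.agent("aflibercept")
        pf = []
        for kd_scale in (1.0, 1e3, 1e6):
            weak = afl.model_copy(update={"kd_assay": afl.kd_assay * kd_scale})
            params = kinetics_params_for_agent(weak, config.design,
                                               drug_t_half_days=5.63)
            pf.append(percent_free_vegf(weak, 30.0, config.design, params,
                                        config.geometry).percent_free)
        assert pf[0] < pf[1] < pf[2]


class TestProtectionTimecourse:
    def test_rank_order_of_protection_loss(self, config, model):
        """First challenge day with p ≥ 0.5 is latest for aflibercept and
        earliest for ranibizumab."""
        crossing = {}
        grid = np.arange(5.0, 80.0, 1.0)
        for agent in config.agents:
            tc = protection_timecourse(agent, config.geometry, config.design,
                                       model, challenge_days=grid)
            above = tc["probability"].to_numpy() >= 0.5
            crossing[agent.name] = grid[np.argmax(above)]
        assert crossing["ranibizumab"] < crossing["brolucizumab"] \
            < crossing["aflibercept"]

    def test_day_zero_challenge_is_protected(self, config, model):
        for agent in config.agents:
            tc = protection_timecourse(agent, config.geometry, config.design,
                                       model, challenge_days=[0.0])
            assert tc["probability"].iloc[0] < 0.2

    def test_vehicle_probability_is_logistic_of_100(self, model):
        assert model.predict(100.0) == pytest.approx(0.85, abs=0.02)

    def test_rank_invariance_under_half_life_perturbation(self, config, model):
        """The protection-duration ordering survives ±25% perturbation of
        all vitreal half-lives."""
        from ocuvegf.config import OBSERVED_HALF_LIVES_DAYS
        grid = np.arange(10.0, 80.0, 2.0)
        for scale in (0.75, 1.25):
            crossing = {}
            for agent in config.agents:
                th = OBSERVED_HALF_LIVES_DAYS[agent.name] * scale
                tc = protection_timecourse(agent, config.geometry, config.design,
                                           model, t_half_days=th,
                                           challenge_days=grid)
                above = tc["probability"].to_numpy() >= 0.5
                crossing[agent.name] = grid[np.argmax(above)]
            assert crossing["ranibizumab"] < crossing["brolucizumab"] \
                < crossing["aflibercept"]

    def test_drug_decay_helper(self, config):
        afl = config.agent("aflibercept")
        c0 = afl.initial_site_concentration_nm(1.5)
        assert drug_sites_at_day(afl, 5.63, 5.63, config.geometry) == \
            pytest.approx(c0 / 2, rel=1e-12)


class TestDesignWindow:
    def test_window_overlaps_reported_range(self, config, model):
        w = find_design_window(config.agents, config.geometry, config.design, model)
        assert not w.empty
        assert w.overlaps(21, 49)

    def test_identical_agents_empty_window(self, config, model):
        afl = config.agent("aflibercept")
        w = find_design_window([afl, afl.model_copy()], config.geometry,
                               config.design, model)
        assert w.empty

    def test_margin_monotonicity(self, config, model):
        grid = np.arange(5.0, 80.0, 2.5)
        w0 = find_design_window(config.agents, config.geometry, config.design,
                                model, margin=0.0, day_grid=grid)
        w1 = find_design_window(config.agents, config.geometry, config.design,
                                model, margin=0.15, day_grid=grid)
        assert not w0.empty and not w1.empty
        assert (w1.end_day - w1.start_day) <= (w0.end_day - w0.start_day)
        assert w0.start_day <= w1.start_day and w1.end_day <= w0.end_day
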