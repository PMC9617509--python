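"""Ocular PK: size-scaling half-life prediction, simulation, and NCA."""

import numpy as np
import pytest

from ocuvegf.config import ASSAY_LLOQ_UG_PER_ML, default_study_config
from ocuvegf.errors import ConfigError, NCAError
from ocuvegf.pk import (
    ConcentrationProfile,
    PkModelParams,
    hydrodynamic_radius,
    nca,
    pool_profiles,
    predict_vitreal_half_life,
    profile_from_frame,
    simulate_profile,
)
from ocuvegf.synthetic import SyntheticStudySpec, generate_vitreous_pk_dataset


class TestHydrodynamicRadius:
    def test_cube_root_scaling_law(self):
        assert hydrodynamic_radius(8.0) == pytest.approx(2 * hydrodynamic_radius(1.0))

    def test_brolucizumab_ranibizumab_radius_ratio(self):
        # (26/48)^(1/3) ≈ 0.8152
        ratio = hydrodynamic_radius(26.0) / hydrodynamic_radius(48.0)
        assert ratio == pytest.approx((26 / 48) ** (1 / 3), rel=1e-12)
        assert ratio == pytest.approx(0.8152, abs=5e-4)

    def test_prefactor_linear(self):
        assert hydrodynamic_radius(50, prefactor=1.32) == pytest.approx(
            2 * hydrodynamic_radius(50, prefactor=0.66))

    def test_nonpositive_mw(self):
        with pytest.raises(ConfigError):
            hydrodynamic_radius(0.0)


class TestHalfLifePrediction:
    def test_anchored_brolucizumab_prediction(self, config):
        """Calibrated to the ranibizumab prediction of 3.8 days, the 26 kDa
        scFv is predicted at ≈3.1 days."""
        broluc = config.agent("brolucizumab")
        t = predict_vitreal_half_life(broluc, config.geometry, anchor=(48.0, 3.8))
        assert t == pytest.approx(3.8 * (26 / 48) ** (1 / 3), rel=1e-6)
        assert round(t, 1) == 3.1

    def test_monotone_in_molecular_weight(self, config):
        geometry = config.geometry
        agents = sorted(config.agents, key=lambda a: a.molecular_weight)
        t_halves = [predict_vitreal_half_life(a, geometry, anchor=(48.0, 3.8))
                    for a in agents]
        assert t_halves == sorted(t_halves)

    def test_predicted_rank_matches_observed_rank(self, config):
        """aflibercept > ranibizumab > brolucizumab, as in the observed
        vitreal half-lives (5.63 > 3.15 > 3.10 days)."""
        t = {a.name: predict_vitreal_half_life(a, config.geometry, anchor=(48.0, 3.8))
             for a in config.agents}
        assert t["aflibercept"] > t["ranibizumab"] > t["brolucizumab"]

    def test_radius_doubling_doubles_half_life(self, config):
        afl = config.agent("aflibercept")
        t1 = predict_vitreal_half_life(
            afl, config.geometry, params=PkModelParams(hydrodynamic_radius=2.0,
                                                       geometry_factor=1e-3))
        t2 = predict_vitreal_half_life(
            afl, config.geometry, params=PkModelParams(hydrodynamic_radius=4.0,
                                                       geometry_factor=1e-3))
        assert t2 == pytest.approx(2 * t1, rel=1e-9)

    def test_fast_aqueous_outflow_leaves_transfer_rate_limiting(self, config):
        """When aqueous turnover is effectively instantaneous the half-life
        equals the one-compartment closed form ln2/k_vt."""
        afl = config.agent("aflibercept")
        k_vt = 0.1
        t = predict_vitreal_half_life(
            afl, config.geometry,
            params=PkModelParams(transfer_rate_vit_to_aq=k_vt,
                                 aqueous_elimination_rate=1e6))
        assert t == pytest.approx(np.log(2) / k_vt, rel=1e-9)

    def test_missing_calibration_raises(self, config):
        with pytest.raises(ConfigError):
            predict_vitreal_half_life(config.agent("aflibercept"), config.geometry)


class TestSimulateProfile:
    def test_noiseless_exact_decay(self, config):
        afl = config.agent("aflibercept")
        prof = simulate_profile(afl, t_half=5.0, schedule=[1, 5, 10], volume_ml=1.5)
        c0 = 1000 / 1.5
        np.testing.assert_allclose(
            prof.concentrations, c0 * 2.0 ** (-prof.times / 5.0), rtol=1e-12)

    def test_lloq_above_c0_flags_everything(self, config):
        afl = config.agent("aflibercept")
        prof = simulate_profile(afl, 5.0, [1, 2, 3], lloq=1e6)
        assert prof.below_lloq_flags.all()

    def test_seed_determinism(self, config):
        afl = config.agent("aflibercept")
        a = simulate_profile(afl, 5.0, [1, 2, 3], noise_cv=0.2, seed=42)
        b = simulate_profile(afl, 5.0, [1, 2, 3], noise_cv=0.2, seed=42)
        np.testing.assert_array_equal(a.concentrations, b.concentrations)


class TestNCA:
    def test_noiseless_monoexponential_closed_form(self, config):
        """AUC_inf = C0·t½/ln2, recovered t½ and C0 exact."""
        afl = config.agent("aflibercept")
        prof = simulate_profile(afl, t_half=5.0, schedule=np.arange(1.0, 11),
                                c0_ug_per_ml=100.0)
        res = nca(prof, dose_ug=1000.0)
        assert res.t_half == pytest.approx(5.0, rel=1e-9)
        assert res.c0 == pytest.approx(100.0, rel=1e-9)
        assert res.auc == pytest.approx(100 * 5 / np.log(2), rel=1e-9)

    def test_identities_hold(self, spec):
        df = generate_vitreous_pk_dataset(spec)
        for agent in spec.agents:
            prof = profile_from_frame(df, agent.name,
                                      lloq=ASSAY_LLOQ_UG_PER_ML[agent.name])
            res = nca(prof, dose_ug=agent.dose_mass)
            assert res.cl * res.auc == pytest.approx(agent.dose_mass, rel=1e-12)
            assert res.t_half * res.lambda_z == pytest.approx(np.log(2), rel=1e-12)
            assert res.auc > 0 and res.vss > 0

    def test_clearance_from_printed_exposures(self):
        """CL = dose/AUC reproduces the reported clearances to 2 decimals:
        1000/4140 → 0.24 and 250/1180 → 0.21 mL/day."""
        assert round(1000 / 4140, 2) == pytest.approx(0.24)
        assert round(250 / 1180, 2) == pytest.approx(0.21)

    def test_terminal_half_life_recovery_envelope(self, config):
        """Destructive-sampling studies at the observed aflibercept terminal
        half-life recover it closely in the median over seeds."""
        afl = config.agent("aflibercept")
        days = np.repeat([5.0, 26, 33, 40, 54, 56], 7)
        recovered = []
        for s in range(25):
            prof = simulate_profile(afl, 5.63, days, noise_cv=0.15,
                                    lloq=6.25e-3, seed=s, c0_ug_per_ml=942.0)
            recovered.append(nca(prof, dose_ug=1000.0).t_half)
        assert np.median(recovered) == pytest.approx(5.63, rel=0.05)

    def test_too_few_points(self):
        prof = ConcentrationProfile(times=[1.0, 2.0], concentrations=[10.0, 5.0])
        with pytest.raises(NCAError, match="3"):
            nca(prof, dose_ug=100)

    def test_no_terminal_decline(self):
        prof = ConcentrationProfile(times=[1.0, 2, 3, 4],
                                    concentrations=[1.0, 2, 3, 4])
        with pytest.raises(NCAError):
            nca(prof, dose_ug=100)

    def test_lloq_censoring_sets_tlast_boundary(self, config):
        afl = config.agent("aflibercept")
        prof = simulate_profile(afl, t_half=2.0, schedule=np.arange(1.0, 15),
                                c0_ug_per_ml=100.0, lloq=1.0)
        res = nca(prof, dose_ug=1000.0)
        # concentrations fall below 1 µg/mL after ~13.3 days
        assert res.t_last < 14.0
        assert res.c_last >= 1.0

    def test_pooling_geometric_mean(self):
        prof = ConcentrationProfile(times=[1.0, 1.0, 2.0, 2.0],
                                    concentrations=[4.0, 16.0, 2.0, 8.0])
        pooled = pool_profiles(prof)
        np.testing.assert_allclose(pooled.concentrations, [8.0, 4.0])

    def test_pooling_stops_at_majority_censored_day(self):
        prof = ConcentrationProfile(times=[1.0, 1.0, 2.0, 2.0, 3.0, 3.0],
                                    concentrations=[4.0, 6.0, 0.1, 0.2, 5.0, 5.0],
                                    lloq=1.0)
        pooled = pool_profiles(prof)
        assert list(pooled.times) == [1.0]
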