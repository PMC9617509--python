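"""Solution-equilibrium binding model and global N-curve K_D fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from ocuvegf.binding import (
    BindingCurve,
    equilibrium_free_fraction,
    fit_ncurve,
    kd_confidence_interval,
    kinexa_signal,
    read_binding_curves,
    write_binding_curves,
)
from ocuvegf.errors import ConfigError, FitError
from ocuvegf.synthetic import KINEXA_DESIGNS, SyntheticStudySpec, generate_kinexa_dataset


def free_fraction_oracle(i_tot, l_tot, kd):
    """Independent oracle: solve the mass balance by bisection on free
    inhibitor F: F·(L − (I − F)) = K·(I − F)."""
    def balance(f):
        bound = i_tot - f
        free_ligand = l_tot - bound
        return f * free_ligand - kd * bound

    f = brentq(balance, max(i_tot - l_tot, 0.0), i_tot, xtol=1e-30, rtol=1e-15)
    return f / i_tot


class TestFreeFraction:
    def test_no_ligand_all_free(self):
        assert equilibrium_free_fraction(1e-12, 0.0, 1e-13) == pytest.approx(1.0)

    def test_against_bisection_oracle(self):
        # 100 pM inhibitor, 50 pM ligand, K_D 1.3 pM
        got = equilibrium_free_fraction(100e-12, 50e-12, 1.3e-12)
        want = free_fraction_oracle(100e-12, 50e-12, 1.3e-12)
        assert got == pytest.approx(want, rel=1e-10)
        assert got == pytest.approx(0.512, abs=5e-4)

    @pytest.mark.parametrize("i,l,k", [
        (2.5e-12, 1e-10, 1.719e-13),   # tight binding, large excess
        (5e-8, 2e-8, 1e-6),            # weak binding
        (1e-9, 1e-9, 1e-9),            # everything equal
    ])
    def test_oracle_equivalence_across_regimes(self, i, l, k):
        assert equilibrium_free_fraction(i, l, k) == pytest.approx(
            free_fraction_oracle(i, l, k), rel=1e-9)

    def test_weak_binding_limit(self):
        i = 1e-10
        assert equilibrium_free_fraction(i, i, 1e6 * i) == pytest.approx(1.0, abs=1e-3)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-13, -9), st.floats(-14, -8), st.floats(-14, -10))
    def test_monotone_in_ligand_and_kd(self, log_i, log_l, log_k):
        i, l, k = 10.0 ** log_i, 10.0 ** log_l, 10.0 ** log_k
        # decreasing in ligand
        assert equilibrium_free_fraction(i, l * 1.5, k) <= \
            equilibrium_free_fraction(i, l, k) + 1e-12
        # increasing in kd
        assert equilibrium_free_fraction(i, l, k * 1.5) >= \
            equilibrium_free_fraction(i, l, k) - 1e-12

    def test_negative_inputs_rejected(self):
        with pytest.raises(ConfigError):
            equilibrium_free_fraction(-1e-12, 0, 1e-12)
        with pytest.raises(ConfigError):
            equilibrium_free_fraction(1e-12, -1, 1e-12)


class TestKinexaSignal:
    def test_saturation_and_zero_ligand(self):
        t = np.geomspace(1e-15, 1e-6, 20)
        sig = kinexa_signal(1e-12, t, 1e-13, amplitude=1.0, background=0.0)
        assert sig[-1] < 1e-3          # saturating ligand removes signal
        low = kinexa_signal(1e-12, np.array([1e-20]), 1e-13, amplitude=1.0,
                            background=0.2)
        assert low[0] == pytest.approx(1.2, abs=1e-6)   # ≈ background + amplitude

    def test_zero_drift_is_nested_identity(self):
        t = np.geomspace(1e-14, 1e-9, 10)
        a = kinexa_signal(1e-12, t, 1e-12, 0.8, 0.1, drift=0.0)
        b = kinexa_signal(1e-12, t, 1e-12, 0.8, 0.1)
        np.testing.assert_array_equal(a, b)


class TestNCurveFit:
    def test_noiseless_recovery_all_designs(self, spec):
        quiet = SyntheticStudySpec(seed=0, noise_cv_binding=0.0)
        for name, truth in [("aflibercept", 171.9e-15),
                            ("brolucizumab", 1.3e-12),
                            ("ranibizumab", 21.8e-12)]:
            curves = generate_kinexa_dataset(quiet, name)
            fit = fit_ncurve(curves, compute_ci=False)
            assert fit.kd == pytest.approx(truth, rel=1e-2)

    def test_noiseless_recovers_per_curve_parameters(self):
        quiet = SyntheticStudySpec(seed=0, noise_cv_binding=0.0)
        curves = generate_kinexa_dataset(quiet, "aflibercept")
        fit = fit_ncurve(curves, compute_ci=False)
        assert np.allclose(fit.per_curve_amplitude, 1.0, atol=1e-4)
        assert np.allclose(fit.per_curve_background, 0.05, atol=1e-4)

    def test_drift_model_reduces_when_drift_absent(self):
        quiet = SyntheticStudySpec(seed=0, noise_cv_binding=0.0)
        curves = generate_kinexa_dataset(quiet, "aflibercept")
        fit = fit_ncurve(curves, use_drift=True, compute_ci=False)
        assert fit.kd == pytest.approx(171.9e-15, rel=1e-2)
        assert np.allclose(fit.per_curve_drift, 0.0, atol=1e-3)

    def test_flat_curve_raises_fit_error(self):
        t = np.geomspace(1e-14, 1e-9, 10)
        flat = BindingCurve(constant_conc=1e-12, titrant_concs=t,
                            signals=np.full(10, 0.5))
        with pytest.raises(FitError, match="flat|signal"):
            fit_ncurve([flat], compute_ci=False)

    def test_too_few_points_rejected(self):
        t = np.geomspace(1e-13, 1e-10, 4)
        c = BindingCurve(1e-12, t, np.linspace(1, 0.2, 4))
        with pytest.raises(ConfigError):
            fit_ncurve([c])

    def test_three_curves_more_precise_than_one(self):
        """Fitting several constant-concentration curves globally tightens
        the K_D estimate (the rationale for the N-curve analysis)."""
        kds_3, kds_1 = [], []
        for s in range(12):
            sp = SyntheticStudySpec(seed=s, noise_cv_binding=0.04)
            curves = generate_kinexa_dataset(sp, "aflibercept")
            kds_3.append(np.log10(fit_ncurve(curves, compute_ci=False).kd))
            kds_1.append(np.log10(fit_ncurve(curves[:1], compute_ci=False).kd))
        assert np.var(kds_3) < np.var(kds_1)


class TestConfidenceInterval:
    def test_noiseless_interval_collapses(self):
        quiet = SyntheticStudySpec(seed=0, noise_cv_binding=0.0)
        curves = generate_kinexa_dataset(quiet, "aflibercept")
        fit = fit_ncurve(curves)
        assert fit.kd_ci_high / fit.kd_ci_low < 1.01

    def test_interval_brackets_estimate_and_nests(self, spec):
        curves = generate_kinexa_dataset(spec, "aflibercept")
        fit = fit_ncurve(curves)
        lo95, hi95 = kd_confidence_interval(fit, curves, level=0.95)
        lo68, hi68 = kd_confidence_interval(fit, curves, level=0.68)
        assert lo95 <= fit.kd <= hi95
        assert lo95 <= lo68 and hi68 <= hi95

    def test_noisy_interval_same_order_as_reported_range(self):
        """At the aflibercept design with 2% noise the 95% CI spans roughly a
        factor 2-5, the order of the reported 67.8-331.7 fM range."""
        widths = []
        for s in range(5):
            sp = SyntheticStudySpec(seed=s)
            curves = generate_kinexa_dataset(sp, "aflibercept")
            fit = fit_ncurve(curves)
            widths.append(fit.kd_ci_high / fit.kd_ci_low)
        med = np.median(widths)
        assert 1.1 < med < 10.0


class TestCurveIO:
    def test_round_trip(self, tmp_path, spec):
        curves = generate_kinexa_dataset(spec, "ranibizumab")
        path = tmp_path / "curves.csv"
        write_binding_curves(curves, path)
        loaded = read_binding_curves(path)
        assert len(loaded) == len(curves)
        by_id = {c.replicate_id: c for c in curves}
        for lc in loaded:
            orig = by_id[lc.replicate_id]
            np.testing.assert_allclose(lc.titrant_concs, orig.titrant_concs)
            np.testing.assert_allclose(lc.signals, orig.signals)

    def test_designs_match_published_spans(self):
        consts, (lo, hi) = KINEXA_DESIGNS["aflibercept"]
        assert consts == [2.5e-12, 5.0e-12, 50.0e-12]
        assert (lo, hi) == (48.8e-15, 1.0e-9)
        assert len(KINEXA_DESIGNS["ranibizumab"][0]) == 2
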