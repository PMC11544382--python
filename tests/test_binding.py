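"""Binding isotherms, two-carrier competition, K_D fitting, conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fidashift.binding import (
    BindingCurve,
    CarrierMixture,
    apom_equivalent_kd,
    fit_binding_curve,
    isotherm_rapp,
    mass_to_molar_kd,
    mixture_fractions,
    mixture_rapp,
    molar_to_mass_kd,
)


def _titration(k_d, r_free, r_complex, levels, noise_cv=0.0, replicates=3, seed=0):
    rng = np.random.default_rng(seed)
    conc = np.repeat(np.asarray(levels, float), replicates)
    r = isotherm_rapp(conc, k_d, r_free, r_complex)
    if noise_cv > 0:
        r = r * (1 + noise_cv * rng.standard_normal(conc.size))
    return BindingCurve(conc, r, unit="mg/mL")


HSA_LEVELS = (0.0, 0.005, 0.01, 0.02, 0.04, 0.08, 0.15, 0.3, 0.6, 1.2, 2.0, 4.0)
HDL_LEVELS = (0.0, 0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 20.0, 25.0)


class TestIsotherm:
    def test_limits_and_midpoint(self):
        assert isotherm_rapp(0.0, 0.02, 0.9, 3.5) == 0.9
        assert isotherm_rapp(0.02, 0.02, 0.9, 3.5) == pytest.approx((0.9 + 3.5) / 2)
        assert isotherm_rapp(1e9, 0.02, 0.9, 3.5) == pytest.approx(3.5, rel=1e-6)

    @given(c=st.floats(0, 100), k=st.floats(1e-3, 10))
    @settings(max_examples=50, derandomize=True)
    def test_bounded_between_free_and_complex(self, c, k):
        r = isotherm_rapp(c, k, 0.9, 3.5)
        assert 0.9 <= r <= 3.5

    def test_monotone_in_concentration(self):
        c = np.linspace(0, 1, 200)
        r = isotherm_rapp(c, 0.02, 0.9, 3.5)
        assert np.all(np.diff(r) > 0)


class TestBindingCurveFit:
    def test_noise_free_exact_recovery(self):
        curve = _titration(0.020, 0.9, 3.5, HSA_LEVELS, replicates=1)
        fit = fit_binding_curve(curve)
        assert fit.k_d == pytest.approx(0.020, rel=1e-6)
        assert fit.r_free == pytest.approx(0.9, rel=1e-6)
        assert fit.r_complex == pytest.approx(3.5, rel=1e-6)

    @pytest.mark.parametrize("k_d,r_complex,levels", [
        (0.020, 3.5, HSA_LEVELS),   # HSA-scale affinity
        (1.25, 5.5, HDL_LEVELS),    # HDL-protein-scale affinity
    ])
    def test_recovery_at_one_percent_noise(self, k_d, r_complex, levels):
        curve = _titration(k_d, 0.9, r_complex, levels, noise_cv=0.01, seed=3)
        fit = fit_binding_curve(curve)
        assert fit.converged
        assert fit.k_d == pytest.approx(k_d, rel=0.10)

    def test_recovery_bias_and_rmse_over_seeds(self):
        """Bias < 5% and RMSE < 15% over 100 seeded 1%-noise titrations."""
        estimates = []
        for seed in range(100):
            curve = _titration(0.020, 0.9, 3.5, HSA_LEVELS, noise_cv=0.01,
                               seed=seed)
            estimates.append(fit_binding_curve(curve).k_d)
        rel = (np.array(estimates) - 0.020) / 0.020
        assert abs(rel.mean()) < 0.05
        assert math.sqrt(np.mean(rel ** 2)) < 0.15

    def test_optimizer_agrees_with_grid_search_oracle(self):
        """Brute-force RSS grid over (K_D, r_complex) locates the same minimum."""
        curve = _titration(0.020, 0.9, 3.5, HSA_LEVELS, noise_cv=0.01,
                           replicates=1, seed=11)  # unweighted objective
        fit = fit_binding_curve(curve)
        kds = np.geomspace(0.002, 0.2, 120)
        rcs = np.linspace(3.0, 4.0, 120)
        best = (None, np.inf)
        for kd in kds:
            for rc in rcs:
                pred = isotherm_rapp(curve.conc, kd, fit.r_free, rc)
                rss = float(np.sum((pred - curve.r_app) ** 2))
                if rss < best[1]:
                    best = ((kd, rc), rss)
        (kd_g, rc_g), _ = best
        # within one grid cell of the optimizer's solution
        assert abs(math.log(kd_g / fit.k_d)) <= math.log(kds[1] / kds[0])
        assert abs(rc_g - fit.r_complex) <= rcs[1] - rcs[0]

    def test_flat_response_flagged(self):
        curve = BindingCurve(np.array(HSA_LEVELS), np.zeros(len(HSA_LEVELS)))
        fit = fit_binding_curve(curve)
        assert not fit.converged
        assert math.isnan(fit.k_d)
        assert "flat_response" in fit.flags

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            BindingCurve(np.array([0, 1, 2, 3.0]), np.array([1, 2, 3, 4.0]))


class TestMixture:
    def _mix(self, hsa, hdl, alpha=0.0):
        return CarrierMixture(hsa_conc=hsa, hdl_protein_conc=hdl,
                              capmix_hdl_attenuation=alpha)

    def test_capmix_invariant_to_hdl_with_zero_attenuation(self):
        lo = mixture_rapp(self._mix(4.0, 0.01), "capillary_mix")
        hi = mixture_rapp(self._mix(4.0, 0.05), "capillary_mix")
        assert lo == hi

    def test_capmix_drops_with_low_albumin(self):
        assert mixture_rapp(self._mix(1.0, 0.05), "capillary_mix") < \
            mixture_rapp(self._mix(4.0, 0.05), "capillary_mix")

    def test_capdis_responds_to_both_carriers(self):
        r = {(a, h): mixture_rapp(self._mix(a, h), "complex_dissociation")
             for a in (1.0, 4.0) for h in (0.01, 0.05)}
        assert r[(4.0, 0.05)] > r[(4.0, 0.01)]
        assert r[(1.0, 0.05)] > r[(1.0, 0.01)]
        assert r[(1.0, 0.05)] < r[(4.0, 0.05)]

    def test_no_carriers_gives_free_radius(self):
        mix = self._mix(0.0, 0.0)
        assert mixture_rapp(mix, "complex_dissociation") == mix.r_free

    @given(a=st.floats(0, 50), h=st.floats(0, 5), alpha=st.floats(0, 1))
    @settings(max_examples=100, derandomize=True)
    def test_fractions_sum_to_one(self, a, h, alpha):
        mix = self._mix(a, h, alpha)
        for method in ("capillary_mix", "complex_dissociation"):
            assert sum(mixture_fractions(mix, method)) == pytest.approx(1.0,
                                                                        abs=1e-12)

    @given(a=st.floats(0, 50), h=st.floats(0, 5))
    @settings(max_examples=100, derandomize=True)
    def test_rapp_bounded(self, a, h):
        mix = self._mix(a, h, alpha=1.0)
        r = mixture_rapp(mix, "complex_dissociation")
        assert mix.r_free - 1e-12 <= r <= max(mix.r_hsa_complex,
                                              mix.r_hdl_complex) + 1e-12

    def test_reduces_to_isotherm_without_hdl(self):
        mix = self._mix(2.0, 0.0)
        r = mixture_rapp(mix, "complex_dissociation")
        assert r == pytest.approx(
            isotherm_rapp(2.0, mix.k_d_hsa, mix.r_free, mix.r_hsa_complex),
            rel=1e-12)

    def test_unit_mismatch_rejected(self):
        mix = CarrierMixture(hsa_conc=1.0, hdl_protein_conc=0.05,
                             conc_unit="ug/mL", k_d_unit="mg/mL")
        with pytest.raises(ValueError):
            mixture_rapp(mix, "capillary_mix")


class TestUnitConversions:
    def test_hsa_kd_in_molar_units(self):
        # 20 ug/mL at 66.5 kDa -> 300 nM to the nearest 10 nM
        nm = mass_to_molar_kd(0.020, 66_500.0) * 1e9
        assert round(nm / 10) * 10 == 300

    def test_simple_mass_to_molar(self):
        # 1 g/L at 1 kDa -> 1 mM
        assert mass_to_molar_kd(1.0, 1000.0) == pytest.approx(1e-3)

    def test_roundtrip(self):
        m = mass_to_molar_kd(0.37, 21_000.0)
        assert molar_to_mass_kd(m, 21_000.0) == pytest.approx(0.37, rel=1e-12)

    def test_apom_equivalent(self):
        assert round(apom_equivalent_kd(1.25, 30.0, 21_000.0), 1) == 1.8

    def test_apom_linearity(self):
        assert apom_equivalent_kd(2.5, 30.0, 21_000.0) == \
            pytest.approx(3.6, abs=0.05)

    def test_apom_reduces_to_mass_conversion_at_unit_fraction(self):
        full = apom_equivalent_kd(1.25, 1000.0, 21_000.0)
        assert full == pytest.approx(mass_to_molar_kd(1.25, 21_000.0) * 1e6,
                                     rel=1e-12)

    def test_zero_molar_mass_rejected(self):
        with pytest.raises(ValueError):
            mass_to_molar_kd(1.0, 0.0)
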