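"""Peak fitting, baseline correction, PDI, and signal-to-noise."""

import math

import numpy as np
import pytest

from fidashift.fitting import (
    FitReport,
    SpeciesFit,
    classify_dispersity,
    compute_pdi,
    compute_snr,
    correct_baseline,
    fit_single_species,
    fit_two_species,
)
from fidashift.physics import (
    Species,
    Taylorgram,
    noise_sd_for_snr,
    simulate_taylorgram,
)


def _report(fractions_radii) -> FitReport:
    species = [SpeciesFit(120.0, 5.0, 1.0, f, 1e-10, r) for f, r in fractions_radii]
    return FitReport(species=species, baseline=(0, 0), pdi=0.0, snr=100.0,
                     snr_interpretable=True, rss=0.0, converged=True)


class TestBaselineCorrection:
    def test_pure_line_corrected_to_zero(self):
        t = np.linspace(0, 240, 1000)
        tg = Taylorgram(t, 5.0 + 0.01 * t)
        out = correct_baseline(tg)
        assert np.max(np.abs(out.signal)) < 1e-9 * 5.0

    def test_recovers_simulated_drift(self, capillary, capmix):
        tg = simulate_taylorgram([Species(3.5, 1.0)], capmix, capillary,
                                 baseline=(2.0, 0.005))
        out = correct_baseline(tg)
        offset, slope = out.meta["baseline_fit"]
        assert offset == pytest.approx(2.0, rel=0.01)
        assert slope == pytest.approx(0.005, rel=0.01)

    def test_idempotent(self, noisy_trace):
        once = correct_baseline(noisy_trace)
        twice = correct_baseline(once)
        scale = np.max(np.abs(once.signal))
        assert np.max(np.abs(twice.signal - once.signal)) < 1e-9 * scale

    def test_window_covering_trace_rejected(self, clean_trace):
        with pytest.raises(ValueError):
            correct_baseline(clean_trace, exclusion_window=1e6)


class TestSingleSpeciesFit:
    def test_noise_free_recovery(self, clean_trace, capillary):
        fit = fit_single_species(clean_trace, capillary)
        assert fit.converged
        assert fit.species[0].r_h == pytest.approx(3.5, rel=1e-3)

    def test_noise_free_exact_without_baseline_step(self, clean_trace, capillary):
        fit = fit_single_species(clean_trace, capillary, baseline_correct=False)
        assert fit.species[0].r_h == pytest.approx(3.5, rel=1e-6)
        assert fit.species[0].t_r == pytest.approx(capillary.t_r, rel=1e-6)

    def test_fit_matches_trace_moments(self, clean_trace, capillary):
        """On noise-free input the Gaussian fit equals the brute-force moments."""
        t, s = clean_trace.time, clean_trace.signal
        mean = float(np.sum(t * s) / np.sum(s))
        var = float(np.sum((t - mean) ** 2 * s) / np.sum(s))
        fit = fit_single_species(clean_trace, capillary, baseline_correct=False)
        assert fit.species[0].t_r == pytest.approx(mean, rel=1e-6)
        assert fit.species[0].sigma_t == pytest.approx(math.sqrt(var), rel=1e-6)

    def test_triplicate_cv_below_precision_envelope(self, capillary, capmix):
        """CV of fitted radii at S/N 100 stays within the assay's precision."""
        mix = [Species(3.5, 1.0)]
        noise = noise_sd_for_snr(mix, capmix, capillary, snr=100.0)
        radii = []
        for seed in (11, 12, 13):
            tg = simulate_taylorgram(mix, capmix, capillary, noise_sd=noise,
                                     seed=seed)
            radii.append(fit_single_species(tg, capillary).species[0].r_h)
        cv = np.std(radii, ddof=1) / np.mean(radii)
        assert cv < 0.02

    def test_parameter_recovery_across_size_range(self, capillary, capmix):
        """Median relative error < 2% over seeded simulations, r_h in [1, 12] nm."""
        rng = np.random.default_rng(2024)
        errors = []
        for k in range(200):
            r_true = float(rng.uniform(1.0, 12.0))
            mix = [Species(r_true, 1.0)]
            noise = noise_sd_for_snr(mix, capmix, capillary, snr=30.0)
            tg = simulate_taylorgram(mix, capmix, capillary, noise_sd=noise,
                                     seed=int(rng.integers(2 ** 31)))
            fit = fit_single_species(tg, capillary)
            errors.append(abs(fit.species[0].r_h - r_true) / r_true)
        assert np.median(errors) < 0.02

    def test_fit_simulate_fit_closure(self, noisy_trace, capillary, capmix):
        first = fit_single_species(noisy_trace, capillary)
        resim = simulate_taylorgram([Species(first.species[0].r_h, 1.0)],
                                    capmix, capillary)
        second = fit_single_species(resim, capillary)
        assert second.species[0].r_h == pytest.approx(first.species[0].r_h,
                                                      rel=1e-3)


class TestTwoSpeciesFit:
    def test_recovers_ninety_ten_mixture(self, capillary, capdis):
        tg = simulate_taylorgram([Species(3.5, 0.9), Species(1.0, 0.1)],
                                 capdis, capillary)
        fit = fit_two_species(tg, capillary)
        assert not fit.degenerate
        # sorted ascending by radius: free indicator first
        assert fit.species[0].r_h < fit.species[1].r_h
        assert fit.species[0].area_fraction == pytest.approx(0.1, abs=0.01)
        assert fit.species[1].area_fraction == pytest.approx(0.9, abs=0.01)
        assert fit.free_indicator_fraction == pytest.approx(0.1, abs=0.01)

    def test_single_species_trace_flagged_degenerate(self, clean_trace, capillary):
        fit = fit_two_species(clean_trace, capillary)
        assert fit.degenerate
        assert len(fit.species) == 1  # fell back to the single-species fit

    def test_never_fits_worse_than_single(self, noisy_trace, capillary):
        single = fit_single_species(noisy_trace, capillary)
        two = fit_two_species(noisy_trace, capillary)
        assert two.rss <= single.rss * (1 + 1e-9)

    def test_fixed_free_radius(self, capillary, capdis):
        tg = simulate_taylorgram([Species(3.5, 0.85), Species(0.9, 0.15)],
                                 capdis, capillary)
        fit = fit_two_species(tg, capillary, r_h_free_fixed=0.9)
        assert fit.species[0].r_h == pytest.approx(0.9, rel=1e-9)
        assert fit.species[0].area_fraction == pytest.approx(0.15, abs=0.01)


class TestPDI:
    def test_single_species_is_zero(self):
        assert compute_pdi(_report([(1.0, 3.5)])) == 0.0

    def test_hand_evaluated_two_species_value(self):
        # 50/50 at 2 and 6 nm: rbar = 4, pdi = (0.5*4 + 0.5*4) / 16 = 0.25
        assert compute_pdi(_report([(0.5, 2.0), (0.5, 6.0)])) == \
            pytest.approx(0.25, rel=1e-12)

    def test_invariant_to_amplitude_scaling(self):
        rep = _report([(0.3, 2.0), (0.7, 5.0)])
        scaled = _report([(0.3, 2.0), (0.7, 5.0)])
        for s in scaled.species:
            object.__setattr__(s, "amplitude", s.amplitude * 37.0)
        assert compute_pdi(rep) == compute_pdi(scaled)

    def test_monodispersity_threshold(self):
        assert classify_dispersity(0.49) == "monodisperse"
        assert classify_dispersity(0.5) == "polydisperse"


class TestSNR:
    def test_definition(self, capillary, capmix):
        mix = [Species(3.5, 1.0)]
        noise = noise_sd_for_snr(mix, capmix, capillary, snr=100.0)
        tg = simulate_taylorgram(mix, capmix, capillary, noise_sd=noise, seed=5)
        snr, interpretable = compute_snr(tg)
        assert snr == pytest.approx(100.0, rel=0.15)
        assert interpretable

    def test_noise_free_reports_infinity(self, clean_trace):
        snr, interpretable = compute_snr(clean_trace)
        assert math.isinf(snr) and interpretable
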