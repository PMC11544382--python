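"""Taylorgram fitting: hydrodynamic radii, polydispersity, signal-to-noise.

Peaks are modelled as Gaussians centred on the shared residence time.  The
single-species fit estimates (amplitude, t_R, sigma); the two-species fit
shares the centre and estimates two widths and amplitudes.  Fitted widths
convert to diffusion coefficients by inverting the Taylor-Aris variance and
to hydrodynamic radii through Stokes-Einstein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .physics import (
    CapillarySetup,
    Taylorgram,
    diffusion_from_sigma,
    sigma_t_from_rh,
    stokes_einstein,
)

__all__ = [
    "SpeciesFit",
    "FitReport",
    "correct_baseline",
    "fit_single_species",
    "fit_two_species",
    "compute_pdi",
    "classify_dispersity",
    "compute_snr",
    "FitConfig",
]

#: PDI below this value counts as a monodisperse solution.
PDI_MONODISPERSE_THRESHOLD = 0.5

#: S/N at or above this value counts as interpretable.
SNR_INTERPRETABLE_THRESHOLD = 30.0

#: Two fitted widths whose ratio is below this are considered unresolved.
SIGMA_DEGENERACY_RATIO = 1.05


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for the peak fits."""

    ftol: float = 1e-12          # relative RSS change tolerance
    xtol: float = 1e-12
    max_nfev: int = 2000
    n_restarts: int = 3          # jittered restarts, best RSS wins
    restart_jitter: float = 0.05
    seed: int = 0
    exclusion_sigmas: float = 4.0  # baseline window half-width, in initial sigma
    detection_snr: float = 3.0     # min component amplitude, in noise SDs


@dataclass(frozen=True)
class SpeciesFit:
    """Fitted parameters of one Gaussian component and derived size."""

    t_r: float
    sigma_t: float
    amplitude: float
    area_fraction: float
    d: float
    r_h: float


@dataclass
class FitReport:
    species: list[SpeciesFit]
    baseline: tuple[float, float]
    pdi: float
    snr: float
    snr_interpretable: bool
    rss: float
    converged: bool
    degenerate: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def r_h(self) -> float:
        """Area-weighted mean hydrodynamic radius, nm."""
        return float(sum(s.area_fraction * s.r_h for s in self.species))

    @property
    def free_indicator_fraction(self) -> float | None:
        """Area fraction of the smallest-radius species (None if single)."""
        if len(self.species) < 2:
            return None
        return self.species[0].area_fraction

    def to_dict(self) -> dict:
        return {
            "species": [
                {
                    "t_r_s": s.t_r,
                    "sigma_t_s": s.sigma_t,
                    "amplitude_au": s.amplitude,
                    "area_fraction": s.area_fraction,
                    "d_m2_s": s.d,
                    "r_h_nm": s.r_h,
                }
                for s in self.species
            ],
            "baseline_offset_au": self.baseline[0],
            "baseline_slope_au_s": self.baseline[1],
            "r_h_nm": self.r_h,
            "pdi": self.pdi,
            "snr": self.snr,
            "snr_interpretable": self.snr_interpretable,
            "rss": self.rss,
            "converged": self.converged,
            "degenerate": self.degenerate,
        }


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _initial_peak_guess(time: np.ndarray, signal: np.ndarray) -> tuple[float, float, float]:
    """(amplitude, center, sigma) moments-free initial guess.

    Center from the argmax, sigma from the full width at half maximum
    (FWHM / 2.3548), amplitude from the peak height.
    """
    i_max = int(np.argmax(signal))
    amp = float(signal[i_max])
    center = float(time[i_max])
    half = amp / 2.0
    above = signal >= half
    if above.any():
        idx = np.flatnonzero(above)
        fwhm = float(time[idx[-1]] - time[idx[0]])
    else:  # pragma: no cover - flat trace
        fwhm = float(time[-1] - time[0]) / 10.0
    sigma = max(fwhm / 2.3548, 2.0 * float(time[1] - time[0]))
    return amp, center, sigma


def _baseline_mask(time: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """True where a sample lies outside the peak exclusion window."""
    return np.abs(time - center) > half_width


def correct_baseline(tg: Taylorgram, exclusion_window: float | None = None,
                     exclusion_sigmas: float = 4.0) -> Taylorgram:
    """Fit and subtract a linear baseline from regions flanking the peak.

    A straight line is least-squares fitted to all samples farther than
    ``exclusion_window`` seconds (default: ``exclusion_sigmas`` times the
    initial width estimate) from the peak apex and subtracted from the whole
    trace.  The fitted (offset, slope) are recorded in ``meta['baseline_fit']``.
    """
    time, signal = tg.time, tg.signal
    # locate the peak on a detrended copy so a strong drift cannot masquerade
    # as the apex
    pre = np.polyfit(time, signal, deg=1)
    detrended = signal - np.polyval(pre, time)
    amp0, center, sigma0 = _initial_peak_guess(time, detrended)
    if amp0 <= 0.0:
        # no discernible peak: the whole trace is baseline
        mask = np.ones(time.size, dtype=bool)
    else:
        if exclusion_window is None:
            exclusion_window = exclusion_sigmas * sigma0
        mask = _baseline_mask(time, center, exclusion_window)
        n_left = int(np.sum(mask & (time < center)))
        n_right = int(np.sum(mask & (time > center)))
        if n_left < 10 or n_right < 10:
            raise ValueError(
                "baseline correction needs >= 10 samples outside the exclusion "
                f"window on each side (got {n_left} left, {n_right} right)"
            )
    coeffs = np.polyfit(time[mask], signal[mask], deg=1)
    corrected = signal - np.polyval(coeffs, time)
    out = tg.copy()
    out.signal = corrected
    out.meta["baseline_fit"] = (float(coeffs[1]), float(coeffs[0]))  # (offset, slope)
    out.meta["baseline_mask"] = mask
    return out


def compute_snr(tg: Taylorgram, exclusion_sigmas: float = 4.0) -> tuple[float, bool]:
    """Signal-to-noise: corrected peak amplitude over baseline residual SD.

    Returns ``(snr, interpretable)``; a noise-free trace yields ``inf`` with
    the interpretable flag set.
    """
    corrected = correct_baseline(tg, exclusion_sigmas=exclusion_sigmas)
    amp = float(np.max(corrected.signal))
    # noise region well clear of the peak so Gaussian tails do not register
    _, center, sigma0 = _initial_peak_guess(corrected.time, corrected.signal)
    far = _baseline_mask(corrected.time, center, 1.5 * exclusion_sigmas * sigma0)
    if not far.any():
        far = corrected.meta["baseline_mask"]
    noise = float(np.std(corrected.signal[far]))
    if noise == 0.0 or amp / max(noise, 1e-300) > 1e6:
        return math.inf, True
    snr = amp / noise
    return snr, snr >= SNR_INTERPRETABLE_THRESHOLD


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def _species_from_params(t_r: float, sigma: float, amp: float, area_fraction: float,
                         capillary: CapillarySetup) -> SpeciesFit:
    d = diffusion_from_sigma(sigma, t_r, capillary.r_c)
    r_h = stokes_einstein(d, capillary.temperature, capillary.viscosity)
    return SpeciesFit(t_r=t_r, sigma_t=sigma, amplitude=amp,
                      area_fraction=area_fraction, d=d, r_h=r_h)


def _restart_fit(residual, p0: np.ndarray, config: FitConfig) -> tuple[np.ndarray, float, bool]:
    """Run jittered restarts of a least-squares fit, keep the lowest RSS."""
    rng = np.random.default_rng(config.seed)
    best = None
    for k in range(config.n_restarts):
        start = p0 if k == 0 else p0 * (1.0 + config.restart_jitter
                                        * rng.standard_normal(p0.size))
        try:
            res = least_squares(residual, start, ftol=config.ftol,
                                xtol=config.xtol, max_nfev=config.max_nfev)
        except Exception:  # pragma: no cover - optimizer blow-up
            continue
        rss = 2.0 * res.cost
        if best is None or rss < best[1]:
            best = (res.x, rss, bool(res.success))
    if best is None:
        return p0, float("inf"), False
    return best


def fit_single_species(tg: Taylorgram, capillary: CapillarySetup | None = None,
                       config: FitConfig | None = None,
                       baseline_correct: bool = True) -> FitReport:
    """Fit one Gaussian A exp(-(t - t_R)^2 / (2 sigma^2)) to a Taylorgram.

    The width is parameterized as log(sigma), so a negative width is
    impossible.  Non-convergence is flagged in the report, never raised.
    """
    capillary = capillary or CapillarySetup()
    config = config or FitConfig()
    snr, interpretable = compute_snr(tg, config.exclusion_sigmas)
    work = correct_baseline(tg, exclusion_sigmas=config.exclusion_sigmas) \
        if baseline_correct else tg
    baseline = work.meta.get("baseline_fit", (0.0, 0.0))
    time, signal = work.time, work.signal

    amp0, center0, sigma0 = _initial_peak_guess(time, signal)
    p0 = np.array([amp0, center0, math.log(sigma0)])

    def residual(p):
        amp, t_r, log_sigma = p
        sigma = math.exp(log_sigma)
        return amp * np.exp(-((time - t_r) ** 2) / (2 * sigma ** 2)) - signal

    p, rss, converged = _restart_fit(residual, p0, config)
    amp, t_r, sigma = float(p[0]), float(p[1]), float(math.exp(p[2]))
    sp = _species_from_params(t_r, sigma, amp, 1.0, capillary)
    return FitReport(species=[sp], baseline=baseline, pdi=0.0, snr=snr,
                     snr_interpretable=interpretable, rss=rss, converged=converged)


def fit_two_species(tg: Taylorgram, capillary: CapillarySetup | None = None,
                    r_h_free_fixed: float | None = None,
                    config: FitConfig | None = None,
                    baseline_correct: bool = True) -> FitReport:
    """Fit two shared-centre Gaussians with distinct widths.

    Intended for resolving a small free-indicator component next to the
    carrier complex.  When ``r_h_free_fixed`` is given, the smaller species'
    width is pinned to the width implied by that radius.  If the two fitted
    widths are indistinguishable (ratio < 1.05) the result is flagged
    degenerate and the single-species fit is returned in its place (with the
    degenerate flag kept).  Output species are sorted by ascending r_h.
    """
    capillary = capillary or CapillarySetup()
    config = config or FitConfig()
    single = fit_single_species(tg, capillary, config, baseline_correct)
    work = correct_baseline(tg, exclusion_sigmas=config.exclusion_sigmas) \
        if baseline_correct else tg
    baseline = work.meta.get("baseline_fit", (0.0, 0.0))
    time, signal = work.time, work.signal

    amp0 = single.species[0].amplitude
    t_r0 = single.species[0].t_r
    sigma0 = single.species[0].sigma_t

    if r_h_free_fixed is not None:
        sigma_free = sigma_t_from_rh(r_h_free_fixed, capillary)

        def residual(p):
            t_r, a1, a2, log_s2 = p
            s2 = math.exp(log_s2)
            g1 = a1 * np.exp(-((time - t_r) ** 2) / (2 * sigma_free ** 2))
            g2 = a2 * np.exp(-((time - t_r) ** 2) / (2 * s2 ** 2))
            return g1 + g2 - signal

        p0 = np.array([t_r0, 0.1 * amp0, 0.9 * amp0, math.log(sigma0)])
        p, rss, converged = _restart_fit(residual, p0, config)
        t_r = float(p[0])
        comps = [(sigma_free, float(p[1])), (float(math.exp(p[3])), float(p[2]))]
    else:
        def residual(p):
            t_r, a1, a2, log_s1, log_s2 = p
            s1, s2 = math.exp(log_s1), math.exp(log_s2)
            g1 = a1 * np.exp(-((time - t_r) ** 2) / (2 * s1 ** 2))
            g2 = a2 * np.exp(-((time - t_r) ** 2) / (2 * s2 ** 2))
            return g1 + g2 - signal

        p0 = np.array([t_r0, 0.1 * amp0, 0.9 * amp0,
                       math.log(0.5 * sigma0), math.log(1.05 * sigma0)])
        p, rss, converged = _restart_fit(residual, p0, config)
        t_r = float(p[0])
        comps = [(float(math.exp(p[3])), float(p[1])),
                 (float(math.exp(p[4])), float(p[2]))]

    sigmas = sorted(s for s, _ in comps)
    degenerate = sigmas[1] / sigmas[0] < SIGMA_DEGENERACY_RATIO
    # a component below the detection limit is noise, not a species
    noise_sd = float(np.std(signal[work.meta["baseline_mask"]])) \
        if "baseline_mask" in work.meta else 0.0
    if noise_sd > 0 and any(abs(a) < config.detection_snr * noise_sd
                            for _, a in comps):
        degenerate = True
    if degenerate or rss > single.rss:
        # fall back to the (never worse) single-species description
        out = FitReport(species=list(single.species), baseline=baseline,
                        pdi=0.0, snr=single.snr,
                        snr_interpretable=single.snr_interpretable,
                        rss=min(rss, single.rss), converged=single.converged,
                        degenerate=True)
        return out

    areas = [abs(a) * s * math.sqrt(2 * math.pi) for s, a in comps]
    total = sum(areas) or 1.0
    species = [
        _species_from_params(t_r, s, a, area / total, capillary)
        for (s, a), area in zip(comps, areas)
    ]
    species.sort(key=lambda sp: sp.r_h)
    report = FitReport(species=species, baseline=baseline, pdi=0.0,
                       snr=single.snr, snr_interpretable=single.snr_interpretable,
                       rss=rss, converged=converged, degenerate=False)
    report.pdi = compute_pdi(report)
    return report


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def compute_pdi(fit: FitReport) -> float:
    """Polydispersity index: area-weighted relative variance of r_h.

    pdi = sum_i f_i (r_i - rbar)^2 / rbar^2 with rbar = sum_i f_i r_i
    (the DLS-style convention).  A single species gives exactly 0.
    """
    if not fit.species:
        raise ValueError("fit contains no species")
    if len(fit.species) == 1:
        return 0.0
    f = np.array([s.area_fraction for s in fit.species])
    r = np.array([s.r_h for s in fit.species])
    rbar = float(np.sum(f * r))
    if rbar == 0:
        return 0.0
    return float(np.sum(f * (r - rbar) ** 2) / rbar ** 2)


def classify_dispersity(pdi: float,
                        threshold: float = PDI_MONODISPERSE_THRESHOLD) -> str:
    """'monodisperse' if pdi < threshold (default 0.5), else 'polydisperse'."""
    if pdi < 0:
        raise ValueError("pdi must be >= 0")
    return "monodisperse" if pdi < threshold else "polydisperse"
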