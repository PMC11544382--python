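"""Synthetic cohorts, plasma compositions, and LC-MS/MS readouts.

The study's plasma samples are not public, so this module generates
cohorts with the statistical structure the analysis expects: group-wise
albumin (HSA) and HDL concentration distributions, a per-patient latent
HDL-bound S1P fraction that drives both the FIDA radii and the LC-MS/MS
fractionation readout, and clinical outcomes (ventilation, survival, CRP)
coupled to the HDL-complex size through logistic links.

Latent apparent radii for both assay methods are computed with the
competitive two-carrier model (:func:`fidashift.binding.mixture_rapp`).
Inside plasma the indicator's apparent HSA affinity is weaker than against
purified albumin (endogenous S1P and fatty acids compete for the binding
sites), and the per-sample HDL term is chosen so the indicator's HDL-bound
fraction equals the sample's latent S1P partition; both choices are plain
generator parameters, not measured facts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import CarrierMixture, mixture_rapp
from .constants import (
    HDL_CHOL_MG_DL_PER_PROTEIN_MG_ML,
    R_H_FREE_INDICATOR,
    R_H_HDL_COMPLEX,
    R_H_HSA_COMPLEX,
)

__all__ = [
    "GroupProfile",
    "GeneratorConfig",
    "StandardCurve",
    "default_profiles",
    "generate_cohort",
    "emulate_lcms",
    "quantify_s1p",
    "fit_standard_curve",
    "make_standard_curve",
]


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupProfile:
    """Distributional description of one clinical group.

    Concentration draws are lognormal around the given medians; the latent
    HDL-bound S1P fraction is Beta-distributed around ``s1p_frac_hdl_median``
    (a two-component mixture when ``low_complex_prob`` > 0, emulating the
    septic-shock subgroup with very low HDL-complex formation).
    """

    name: str
    n: int
    hsa_median_g_l: float
    hdl_median_mg_dl: float
    s1p_frac_hdl_median: float
    hsa_sigma: float = 0.15          # lognormal sigma
    hdl_sigma: float = 0.25
    frac_kappa: float = 40.0         # Beta concentration of the latent fraction
    low_complex_prob: float = 0.0
    low_complex_frac: float = 0.2
    sofa_median: float | None = None
    sofa_iqr: tuple[float, float] | None = None
    total_s1p_pmol_median: float = 400.0
    total_s1p_sigma: float = 0.3

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"group {self.name!r}: n must be > 0")
        if self.hsa_median_g_l <= 0 or self.hdl_median_mg_dl <= 0:
            raise ValueError(f"group {self.name!r}: medians must be positive")
        if not 0 < self.s1p_frac_hdl_median < 1:
            raise ValueError(f"group {self.name!r}: fraction median must be in (0,1)")
        if not 0 <= self.low_complex_prob <= 1:
            raise ValueError("low_complex_prob must be in [0, 1]")


def default_profiles() -> dict[str, GroupProfile]:
    """Study-condition group profiles.

    Group sizes 14/11/36/16 and SOFA medians with IQRs follow the cohort
    description; HSA medians 43/25/22/17 g/L and HDL medians 61/61/34/13
    mg/dL follow the reported group-wise concentrations (the trauma group
    shows no HDL decrease).  The HDL-bound S1P fraction medians encode the
    carrier shift from HSA toward HDL in patients, with a bimodal
    septic-shock group containing a low-complex subpopulation.
    """
    return {
        "control": GroupProfile(
            name="control", n=14, hsa_median_g_l=43.0, hdl_median_mg_dl=61.0,
            s1p_frac_hdl_median=0.55, total_s1p_pmol_median=400.0,
        ),
        "trauma": GroupProfile(
            name="trauma", n=11, hsa_median_g_l=25.0, hdl_median_mg_dl=61.0,
            s1p_frac_hdl_median=0.80, sofa_median=4, sofa_iqr=(3, 5),
            total_s1p_pmol_median=480.0,
        ),
        "sepsis": GroupProfile(
            name="sepsis", n=36, hsa_median_g_l=22.0, hdl_median_mg_dl=34.0,
            s1p_frac_hdl_median=0.75, sofa_median=4, sofa_iqr=(2, 6),
            total_s1p_pmol_median=420.0,
        ),
        "septic_shock": GroupProfile(
            name="septic_shock", n=16, hsa_median_g_l=17.0, hdl_median_mg_dl=13.0,
            s1p_frac_hdl_median=0.70, low_complex_prob=0.35, low_complex_frac=0.20,
            sofa_median=8, sofa_iqr=(7, 11), total_s1p_pmol_median=300.0,
        ),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the cohort generator (units in field names or docstring).

    ``kd_hsa_plasma_mg_ml`` is the apparent indicator-HSA dissociation
    constant inside 10% plasma; it is much weaker than against purified
    albumin because endogenous ligands occupy HSA's fatty-acid sites.
    ``rh_noise_cv`` is the relative measurement noise of a fitted radius
    (FIDA-level precision).  Outcome couplings are logistic in the latent
    complex-dissociation radius: larger HDL complexes mean lower ventilation
    and death probabilities.
    """

    plasma_dilution: float = 0.10
    kd_hsa_plasma_mg_ml: float = 1.0
    r_free: float = R_H_FREE_INDICATOR
    r_hsa_complex: float = R_H_HSA_COMPLEX
    r_hdl_complex: float = R_H_HDL_COMPLEX
    rh_noise_cv: float = 0.015
    vent_slope_per_nm: float = 1.2
    vent_midpoint_nm: float = 4.1
    death_slope_per_nm: float = 4.0
    death_midpoint_nm: float = 3.9
    crp_median_ventilated: float = 160.0
    crp_median_not_ventilated: float = 105.0
    crp_sigma: float = 0.45
    s1p_frac_other_carriers: float = 0.08
    lcms_cv: float = 0.20
    lcms_recovery_hsa: float = 0.95
    lcms_recovery_hdl: float = 0.85
    lcms_missing_prob: float = 0.15


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _lognormal_sigma_from_iqr(q1: float, q3: float) -> float:
    # IQR of a lognormal: exp(mu +/- 0.6745 sigma)
    return math.log(q3 / q1) / (2.0 * 0.674489750196082)


# ---------------------------------------------------------------------------
# latent radii
# ---------------------------------------------------------------------------

def _latent_radii(hsa_g_l: float, hdl_mg_dl: float, frac_hdl: float,
                  cfg: GeneratorConfig) -> tuple[float, float]:
    """Latent (r_capmix, r_capdis) of one plasma sample, nm."""
    c_hsa = hsa_g_l * cfg.plasma_dilution               # g/L == mg/mL
    c_hdl = (hdl_mg_dl / HDL_CHOL_MG_DL_PER_PROTEIN_MG_ML) * cfg.plasma_dilution
    h = c_hsa / cfg.kd_hsa_plasma_mg_ml
    # HDL term chosen so the indicator's HDL-bound fraction equals the
    # sample's latent S1P partition: g = f (1 + h) / (1 - f)
    frac_hdl = min(max(frac_hdl, 1e-9), 1.0 - 1e-9)
    g = frac_hdl * (1.0 + h) / (1.0 - frac_hdl)
    kd_hdl_eff = c_hdl / g if g > 0 else math.inf
    mix = CarrierMixture(
        hsa_conc=c_hsa, hdl_protein_conc=c_hdl,
        k_d_hsa=cfg.kd_hsa_plasma_mg_ml, k_d_hdl=kd_hdl_eff,
        r_free=cfg.r_free, r_hsa_complex=cfg.r_hsa_complex,
        r_hdl_complex=cfg.r_hdl_complex, capmix_hdl_attenuation=0.0,
    )
    r_capmix = mixture_rapp(mix, "capillary_mix")
    r_capdis = mixture_rapp(mix, "complex_dissociation")
    return r_capmix, r_capdis


# ---------------------------------------------------------------------------
# LC-MS/MS emulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardCurve:
    """Linear isotope-dilution calibration: area ratio vs analyte pmol."""

    slope: float               # ratio per pmol
    intercept: float
    r_squared: float
    n_levels: int

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("standard-curve slope must be > 0")


def fit_standard_curve(pmol_levels, area_ratios) -> StandardCurve:
    """Least-squares line through (pmol, analyte/IS area ratio) points."""
    x = np.asarray(pmol_levels, dtype=float)
    y = np.asarray(area_ratios, dtype=float)
    if x.size < 4:
        raise ValueError("standard curve needs >= 4 levels")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(slope=float(slope), intercept=float(intercept),
                         r_squared=r2, n_levels=int(x.size))


#: Instrument response factors (area per pmol) for the analyte and the
#: C17-S1P internal standard; arbitrary but fixed detector scale.
RESPONSE_FACTOR_S1P = 1_000.0
RESPONSE_FACTOR_IS = 950.0

#: Internal standard spiked per fraction, pmol.
IS_PMOL = 100.0


def make_standard_curve(levels=(10.0, 25.0, 50.0, 100.0, 200.0),
                        noise_cv: float = 0.0,
                        seed: int | None = None) -> StandardCurve:
    """Emulate and fit a spiked dilution series of S1P against 100 pmol IS."""
    rng = np.random.default_rng(seed)
    levels = np.asarray(levels, dtype=float)
    analyte = RESPONSE_FACTOR_S1P * levels
    is_area = RESPONSE_FACTOR_IS * IS_PMOL
    if noise_cv > 0:
        analyte = analyte * rng.lognormal(0.0, noise_cv, size=levels.size)
    return fit_standard_curve(levels, analyte / is_area)


def quantify_s1p(analyte_area: float, is_area: float,
                 curve: StandardCurve) -> tuple[float, bool]:
    """Isotope-dilution quantification: pmol from the area ratio.

    pmol = (analyte/IS - intercept) / slope.  Negative results are clipped
    to 0 and flagged (second return value True when clipping occurred).
    """
    if is_area == 0:
        raise ValueError("internal-standard area must be nonzero")
    pmol = (analyte_area / is_area - curve.intercept) / curve.slope
    if pmol < 0:
        return 0.0, True
    return float(pmol), False


def emulate_lcms(total_s1p_pmol: float, frac_hdl: float, frac_other: float,
                 curve: StandardCurve, cfg: GeneratorConfig,
                 rng: np.random.Generator) -> dict:
    """Emulate the fractionation + LC-MS/MS readout of one plasma sample.

    The sample's S1P splits over (HDL, HSA, other lipoproteins); each
    measured fraction gets its own extraction with fraction-specific
    recovery and multiplicative lognormal noise on the analyte and IS areas.
    Derived fractions are the quantified amounts relative to the summed
    quantified S1P including the other-lipoprotein pool, so reported HSA +
    HDL fractions never exceed 1.
    """
    share_hdl = frac_hdl * (1.0 - frac_other)
    share_hsa = (1.0 - frac_hdl) * (1.0 - frac_other)
    shares = {"hdl": share_hdl, "hsa": share_hsa, "other": frac_other}
    recovery = {"hdl": cfg.lcms_recovery_hdl, "hsa": cfg.lcms_recovery_hsa,
                "other": cfg.lcms_recovery_hsa}
    # split the ratio-level CV between the two area draws
    area_cv = cfg.lcms_cv / math.sqrt(2.0)
    out: dict = {"areas": {}, "pmol": {}, "flags": {}}
    for frac, share in shares.items():
        pmol_true = total_s1p_pmol * share * recovery[frac]
        noise_a = rng.lognormal(0.0, area_cv) if cfg.lcms_cv > 0 else 1.0
        noise_i = rng.lognormal(0.0, area_cv) if cfg.lcms_cv > 0 else 1.0
        analyte_area = RESPONSE_FACTOR_S1P * pmol_true * noise_a
        is_area = RESPONSE_FACTOR_IS * IS_PMOL * noise_i
        pmol, clipped = quantify_s1p(analyte_area, is_area, curve)
        out["areas"][frac] = {"s1p": analyte_area, "c17_s1p": is_area}
        out["pmol"][frac] = pmol
        out["flags"][frac] = clipped
    total = sum(out["pmol"].values())
    if total > 0:
        out["frac_hdl"] = out["pmol"]["hdl"] / total
        out["frac_hsa"] = out["pmol"]["hsa"] / total
    else:  # pragma: no cover - degenerate zero-signal sample
        out["frac_hdl"] = math.nan
        out["frac_hsa"] = math.nan
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _draw_fraction(profile: GroupProfile, rng: np.random.Generator) -> float:
    """Latent HDL-bound S1P fraction of one patient (Beta, optional mixture)."""
    if profile.low_complex_prob > 0 and rng.uniform() < profile.low_complex_prob:
        mean = profile.low_complex_frac
    else:
        mean = profile.s1p_frac_hdl_median
    kappa = profile.frac_kappa
    a, b = mean * kappa, (1.0 - mean) * kappa
    return float(rng.beta(a, b))


def _draw_sofa(profile: GroupProfile, rng: np.random.Generator) -> float | None:
    if profile.sofa_median is None:
        return None
    sigma = 0.4
    if profile.sofa_iqr is not None:
        sigma = _lognormal_sigma_from_iqr(*profile.sofa_iqr)
    val = rng.lognormal(math.log(profile.sofa_median), sigma)
    return int(np.clip(round(val), 0, 24))


def generate_cohort(profiles: dict[str, GroupProfile] | None = None,
                    seed: int = 0,
                    config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Generate one synthetic cohort table.

    One row per sample with columns: sample_id, group, hsa_g_l, hdl_mg_dl,
    s1p_frac_hdl_true, total_s1p_pmol, r_capmix_latent, r_capdis_latent,
    r_capmix, r_capdis, sofa, ventilated, survived, crp, lcms_frac_hsa,
    lcms_frac_hdl.  Deterministic for a fixed (profiles, seed, config).
    """
    profiles = profiles if profiles is not None else default_profiles()
    for p in profiles.values():
        if p.n <= 0:  # re-validate externally supplied profiles
            raise ValueError(f"group {p.name!r}: n must be > 0")
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    curve = make_standard_curve()

    rows = []
    for name, prof in profiles.items():
        is_control = name == "control"
        for i in range(prof.n):
            hsa = float(rng.lognormal(math.log(prof.hsa_median_g_l), prof.hsa_sigma))
            hdl = float(rng.lognormal(math.log(prof.hdl_median_mg_dl), prof.hdl_sigma))
            frac = _draw_fraction(prof, rng)
            r_mix, r_dis = _latent_radii(hsa, hdl, frac, cfg)
            r_mix_obs = r_mix * (1.0 + cfg.rh_noise_cv * rng.standard_normal())
            r_dis_obs = r_dis * (1.0 + cfg.rh_noise_cv * rng.standard_normal())

            sofa = None if is_control else _draw_sofa(prof, rng)
            if is_control:
                ventilated = survived = None
                crp = None
            else:
                p_vent = float(_sigmoid(-cfg.vent_slope_per_nm
                                        * (r_dis - cfg.vent_midpoint_nm)))
                p_death = float(_sigmoid(-cfg.death_slope_per_nm
                                         * (r_dis - cfg.death_midpoint_nm)))
                ventilated = bool(rng.uniform() < p_vent)
                survived = bool(rng.uniform() >= p_death)
                crp_median = (cfg.crp_median_ventilated if ventilated
                              else cfg.crp_median_not_ventilated)
                crp = float(rng.lognormal(math.log(crp_median), cfg.crp_sigma))

            total_s1p = float(rng.lognormal(math.log(prof.total_s1p_pmol_median),
                                            prof.total_s1p_sigma))
            if rng.uniform() < cfg.lcms_missing_prob:
                frac_hdl_obs = frac_hsa_obs = math.nan
            else:
                lcms = emulate_lcms(total_s1p, frac,
                                    cfg.s1p_frac_other_carriers, curve, cfg, rng)
                frac_hdl_obs = lcms["frac_hdl"]
                frac_hsa_obs = lcms["frac_hsa"]

            rows.append({
                "sample_id": f"{name}_{i + 1:02d}",
                "group": name,
                "hsa_g_l": hsa,
                "hdl_mg_dl": hdl,
                "s1p_frac_hdl_true": frac,
                "total_s1p_pmol": total_s1p,
                "r_capmix_latent": r_mix,
                "r_capdis_latent": r_dis,
                "r_capmix": r_mix_obs,
                "r_capdis": r_dis_obs,
                "sofa": sofa,
                "ventilated": ventilated,
                "survived": survived,
                "crp": crp,
                "lcms_frac_hsa": frac_hsa_obs,
                "lcms_frac_hdl": frac_hdl_obs,
            })
    df = pd.DataFrame(rows)
    df["delta_rh"] = df["r_capdis"] - df["r_capmix"]
    return df
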