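"""Equilibrium binding models for the indicator-carrier system.

The fluorescent indicator (S1P-FITC) is present far below its carriers'
binding-site concentrations, so a 1:1 fast-exchange model applies: the
apparent hydrodynamic radius is the population-weighted mean of the free
and bound radii,

    r_app = (1 - f_b) r_free + f_b r_complex,   f_b = C / (K_D + C).

For two competing carriers (HSA and HDL) the partition generalizes to

    f_free = 1 / (1 + C_HSA/K_HSA + beta * C_HDL/K_HDL)

where beta encodes the method's kinetic window: the capillary-mix method
leaves too little time for the slow S1P-FITC/HDL association (beta = alpha,
default 0), while the complex-dissociation method probes the pre-equilibrated
state (beta = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import (
    APOM_MG_PER_G_HDL,
    APOM_MOLAR_MASS,
    HSA_MOLAR_MASS,
    KD_HDL_MG_PER_ML,
    KD_HSA_MG_PER_ML,
    R_H_FREE_INDICATOR,
    R_H_HDL_COMPLEX,
    R_H_HSA_COMPLEX,
)

__all__ = [
    "BindingCurve",
    "BindingFit",
    "CarrierMixture",
    "isotherm_rapp",
    "fit_binding_curve",
    "mixture_rapp",
    "mixture_fractions",
    "mass_to_molar_kd",
    "molar_to_mass_kd",
    "apom_equivalent_kd",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BindingCurve:
    """A titration: apparent radius versus analyte concentration.

    conc and r_app are parallel vectors (replicate points repeat the
    concentration); ``unit`` tags the concentration axis and is carried into
    the fitted K_D.
    """

    conc: np.ndarray
    r_app: np.ndarray
    unit: str = "mg/mL"
    method: str = "capillary_mix"

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        self.r_app = np.asarray(self.r_app, dtype=float)
        if self.conc.shape != self.r_app.shape or self.conc.ndim != 1:
            raise ValueError("conc and r_app must be 1-D arrays of equal length")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be >= 0")
        if np.unique(self.conc).size < 5:
            raise ValueError("need at least 5 distinct concentration levels")


@dataclass
class BindingFit:
    k_d: float
    r_free: float
    r_complex: float
    k_d_se: float
    r_free_se: float
    r_complex_se: float
    rss: float
    unit: str
    converged: bool
    extrapolated: bool
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "k_d": self.k_d, "k_d_se": self.k_d_se, "unit": self.unit,
            "r_free_nm": self.r_free, "r_free_se": self.r_free_se,
            "r_complex_nm": self.r_complex, "r_complex_se": self.r_complex_se,
            "rss": self.rss, "converged": self.converged,
            "extrapolated": self.extrapolated, "flags": list(self.flags),
        }


@dataclass(frozen=True)
class CarrierMixture:
    """Concentrations and binding parameters of the two-carrier system.

    All concentrations and dissociation constants are in mg/mL (HDL as
    protein mass).  ``capmix_hdl_attenuation`` (alpha) scales the effective
    HDL occupancy in the capillary-mix method: 0 means no S1P-FITC/HDL
    complex forms within the mixing window.
    """

    hsa_conc: float
    hdl_protein_conc: float
    k_d_hsa: float = KD_HSA_MG_PER_ML
    k_d_hdl: float = KD_HDL_MG_PER_ML
    r_free: float = R_H_FREE_INDICATOR
    r_hsa_complex: float = R_H_HSA_COMPLEX
    r_hdl_complex: float = R_H_HDL_COMPLEX
    capmix_hdl_attenuation: float = 0.0
    conc_unit: str = "mg/mL"
    k_d_unit: str = "mg/mL"

    def __post_init__(self) -> None:
        if self.hsa_conc < 0 or self.hdl_protein_conc < 0:
            raise ValueError("concentrations must be >= 0")
        if not 0.0 <= self.capmix_hdl_attenuation <= 1.0:
            raise ValueError("capmix_hdl_attenuation must lie in [0, 1]")
        if self.k_d_hsa <= 0 or self.k_d_hdl <= 0:
            raise ValueError("dissociation constants must be > 0")


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def isotherm_rapp(conc, k_d: float, r_free: float, r_complex: float):
    """Apparent radius of a 1:1 fast-exchange isotherm (vectorized).

    f_b = C / (K_D + C);  r_app = (1 - f_b) r_free + f_b r_complex.
    """
    if k_d <= 0:
        raise ValueError("k_d must be > 0")
    conc = np.asarray(conc, dtype=float)
    f_b = conc / (k_d + conc)
    out = (1.0 - f_b) * r_free + f_b * r_complex
    return float(out) if out.ndim == 0 else out


def mixture_fractions(mix: CarrierMixture, method: str) -> tuple[float, float, float]:
    """(f_free, f_hsa, f_hdl) indicator partition for a method.

    Competitive binding with the indicator far below site concentrations.
    Fractions sum to 1 by construction.
    """
    if method == "capillary_mix":
        beta = mix.capmix_hdl_attenuation
    elif method == "complex_dissociation":
        beta = 1.0
    else:
        raise ValueError(f"unknown method {method!r}")
    if mix.conc_unit != mix.k_d_unit:
        raise ValueError(
            f"concentration unit {mix.conc_unit!r} does not match "
            f"K_D unit {mix.k_d_unit!r}"
        )
    h = mix.hsa_conc / mix.k_d_hsa
    g = beta * mix.hdl_protein_conc / mix.k_d_hdl
    f_free = 1.0 / (1.0 + h + g)
    return f_free, h * f_free, g * f_free


def mixture_rapp(mix: CarrierMixture, method: str) -> float:
    """Apparent radius of the indicator in an HSA/HDL mixture."""
    f_free, f_hsa, f_hdl = mixture_fractions(mix, method)
    return (f_free * mix.r_free + f_hsa * mix.r_hsa_complex
            + f_hdl * mix.r_hdl_complex)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_binding_curve(curve: BindingCurve, extrapolation_factor: float = 3.0) -> BindingFit:
    """Weighted nonlinear least-squares fit of the 1:1 isotherm.

    Replicated concentrations are weighted by inverse replicate variance
    when replicate spread is informative, otherwise the fit is unweighted.
    K_D is parameterized on a log scale.  A K_D beyond
    ``extrapolation_factor`` times the highest tested concentration is
    flagged as extrapolated; a flat response is flagged as a failure and no
    K_D is reported (NaN).
    """
    conc, r_app = curve.conc, curve.r_app

    span = float(np.ptp(r_app))
    if span <= 0 or span < 1e-9 * max(abs(float(np.mean(r_app))), 1.0):
        return BindingFit(
            k_d=math.nan, r_free=math.nan, r_complex=math.nan,
            k_d_se=math.nan, r_free_se=math.nan, r_complex_se=math.nan,
            rss=math.nan, unit=curve.unit, converged=False, extrapolated=False,
            flags=["flat_response"],
        )

    # inverse-variance weights from replicate structure, if present
    weights = np.ones_like(r_app)
    levels, inverse = np.unique(conc, return_inverse=True)
    if levels.size < conc.size:
        var = np.array([np.var(r_app[inverse == i], ddof=1)
                        if np.sum(inverse == i) > 1 else np.nan
                        for i in range(levels.size)])
        if np.isfinite(var).any():
            fill = float(np.nanmean(var[var > 0])) if np.any(var > 0) else 1.0
            var = np.where(np.isfinite(var) & (var > 0), var, fill)
            weights = 1.0 / np.sqrt(var[inverse])

    r_free0 = float(r_app[np.argmin(conc)])
    r_complex0 = float(np.max(r_app))
    half = r_free0 + 0.5 * (r_complex0 - r_free0)
    above = conc[r_app >= half]
    k_d0 = float(above.min()) if above.size and above.min() > 0 \
        else float(np.median(conc[conc > 0]))

    def residual(p):
        log_kd, r_free, r_complex = p
        return weights * (isotherm_rapp(conc, math.exp(log_kd), r_free, r_complex)
                          - r_app)

    p0 = np.array([math.log(k_d0), r_free0, r_complex0])
    res = least_squares(residual, p0, ftol=1e-12, xtol=1e-12, max_nfev=5000)
    log_kd, r_free, r_complex = res.x
    k_d = float(math.exp(log_kd))
    rss = float(2.0 * res.cost)

    # standard errors from the Jacobian (Gauss-Newton covariance)
    dof = max(conc.size - 3, 1)
    try:
        jtj_inv = np.linalg.pinv(res.jac.T @ res.jac)
        cov = jtj_inv * rss / dof
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        k_d_se = k_d * float(se[0])  # delta method for log-parameterization
        r_free_se, r_complex_se = float(se[1]), float(se[2])
    except np.linalg.LinAlgError:  # pragma: no cover
        k_d_se = r_free_se = r_complex_se = math.nan

    flags: list[str] = []
    extrapolated = k_d > extrapolation_factor * float(conc.max())
    if extrapolated:
        flags.append("k_d_extrapolated")
    converged = bool(res.success) and not extrapolated
    if not res.success:
        flags.append("optimizer_did_not_converge")
    return BindingFit(
        k_d=k_d, r_free=float(r_free), r_complex=float(r_complex),
        k_d_se=k_d_se, r_free_se=r_free_se, r_complex_se=r_complex_se,
        rss=rss, unit=curve.unit, converged=converged,
        extrapolated=extrapolated, flags=flags,
    )


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def mass_to_molar_kd(k_d_mass_mg_per_ml: float, molar_mass_g_per_mol: float) -> float:
    """Convert a mass-based K_D (mg/mL) to molar (mol/L).

    mg/mL = g/L, so K_D [M] = K_D [g/L] / M [g/mol].
    """
    if k_d_mass_mg_per_ml <= 0:
        raise ValueError("k_d must be > 0")
    if molar_mass_g_per_mol <= 0:
        raise ValueError("molar mass must be > 0")
    return k_d_mass_mg_per_ml / molar_mass_g_per_mol


def molar_to_mass_kd(k_d_molar: float, molar_mass_g_per_mol: float) -> float:
    """Inverse of :func:`mass_to_molar_kd` (returns mg/mL)."""
    if k_d_molar <= 0 or molar_mass_g_per_mol <= 0:
        raise ValueError("inputs must be > 0")
    return k_d_molar * molar_mass_g_per_mol


def apom_equivalent_kd(
    k_d_hdl_protein_mg_per_ml: float = KD_HDL_MG_PER_ML,
    apom_mass_fraction_mg_per_g: float = APOM_MG_PER_G_HDL,
    apom_molar_mass_g_per_mol: float = APOM_MOLAR_MASS,
) -> float:
    """K_D re-expressed against ApoM, the S1P-binding protein of HDL (in uM).

    The HDL-protein K_D is scaled by the ApoM mass fraction (mg ApoM per g
    HDL protein) and converted to molar with the ApoM molar mass.
    """
    if min(k_d_hdl_protein_mg_per_ml, apom_mass_fraction_mg_per_g,
           apom_molar_mass_g_per_mol) <= 0:
        raise ValueError("inputs must be > 0")
    apom_mg_per_ml = k_d_hdl_protein_mg_per_ml * apom_mass_fraction_mg_per_g / 1000.0
    return mass_to_molar_kd(apom_mg_per_ml, apom_molar_mass_g_per_mol) * 1e6
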