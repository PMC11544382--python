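"""Analytic Taylor-Aris dispersion model.

In flow-induced dispersion analysis (FIDA) a nanolitre plug of fluorescent
indicator is mobilized through a narrow capillary under laminar Poiseuille
flow.  Radial diffusion couples to the parabolic velocity profile and the
plug disperses axially; at the detector the plug appears as a near-Gaussian
peak (a "Taylorgram") whose temporal variance encodes the molecular
diffusion coefficient

    sigma_t^2 = r_c^2 * t_R / (24 * D)

(pure Taylor regime, axial molecular diffusion neglected).  The diffusion
coefficient converts to a hydrodynamic radius through the Stokes-Einstein
relation R_h = k_B T / (6 pi eta D).

This module provides those closed forms, a regime-validity check, a
Taylorgram simulator for species mixtures, and a brute-force Langevin
(random-walk) dispersion simulator used as an independent physics oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import (
    ETA_WATER_37C,
    INDICATOR_CAPDIS_NM,
    INDICATOR_CAPMIX_NM,
    K_B,
    T_CAPILLARY,
)

__all__ = [
    "CapillarySetup",
    "AssayProtocol",
    "Species",
    "Taylorgram",
    "stokes_einstein",
    "diffusion_from_rh",
    "temporal_variance",
    "sigma_t_from_rh",
    "taylor_validity",
    "simulate_taylorgram",
    "noise_sd_for_snr",
    "langevin_temporal_variance",
    "capmix_protocol",
    "capdis_protocol",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CapillarySetup:
    """Capillary geometry and solvent conditions.

    Parameters
    ----------
    r_c : float
        Inner capillary radius, m.
    length_to_detector : float
        Capillary length from inlet to the detection window, m.
    temperature : float
        Absolute temperature inside the capillary, K.
    viscosity : float
        Dynamic viscosity of the run buffer, Pa*s.
    t_r : float
        Mean residence time of the plug to the detector, s.  The mean flow
        velocity follows as ``u = length_to_detector / t_r``.
    """

    r_c: float = 37.5e-6
    length_to_detector: float = 0.84
    temperature: float = T_CAPILLARY
    viscosity: float = ETA_WATER_37C
    t_r: float = 120.0

    def __post_init__(self) -> None:
        for name in ("r_c", "length_to_detector", "temperature", "viscosity", "t_r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"CapillarySetup.{name} must be strictly positive")

    @property
    def mean_velocity(self) -> float:
        """Mean flow velocity u = L / t_R, m/s."""
        return self.length_to_detector / self.t_r


@dataclass(frozen=True)
class ProtocolStep:
    fluid: str
    pressure_mbar: float
    duration_s: float


@dataclass(frozen=True)
class AssayProtocol:
    """One of the two FIDA measurement modes.

    ``capillary_mix`` (CapMix): indicator and analyte mix inside the
    capillary during mobilization, so only fast-associating binders (HSA)
    form complexes before detection.  ``complex_dissociation`` (CapDis):
    indicator and analyte are pre-equilibrated and the plug is mobilized
    with buffer, so equilibrated complexes (including HDL) are observed.
    """

    method: str  # "capillary_mix" | "complex_dissociation"
    indicator_conc_nm: float
    steps: tuple[ProtocolStep, ...]

    def __post_init__(self) -> None:
        if self.method not in ("capillary_mix", "complex_dissociation"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.indicator_conc_nm <= 0:
            raise ValueError("indicator_conc_nm must be > 0")
        if not self.steps:
            raise ValueError("protocol needs at least one step")
        final = self.steps[-1]
        expected = "analyte" if self.method == "capillary_mix" else "buffer"
        if final.fluid != expected:
            raise ValueError(
                f"final step of {self.method} must mobilize with {expected!r}, "
                f"got {final.fluid!r}"
            )


def _standard_steps(mobilization_fluid: str) -> tuple[ProtocolStep, ...]:
    # Rinse / equilibrate / fill / inject / mobilize step table of the
    # instrument method used for both modes.
    return (
        ProtocolStep("naoh_1M", 3500.0, 45.0),
        ProtocolStep("pbs", 3500.0, 75.0),
        ProtocolStep("analyte", 3500.0, 30.0),
        ProtocolStep("indicator", 50.0, 10.0),
        ProtocolStep(mobilization_fluid, 400.0, 200.0),
    )


def capmix_protocol(indicator_conc_nm: float = INDICATOR_CAPMIX_NM) -> AssayProtocol:
    """Capillary-mix protocol (default 50 nM indicator)."""
    return AssayProtocol("capillary_mix", indicator_conc_nm, _standard_steps("analyte"))


def capdis_protocol(indicator_conc_nm: float = INDICATOR_CAPDIS_NM) -> AssayProtocol:
    """Complex-dissociation protocol (default 500 nM indicator)."""
    return AssayProtocol(
        "complex_dissociation", indicator_conc_nm, _standard_steps("buffer")
    )


@dataclass(frozen=True)
class Species:
    """One diffusing species in the detected plug.

    r_h in nm; amplitude_fraction is the species' share of the total peak
    area (fractions across a mixture must sum to 1).
    """

    r_h: float
    amplitude_fraction: float

    def __post_init__(self) -> None:
        if self.r_h <= 0:
            raise ValueError("Species.r_h must be > 0")
        if not 0.0 <= self.amplitude_fraction <= 1.0:
            raise ValueError("amplitude_fraction must lie in [0, 1]")


@dataclass
class Taylorgram:
    """A detector-time fluorescence trace.

    time must be uniformly sampled (within 1e-9 relative) with >= 50
    samples; signal is in arbitrary fluorescence units.
    """

    time: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.signal.shape:
            raise ValueError("time and signal must be 1-D arrays of equal length")
        if self.time.size < 50:
            raise ValueError("a Taylorgram needs at least 50 samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if np.max(np.abs(dt - dt[0])) > 1e-9 * max(abs(dt[0]), 1e-300):
            raise ValueError("time must be uniformly sampled (1e-9 relative)")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def copy(self) -> "Taylorgram":
        return Taylorgram(self.time.copy(), self.signal.copy(), dict(self.meta))


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def stokes_einstein(d: float, temperature: float = T_CAPILLARY,
                    viscosity: float = ETA_WATER_37C) -> float:
    """Hydrodynamic radius (nm) from a diffusion coefficient (m^2/s).

    R_h = k_B T / (6 pi eta D).
    """
    if d <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("stokes_einstein requires strictly positive inputs")
    r_m = K_B * temperature / (6.0 * math.pi * viscosity * d)
    return r_m * 1e9


def diffusion_from_rh(r_h_nm: float, temperature: float = T_CAPILLARY,
                      viscosity: float = ETA_WATER_37C) -> float:
    """Diffusion coefficient (m^2/s) from a hydrodynamic radius (nm).

    Exact algebraic inverse of :func:`stokes_einstein`.
    """
    if r_h_nm <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("diffusion_from_rh requires strictly positive inputs")
    return K_B * temperature / (6.0 * math.pi * viscosity * r_h_nm * 1e-9)


def temporal_variance(d: float, t_r: float, r_c: float) -> float:
    """Temporal peak variance sigma_t^2 (s^2) of the Taylor-dispersed plug.

    sigma_t^2 = r_c^2 t_R / (24 D); axial molecular diffusion is neglected
    (pure Taylor regime -- guard with :func:`taylor_validity`).
    """
    if d <= 0 or t_r <= 0 or r_c <= 0:
        raise ValueError("temporal_variance requires strictly positive inputs")
    return r_c ** 2 * t_r / (24.0 * d)


def diffusion_from_sigma(sigma_t: float, t_r: float, r_c: float) -> float:
    """Invert :func:`temporal_variance`: D = r_c^2 t_R / (24 sigma_t^2)."""
    if sigma_t <= 0 or t_r <= 0 or r_c <= 0:
        raise ValueError("diffusion_from_sigma requires strictly positive inputs")
    return r_c ** 2 * t_r / (24.0 * sigma_t ** 2)


def sigma_t_from_rh(r_h_nm: float, capillary: CapillarySetup) -> float:
    """Peak SD (s) of a species of given hydrodynamic radius (nm)."""
    d = diffusion_from_rh(r_h_nm, capillary.temperature, capillary.viscosity)
    return math.sqrt(temporal_variance(d, capillary.t_r, capillary.r_c))


@dataclass(frozen=True)
class TaylorValidity:
    tau: float
    peclet: float
    ok: bool


def taylor_validity(d: float, t_r: float, r_c: float, u: float,
                    tau_min: float = 1.4, pe_min: float = 69.0) -> TaylorValidity:
    """Check the standard Taylor-regime criteria.

    tau = D t_R / r_c^2 (dimensionless residence time; radial equilibration)
    and Pe = u r_c / D (advection over axial diffusion).  ``ok`` is True iff
    tau >= tau_min and Pe >= pe_min (boundaries inclusive).
    """
    if min(d, t_r, r_c, u) <= 0:
        raise ValueError("taylor_validity requires strictly positive inputs")
    tau = d * t_r / r_c ** 2
    pe = u * r_c / d
    return TaylorValidity(tau=tau, peclet=pe, ok=(tau >= tau_min and pe >= pe_min))


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

#: Peak area contributed per nM of indicator, AU*s.  Arbitrary detector
#: scale; fixed so signal amplitudes are reproducible across runs.
AREA_PER_NM = 1.0


def simulate_taylorgram(
    mixture: Sequence[Species],
    protocol: AssayProtocol,
    capillary: CapillarySetup | None = None,
    baseline: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int | None = None,
    duration: float | None = None,
    dt: float = 0.05,
) -> Taylorgram:
    """Simulate a Taylorgram of a species mixture.

    signal(t) = offset + slope*t + sum_i A_i exp(-(t - t_R)^2 / (2 sigma_i^2))
    + N(0, noise_sd^2).  All species share the residence time t_R; each
    sigma_i follows from the species' diffusion coefficient through
    :func:`temporal_variance`.  The summed Gaussian area is proportional to
    the protocol's indicator concentration, split by amplitude fractions.
    """
    if not mixture:
        raise ValueError("mixture must contain at least one species")
    fractions = np.array([s.amplitude_fraction for s in mixture], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"amplitude fractions must sum to 1, got {fractions.sum()!r}")
    capillary = capillary or CapillarySetup()
    if duration is None:
        duration = 2.0 * capillary.t_r

    offset, slope = baseline
    time = np.arange(0.0, duration + 0.5 * dt, dt)
    signal = offset + slope * time
    total_area = AREA_PER_NM * protocol.indicator_conc_nm
    for sp in mixture:
        sigma = sigma_t_from_rh(sp.r_h, capillary)
        area = total_area * sp.amplitude_fraction
        amp = area / (sigma * math.sqrt(2.0 * math.pi))
        signal = signal + amp * np.exp(
            -((time - capillary.t_r) ** 2) / (2.0 * sigma ** 2)
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=time.size)

    meta = {
        "capillary": capillary,
        "protocol": protocol,
        "baseline": (offset, slope),
        "noise_sd": noise_sd,
        "seed": seed,
        "true_species": tuple(mixture),
    }
    return Taylorgram(time=time, signal=signal, meta=meta)


def noise_sd_for_snr(mixture: Sequence[Species], protocol: AssayProtocol,
                     capillary: CapillarySetup | None = None,
                     snr: float = 100.0) -> float:
    """Noise SD (AU) that yields a target peak signal-to-noise ratio.

    S/N is defined as peak amplitude over baseline noise SD; the peak
    amplitude is evaluated at the shared residence time.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    capillary = capillary or CapillarySetup()
    total_area = AREA_PER_NM * protocol.indicator_conc_nm
    amp = 0.0
    for sp in mixture:
        sigma = sigma_t_from_rh(sp.r_h, capillary)
        amp += total_area * sp.amplitude_fraction / (sigma * math.sqrt(2.0 * math.pi))
    return amp / snr


# ---------------------------------------------------------------------------
# brute-force Langevin oracle
# ---------------------------------------------------------------------------

def langevin_temporal_variance(
    d: float,
    capillary: CapillarySetup | None = None,
    n_walkers: int = 10_000,
    dt: float = 0.02,
    seed: int | None = None,
) -> float:
    """Temporal peak variance from a random-walk dispersion simulation.

    Walkers start uniformly over the capillary cross-section, diffuse in the
    transverse plane (reflecting at the wall) and are advected by the
    Poiseuille profile u(r) = 2 u_mean (1 - (r/r_c)^2).  The empirical
    variance of the axial positions at t = t_R, divided by u_mean^2,
    estimates sigma_t^2 independently of the closed form.  Axial molecular
    diffusion is omitted, matching the closed form's assumption.
    """
    capillary = capillary or CapillarySetup()
    rng = np.random.default_rng(seed)
    r_c = capillary.r_c
    u_mean = capillary.mean_velocity
    n_steps = int(round(capillary.t_r / dt))

    # uniform start over the disk
    rad = r_c * np.sqrt(rng.uniform(size=n_walkers))
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n_walkers)
    y = rad * np.cos(theta)
    z = rad * np.sin(theta)
    x = np.zeros(n_walkers)

    step_sd = math.sqrt(2.0 * d * dt)
    for _ in range(n_steps):
        r2 = y * y + z * z
        x += 2.0 * u_mean * (1.0 - r2 / r_c ** 2) * dt
        y += rng.normal(0.0, step_sd, size=n_walkers)
        z += rng.normal(0.0, step_sd, size=n_walkers)
        # radial reflection at the wall
        r = np.hypot(y, z)
        outside = r > r_c
        if np.any(outside):
            scale = (2.0 * r_c - r[outside]) / r[outside]
            y[outside] *= scale
            z[outside] *= scale

    return float(np.var(x) / u_mean ** 2)
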