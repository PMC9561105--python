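"""Closed-form particle physics near a wall.

A micrometre-sized bead denser than the surrounding medium sediments towards
the sensor surface, but thermal agitation keeps it hovering: at equilibrium the
particle-surface gap height h follows a barometric (exponential) distribution
with mean h_B = kT / (Δρ·V·g).  Close to the wall, hydrodynamic coupling slows
the bead down, so its in-plane diffusivity is the free Stokes-Einstein value
D0 = kT/(6πηa) multiplied by a height-dependent hindrance factor f∥(h, a) ≤ 1.
Averaging D0·f∥ over the equilibrium height distribution yields the
*characteristic diffusivity* that an experiment actually observes for the
unbound state.

Units are fixed package-wide: lengths in μm, time in s, temperature in K,
densities in g/cm³, viscosity in mPa·s.  All conversions are internal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

__all__ = [
    "BOLTZMANN_J_PER_K",
    "STANDARD_GRAVITY",
    "ParticleSpec",
    "HeightModel",
    "stokes_einstein_d0",
    "boltzmann_mean_height",
    "height_model_for",
    "sample_heights",
    "hindered_parallel",
    "hindered_perpendicular",
    "characteristic_diffusivity",
]

BOLTZMANN_J_PER_K = 1.380649e-23
STANDARD_GRAVITY = 9.81  # m/s^2

#: Near-contact floor for the parallel-hindrance series, where the truncated
#: Faxén expansion degrades; configurable per call.
DEFAULT_HINDRANCE_FLOOR = 0.05


class InvalidSpecError(ValueError):
    """A physically inconsistent particle or medium specification."""


@dataclass(frozen=True)
class ParticleSpec:
    """Physical description of a bead and its medium.

    Parameters
    ----------
    radius_um : float
        Particle radius a (μm).
    density_p : float
        Particle density ρ_p (g/cm³).  Must exceed the medium density for the
        bead to sediment towards the surface.
    density_m : float
        Medium density ρ_m (g/cm³); water is 1.0.
    viscosity_mPas : float
        Dynamic viscosity η (mPa·s); water at 23 °C is 0.93.
    temperature_K : float
        Absolute temperature (K); room temperature default 296 K.
    """

    radius_um: float
    density_p: float = 1.6
    density_m: float = 1.0
    viscosity_mPas: float = 0.93
    temperature_K: float = 296.0

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise InvalidSpecError(f"radius must be > 0 μm, got {self.radius_um}")
        if self.viscosity_mPas <= 0:
            raise InvalidSpecError(f"viscosity must be > 0 mPa·s, got {self.viscosity_mPas}")
        if self.temperature_K <= 0:
            raise InvalidSpecError(f"temperature must be > 0 K, got {self.temperature_K}")

    @property
    def diameter_um(self) -> float:
        return 2.0 * self.radius_um


@dataclass(frozen=True)
class HeightModel:
    """Equilibrium (barometric) gap-height distribution above the substrate.

    Heights are exponentially distributed on h ≥ 0 with mean ``mean_height_um``
    = kT/(Δρ·V·g), the ratio of thermal energy to buoyant weight.
    """

    mean_height_um: float
    gravity: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        if self.mean_height_um <= 0:
            raise InvalidSpecError(f"mean height must be > 0 μm, got {self.mean_height_um}")


def stokes_einstein_d0(spec: ParticleSpec) -> float:
    """Free (bulk) Stokes-Einstein diffusivity D0 = kT/(6πηa) in μm²/s."""
    a_m = spec.radius_um * 1e-6
    eta = spec.viscosity_mPas * 1e-3  # Pa·s
    d_m2s = BOLTZMANN_J_PER_K * spec.temperature_K / (6.0 * np.pi * eta * a_m)
    return d_m2s * 1e12


def boltzmann_mean_height(spec: ParticleSpec, gravity: float = STANDARD_GRAVITY) -> float:
    """Mean of the barometric height distribution, kT/(Δρ·V·g), in μm.

    Raises
    ------
    InvalidSpecError
        If ρ_p ≤ ρ_m (a neutrally buoyant or rising particle has no
        equilibrium sedimentation height).
    """
    delta_rho = (spec.density_p - spec.density_m) * 1000.0  # kg/m^3
    if delta_rho <= 0:
        raise InvalidSpecError(
            "particle density must exceed medium density for sedimentation "
            f"(ρ_p={spec.density_p}, ρ_m={spec.density_m} g/cm³)"
        )
    a_m = spec.radius_um * 1e-6
    volume = (4.0 / 3.0) * np.pi * a_m**3
    h_m = BOLTZMANN_J_PER_K * spec.temperature_K / (delta_rho * volume * gravity)
    return h_m * 1e6


def height_model_for(spec: ParticleSpec, gravity: float = STANDARD_GRAVITY) -> HeightModel:
    """Convenience: build the barometric HeightModel implied by a ParticleSpec."""
    return HeightModel(boltzmann_mean_height(spec, gravity), gravity)


def sample_heights(model: HeightModel, n: int, seed=None) -> np.ndarray:
    """Draw n i.i.d. gap heights (μm) from the barometric distribution.

    ``seed`` may be an int, a ``numpy.random.Generator`` or ``SeedSequence``;
    a fixed seed reproduces the sequence exactly.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return rng.exponential(model.mean_height_um, size=n)


def hindered_parallel(h, a: float, floor: float = DEFAULT_HINDRANCE_FLOOR):
    """Wall-drag correction f∥ ∈ (0, 1] for motion parallel to the substrate.

    Fifth-order Faxén series in β = a/(a+h) (method-of-reflections result for
    a sphere translating parallel to a plane wall):

        f∥(β) = 1 − (9/16)β + (1/8)β³ − (45/256)β⁴ − (1/16)β⁵

    The truncated series does not capture the logarithmic lubrication
    divergence at contact, so it is clamped below at ``floor`` (default 0.05).
    Accepts scalar or array h; vectorised.
    """
    if a <= 0:
        raise InvalidSpecError(f"radius must be > 0, got {a}")
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr < 0):
        raise ValueError("gap height h must be >= 0")
    beta = a / (a + h_arr)
    f = (
        1.0
        - (9.0 / 16.0) * beta
        + (1.0 / 8.0) * beta**3
        - (45.0 / 256.0) * beta**4
        - (1.0 / 16.0) * beta**5
    )
    f = np.clip(f, floor, 1.0)
    return float(f) if np.isscalar(h) or h_arr.ndim == 0 else f


def hindered_perpendicular(h, a: float):
    """Wall-drag correction f⊥ for motion normal to the substrate.

    Brenner-type rational approximation

        f⊥(h) = (6h² + 2ah) / (6h² + 9ah + 2a²)

    which vanishes linearly at contact (lubrication) and tends to 1 far from
    the wall.  Used by the simulator's height dynamics; the analysis layer
    never needs it.
    """
    if a <= 0:
        raise InvalidSpecError(f"radius must be > 0, got {a}")
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr < 0):
        raise ValueError("gap height h must be >= 0")
    f = (6.0 * h_arr**2 + 2.0 * a * h_arr) / (6.0 * h_arr**2 + 9.0 * a * h_arr + 2.0 * a**2)
    return float(f) if np.isscalar(h) or h_arr.ndim == 0 else f


def characteristic_diffusivity(
    spec: ParticleSpec,
    model: HeightModel | None = None,
    floor: float = DEFAULT_HINDRANCE_FLOOR,
) -> float:
    """Height-averaged in-plane diffusivity E[D0·f∥(h, a)] in μm²/s.

    The expectation is taken over the exponential barometric height
    distribution by adaptive quadrature.  Always strictly below the free
    Stokes-Einstein value because f∥ ≤ 1.
    """
    if model is None:
        model = height_model_for(spec)
    d0 = stokes_einstein_d0(spec)
    h_b = model.mean_height_um
    a = spec.radius_um

    def integrand(u):
        # substitute h = h_B * u so the exponential weight is exp(-u)
        return hindered_parallel(h_b * u, a, floor=floor) * np.exp(-u)

    val, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    if not np.isfinite(val) or err > 1e-6 * max(val, 1e-12):
        raise RuntimeError(
            f"height-average quadrature did not converge (value={val}, abserr={err})"
        )
    return d0 * val
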