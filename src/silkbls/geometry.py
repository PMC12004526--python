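"""Scattering geometry: probed phonon wave vectors and velocity conversion.

In Brillouin light spectroscopy the probed phonon wave vector
``q = k_s - k_i`` depends on the scattering geometry:

* transmission:    q∥ = (4π/λ)·sin(θ/2), independent of the refractive index,
  directed in the sample plane;
* reflection:      q⊥ = (4π/λ)·√(n² − cos²(θ/2)), index dependent, directed
  normal to the sample surface;
* backscattering:  q_bs = 4πn/λ (the θ→180° limit of the reflection form).

A phonon of frequency shift f (GHz) probed at wave vector q propagates with
phase velocity c = 2πf/q.  All functions accept the interface units of the
field (nm, degrees, GHz) and work in SI internally; ``WaveVector.magnitude``
is in 1/m with an ``inv_nm`` convenience property.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import ConfigError, PhysicalDomainError

GEOMETRIES = ("transmission", "reflection", "backscattering")
POLARIZATIONS = ("VV", "VH")


@dataclass(frozen=True)
class ScatteringConfig:
    """Laser/goniometer configuration of one BLS measurement.

    Parameters
    ----------
    wavelength_nm : float
        Vacuum laser wavelength (nm); 532 nm for the green laser used here.
    theta_deg : float
        Scattering angle between incident and scattered wave vectors (deg).
    n : float
        Refractive index of the sample (dimensionless, ≥ 1).
    geometry : {"transmission", "reflection", "backscattering"}
    polarization : {"VV", "VH"}
        Polarization of incident/scattered light relative to the scattering
        plane; VV selects longitudinal-type modes, VH transverse-type.
    """

    wavelength_nm: float
    theta_deg: float = 90.0
    n: float = 1.0
    geometry: str = "transmission"
    polarization: str = "VV"

    def __post_init__(self):
        if not self.wavelength_nm > 0:
            raise ConfigError(f"wavelength must be positive, got {self.wavelength_nm} nm")
        if not 0 < self.theta_deg <= 180:
            raise ConfigError(f"scattering angle must be in (0, 180], got {self.theta_deg}")
        if self.n < 1:
            raise ConfigError(f"refractive index must be >= 1, got {self.n}")
        if self.geometry not in GEOMETRIES:
            raise ConfigError(f"geometry must be one of {GEOMETRIES}, got {self.geometry!r}")
        if self.polarization not in POLARIZATIONS:
            raise ConfigError(f"polarization must be one of {POLARIZATIONS}, got {self.polarization!r}")

    def with_(self, **kw) -> "ScatteringConfig":
        return replace(self, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "ScatteringConfig":
        """Build from a JSON/YAML mapping with keys lambda_nm, theta_deg, n, geometry, polarization."""
        try:
            return cls(
                wavelength_nm=float(d["lambda_nm"]),
                theta_deg=float(d.get("theta_deg", 90.0)),
                n=float(d.get("n", 1.0)),
                geometry=str(d.get("geometry", "transmission")),
                polarization=str(d.get("polarization", "VV")),
            )
        except KeyError as e:  # pragma: no cover - trivial
            raise ConfigError(f"missing config key: {e}") from e

    def to_dict(self) -> dict:
        return {
            "lambda_nm": self.wavelength_nm,
            "theta_deg": self.theta_deg,
            "n": self.n,
            "geometry": self.geometry,
            "polarization": self.polarization,
        }


@dataclass(frozen=True)
class WaveVector:
    """A probed phonon wave vector.

    Attributes
    ----------
    magnitude : float
        |q| in 1/m (SI).  Use :attr:`inv_nm` for the customary nm⁻¹.
    alpha_deg : float
        Angle between q and the fiber symmetry axis; 0° means q parallel
        to the axis.
    index_dependent : bool
        Whether |q| depends on the refractive index of the sample.
    """

    magnitude: float
    alpha_deg: float = 0.0
    index_dependent: bool = False

    def __post_init__(self):
        if not self.magnitude > 0:
            raise ConfigError(f"wave vector magnitude must be positive, got {self.magnitude}")
        if not 0 <= self.alpha_deg <= 90:
            raise ConfigError(f"alpha must be in [0, 90] deg, got {self.alpha_deg}")

    @property
    def inv_nm(self) -> float:
        """|q| in nm⁻¹."""
        return self.magnitude * 1e-9


def q_transmission(config: ScatteringConfig, alpha_deg: float = 0.0) -> WaveVector:
    """In-plane wave vector q∥ = (4π/λ)·sin(θ/2) for the transmission geometry.

    Independent of the refractive index.  For λ = 532 nm, θ = 90° this is
    the paper-typical q∥ = 0.0167 nm⁻¹.
    """
    lam_m = config.wavelength_nm * 1e-9
    half = math.radians(config.theta_deg / 2.0)
    return WaveVector(4 * math.pi / lam_m * math.sin(half), alpha_deg, index_dependent=False)


def q_reflection(config: ScatteringConfig, alpha_deg: float = 90.0) -> WaveVector:
    """Surface-normal wave vector q⊥ = (4π/λ)·√(n² − cos²(θ/2)) (reflection geometry).

    Raises
    ------
    PhysicalDomainError
        If n² < cos²(θ/2), which no real scattering configuration satisfies.
    """
    lam_m = config.wavelength_nm * 1e-9
    half = math.radians(config.theta_deg / 2.0)
    disc = config.n**2 - math.cos(half) ** 2
    if disc < 0:
        raise PhysicalDomainError(
            f"n^2 = {config.n**2:.4f} < cos^2(theta/2) = {math.cos(half)**2:.4f}: "
            "no propagating phonon is probed in this configuration"
        )
    return WaveVector(4 * math.pi / lam_m * math.sqrt(disc), alpha_deg, index_dependent=True)


def q_backscatter(config: ScatteringConfig, alpha_deg: float = 0.0) -> WaveVector:
    """Backscattering wave vector q_bs = 4πn/λ.

    This is also the wave vector of the spurious backscattering-leakage path
    that produces the strong QL peak in transmission spectra of fibers.
    """
    lam_m = config.wavelength_nm * 1e-9
    return WaveVector(4 * math.pi * config.n / lam_m, alpha_deg, index_dependent=True)


def wavevector_for(config: ScatteringConfig, alpha_deg: float | None = None) -> WaveVector:
    """Dispatch on ``config.geometry``; default α is 0° in-axis, 90° for reflection."""
    if config.geometry == "transmission":
        return q_transmission(config, 0.0 if alpha_deg is None else alpha_deg)
    if config.geometry == "reflection":
        return q_reflection(config, 90.0 if alpha_deg is None else alpha_deg)
    return q_backscatter(config, 0.0 if alpha_deg is None else alpha_deg)


def leakage_alpha_deg(theta_deg: float, n: float) -> float:
    """Oblique angle α = arcsin(sin θ / n) of the backscattering-leakage phonon.

    This is the refraction-style form for the angle between the leaked
    backscattering wave vector and the fiber axis.  The actual angle depends
    on how the fiber axis is oriented relative to the scattering plane, which
    varies between setups, so downstream code treats α for the leakage mode
    as user-supplied; this helper is a convenience only.
    """
    s = math.sin(math.radians(theta_deg)) / n
    if not -1 <= s <= 1:
        raise PhysicalDomainError(f"sin(theta)/n = {s:.4f} outside [-1, 1]")
    return math.degrees(math.asin(s))


def velocity_from_shift(f_ghz: float, q: WaveVector) -> float:
    """Phase velocity c = 2πf/q in m/s from a frequency shift in GHz.

    The shift may be a Stokes/anti-Stokes average; its absolute value is used.
    """
    if q.magnitude <= 0:
        raise PhysicalDomainError(
            f"cannot convert a frequency shift to a velocity at q = {q.magnitude}; "
            "the probed wave vector must be positive"
        )
    return 2 * math.pi * abs(f_ghz) * 1e9 / q.magnitude


def shift_from_velocity(c_mps: float, q: WaveVector) -> float:
    """Inverse of :func:`velocity_from_shift`: f = cq/2π in GHz."""
    return c_mps * q.magnitude / (2 * math.pi) / 1e9
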