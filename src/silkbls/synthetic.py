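"""Synthetic BLS spectra and velocity datasets with the assumed noise structure.

Spectra are Lorentzian doublets at ±cq/2π (Stokes / anti-Stokes symmetric)
on a flat baseline with photon-counting (Poisson) noise by default; velocity
datasets are Christoffel forward-model values c(α) with i.i.d. Gaussian
errors.  Randomness is drawn from per-peak / per-datum substreams spawned
from the master seed, so adding a peak to a model never perturbs the noise
of the existing ones, and a fixed seed reproduces output bitwise.

``fixtures()`` returns the reference stiffness tensors of silkworm
(Bombyx mori) and spider (Nephila pilipes dragline) silk at 0% and 10%
tensile strain, plus the isotropic regenerated-fibroin film constants, at
full published precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Sequence

import numpy as np

from .christoffel import TIElasticTensor, velocities_ti
from .errors import ValidationError
from .geometry import ScatteringConfig, q_backscatter, shift_from_velocity, wavevector_for
from .inversion import VelocityDatum
from .spectral import Spectrum

#: laser vacuum wavelength used throughout (nm)
WAVELENGTH_NM = 532.0
#: silk refractive index
REFRACTIVE_INDEX = 1.54
#: mass densities (kg/m^3): silkworm fiber, regenerated fibroin film, and the
#: literature value for spider dragline silk (not re-measured here; it only
#: affects synthetic velocity generation, never tensor-to-moduli conversion)
RHO_FIBER = 1350.0
RHO_FILM = 1170.0
RHO_SPIDER = 1200.0


@dataclass(frozen=True)
class IsotropicFilmFixture:
    """Measured isotropic film constants: sound velocities (m/s) and density (kg/m³)."""

    c_L: float
    c_T: float
    rho: float
    n: float


def _ti(C11, C13, C33, C44, C66, C12, rho) -> TIElasticTensor:
    return TIElasticTensor(C11=C11, C12=C12, C13=C13, C33=C33, C44=C44, C66=C66, rho=rho)


_FIXTURES = MappingProxyType(
    {
        # stiffness constants in GPa, exactly as published (C12 as printed)
        "silkworm_0": _ti(C11=13.0, C13=8.6, C33=32.1, C44=4.5, C66=4.5, C12=4.0, rho=RHO_FIBER),
        "silkworm_10": _ti(C11=13.2, C13=8.9, C33=32.5, C44=4.6, C66=4.6, C12=4.0, rho=RHO_FIBER),
        "spider_0": _ti(C11=14.4, C13=8.0, C33=26.6, C44=4.1, C66=3.1, C12=8.2, rho=RHO_SPIDER),
        "spider_10": _ti(C11=13.8, C13=6.9, C33=30.3, C44=4.2, C66=3.9, C12=5.9, rho=RHO_SPIDER),
        "film": IsotropicFilmFixture(c_L=3235.0, c_T=1590.0, rho=RHO_FILM, n=REFRACTIVE_INDEX),
    }
)


def fixtures() -> MappingProxyType:
    """Immutable mapping of named reference fixtures.

    Keys: ``silkworm_0``, ``silkworm_10``, ``spider_0``, ``spider_10``
    (each a :class:`TIElasticTensor`) and ``film``
    (an :class:`IsotropicFilmFixture`).
    """
    return _FIXTURES


def default_config(geometry: str = "transmission", polarization: str = "VV",
                   theta_deg: float | None = None) -> ScatteringConfig:
    """The paper-typical configuration: 532 nm laser, n = 1.54, θ = 90° (120° in reflection)."""
    if theta_deg is None:
        theta_deg = 120.0 if geometry == "reflection" else 90.0
    return ScatteringConfig(
        wavelength_nm=WAVELENGTH_NM, theta_deg=theta_deg, n=REFRACTIVE_INDEX,
        geometry=geometry, polarization=polarization,
    )


@dataclass(frozen=True)
class SpectrumModel:
    """Recipe for one synthetic spectrum.

    ``peaks`` maps acoustic branches to sound velocities (m/s); each peak is
    placed at f = cq/2π using the wave vector its branch probes: the
    configured geometry's q for ordinary peaks and the backscattering-leakage
    q_bs for a ``QL`` peak in transmission.
    """

    peaks: tuple[tuple[str, float], ...]  # (branch, velocity m/s)
    fwhm_ghz: float = 0.8
    amplitude: float = 1000.0
    baseline: float = 10.0
    noise: str = "poisson"  # none | gaussian | poisson
    noise_sigma: float = 5.0  # counts, gaussian only
    seed: int = 0

    def __post_init__(self):
        if self.fwhm_ghz <= 0 or self.amplitude <= 0:
            raise ValidationError("fwhm and amplitude must be positive")
        if self.noise not in ("none", "gaussian", "poisson"):
            raise ValidationError(f"unknown noise model {self.noise!r}")


def generate_spectrum(
    model: SpectrumModel,
    config: ScatteringConfig,
    f_max_ghz: float = 25.0,
    df_ghz: float = 0.02,
    alpha_deg: float = 0.0,
    two_sided: bool = True,
) -> Spectrum:
    """Synthesize a spectrum of Lorentzian doublets at ω_B = ±cq.

    Raises
    ------
    ValidationError
        If any requested peak falls outside the frequency grid, listing the
        offenders.
    """
    half = np.arange(df_ghz, f_max_ghz + df_ghz / 2, df_ghz)
    f = np.concatenate([-half[::-1], [0.0], half]) if two_sided else half
    y = np.full_like(f, float(model.baseline))
    hwhm = model.fwhm_ghz / 2.0
    offenders = []
    centers = []
    for branch, c in model.peaks:
        if branch == "QL" and config.geometry == "transmission":
            q = q_backscatter(config)
        else:
            q = wavevector_for(config, alpha_deg)
        fc = shift_from_velocity(c, q)
        if fc + hwhm > f_max_ghz:
            offenders.append(f"{branch}: {fc:.2f} GHz (grid limit {f_max_ghz} GHz)")
        centers.append(fc)
    if offenders:
        raise ValidationError("peaks outside the frequency grid: " + "; ".join(offenders))
    contribs = []
    for fc in centers:
        sides = (fc, -fc) if two_sided else (fc,)
        contribs.append(
            sum(model.amplitude * hwhm**2 / ((f - s) ** 2 + hwhm**2) for s in sides)
        )
    # Substream 0 belongs to the baseline/detector, substream i+1 to peak i:
    # Poisson counts are drawn component-wise and summed, which is
    # distributionally identical to Poisson noise on the total signal but keeps
    # existing draws untouched when a peak is added to the model.
    streams = np.random.SeedSequence(model.seed).spawn(len(model.peaks) + 1)
    if model.noise == "poisson":
        y = np.zeros_like(f)
        for contrib, ss in zip([np.full_like(f, float(model.baseline))] + contribs, streams):
            y += np.random.default_rng(ss).poisson(np.clip(contrib, 0, None)).astype(float)
    else:
        y += sum(contribs)
        if model.noise == "gaussian":
            rng = np.random.default_rng(streams[0])
            y = np.clip(y + rng.normal(0, model.noise_sigma, size=f.shape), 0, None)
    return Spectrum(frequency_ghz=f, intensity=y, config=config)


@dataclass(frozen=True)
class DatasetDesign:
    """Design of a synthetic angle-dependent velocity dataset."""

    tensor: TIElasticTensor
    alpha_grid_deg: tuple[float, ...] = tuple(range(0, 91, 10))
    branches: tuple[str, ...] = ("QL", "QT", "PT")
    sigma_c: float = 50.0  # m/s
    seed: int = 0

    def __post_init__(self):
        if len(self.alpha_grid_deg) == 0:
            raise ValidationError("alpha grid must not be empty")
        if self.sigma_c < 0:
            raise ValidationError("sigma_c must be >= 0")


def generate_velocity_dataset(design: DatasetDesign) -> list[VelocityDatum]:
    """Draw c(α) from the Christoffel forward model plus Gaussian noise σ_c.

    Each (α, branch) cell uses its own substream of the master seed; σ_c is
    recorded on every datum (a 1 m/s floor is used for weighting when
    σ_c = 0, i.e. noiseless designs).
    """
    alphas = np.asarray(design.alpha_grid_deg, dtype=float)
    bv = velocities_ti(design.tensor, alphas)
    cells = [(a_i, b) for a_i in range(len(alphas)) for b in design.branches]
    streams = np.random.SeedSequence(design.seed).spawn(len(cells))
    out = []
    for (a_i, branch), ss in zip(cells, streams):
        c_true = float(np.asarray(bv.branch(branch))[a_i])
        noise = np.random.default_rng(ss).normal(0.0, design.sigma_c) if design.sigma_c > 0 else 0.0
        out.append(
            VelocityDatum(
                alpha_deg=float(alphas[a_i]),
                branch=branch,
                c=c_true + noise,
                sigma_c=design.sigma_c if design.sigma_c > 0 else 1.0,
            )
        )
    return out


def film_spectrum_models(seed: int = 0) -> dict[str, SpectrumModel]:
    """VV and VH spectrum recipes for the isotropic fibroin film."""
    film = _FIXTURES["film"]
    return {
        "VV": SpectrumModel(peaks=(("L_par", film.c_L),), seed=seed),
        "VH": SpectrumModel(peaks=(("PT", film.c_T),), amplitude=120.0, seed=seed + 1),
    }


def fiber_transmission_model(tensor: TIElasticTensor, alpha_deg: float = 0.0,
                             include_leakage: bool = True, seed: int = 0) -> SpectrumModel:
    """VV transmission recipe for a fiber: QT + L∥ at q∥ plus the leakage QL at q_bs."""
    bv = velocities_ti(tensor, alpha_deg)
    leak = velocities_ti(tensor, 63.0)  # oblique leakage path; angle is setup-dependent
    peaks = [("QT", float(bv.c_QT)), ("L_par", float(bv.c_QL))]
    if include_leakage:
        peaks.append(("QL", float(leak.c_QL)))
    return SpectrumModel(peaks=tuple(peaks), seed=seed)
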