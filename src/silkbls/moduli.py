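"""Engineering moduli from stiffness tensors and from sound velocities.

For a transversely isotropic solid (fiber axis = "3") the engineering
constants follow from the compliance S = C⁻¹:

    E∥  = E3  = 1/S33 = C33 − 2·C13²/(C11+C12)
    E⊥  = E1  = 1/S11 = (C11−C12)·[(C11+C12)·C33 − 2·C13²]/(C11·C33 − C13²)
    ν31 = ν32 = −S13/S33 = C13/(C11+C12)
    ν12 = −S12/S11 = (C12·C33 − C13²)/(C11·C33 − C13²)
    G13 = G23 = C44,   G12 = C66 = (C11−C12)/2
    K   = 1/Σ_{i,j≤3} S_ij  (Reuss, uniform-stress bulk modulus)
        = [C33·(C11+C12) − 2·C13²]/(C11 + C12 + 2·C33 − 4·C13)

For an elastically isotropic medium probed by light scattering the
longitudinal and shear moduli are M = ρc_L² and G = ρc_T², with Poisson's
ratio ν = (r² − 2)/(2(r² − 1)), r = c_L/c_T, Young's modulus E = 2G(1+ν)
and bulk modulus K = M − 4G/3.

Uncertainties on the tensor-derived moduli are first-order (delta-method)
propagations of a covariance over the stiffness constants, computed with a
central-difference Jacobian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .christoffel import TIElasticTensor
from .errors import PhysicalDomainError, ValidationError
from .geometry import WaveVector, velocity_from_shift

GPA = 1e9

MODULI_FIELDS = ("E_axial", "E_lateral", "anisotropy_ratio", "G_13", "G_12", "K", "nu_31", "nu_12")


@dataclass(frozen=True)
class EngineeringModuli:
    """Engineering constants of a transversely isotropic fiber (GPa; ν dimensionless).

    ``se`` holds delta-method standard errors keyed by field name when a
    covariance over the stiffness constants was supplied.
    """

    E_axial: float
    E_lateral: float
    anisotropy_ratio: float
    G_13: float
    G_12: float
    K: float
    nu_31: float
    nu_12: float
    se: Mapping[str, float] | None = None

    def as_dict(self, round_to: Mapping[str, int] | None = None) -> dict:
        d = {k: getattr(self, k) for k in MODULI_FIELDS}
        if round_to:
            d = {k: round(v, round_to.get(k, 6)) for k, v in d.items()}
        if self.se is not None:
            d["se"] = dict(self.se)
        return d


@dataclass(frozen=True)
class IsotropicElastic:
    """Isotropic elasticity from longitudinal and transverse sound velocities."""

    c_L: float
    c_T: float
    rho: float
    M: float
    G: float
    nu: float
    E: float
    K: float


def _moduli_values(tensor: TIElasticTensor) -> dict:
    C = tensor.voigt_matrix(si=False)  # GPa; work in GPa, outputs are GPa
    det_check = tensor.C11 * tensor.C33 - tensor.C13**2
    if det_check <= 0 or tensor.C11 + tensor.C12 <= 0:
        raise ValidationError(
            "tensor is not physical: C11*C33 - C13^2 and C11 + C12 must be positive"
        )
    S = np.linalg.inv(C)
    E3 = 1.0 / S[2, 2]
    E1 = 1.0 / S[0, 0]
    return {
        "E_axial": E3,
        "E_lateral": E1,
        "anisotropy_ratio": E3 / E1,
        "G_13": tensor.C44,
        "G_12": tensor.C66,
        "K": 1.0 / S[:3, :3].sum(),
        "nu_31": -S[0, 2] / S[2, 2],
        "nu_12": -S[0, 1] / S[0, 0],
    }


_FREE_ORDER = ("C11", "C33", "C44", "C13", "C66")


def moduli_from_tensor(
    tensor: TIElasticTensor,
    covariance: np.ndarray | None = None,
    param_names: Sequence[str] | None = None,
) -> EngineeringModuli:
    """Engineering moduli from a transversely isotropic stiffness tensor.

    Parameters
    ----------
    tensor : TIElasticTensor
    covariance : ndarray, optional
        Covariance matrix (GPa²) over the free stiffness constants listed in
        ``param_names`` (default ``("C11","C33","C44","C13")``, with C66
        locked to C44 and C12 to C11 − 2·C66 when absent from the names).
        Standard errors are then propagated to every modulus by the delta
        method.
    """
    vals = _moduli_values(tensor)
    se = None
    if covariance is not None:
        names = tuple(param_names) if param_names is not None else _FREE_ORDER[:4]
        cov = np.atleast_2d(np.asarray(covariance, dtype=float))
        if cov.shape != (len(names), len(names)):
            raise ValidationError(
                f"covariance shape {cov.shape} does not match parameters {names}"
            )
        jac = _numerical_jacobian(tensor, names)
        var = np.einsum("ki,ij,kj->k", jac, cov, jac)
        se = {f: float(math.sqrt(max(v, 0.0))) for f, v in zip(MODULI_FIELDS, var)}
    return EngineeringModuli(**vals, se=se)


def _perturbed(tensor: TIElasticTensor, names: Sequence[str], x: np.ndarray) -> TIElasticTensor:
    d = tensor.as_dict()
    for k, v in zip(names, x):
        d[k] = v
    if "C66" not in names:
        d["C66"] = d["C44"] if tensor.constraint_c66_equals_c44 else tensor.C66
    # keep the hexagonal identity exact under perturbation
    d["C12"] = d["C11"] - 2 * d["C66"]
    return TIElasticTensor(**d)


def _numerical_jacobian(tensor: TIElasticTensor, names: Sequence[str], h: float = 1e-5) -> np.ndarray:
    """d(moduli)/d(constants), central differences; rows follow MODULI_FIELDS."""
    x0 = np.array([getattr(tensor, k) for k in names], dtype=float)
    jac = np.zeros((len(MODULI_FIELDS), len(names)))
    for j in range(len(names)):
        for sgn in (+1, -1):
            x = x0.copy()
            x[j] += sgn * h
            vals = _moduli_values(_perturbed(tensor, names, x))
            jac[:, j] += sgn * np.array([vals[f] for f in MODULI_FIELDS])
    return jac / (2 * h)


def isotropic_moduli(c_L: float, c_T: float, rho: float) -> IsotropicElastic:
    """Isotropic elastic constants from measured sound velocities.

    M = ρc_L² and G = ρc_T² (GPa); ν = (r²−2)/(2(r²−1)) with r = c_L/c_T;
    E = 2G(1+ν); K = M − 4G/3.

    Raises
    ------
    PhysicalDomainError
        If c_L ≤ c_T, or c_L ≤ √(4/3)·c_T (which would give K ≤ 0).
    """
    if not (c_L > 0 and c_T > 0 and rho > 0):
        raise PhysicalDomainError("velocities and density must be positive")
    if c_L <= c_T:
        raise PhysicalDomainError(f"c_L = {c_L} must exceed c_T = {c_T}")
    if c_L <= math.sqrt(4.0 / 3.0) * c_T:
        raise PhysicalDomainError(
            f"c_L = {c_L} <= sqrt(4/3)*c_T = {math.sqrt(4/3)*c_T:.1f}: bulk modulus would be <= 0"
        )
    M = rho * c_L**2 / GPA
    G = rho * c_T**2 / GPA
    r2 = (c_L / c_T) ** 2
    nu = (r2 - 2.0) / (2.0 * (r2 - 1.0))
    return IsotropicElastic(
        c_L=c_L, c_T=c_T, rho=rho, M=M, G=G, nu=nu, E=2 * G * (1 + nu), K=M - 4 * G / 3
    )


def longitudinal_modulus(f_ghz: float, q: WaveVector, rho: float) -> float:
    """Longitudinal modulus M = ρ(2πf/q)² in GPa from one phonon peak.

    With q along (normal to) the fiber axis this is M∥ = C33 (M⊥ = C11);
    the same expression applied to a transverse peak yields the shear
    modulus ρc_T².
    """
    if rho <= 0:
        raise PhysicalDomainError(f"density must be positive, got {rho}")
    c = velocity_from_shift(f_ghz, q)
    return rho * c**2 / GPA
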