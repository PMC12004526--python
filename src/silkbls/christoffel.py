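"""Christoffel forward model for transversely isotropic media.

A transversely isotropic (hexagonal) elastic solid with the symmetry (fiber)
axis along "3" has five independent stiffness constants C11, C33, C44, C13,
C66, with C12 = C11 − 2·C66.  For a phonon propagating at angle α to the
fiber axis the Christoffel equation Γ·u = ρc²·u factorizes into a pure
transverse branch polarized normal to the (q, axis) plane,

    ρ c_PT² = C66 sin²α + C44 cos²α,

and a quasi-longitudinal / quasi-transverse pair

    ρ c²_{QL,QT} = ½ [ C11 sin²α + C33 cos²α + C44
        ± √( (C11 sin²α − C33 cos²α + C44 cos 2α)² + 4 (C13+C44)² sin²α cos²α ) ],

with QL taking the + root.  At α = 0° and 90° these reduce to pure modes:
c_QL(0) = √(C33/ρ), c_QL(90) = √(C11/ρ), c_PT(90) = √(C66/ρ), etc.

``christoffel_eigensolve`` provides an independent route through the full
3×3 acoustic tensor Γ_ik = C_ijkl n_j n_l / ρ, used to cross-validate the
closed forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ValidationError

GPA = 1e9

#: absolute tolerance (GPa) for the hexagonal identity C12 = C11 - 2 C66;
#: loose enough to admit constants rounded to 0.1 GPa, as printed in tables.
C12_IDENTITY_ATOL = 0.15


@dataclass(frozen=True)
class TIElasticTensor:
    """Transversely isotropic stiffness tensor (GPa) with mass density (kg/m³).

    The fiber axis is the Voigt "3" axis.  C12 is stored explicitly so that
    table-rounded constants can be represented exactly, but it must satisfy
    C12 = C11 − 2·C66 within ``C12_IDENTITY_ATOL``.
    """

    C11: float
    C12: float
    C13: float
    C33: float
    C44: float
    C66: float
    rho: float

    def __post_init__(self):
        self.validate()

    @classmethod
    def from_constants(
        cls, C11: float, C33: float, C44: float, C13: float, rho: float, C66: float | None = None
    ) -> "TIElasticTensor":
        """Build from the independent constants; C66 defaults to C44 and C12 is derived."""
        if C66 is None:
            C66 = C44
        return cls(C11=C11, C12=C11 - 2 * C66, C13=C13, C33=C33, C44=C44, C66=C66, rho=rho)

    def validate(self) -> None:
        if not self.rho > 0:
            raise ValidationError(f"density must be positive, got {self.rho}")
        if abs(self.C12 - (self.C11 - 2 * self.C66)) > C12_IDENTITY_ATOL:
            raise ValidationError(
                f"hexagonal identity violated: C12 = {self.C12} but C11 - 2*C66 = "
                f"{self.C11 - 2 * self.C66}"
            )
        if not (self.C44 > 0 and self.C66 > 0):
            raise ValidationError("shear constants C44, C66 must be positive")
        if not self.C11 > abs(self.C12):
            raise ValidationError(f"need C11 > |C12|, got C11={self.C11}, C12={self.C12}")
        if not (self.C11 + self.C12) * self.C33 > 2 * self.C13**2:
            raise ValidationError(
                f"need (C11+C12)*C33 > 2*C13^2 for positive definiteness, got "
                f"({self.C11}+{self.C12})*{self.C33} <= 2*{self.C13}^2"
            )

    @property
    def constraint_c66_equals_c44(self) -> bool:
        return abs(self.C66 - self.C44) < 1e-12

    def as_dict(self) -> dict:
        return {
            "C11": self.C11, "C12": self.C12, "C13": self.C13,
            "C33": self.C33, "C44": self.C44, "C66": self.C66, "rho": self.rho,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TIElasticTensor":
        return cls(**{k: float(d[k]) for k in ("C11", "C12", "C13", "C33", "C44", "C66", "rho")})

    def voigt_matrix(self, si: bool = False) -> np.ndarray:
        """6×6 stiffness in Voigt notation (GPa, or Pa when ``si``)."""
        C = np.zeros((6, 6))
        C[0, 0] = C[1, 1] = self.C11
        C[2, 2] = self.C33
        C[0, 1] = C[1, 0] = self.C12
        C[0, 2] = C[2, 0] = C[1, 2] = C[2, 1] = self.C13
        C[3, 3] = C[4, 4] = self.C44
        C[5, 5] = self.C66
        return C * GPA if si else C

    def stiffness_4th_order(self) -> np.ndarray:
        """Full C_ijkl in Pa, rebuilt from the Voigt matrix."""
        C6 = self.voigt_matrix(si=True)
        voigt = {(0, 0): 0, (1, 1): 1, (2, 2): 2, (1, 2): 3, (2, 1): 3,
                 (0, 2): 4, (2, 0): 4, (0, 1): 5, (1, 0): 5}
        C = np.empty((3, 3, 3, 3))
        for ij, I in voigt.items():
            for kl, J in voigt.items():
                C[ij[0], ij[1], kl[0], kl[1]] = C6[I, J]
        return C


@dataclass(frozen=True)
class BranchVelocities:
    """Phase velocities (m/s) of the three acoustic branches at angle α (deg)."""

    alpha_deg: np.ndarray | float
    c_QL: np.ndarray | float
    c_QT: np.ndarray | float
    c_PT: np.ndarray | float

    def branch(self, name: str):
        return {"QL": self.c_QL, "QT": self.c_QT, "PT": self.c_PT}[name]


def velocities_ti(tensor: TIElasticTensor, alpha_deg) -> BranchVelocities:
    """Closed-form TI branch velocities at propagation angle(s) α (deg).

    Vectorized over ``alpha_deg``.  QL takes the + root of the coupled
    longitudinal/transverse pair and satisfies c_QL ≥ c_QT everywhere.
    """
    tensor.validate()
    a = np.radians(np.asarray(alpha_deg, dtype=float))
    s2, c2 = np.sin(a) ** 2, np.cos(a) ** 2
    C11, C33, C44, C13, C66 = (
        tensor.C11 * GPA, tensor.C33 * GPA, tensor.C44 * GPA, tensor.C13 * GPA, tensor.C66 * GPA,
    )
    rho = tensor.rho
    pt = (C66 * s2 + C44 * c2) / rho
    half_sum = C11 * s2 + C33 * c2 + C44
    disc = (C11 * s2 - C33 * c2 + C44 * np.cos(2 * a)) ** 2 + 4 * (C13 + C44) ** 2 * s2 * c2
    root = np.sqrt(disc)
    ql = (half_sum + root) / (2 * rho)
    qt = (half_sum - root) / (2 * rho)
    out = BranchVelocities(
        alpha_deg=np.degrees(a) if a.ndim else float(alpha_deg),
        c_QL=np.sqrt(ql), c_QT=np.sqrt(qt), c_PT=np.sqrt(pt),
    )
    return out


def christoffel_eigensolve(tensor: TIElasticTensor, direction) -> np.ndarray:
    """Acoustic-tensor eigensolver: the three phase velocities along ``direction``.

    Builds Γ_ik = C_ijkl n_j n_l / ρ from the full fourth-order stiffness and
    returns the square roots of its eigenvalues, sorted descending.  Serves as
    a brute-force oracle for :func:`velocities_ti`.
    """
    n = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValidationError("propagation direction must be nonzero")
    if abs(norm - 1.0) > 1e-9:
        warnings.warn(f"direction norm {norm:.6g} != 1; normalizing", stacklevel=2)
        n = n / norm
    C = tensor.stiffness_4th_order()
    gamma = np.einsum("ijkl,j,l->ik", C, n, n) / tensor.rho
    evals = np.linalg.eigvalsh(gamma)
    return np.sqrt(evals[::-1])


def direction_from_alpha(alpha_deg: float) -> np.ndarray:
    """Unit propagation direction at angle α from the fiber ("3") axis, in the 1–3 plane."""
    a = np.radians(alpha_deg)
    return np.array([np.sin(a), 0.0, np.cos(a)])
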