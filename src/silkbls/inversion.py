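"""Weighted nonlinear inversion of angle-dependent sound velocities.

Fits the transversely isotropic Christoffel forward model c(α; C) to a
dataset of (α, branch, c, σ_c) points by minimizing

    χ² = Σ_i [ (c_i − c_model(α_i, branch_i; C)) / σ_i ]²

over the free stiffness constants — four (C11, C33, C44, C13) under the
C66 = C44 constraint appropriate when the pure transverse branch is only
observed on-axis, or five (… , C66) when off-axis PT data exist.

Phase velocities depend on C13 only through (C13 + C44)², so its sign is not
identifiable from velocity data alone; the conventional C13 + C44 > 0 branch
is reported (the data-driven initialization starts there and the optimizer
stays on it).  Positive definiteness is enforced by reparameterizing
C13 = t·√((C11 − C66)·C33) with t ∈ (−1, 1), so every iterate is a valid
tensor; the optimizer is scipy's bounded trust-region reflective least
squares.  The covariance is Jacobian-based and scaled by χ²/dof; a
residual-resampling bootstrap provides an independent uncertainty estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .christoffel import TIElasticTensor, velocities_ti
from .errors import FitConvergenceError, IdentifiabilityError, ValidationError

ConstraintMode = Literal["C66_equals_C44", "C66_free"]

#: default relative velocity uncertainty when a datum carries none
DEFAULT_REL_SIGMA = 0.01

_CII_BOUNDS = (1e-3, 200.0)  # GPa
_T_BOUND = 0.999


@dataclass(frozen=True)
class VelocityDatum:
    """One angle-dependent velocity observation."""

    alpha_deg: float
    branch: str  # QL | QT | PT
    c: float  # m/s
    sigma_c: float  # m/s

    def __post_init__(self):
        if self.branch not in ("QL", "QT", "PT"):
            raise ValidationError(f"branch must be QL/QT/PT, got {self.branch!r}")
        if not 0 <= self.alpha_deg <= 90:
            raise ValidationError(f"alpha must be in [0, 90], got {self.alpha_deg}")
        if not self.c > 0 or not self.sigma_c > 0:
            raise ValidationError("velocity and its uncertainty must be positive")


@dataclass
class TensorFitResult:
    """Result of :func:`fit_elastic_tensor`."""

    tensor: TIElasticTensor
    param_names: tuple[str, ...]
    covariance: np.ndarray  # GPa^2, over param_names
    chi2_dof: float
    constraint_mode: str
    residuals: np.ndarray  # m/s, c_obs - c_model
    n_data: int

    @property
    def se(self) -> dict[str, float]:
        """Standard errors (GPa) of the free constants."""
        d = np.sqrt(np.clip(np.diag(self.covariance), 0, None))
        return dict(zip(self.param_names, d.tolist()))

    def report(self) -> dict:
        return {
            "constants_GPa": self.tensor.as_dict(),
            "standard_errors_GPa": self.se,
            "chi2_dof": self.chi2_dof,
            "constraint_mode": self.constraint_mode,
            "n_data": self.n_data,
        }


def _with_default_sigma(data: Sequence[VelocityDatum]) -> list[VelocityDatum]:
    return list(data)


def check_identifiability(data: Sequence[VelocityDatum]) -> None:
    """Raise unless the design constrains all four coupled-branch constants.

    C33 needs a QL point near α = 0, C11 one near α = 90, and C13 enters
    the model only through the off-diagonal coupling ∝ sin²α·cos²α, so at
    least two QL/QT points at oblique angles are required.
    """
    ql = [d for d in data if d.branch == "QL"]
    if not any(d.alpha_deg <= 20 for d in ql):
        raise IdentifiabilityError("no QL datum near alpha=0: C33 is unconstrained")
    if not any(d.alpha_deg >= 70 for d in ql):
        raise IdentifiabilityError("no QL datum near alpha=90: C11 is unconstrained")
    oblique = [d for d in data if d.branch in ("QL", "QT") and 15 < d.alpha_deg < 75]
    if len(oblique) < 2:
        raise IdentifiabilityError(
            "C13 is unidentifiable: the design needs >= 2 QL or QT points at "
            "oblique alpha (15-75 deg); only pure-mode angles were provided"
        )


def _pack(tensor_like: dict, free_c66: bool) -> np.ndarray:
    C11, C33, C44, C13 = (tensor_like[k] for k in ("C11", "C33", "C44", "C13"))
    C66 = tensor_like["C66"] if free_c66 else C44
    scale = np.sqrt(max(C11 - C66, 1e-6) * C33)
    t = np.clip(C13 / scale, -_T_BOUND, _T_BOUND)
    x = [C11, C33, C44, t]
    if free_c66:
        x.append(C66)
    return np.asarray(x, dtype=float)


def _unpack(x: np.ndarray, rho: float, free_c66: bool) -> TIElasticTensor:
    C11, C33, C44, t = x[:4]
    C66 = x[4] if free_c66 else C44
    C13 = t * np.sqrt(max(C11 - C66, 1e-9) * C33)
    return TIElasticTensor.from_constants(C11=C11, C33=C33, C44=C44, C13=C13, rho=rho, C66=C66)


def _model_velocities(tensor: TIElasticTensor, alphas: np.ndarray, branches: np.ndarray) -> np.ndarray:
    bv = velocities_ti(tensor, alphas)
    out = np.empty(len(alphas))
    for name in ("QL", "QT", "PT"):
        m = branches == name
        if m.any():
            out[m] = np.asarray(bv.branch(name))[m]
    return out


def initial_tensor(data: Sequence[VelocityDatum], rho: float, free_c66: bool) -> dict:
    """Deterministic pure-mode starting values.

    C33 ← ρ·c_QL(α≈0)², C11 ← ρ·c_QL(α≈90)², C44 ← ρ·c_PT², and the
    heuristic C13 ← 0.9·√(C11·C33) − C44.
    """
    ql = sorted((d for d in data if d.branch == "QL"), key=lambda d: d.alpha_deg)
    c33 = rho * ql[0].c ** 2 / 1e9
    c11 = rho * ql[-1].c ** 2 / 1e9
    pt = [d for d in data if d.branch == "PT"] or [d for d in data if d.branch == "QT"]
    c44 = rho * min(d.c for d in pt) ** 2 / 1e9 if pt else 0.15 * c33
    c13 = 0.9 * np.sqrt(c11 * c33) - c44
    c66 = c44
    if free_c66:
        pt_hi = [d for d in data if d.branch == "PT" and d.alpha_deg >= 70]
        if pt_hi:
            c66 = rho * np.mean([d.c for d in pt_hi]) ** 2 / 1e9
    return {"C11": c11, "C33": c33, "C44": c44, "C13": c13, "C66": c66}


def fit_elastic_tensor(
    data: Sequence[VelocityDatum],
    rho: float,
    constraint_mode: ConstraintMode = "C66_equals_C44",
    init: TIElasticTensor | dict | None = None,
) -> TensorFitResult:
    """Invert a velocity dataset to the TI stiffness constants.

    Parameters
    ----------
    data : sequence of VelocityDatum
        Must contain QL points near α = 0 and α = 90 and at least two
        oblique QL/QT points (see :func:`check_identifiability`).
    rho : float
        Mass density (kg/m³).
    constraint_mode : {"C66_equals_C44", "C66_free"}
        Four- or five-constant fit.  The five-constant fit requires PT data
        away from α = 0, which alone inform C66.
    init : TIElasticTensor or dict, optional
        Starting constants; pure-mode initialization by default.

    Raises
    ------
    IdentifiabilityError, FitConvergenceError
    """
    if rho <= 0:
        raise ValidationError(f"density must be positive, got {rho}")
    if constraint_mode not in ("C66_equals_C44", "C66_free"):
        raise ValidationError(f"unknown constraint mode {constraint_mode!r}")
    data = list(data)
    check_identifiability(data)
    free_c66 = constraint_mode == "C66_free"
    if free_c66 and not any(d.branch == "PT" and d.alpha_deg > 15 for d in data):
        raise IdentifiabilityError(
            "C66_free requires off-axis PT data; only on-axis PT observed "
            "(use the C66_equals_C44 constraint instead)"
        )

    alphas = np.array([d.alpha_deg for d in data])
    branches = np.array([d.branch for d in data])
    c_obs = np.array([d.c for d in data])
    sig = np.array([d.sigma_c for d in data])

    def residuals(x):
        try:
            tensor = _unpack(x, rho, free_c66)
        except ValidationError:
            return np.full(len(data), 1e6)
        return (c_obs - _model_velocities(tensor, alphas, branches)) / sig

    if init is None:
        start = initial_tensor(data, rho, free_c66)
    elif isinstance(init, TIElasticTensor):
        start = init.as_dict()
    else:
        start = dict(init)
    x0 = _pack(start, free_c66)

    nfree = 5 if free_c66 else 4
    lo = [_CII_BOUNDS[0]] * 3 + [-_T_BOUND] + ([_CII_BOUNDS[0]] if free_c66 else [])
    hi = [_CII_BOUNDS[1]] * 3 + [_T_BOUND] + ([_CII_BOUNDS[1]] if free_c66 else [])

    rng = np.random.default_rng(0)
    best = None
    for attempt in range(11):
        x_start = x0 if attempt == 0 else np.clip(
            x0 * (1 + 0.2 * rng.standard_normal(len(x0))), lo, hi
        )
        sol = least_squares(residuals, x_start, bounds=(lo, hi), method="trf", x_scale="jac")
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and sol.cost < 1e12:
            best = sol if sol.cost <= best.cost else best
            if attempt == 0 or best.success:
                break
    if best is None or not best.success:
        raise FitConvergenceError(
            "tensor fit failed to converge from 10 perturbed starts",
            last_iterate=None if best is None else _unpack(best.x, rho, free_c66).as_dict(),
        )

    tensor = _unpack(best.x, rho, free_c66)
    dof = max(len(data) - nfree, 1)
    chi2_dof = 2 * best.cost / dof

    # covariance over the physical constants, via numerical Jacobian at the solution
    names = ("C11", "C33", "C44", "C13") + (("C66",) if free_c66 else ())
    cov = _physical_covariance(tensor, names, alphas, branches, sig, chi2_dof)
    resid = c_obs - _model_velocities(tensor, alphas, branches)
    return TensorFitResult(
        tensor=tensor,
        param_names=names,
        covariance=cov,
        chi2_dof=chi2_dof,
        constraint_mode=constraint_mode,
        residuals=resid,
        n_data=len(data),
    )


def _physical_covariance(tensor, names, alphas, branches, sig, chi2_dof, h=1e-5):
    base = tensor.as_dict()
    free_c66 = "C66" in names

    def model_of(vals):
        d = dict(base)
        d.update(vals)
        if not free_c66:
            d["C66"] = d["C44"]
        d["C12"] = d["C11"] - 2 * d["C66"]
        t = TIElasticTensor(**d)
        return _model_velocities(t, alphas, branches)

    J = np.zeros((len(alphas), len(names)))
    for j, nm in enumerate(names):
        up = model_of({nm: base[nm] + h})
        dn = model_of({nm: base[nm] - h})
        J[:, j] = (up - dn) / (2 * h) / sig
    JtJ = J.T @ J
    try:
        cov = np.linalg.inv(JtJ) * chi2_dof
    except np.linalg.LinAlgError:  # pragma: no cover - near-singular design
        cov = np.linalg.pinv(JtJ) * chi2_dof
    return cov


def bootstrap_uncertainty(
    data: Sequence[VelocityDatum],
    rho: float,
    constraint_mode: ConstraintMode = "C66_equals_C44",
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.683,
) -> dict[str, tuple[float, float]]:
    """Residual-resampling bootstrap percentile intervals for the constants.

    Standardized residuals of the point fit are resampled with replacement,
    rescaled by each datum's σ_c and added back to the model velocities; the
    fit is repeated ``n_boot`` times.  Deterministic under a fixed seed.
    """
    if n_boot < 100:
        raise ValidationError(f"n_boot must be >= 100, got {n_boot}")
    base = fit_elastic_tensor(data, rho, constraint_mode)
    sig = np.array([d.sigma_c for d in data])
    std_resid = base.residuals / sig
    alphas = np.array([d.alpha_deg for d in data])
    branches = np.array([d.branch for d in data])
    c_model = np.array([d.c for d in data]) - base.residuals
    if np.allclose(base.residuals, 0):
        warnings.warn("all residuals are zero; bootstrap intervals are degenerate", stacklevel=2)
        est = {k: base.tensor.as_dict()[k] for k in base.param_names}
        return {k: (v, v) for k, v in est.items()}
    rng = np.random.default_rng(seed)
    draws = {k: [] for k in base.param_names}
    for _ in range(n_boot):
        r = rng.choice(std_resid, size=len(data), replace=True)
        c_new = c_model + r * sig
        boot_data = [
            VelocityDatum(a, b, max(c, 1.0), s)
            for a, b, c, s in zip(alphas, branches, c_new, sig)
        ]
        try:
            res = fit_elastic_tensor(boot_data, rho, constraint_mode, init=base.tensor)
        except (FitConvergenceError, ValidationError):  # pragma: no cover - rare
            continue
        for k in base.param_names:
            draws[k].append(res.tensor.as_dict()[k])
    q = (1 - level) / 2
    return {
        k: (float(np.quantile(v, q)), float(np.quantile(v, 1 - q))) for k, v in draws.items()
    }
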