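"""Lorentzian peak extraction from BLS spectra and acoustic-branch labeling.

A BLS spectrum is a set of photon counts on a grid of signed frequency
shifts (GHz).  Phonon peaks are modeled as Lorentzians on a first-order
polynomial baseline and fitted by least squares (lmfit); peak-center
uncertainties come from the fit covariance scaled by √(χ²/dof), so over- or
under-dispersed counting noise inflates or deflates them accordingly.

Branch taxonomy (fiber with symmetry axis "3"):

* ``L_par``  — longitudinal phonon along the axis (VV, transmission, q∥);
* ``L_perp`` — longitudinal phonon normal to the axis (VV, reflection, q⊥);
* ``QL``     — quasi-longitudinal, here usually the backscattering-leakage
  mode at q_bs = 4πn/λ appearing in transmission spectra;
* ``QT``     — quasi-transverse;
* ``PT``     — pure transverse (VH spectra).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from lmfit import Parameters
from lmfit.models import ConstantModel, LinearModel, LorentzianModel
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

from .errors import FitConvergenceError, ValidationError
from .geometry import (
    ScatteringConfig,
    WaveVector,
    q_backscatter,
    velocity_from_shift,
    wavevector_for,
)

BRANCHES = ("L_par", "L_perp", "QL", "QT", "PT", "unassigned")


@dataclass(frozen=True)
class Spectrum:
    """One BLS spectrum: signed frequency-shift grid (GHz) and counts."""

    frequency_ghz: np.ndarray
    intensity: np.ndarray
    config: ScatteringConfig
    mask: Sequence[tuple[float, float]] | None = None  # excluded (lo, hi) GHz windows

    def __post_init__(self):
        f = np.asarray(self.frequency_ghz, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if f.ndim != 1 or f.shape != y.shape:
            raise ValidationError("frequency grid and intensity must be equal-length 1-D arrays")
        if not np.all(np.diff(f) > 0):
            raise ValidationError("frequency grid must be strictly increasing")
        if not np.all(np.isfinite(y)) or np.any(y < 0):
            raise ValidationError("intensity must be finite and non-negative")
        object.__setattr__(self, "frequency_ghz", f)
        object.__setattr__(self, "intensity", y)

    def masked(self) -> tuple[np.ndarray, np.ndarray]:
        """Grid and counts with masked windows (e.g. the elastic line) removed."""
        keep = np.ones_like(self.frequency_ghz, dtype=bool)
        for lo, hi in self.mask or ():
            keep &= ~((self.frequency_ghz >= lo) & (self.frequency_ghz <= hi))
        return self.frequency_ghz[keep], self.intensity[keep]


@dataclass(frozen=True)
class PhononPeak:
    """A fitted Brillouin peak.

    ``center_f`` is the signed fitted center (GHz); anti-Stokes peaks are
    positive.  ``amplitude`` is the peak height above baseline in counts.
    """

    center_f: float
    sigma_f: float
    fwhm: float
    amplitude: float
    branch: str = "unassigned"
    overlap_warning: bool = False
    note: str = ""

    def __post_init__(self):
        if self.branch not in BRANCHES:
            raise ValidationError(f"unknown branch {self.branch!r}")
        if not self.fwhm > 0:
            raise ValidationError(f"FWHM must be positive, got {self.fwhm}")
        if self.sigma_f < 0:
            raise ValidationError(f"sigma_f must be >= 0, got {self.sigma_f}")

    def with_branch(self, branch: str, note: str = "") -> "PhononPeak":
        return replace(self, branch=branch, note=note)


@dataclass
class FitDiagnostics:
    chi2: float
    chi2_dof: float
    n_eval: int
    success: bool
    message: str


def _initial_guesses(f: np.ndarray, y: np.ndarray, n_peaks: int) -> list[tuple[float, float, float]]:
    """(center, fwhm, height) guesses from local maxima of the median-filtered signal."""
    smooth = median_filter(y, size=5, mode="nearest")
    base = np.median(smooth)
    prom = max((smooth.max() - base) * 0.05, 1e-12)
    idx, props = find_peaks(smooth, prominence=prom)
    if len(idx) < n_peaks:
        # fall back to the n highest channels, spread apart
        order = np.argsort(smooth)[::-1]
        idx = []
        for i in order:
            if all(abs(f[i] - f[j]) > (f[-1] - f[0]) / (4 * n_peaks) for j in idx):
                idx.append(i)
            if len(idx) == n_peaks:
                break
        idx = np.asarray(sorted(idx))
    else:
        top = np.argsort(props["prominences"])[::-1][:n_peaks]
        idx = np.sort(idx[top])
    df = np.median(np.diff(f))
    return [(float(f[i]), max(5 * df, 0.1), float(max(smooth[i] - base, prom))) for i in idx]


def fit_peaks(
    spectrum: Spectrum,
    n_peaks: int,
    init: Sequence[tuple[float, float, float]] | None = None,
    resolution_ghz: float | None = None,
    weighting: str = "poisson",
) -> tuple[list[PhononPeak], FitDiagnostics]:
    """Fit ``n_peaks`` Lorentzians plus a linear baseline to a spectrum.

    Parameters
    ----------
    spectrum : Spectrum
    n_peaks : int
        Number of Lorentzian components.
    init : sequence of (center_GHz, fwhm_GHz, height_counts), optional
        Starting values; found automatically from local maxima of the
        median-filtered (window 5) signal when omitted.
    resolution_ghz : float, optional
        FWHM of a Gaussian instrument-resolution function; when given each
        line is a Voigt profile with that fixed Gaussian width instead of a
        plain Lorentzian.
    weighting : {"poisson", "none"}
        "poisson" weights channels by 1/√counts, matching photon-counting
        statistics; "none" fits unweighted.

    Returns
    -------
    peaks, diagnostics
        Peaks sorted by center frequency, with 1σ center uncertainties from
        the covariance scaled by √(χ²/dof).  Peaks closer than half their
        mean FWHM carry ``overlap_warning``.

    Raises
    ------
    FitConvergenceError
        If the optimizer does not converge; the exception carries the last
        parameter iterate.
    """
    if n_peaks < 1:
        raise ValidationError(f"n_peaks must be >= 1, got {n_peaks}")
    f, y = spectrum.masked()
    guesses = list(init) if init is not None else _initial_guesses(f, y, n_peaks)
    if len(guesses) != n_peaks:
        raise ValidationError(f"need {n_peaks} initial guesses, got {len(guesses)}")
    for c, _, _ in guesses:
        if not f[0] <= c <= f[-1]:
            raise ValidationError(f"initial center {c} GHz outside grid [{f[0]}, {f[-1]}]")

    model = LinearModel(prefix="bl_")
    params = model.make_params(slope=0.0, intercept=float(np.median(y)))
    span = f[-1] - f[0]
    for i, (c, w, h) in enumerate(guesses):
        if resolution_ghz is not None:
            from lmfit.models import VoigtModel

            comp = VoigtModel(prefix=f"p{i}_")
        else:
            comp = LorentzianModel(prefix=f"p{i}_")
        model = model + comp
        sigma = max(w, 1e-3) / 2.0  # Lorentzian HWHM
        params.update(comp.make_params())
        params[f"p{i}_center"].set(value=c, min=f[0], max=f[-1])
        params[f"p{i}_sigma"].set(value=sigma, min=1e-4, max=span)
        params[f"p{i}_amplitude"].set(value=h * np.pi * sigma, min=0)
        if resolution_ghz is not None:
            params[f"p{i}_gamma"].set(value=sigma, min=1e-4, max=span, vary=True)
            params[f"p{i}_sigma"].set(value=resolution_ghz / 2.3548, vary=False)

    weights = 1.0 / np.sqrt(np.clip(y, 1.0, None)) if weighting == "poisson" else None
    result = model.fit(y, params, x=f, weights=weights)
    if not result.success:
        raise FitConvergenceError(
            f"peak fit did not converge: {result.message}",
            last_iterate={k: v.value for k, v in result.params.items()},
        )

    peaks = []
    for i in range(n_peaks):
        p = result.params
        center = p[f"p{i}_center"].value
        stderr = p[f"p{i}_center"].stderr  # lmfit already scales covariance by chi2/dof
        if resolution_ghz is not None:
            fwhm = 2 * p[f"p{i}_gamma"].value
        else:
            fwhm = p[f"p{i}_fwhm"].value
        height = p[f"p{i}_height"].value if f"p{i}_height" in p else (
            p[f"p{i}_amplitude"].value / (np.pi * p[f"p{i}_sigma"].value)
        )
        peaks.append(
            PhononPeak(
                center_f=float(center),
                sigma_f=float(stderr) if stderr is not None else 0.0,
                fwhm=float(fwhm),
                amplitude=float(height),
            )
        )
    peaks.sort(key=lambda pk: pk.center_f)
    # overlap flag: centers closer than half the mean FWHM of the pair
    flagged = [False] * n_peaks
    for i in range(n_peaks - 1):
        gap = peaks[i + 1].center_f - peaks[i].center_f
        if gap < 0.25 * (peaks[i].fwhm + peaks[i + 1].fwhm):
            flagged[i] = flagged[i + 1] = True
    peaks = [replace(pk, overlap_warning=fl) for pk, fl in zip(peaks, flagged)]
    diag = FitDiagnostics(
        chi2=float(result.chisqr),
        chi2_dof=float(result.redchi),
        n_eval=int(result.nfev),
        success=bool(result.success),
        message=str(result.message),
    )
    return peaks, diag


def classify_branch(
    peak: PhononPeak,
    config: ScatteringConfig,
    alpha_deg: float = 0.0,
    candidate_velocities: dict[str, float] | None = None,
    rtol: float = 0.10,
) -> PhononPeak:
    """Assign an acoustic-branch label to a fitted peak.

    Rules, in order:

    * VH spectra probe the pure transverse mode; at α ≈ 0 the label is PT
      (off-axis VH peaks are left unassigned — quasi-mode leakage into VH is
      outside the model).
    * VV + reflection geometry probes the longitudinal phonon normal to the
      fiber axis: L_perp.
    * VV + backscattering: QL by construction.
    * VV + transmission is ambiguous between L_par/QT (at q∥) and the
      backscattering-leakage QL (at q_bs).  If ``candidate_velocities``
      (branch → expected velocity in m/s) is given, each hypothesis converts
      the fitted frequency to a velocity with its own wave vector and the
      best relative match within ``rtol`` wins; otherwise the peak stays
      unassigned with an explanatory note.
    """
    f = abs(peak.center_f)
    if config.polarization == "VH":
        if alpha_deg <= 15:
            return peak.with_branch("PT")
        return peak.with_branch("unassigned", note=f"VH peak at alpha={alpha_deg} deg: off-axis transverse modes are not classified")
    if config.geometry == "reflection":
        return peak.with_branch("L_perp")
    if config.geometry == "backscattering":
        return peak.with_branch("QL")
    # VV transmission
    if not candidate_velocities:
        return peak.with_branch(
            "unassigned",
            note="VV transmission peak needs candidate velocities to separate L_par/QT (q_par) from leakage QL (q_bs)",
        )
    q_par = wavevector_for(config, alpha_deg)
    q_bs = q_backscatter(config)
    best, best_err = None, rtol
    for branch, c_ref in candidate_velocities.items():
        if branch not in ("L_par", "QT", "QL"):
            continue
        q = q_bs if branch == "QL" else q_par
        c_implied = velocity_from_shift(f, q)
        err = abs(c_implied - c_ref) / c_ref
        if err < best_err:
            best, best_err = branch, err
    if best is None:
        return peak.with_branch(
            "unassigned",
            note=f"no candidate branch velocity within {rtol:.0%} of the implied velocity",
        )
    return peak.with_branch(best)


def classify_spectrum_peaks(
    peaks: Sequence[PhononPeak],
    config: ScatteringConfig,
    alpha_deg: float = 0.0,
    candidate_velocities: dict[str, float] | None = None,
) -> list[PhononPeak]:
    """Classify every peak of one spectrum.

    For a three-peak VV transmission spectrum without candidate velocities the
    frequency rank order QT < L_par < QL (leakage at the larger q_bs) is used.
    """
    peaks = sorted(peaks, key=lambda p: abs(p.center_f))
    if (
        candidate_velocities is None
        and config.polarization == "VV"
        and config.geometry == "transmission"
        and len(peaks) == 3
    ):
        return [
            peaks[0].with_branch("QT"),
            peaks[1].with_branch("L_par"),
            peaks[2].with_branch("QL", note="assigned to the backscattering-leakage wave vector q_bs"),
        ]
    return [classify_branch(p, config, alpha_deg, candidate_velocities) for p in peaks]
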