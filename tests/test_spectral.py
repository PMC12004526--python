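"""Lorentzian peak extraction and acoustic-branch classification."""

import numpy as np
import pytest

from silkbls import (
    PhononPeak,
    ScatteringConfig,
    Spectrum,
    classify_branch,
    classify_spectrum_peaks,
    fit_peaks,
    q_backscatter,
    q_transmission,
    shift_from_velocity,
)
from silkbls.synthetic import fiber_transmission_model, generate_spectrum


def lorentzian_spectrum(center=13.2, fwhm=0.8, height=1000.0, baseline=10.0,
                        noise_seed=None, scale=1.0, config=None):
    f = np.arange(5.0, 20.0, 0.02)
    hwhm = fwhm / 2
    y = baseline + height * hwhm**2 / ((f - center) ** 2 + hwhm**2)
    if noise_seed is not None:
        y = np.random.default_rng(noise_seed).poisson(y).astype(float)
    cfg = config or ScatteringConfig(wavelength_nm=532, theta_deg=90, n=1.54)
    return Spectrum(frequency_ghz=f, intensity=y * scale, config=cfg)


def test_noiseless_center_recovered_to_machine_precision():
    peaks, diag = fit_peaks(lorentzian_spectrum(), n_peaks=1)
    assert abs(peaks[0].center_f - 13.2) < 1e-6
    assert peaks[0].fwhm == pytest.approx(0.8, abs=1e-6)
    assert peaks[0].amplitude == pytest.approx(1000.0, rel=1e-5)
    assert diag.chi2_dof < 1e-12


def test_center_recovery_under_poisson_noise_is_calibrated():
    """Monte-Carlo: the fitted center covers the truth within 2 sigma in >= 47/50
    replicates, and the mean bias stays below 5% of the linewidth (SNR ~ 100)."""
    hits, centers = 0, []
    for seed in range(50):
        peaks, _ = fit_peaks(lorentzian_spectrum(noise_seed=seed), n_peaks=1)
        p = peaks[0]
        centers.append(p.center_f)
        if abs(p.center_f - 13.2) <= 2 * p.sigma_f:
            hits += 1
    assert hits >= 47
    assert abs(np.mean(centers) - 13.2) < 0.05 * 0.8


def test_intensity_rescaling_equivariance():
    p1, _ = fit_peaks(lorentzian_spectrum(), n_peaks=1)
    p7, _ = fit_peaks(lorentzian_spectrum(scale=7.0), n_peaks=1)
    assert p7[0].center_f == pytest.approx(p1[0].center_f, abs=1e-9)
    assert p7[0].amplitude == pytest.approx(7 * p1[0].amplitude, rel=1e-6)


def test_mirrored_spectrum_gives_negated_center():
    spec = lorentzian_spectrum()
    mirrored = Spectrum(
        frequency_ghz=-spec.frequency_ghz[::-1],
        intensity=spec.intensity[::-1],
        config=spec.config,
    )
    peaks, _ = fit_peaks(mirrored, n_peaks=1)
    assert peaks[0].center_f == pytest.approx(-13.2, abs=1e-6)


def test_elastic_line_mask_is_honored():
    spec = lorentzian_spectrum()
    masked = Spectrum(
        frequency_ghz=spec.frequency_ghz,
        intensity=spec.intensity,
        config=spec.config,
        mask=[(5.0, 7.0)],
    )
    f, y = masked.masked()
    assert f.min() > 7.0
    peaks, _ = fit_peaks(masked, n_peaks=1)
    assert abs(peaks[0].center_f - 13.2) < 1e-6


def test_overlapping_peaks_are_flagged():
    f = np.arange(5.0, 20.0, 0.02)
    y = 10.0
    for c in (12.0, 12.3):
        y = y + 800 * 0.4**2 / ((f - c) ** 2 + 0.4**2)
    spec = Spectrum(f, np.asarray(y), ScatteringConfig(532))
    peaks, _ = fit_peaks(spec, n_peaks=2, init=[(12.0, 0.8, 800), (12.3, 0.8, 800)])
    assert all(p.overlap_warning for p in peaks)


def test_three_peak_fiber_spectrum_recovered_in_rank_order(silkworm, transmission_cfg):
    model = fiber_transmission_model(silkworm, seed=3)
    spec = generate_spectrum(model, transmission_cfg)
    peaks, _ = fit_peaks(spec, n_peaks=6)  # three Stokes + three anti-Stokes
    anti = sorted([p for p in peaks if p.center_f > 0], key=lambda p: p.center_f)
    assert len(anti) == 3
    labeled = classify_spectrum_peaks(anti, transmission_cfg)
    assert [p.branch for p in labeled] == ["QT", "L_par", "QL"]
    # QT and L_par sit at q_par, the leakage QL at the larger q_bs
    f_l = shift_from_velocity(4876.2, q_transmission(transmission_cfg))
    assert labeled[1].center_f == pytest.approx(f_l, abs=0.05)


class TestClassifyBranch:
    peak = PhononPeak(center_f=4.94, sigma_f=0.01, fwhm=0.5, amplitude=100.0)

    def test_vh_on_axis_is_pure_transverse(self):
        cfg = ScatteringConfig(532, 90, 1.54, polarization="VH")
        assert classify_branch(self.peak, cfg, alpha_deg=0).branch == "PT"

    def test_vv_reflection_is_lateral_longitudinal(self, reflection_cfg):
        assert classify_branch(self.peak, reflection_cfg).branch == "L_perp"

    def test_vv_transmission_resolves_leakage_by_wavevector_consistency(self, transmission_cfg):
        # a peak whose frequency matches c*q_bs/2pi rather than c*q_par/2pi
        c_ref = 3500.0
        f_leak = shift_from_velocity(c_ref, q_backscatter(transmission_cfg))
        leak = PhononPeak(center_f=f_leak, sigma_f=0.02, fwhm=0.8, amplitude=500.0)
        out = classify_branch(
            leak, transmission_cfg, alpha_deg=0,
            candidate_velocities={"L_par": c_ref, "QL": c_ref},
        )
        assert out.branch == "QL"

    def test_ambiguous_assignment_is_explained(self, transmission_cfg):
        out = classify_branch(self.peak, transmission_cfg)
        assert out.branch == "unassigned"
        assert out.note
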