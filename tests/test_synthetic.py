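"""Synthetic spectra / velocity datasets: determinism, noise calibration, fixtures."""

import numpy as np
import pytest

from silkbls import (
    DatasetDesign,
    SpectrumModel,
    ValidationError,
    default_config,
    fixtures,
    generate_spectrum,
    generate_velocity_dataset,
)


def test_seeded_spectra_are_bitwise_reproducible(transmission_cfg):
    m = SpectrumModel(peaks=(("L_par", 4960.0),), noise="poisson", seed=123)
    s1 = generate_spectrum(m, transmission_cfg)
    s2 = generate_spectrum(m, transmission_cfg)
    assert np.array_equal(s1.intensity, s2.intensity)
    s3 = generate_spectrum(SpectrumModel(peaks=(("L_par", 4960.0),), noise="poisson", seed=124),
                           transmission_cfg)
    assert not np.array_equal(s1.intensity, s3.intensity)


def test_adding_a_peak_preserves_existing_draws(transmission_cfg):
    """Per-component substreams: noise already drawn does not change when a
    peak is added to the model."""
    m1 = SpectrumModel(peaks=(("QT", 1860.0),), baseline=50.0, noise="gaussian",
                       noise_sigma=5.0, seed=9)
    m2 = SpectrumModel(peaks=(("QT", 1860.0), ("L_par", 4960.0)), baseline=50.0,
                       noise="gaussian", noise_sigma=5.0, seed=9)
    one = generate_spectrum(m1, transmission_cfg)
    two = generate_spectrum(m2, transmission_cfg)
    # identical detector-noise draws: the difference is exactly the noiseless
    # Lorentzian doublet of the added peak
    diff = two.intensity - one.intensity
    clean = generate_spectrum(
        SpectrumModel(peaks=(("L_par", 4960.0),), baseline=0.0, noise="none", seed=9),
        transmission_cfg,
    )
    assert np.allclose(diff, clean.intensity, atol=1e-9)
    # and for Poisson counting noise, adding a peak can only add counts
    p1 = generate_spectrum(SpectrumModel(peaks=(("QT", 1860.0),), seed=9), transmission_cfg)
    p2 = generate_spectrum(
        SpectrumModel(peaks=(("QT", 1860.0), ("L_par", 4960.0)), seed=9), transmission_cfg
    )
    assert np.all(p2.intensity >= p1.intensity)


def test_stokes_antistokes_symmetry_is_exact(transmission_cfg):
    m = SpectrumModel(peaks=(("L_par", 4960.0), ("QT", 1860.0)), noise="none")
    s = generate_spectrum(m, transmission_cfg)
    assert np.allclose(s.intensity, s.intensity[::-1], rtol=0, atol=1e-9)


def test_gaussian_velocity_noise_matches_requested_sigma(silkworm):
    """Empirical sd over ~10^4 draws within 3% of sigma_c."""
    design = DatasetDesign(
        tensor=silkworm, alpha_grid_deg=tuple(np.linspace(0, 90, 3400)), sigma_c=50.0, seed=0
    )
    data = generate_velocity_dataset(design)
    from silkbls import velocities_ti

    alphas = np.array([d.alpha_deg for d in data])
    bv = velocities_ti(silkworm, alphas)
    truth = np.empty(len(data))
    for name in ("QL", "QT", "PT"):
        mask = np.array([d.branch == name for d in data])
        truth[mask] = np.asarray(bv.branch(name))[mask]
    resid = np.array([d.c for d in data]) - truth
    assert abs(resid.std() - 50.0) / 50.0 < 0.03
    assert len(data) >= 10000


def test_noiseless_dataset_equals_forward_model(silkworm):
    from silkbls import velocities_ti

    data = generate_velocity_dataset(DatasetDesign(tensor=silkworm, sigma_c=0.0))
    for d in data:
        assert d.c == pytest.approx(float(velocities_ti(silkworm, d.alpha_deg).branch(d.branch)))


def test_peaks_outside_grid_are_reported(transmission_cfg):
    m = SpectrumModel(peaks=(("L_par", 4960.0),), noise="none")
    with pytest.raises(ValidationError, match="L_par"):
        generate_spectrum(m, transmission_cfg, f_max_ghz=8.0)


def test_fixture_constants_match_published_values():
    fx = fixtures()
    assert fx["silkworm_0"].C33 == 32.1
    assert fx["silkworm_0"].C12 == 4.0
    assert fx["spider_10"].C33 == 30.3
    assert fx["spider_0"].C66 == 3.1
    assert fx["film"].rho == 1170
    assert fx["film"].c_L == 3235
    with pytest.raises(TypeError):
        fx["new"] = None  # immutable mapping


def test_fig2a_style_emulation_orders_three_branches(silkworm):
    """VV transmission with leakage enabled: QT < L_par < leakage QL in frequency."""
    from silkbls.synthetic import fiber_transmission_model

    cfg = default_config()
    m = fiber_transmission_model(silkworm, include_leakage=True)
    s = generate_spectrum(SpectrumModel(peaks=m.peaks, noise="none"), cfg)
    pos = s.frequency_ghz > 0
    f, y = s.frequency_ghz[pos], s.intensity[pos]
    from scipy.signal import find_peaks

    idx, _ = find_peaks(y, prominence=100)
    assert len(idx) == 3  # three resolved anti-Stokes peaks, rank order QT < L_par < QL
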