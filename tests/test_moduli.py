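"""Engineering moduli from stiffness tensors and from sound velocities."""

import math

import numpy as np
import pytest

from silkbls import (
    PhysicalDomainError,
    TIElasticTensor,
    WaveVector,
    isotropic_moduli,
    longitudinal_modulus,
    moduli_from_tensor,
    velocities_ti,
)


class TestModuliFromTensor:
    def test_silkworm_reference_values(self, silkworm):
        m = moduli_from_tensor(silkworm)
        assert m.E_axial == pytest.approx(23.4, abs=0.05)
        assert m.E_lateral == pytest.approx(10.4, abs=0.05)
        assert m.K == pytest.approx(8.5, abs=0.05)
        assert m.nu_31 == pytest.approx(0.51, abs=0.005)
        assert m.nu_12 == pytest.approx(0.16, abs=0.005)
        assert m.G_13 == m.G_12 == 4.5

    def test_spider_reference_values(self, spider):
        m = moduli_from_tensor(spider)
        assert m.E_axial == pytest.approx(20.9, abs=0.05)
        assert m.E_lateral == pytest.approx(9.2, abs=0.05)
        assert m.K == pytest.approx(10.8, abs=0.05)
        assert m.nu_31 == pytest.approx(0.35, abs=0.005)
        assert m.nu_12 == pytest.approx(0.48, abs=0.005)

    def test_isotropic_reduction(self):
        M0, G0 = 12.0, 3.0
        iso = TIElasticTensor.from_constants(C11=M0, C33=M0, C44=G0, C13=M0 - 2 * G0, rho=1200)
        m = moduli_from_tensor(iso)
        K0 = M0 - 4 * G0 / 3
        assert m.E_axial == pytest.approx(m.E_lateral, rel=1e-12)
        assert m.E_axial == pytest.approx(9 * K0 * G0 / (3 * K0 + G0), rel=1e-12)
        assert m.nu_31 == pytest.approx(m.nu_12, rel=1e-12)
        assert m.anisotropy_ratio == pytest.approx(1.0, rel=1e-12)

    def test_isotropic_reduction_matches_velocity_route(self):
        """The same isotropic solid, entered as a tensor or as (c_L, c_T, rho)."""
        M0, G0, rho = 12.244, 2.958, 1170.0
        iso_t = TIElasticTensor.from_constants(C11=M0, C33=M0, C44=G0, C13=M0 - 2 * G0, rho=rho)
        bv = velocities_ti(iso_t, 0.0)
        iso_v = isotropic_moduli(float(bv.c_QL), float(bv.c_PT), rho)
        m = moduli_from_tensor(iso_t)
        assert m.E_axial == pytest.approx(iso_v.E, rel=1e-9)
        assert m.nu_31 == pytest.approx(iso_v.nu, rel=1e-9)
        assert m.K == pytest.approx(iso_v.K, rel=1e-9)

    def test_tensor_moduli_tensor_round_trip(self, silkworm):
        """Rebuilding the compliance from the engineering constants recovers the tensor."""
        m = moduli_from_tensor(silkworm)
        S = np.zeros((6, 6))
        S[0, 0] = S[1, 1] = 1 / m.E_lateral
        S[2, 2] = 1 / m.E_axial
        S[0, 2] = S[2, 0] = S[1, 2] = S[2, 1] = -m.nu_31 / m.E_axial
        S[0, 1] = S[1, 0] = -m.nu_12 / m.E_lateral
        S[3, 3] = S[4, 4] = 1 / m.G_13
        S[5, 5] = 1 / m.G_12
        C = np.linalg.inv(S)
        for (i, j), name in {(0, 0): "C11", (0, 1): "C12", (0, 2): "C13",
                             (2, 2): "C33", (3, 3): "C44", (5, 5): "C66"}.items():
            assert C[i, j] == pytest.approx(getattr(silkworm, name), rel=1e-9)

    def test_delta_method_uncertainties_scale_linearly(self, silkworm):
        cov = np.diag([0.3, 1.0, 0.1, 0.3]) ** 2  # (C11, C33, C44, C13) standard errors
        se1 = moduli_from_tensor(silkworm, covariance=cov).se
        se2 = moduli_from_tensor(silkworm, covariance=4 * cov).se
        for k in se1:
            if se1[k] > 0:
                assert se2[k] == pytest.approx(2 * se1[k], rel=1e-6)
        # with the published constant uncertainties, the axial modulus error is ~1 GPa
        assert 0.5 < se1["E_axial"] < 2.0


class TestIsotropicModuli:
    def test_fibroin_film_reference(self):
        iso = isotropic_moduli(3235, 1590, 1170)
        assert iso.M == pytest.approx(12.2, abs=0.05)
        assert iso.G == pytest.approx(3.0, abs=0.05)
        assert iso.nu == pytest.approx(0.34, abs=0.005)

    def test_poisson_zero_at_sqrt2_ratio(self):
        iso = isotropic_moduli(math.sqrt(2) * 1590, 1590, 1170)
        assert iso.nu == pytest.approx(0.0, abs=1e-12)

    def test_incompressible_limit(self):
        iso = isotropic_moduli(1860 * 200, 1860, 1350)
        assert iso.nu == pytest.approx(0.5, abs=1e-4)

    def test_unphysical_velocity_order_rejected(self):
        with pytest.raises(PhysicalDomainError):
            isotropic_moduli(1500, 1600, 1170)
        with pytest.raises(PhysicalDomainError):
            isotropic_moduli(1600, 1590, 1170)  # K would be negative


class TestLongitudinalModulus:
    Q = WaveVector(magnitude=0.0167e9)

    def test_fiber_shear_modulus(self):
        # transverse phonon at c_T = 1860 m/s: rho c_T^2 = 4.7 GPa
        f = 1860 * self.Q.magnitude / (2 * math.pi) / 1e9
        assert longitudinal_modulus(f, self.Q, 1350) == pytest.approx(4.7, abs=0.05)

    def test_lateral_longitudinal_modulus(self):
        f = 3100 * self.Q.magnitude / (2 * math.pi) / 1e9
        assert longitudinal_modulus(f, self.Q, 1350) == pytest.approx(13.0, abs=0.05)

    def test_zero_frequency(self):
        assert longitudinal_modulus(0.0, self.Q, 1350) == 0.0
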