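"""Passive material law: energy/stress consistency, tension-only anisotropy,
infarct stiffening and frame indifference."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lvmech.constitutive import (Deformation, PassiveParams, active_cauchy_stress,
                                 fiber_stress, normalize_by_sbp, passive_energy,
                                 passive_cauchy_stress, elastic_energy,
                                 INFARCT_STIFFENING)

F0 = np.eye(3)
EX, EY, EZ = np.eye(3)


def _ho_energy_oracle(p, F, f0, s0):
    """Independent term-by-term evaluation of the Holzapfel-Ogden energy
    (isochoric isotropic invariant, tension-only anisotropic terms)."""
    C = F.T @ F
    J = np.linalg.det(F)
    I1b = J ** (-2 / 3) * np.trace(C)
    I4f = f0 @ C @ f0
    I4s = s0 @ C @ s0
    I8 = f0 @ C @ s0
    w = p.a / (2 * p.b) * (np.exp(p.b * (I1b - 3)) - 1)
    if I4f > 1:
        w += p.a_f / (2 * p.b_f) * (np.exp(p.b_f * (I4f - 1) ** 2) - 1)
    if I4s > 1:
        w += p.a_s / (2 * p.b_s) * (np.exp(p.b_s * (I4s - 1) ** 2) - 1)
    w += p.a_fs / (2 * p.b_fs) * (np.exp(p.b_fs * I8 ** 2) - 1)
    return w


def _rand_deformation(rng, scale=0.15):
    """Random admissible deformation gradient near the identity."""
    F = np.eye(3) + scale * rng.standard_normal((3, 3))
    if np.linalg.det(F) <= 0.05:
        F = np.eye(3)
    return Deformation(F=F, f0=EX, s0=EY)


def uniaxial_fiber_stretch(lam):
    """Incompressible uniaxial stretch along the fibre axis e_x."""
    return Deformation(F=np.diag([lam, lam ** -0.5, lam ** -0.5]), f0=EX, s0=EY)


def simple_shear_fs(k):
    """Simple shear in the fibre-sheet plane: x gains k * y."""
    F = np.eye(3)
    F[0, 1] = k
    return Deformation(F=F, f0=EX, s0=EY)


class TestPassiveEnergy:
    def test_reference_state_has_zero_energy_and_stress(self, p_healthy):
        d = Deformation(F=F0, f0=EX, s0=EY)
        assert passive_energy(p_healthy, d, 0.0) == pytest.approx(0.0, abs=1e-14)
        assert np.allclose(passive_cauchy_stress(p_healthy, d, 0.0), 0.0, atol=1e-12)

    def test_uniaxial_fiber_stretch_matches_independent_oracle(self, p_healthy):
        d = uniaxial_fiber_stretch(1.1)
        expect = _ho_energy_oracle(p_healthy, d.F, d.f0, d.s0)
        assert passive_energy(p_healthy, d, 0.0) == pytest.approx(expect, rel=1e-12)
        assert expect > 0

    def test_scar_is_exactly_fifty_fold_stiffer(self, p_healthy):
        d = simple_shear_fs(0.2)
        w0 = passive_energy(p_healthy, d, 0.0)
        w1 = passive_energy(p_healthy, d, 1.0)
        assert w0 > 0
        assert w1 / w0 == pytest.approx(INFARCT_STIFFENING, rel=1e-12)

    @pytest.mark.parametrize("M", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_infarct_scaling_linear_in_extent(self, p_healthy, M):
        d = uniaxial_fiber_stretch(1.08)  # isochoric: no penalty term
        w0 = passive_energy(p_healthy, d, 0.0)
        assert passive_energy(p_healthy, d, M) / w0 == pytest.approx(
            1 + (INFARCT_STIFFENING - 1) * M, rel=1e-12)

    def test_energy_is_objective_under_rotations(self, p_healthy, rng):
        d = _rand_deformation(rng)
        w = passive_energy(p_healthy, d, 0.3)
        for _ in range(10):
            A = rng.standard_normal((3, 3))
            Q, _ = np.linalg.qr(A)
            if np.linalg.det(Q) < 0:
                Q[:, 0] *= -1
            d_rot = Deformation(F=Q @ d.F, f0=d.f0, s0=d.s0)
            assert passive_energy(p_healthy, d_rot, 0.3) == pytest.approx(w, abs=1e-10)

    def test_compressed_fibers_bear_no_anisotropic_load(self, p_healthy):
        d = uniaxial_fiber_stretch(0.95)
        stiffer = PassiveParams(**{**p_healthy.to_dict(), "a_f": p_healthy.a_f * 100})
        assert passive_energy(p_healthy, d, 0.0) == pytest.approx(
            passive_energy(stiffer, d, 0.0), rel=1e-14)
        s1 = passive_cauchy_stress(p_healthy, d, 0.0)
        s2 = passive_cauchy_stress(stiffer, d, 0.0)
        assert np.allclose(s1, s2, atol=1e-12)

    def test_invalid_deformations_are_rejected(self, p_healthy):
        with pytest.raises(ValueError):
            Deformation(F=np.diag([1.0, 1.0, -1.0]), f0=EX, s0=EY)
        with pytest.raises(ValueError):
            Deformation(F=np.full((3, 3), np.nan), f0=EX, s0=EY)
        with pytest.raises(ValueError):
            Deformation(F=F0, f0=EX, s0=EX)  # not orthogonal


class TestStressEnergyConsistency:
    def _fd_cauchy(self, p, d, M, h=1e-6):
        """Finite-difference first Piola stress pushed forward to Cauchy."""
        F = d.F
        P = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[i, j] += h
                Fm[i, j] -= h
                wp = passive_energy(p, Deformation(F=Fp, f0=d.f0, s0=d.s0), M)
                wm = passive_energy(p, Deformation(F=Fm, f0=d.f0, s0=d.s0), M)
                P[i, j] = (wp - wm) / (2 * h)
        return P @ F.T / np.linalg.det(F)

    def test_stress_equals_energy_gradient(self, p_healthy, rng):
        checked = 0
        for _ in range(100):
            d = _rand_deformation(rng)
            sig = passive_cauchy_stress(p_healthy, d, 0.4)
            fd = self._fd_cauchy(p_healthy, d, 0.4)
            scale = max(1.0, np.abs(fd).max())
            assert np.allclose(sig, fd, atol=1e-4 * scale), (sig, fd)
            checked += 1
        assert checked == 100

    def test_stress_is_symmetric(self, p_healthy, rng):
        for _ in range(20):
            d = _rand_deformation(rng)
            sig = passive_cauchy_stress(p_healthy, d, 0.2)
            assert np.allclose(sig, sig.T, atol=1e-10)


class TestStressProjections:
    def test_active_stress_is_rank_one_along_fibers(self):
        d = Deformation(F=F0, f0=EX, s0=EY)
        sig = active_cauchy_stress(10.0, d)
        expect = np.zeros((3, 3))
        expect[0, 0] = 10.0
        assert np.allclose(sig, expect)
        assert np.allclose(active_cauchy_stress(0.0, d), 0.0)

    def test_fiber_projection_recovers_active_tension(self, rng):
        for _ in range(25):
            d = _rand_deformation(rng)
            T_a = float(rng.uniform(0, 100))
            sig = active_cauchy_stress(T_a, d)
            assert fiber_stress(sig, d) == pytest.approx(T_a, rel=1e-10)

    def test_fiber_stress_of_isotropic_tensor_is_the_pressure(self, rng):
        d = _rand_deformation(rng)
        assert fiber_stress(3.7 * np.eye(3), d) == pytest.approx(3.7)

    def test_projection_is_additive(self, p_healthy, rng):
        d = uniaxial_fiber_stretch(1.12)
        sp = passive_cauchy_stress(p_healthy, d, 0.0)
        sa = active_cauchy_stress(25.0, d)
        total = fiber_stress(sp + sa, d)
        assert total == pytest.approx(fiber_stress(sp, d) + fiber_stress(sa, d),
                                      rel=1e-12)

    def test_normalization_by_sbp(self):
        assert normalize_by_sbp(0.0, 120.0) == 0.0
        assert normalize_by_sbp(65.07, 144.6) == pytest.approx(0.45, abs=5e-3)
        assert normalize_by_sbp(65.23, 118.6) == pytest.approx(0.55, abs=5e-3)
        with pytest.raises(ValueError):
            normalize_by_sbp(1.0, 0.0)

    def test_degenerate_fiber_direction_raises(self):
        d = Deformation(F=F0, f0=EX, s0=EY)
        d.F = np.diag([1e-15, 1.0, 1.0])  # bypass validation to hit the guard
        with pytest.raises(ValueError):
            active_cauchy_stress(1.0, d)


class TestParams:
    def test_positive_coefficients_enforced(self):
        with pytest.raises(ValueError):
            PassiveParams(a=-0.1, b=2.6, a_f=3.34, b_f=2.73, a_s=0.69,
                          b_s=1.11, a_fs=0.31, b_fs=2.58)

    def test_yaml_round_trip(self, tmp_path, p_healthy):
        p_healthy.to_yaml(tmp_path / "p.yaml")
        assert PassiveParams.from_yaml(tmp_path / "p.yaml") == p_healthy

    @given(st.floats(1.0, 1.3), st.floats(0.0, 1.0))
    def test_energy_nonnegative_and_monotone_in_extent(self, lam, M):
        p = PassiveParams.healthy()
        d = uniaxial_fiber_stretch(lam)
        w = elastic_energy(p, d.F, d.f0, d.s0, M)
        assert w >= 0
        assert w >= elastic_energy(p, d.F, d.f0, d.s0, 0.0) - 1e-12
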