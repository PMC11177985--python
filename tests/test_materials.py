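"""Constitutive model: closed-form examples and a finite-difference oracle."""

import numpy as np
import pytest

from strain2infarct.materials import (DeformationState, FiberCompressionError,
                                      FiberFrame, InvalidDeformationError,
                                      MaterialParameters, active_second_pk,
                                      batch_cauchy_stress,
                                      decompose_deformation,
                                      passive_dev_second_pk,
                                      passive_strain_energy,
                                      total_cauchy_stress,
                                      volumetric_pressure)

PARAMS = MaterialParameters(c=1.2, B1=8.0, B2=3.0, B3=5.0, K=100.0)
FRAME_X = FiberFrame.from_fiber_direction([1.0, 0.0, 0.0])


def _random_F(rng):
    F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
    J = np.linalg.det(F)
    if J <= 0:
        F = np.eye(3) + 0.02 * rng.standard_normal((3, 3))
        J = np.linalg.det(F)
    target = rng.uniform(0.8, 1.2)
    return F * (target / J) ** (1.0 / 3.0)


class TestDecompose:
    def test_identity(self):
        st = decompose_deformation(np.eye(3))
        assert st.J == pytest.approx(1.0)
        np.testing.assert_allclose(st.E, 0.0, atol=1e-14)
        np.testing.assert_allclose(st.E_bar, 0.0, atol=1e-14)

    def test_uniaxial_stretch(self):
        st = decompose_deformation(np.diag([1.1, 1.0, 1.0]))
        assert st.J == pytest.approx(1.1)
        assert st.E[0, 0] == pytest.approx((1.1 ** 2 - 1) / 2)
        assert abs(np.linalg.det(st.F_bar) - 1.0) < 1e-10

    def test_simple_shear(self):
        F = np.eye(3)
        F[0, 1] = 0.2
        st = decompose_deformation(F)
        assert st.J == pytest.approx(1.0)
        assert st.E[0, 1] == pytest.approx(0.1)
        assert st.E[1, 1] == pytest.approx(0.02)
        assert st.E[0, 0] == pytest.approx(0.0)

    def test_negative_jacobian_rejected(self):
        with pytest.raises(InvalidDeformationError):
            decompose_deformation(np.diag([-1.0, 1.0, 1.0]))


class TestEnergy:
    def test_reference_energy_zero(self):
        st = decompose_deformation(np.eye(3))
        w_dev, w_vol = passive_strain_energy(st, PARAMS, FRAME_X)
        assert w_dev == pytest.approx(0.0)
        assert w_vol == pytest.approx(0.0)

    def test_fiber_strain_closed_form(self):
        p = MaterialParameters(c=1.0, B1=2.0, B2=1.0, B3=1.0, K=1.0)
        E_bar = np.diag([0.1, 0.0, 0.0])
        st = DeformationState(F=np.eye(3), J=1.0, F_bar=np.eye(3),
                              E=E_bar, E_bar=E_bar)
        w_dev, w_vol = passive_strain_energy(st, p, FRAME_X)
        assert w_dev == pytest.approx(np.exp(0.02) - 1.0)
        assert w_vol == pytest.approx(0.0)

    def test_volumetric_closed_form(self):
        p = MaterialParameters(c=1.0, B1=1.0, B2=1.0, B3=1.0, K=100.0)
        st = decompose_deformation(np.eye(3) * 1.2 ** (1.0 / 3.0))
        _, w_vol = passive_strain_energy(st, p, FRAME_X)
        assert w_vol == pytest.approx(50.0 * ((1.44 - 1.0) / 2.0 - np.log(1.2)))

    def test_volumetric_energy_minimum_at_reference(self):
        # dW_vol/dJ changes sign at J = 1 and W_vol >= 0 on both sides
        for J in (0.8, 0.9, 1.1, 1.3):
            st = decompose_deformation(np.eye(3) * J ** (1.0 / 3.0))
            _, w_vol = passive_strain_energy(st, PARAMS, FRAME_X)
            assert w_vol > 0
        assert volumetric_pressure(0.99, PARAMS) < 0 < volumetric_pressure(1.01, PARAMS)
        assert volumetric_pressure(1.0, PARAMS) == pytest.approx(0.0)


class TestActive:
    def test_zero_fiber_strain(self):
        p = MaterialParameters(c=1, B1=1, B2=1, B3=1, K=1, T_Ca=10.0, beta=1.5)
        S = active_second_pk(np.zeros((3, 3)), FRAME_X, p)
        np.testing.assert_allclose(S, 10.0 * np.outer(FRAME_X.N, FRAME_X.N))

    def test_infarct_has_no_contraction(self, rng):
        p = MaterialParameters(c=1, B1=1, B2=1, B3=1, K=1, T_Ca=0.0, beta=1.5)
        E = 0.1 * rng.standard_normal((3, 3))
        E = 0.5 * (E + E.T)
        np.testing.assert_allclose(active_second_pk(E, FRAME_X, p), 0.0)

    def test_stretched_fiber_closed_form(self):
        # lambda = 1.1 -> Ef = 0.105, Ta = 10*(1 + 1.5*0.1) = 11.5
        p = MaterialParameters(c=1, B1=1, B2=1, B3=1, K=1, T_Ca=10.0, beta=1.5)
        E = np.diag([0.105, 0.0, 0.0])
        S = active_second_pk(E, FRAME_X, p)
        assert S[0, 0] == pytest.approx(11.5 / 1.21)
        assert np.linalg.matrix_rank(S, tol=1e-10) == 1

    def test_unphysical_compression_rejected(self):
        p = MaterialParameters(c=1, B1=1, B2=1, B3=1, K=1, T_Ca=1.0)
        with pytest.raises(FiberCompressionError):
            active_second_pk(np.diag([-0.6, 0.0, 0.0]), FRAME_X, p)

    def test_active_tension_monotone_in_fiber_strain(self):
        p = MaterialParameters(c=1, B1=1, B2=1, B3=1, K=1, T_Ca=7.0, beta=2.0)
        efs = np.linspace(-0.45, 0.5, 50)
        ta = [p.T_Ca * (1 + p.beta * (np.sqrt(2 * ef + 1) - 1)) for ef in efs]
        assert np.all(np.diff(ta) >= 0)


class TestTotalStress:
    def test_stress_free_reference(self):
        st = decompose_deformation(np.eye(3))
        T = total_cauchy_stress(st, FRAME_X, PARAMS)
        np.testing.assert_allclose(T, 0.0, atol=1e-10)

    def test_active_stress_at_identity(self):
        p = MaterialParameters(c=1.2, B1=8, B2=3, B3=5, K=100, T_Ca=10.0)
        st = decompose_deformation(np.eye(3))
        T = total_cauchy_stress(st, FRAME_X, p)
        np.testing.assert_allclose(T, 10.0 * np.outer(FRAME_X.N, FRAME_X.N),
                                   atol=1e-10)

    def test_symmetry(self, rng):
        p = MaterialParameters(c=1.2, B1=8, B2=3, B3=5, K=100, T_Ca=5.0,
                               beta=1.5)
        for _ in range(20):
            frame = FiberFrame.from_fiber_direction(rng.standard_normal(3))
            T = total_cauchy_stress(decompose_deformation(_random_F(rng)),
                                    frame, p)
            np.testing.assert_allclose(T, T.T, atol=1e-10)

    def test_passive_stress_matches_energy_finite_differences(self, rng):
        """dW_dev/dEbar and dW_vol/dJ against central differences (h=1e-6)."""
        h = 1e-6
        for _ in range(100):
            frame = FiberFrame.from_fiber_direction(rng.standard_normal(3))
            st = decompose_deformation(_random_F(rng))
            S = passive_dev_second_pk(st, PARAMS, frame)
            S_fd = np.zeros((3, 3))
            for i in range(3):
                for j in range(i, 3):
                    dE = np.zeros((3, 3))
                    dE[i, j] = dE[j, i] = h
                    wp = _w_dev(st.E_bar + dE, PARAMS, frame)
                    wm = _w_dev(st.E_bar - dE, PARAMS, frame)
                    d = (wp - wm) / (2 * h)
                    # symmetric perturbation: off-diagonals collect both entries
                    S_fd[i, j] = S_fd[j, i] = d / (2.0 if i != j else 1.0)
            assert np.abs(S - S_fd).max() <= 1e-5 * (1 + np.abs(S_fd).max())
            p_fd = (_w_vol(st.J + h, PARAMS) - _w_vol(st.J - h, PARAMS)) / (2 * h)
            assert abs(volumetric_pressure(st.J, PARAMS) - p_fd) \
                <= 1e-5 * (1 + abs(p_fd))


def _w_dev(E_bar, p, frame):
    st = DeformationState(F=np.eye(3), J=1.0, F_bar=np.eye(3),
                          E=E_bar, E_bar=E_bar)
    return passive_strain_energy(st, p, frame)[0]


def _w_vol(J, p):
    st = DeformationState(F=np.eye(3), J=J, F_bar=np.eye(3),
                          E=np.zeros((3, 3)), E_bar=np.zeros((3, 3)))
    return passive_strain_energy(st, p, None)[1]


class TestInterfaces:
    def test_parameters_json_round_trip(self):
        p = MaterialParameters(c=1.2, B1=8, B2=3, B3=5, K=100, T_Ca=4.0,
                               beta=1.5)
        assert MaterialParameters.from_json(p.to_json()) == p

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            MaterialParameters(c=-1, B1=1, B2=1, B3=1, K=1)
        with pytest.raises(ValueError):
            MaterialParameters(c=1, B1=1, B2=1, B3=1, K=1, T_Ca=-2)

    def test_batch_csv_round_trip(self, rng, tmp_path):
        import pandas as pd

        rows = [_random_F(rng).ravel() for _ in range(5)]
        table = pd.DataFrame(rows, columns=[f"F{i}{j}" for i in (1, 2, 3)
                                            for j in (1, 2, 3)])
        out = batch_cauchy_stress(table, PARAMS, FRAME_X)
        path = tmp_path / "stress.csv"
        out.to_csv(path, index=False)
        back = pd.read_csv(path)
        T0 = total_cauchy_stress(
            decompose_deformation(rows[0].reshape(3, 3)), FRAME_X, PARAMS)
        assert back.loc[0, "T11"] == pytest.approx(T0[0, 0])

    def test_frame_orthonormality_enforced(self):
        with pytest.raises(ValueError):
            FiberFrame(N=np.array([1.0, 0, 0]), e2=np.array([1.0, 0, 0]),
                       e3=np.array([0, 0, 1.0]))
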