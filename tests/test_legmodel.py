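"""Leg kinematics and dynamics against geometric and variational oracles."""

import dataclasses

import numpy as np
import pytest

from neurogait.legmodel import (LegParams, LegState, coriolis_matrix,
                                coriolis_vector, dh_forward_kinematics,
                                generalized_forces, gravity_vector,
                                inverse_dynamics, joint_torques_from_generalized,
                                link_com_positions, mass_matrix,
                                passive_simulate, total_energy)

LP = LegParams()


def planar_transform(theta, length):
    """Homogeneous transform: rotate by theta (from straight down), then
    translate along the link."""
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    trans = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, -length], [0.0, 0.0, 1.0]])
    return rot @ trans


class TestForwardKinematics:
    def test_straight_down(self):
        fk = dh_forward_kinematics([0.0, 0.0], LP)
        assert np.allclose(fk["ankle"], [0.0, -0.4])

    def test_horizontal_leg(self):
        fk = dh_forward_kinematics([np.pi / 2, np.pi / 2], LP)
        assert np.allclose(fk["ankle"], [0.4, 0.0], atol=1e-12)

    def test_matches_transform_chain_oracle(self, rng):
        """20 random poses against a product of planar homogeneous
        transforms."""
        for _ in range(20):
            q = rng.uniform(-np.pi, np.pi, 2)
            fk = dh_forward_kinematics(q, LP)
            t1 = planar_transform(q[0], LP.L1)
            knee = (t1 @ [0.0, 0.0, 1.0])[:2]
            # second link angle is absolute: rotate relative to link 1
            t2 = t1 @ planar_transform(q[1] - q[0], LP.L2)
            ankle = (t2 @ [0.0, 0.0, 1.0])[:2]
            assert np.allclose(fk["knee"], knee, atol=1e-12)
            assert np.allclose(fk["ankle"], ankle, atol=1e-12)


class TestComPositions:
    def test_straight_down(self):
        x1, y1, x2, y2 = link_com_positions(LegState([0.0, 0.0]), LP)
        assert (x1, y1) == pytest.approx((0.0, -LP.r1))
        assert (x2, y2) == pytest.approx((0.0, -LP.L1 - LP.r2))

    def test_thigh_horizontal(self):
        x1, y1, _, _ = link_com_positions(LegState([np.pi / 2, 0.0]), LP)
        assert x1 == pytest.approx(LP.r1)
        assert y1 == pytest.approx(0.0, abs=1e-15)

    def test_random_pose_formula_substitution(self, rng):
        th1, th2 = rng.uniform(-np.pi, np.pi, 2)
        x1, y1, x2, y2 = link_com_positions(LegState([th1, th2]), LP)
        assert x1 == pytest.approx(LP.r1 * np.sin(th1))
        assert y1 == pytest.approx(-LP.r1 * np.cos(th1))
        assert x2 == pytest.approx(LP.L1 * np.sin(th1) + LP.r2 * np.sin(th2))
        assert y2 == pytest.approx(-LP.L1 * np.cos(th1) - LP.r2 * np.cos(th2))


def lagrangian(q, qd, p: LegParams) -> float:
    """Independent Lagrangian: T − V assembled from COM velocities obtained
    by finite-differencing the position formulas."""
    h = 1e-6

    def com(qv):
        s = LegState(qv)
        x1, y1, x2, y2 = link_com_positions(s, p)
        return np.array([x1, y1, x2, y2])

    jac = np.empty((4, 2))
    for j in range(2):
        e = np.zeros(2)
        e[j] = h
        jac[:, j] = (com(q + e) - com(q - e)) / (2 * h)
    v = jac @ qd
    T = (0.5 * p.m1 * (v[0] ** 2 + v[1] ** 2) + 0.5 * p.I1 * qd[0] ** 2
         + 0.5 * p.m2 * (v[2] ** 2 + v[3] ** 2) + 0.5 * p.I2 * qd[1] ** 2)
    x1, y1, x2, y2 = com(q)
    V = p.m1 * p.g * y1 + p.m2 * p.g * y2
    return T - V


def euler_lagrange_oracle(q, qd, qdd, p: LegParams) -> np.ndarray:
    """Q_i = d/dt(∂L/∂q̇_i) − ∂L/∂q_i by central differences along the
    trajectory q(t) = q + q̇ t + ½ q̈ t²."""
    h = 1e-4

    def dL_dqd(qv, qdv):
        out = np.empty(2)
        for i in range(2):
            e = np.zeros(2)
            e[i] = h
            out[i] = (lagrangian(qv, qdv + e, p)
                      - lagrangian(qv, qdv - e, p)) / (2 * h)
        return out

    ht = 1e-4
    q_plus = q + qd * ht + 0.5 * qdd * ht ** 2
    q_minus = q - qd * ht + 0.5 * qdd * ht ** 2
    qd_plus = qd + qdd * ht
    qd_minus = qd - qdd * ht
    dt_term = (dL_dqd(q_plus, qd_plus) - dL_dqd(q_minus, qd_minus)) / (2 * ht)

    dq_term = np.empty(2)
    for i in range(2):
        e = np.zeros(2)
        e[i] = h
        dq_term[i] = (lagrangian(q + e, qd, p)
                      - lagrangian(q - e, qd, p)) / (2 * h)
    return dt_term - dq_term


class TestInverseDynamics:
    def test_hanging_rest_needs_no_torque(self):
        st = LegState([0.0, 0.0], [0.0, 0.0], [0.0, 0.0])
        assert np.allclose(inverse_dynamics(st, LP), 0.0)

    def test_static_horizontal_gravity_moments(self):
        """Hip torque carries every gravity moment about the hip; the knee
        only its own link's moment."""
        st = LegState([np.pi / 2, np.pi / 2], [0.0, 0.0], [0.0, 0.0])
        tau = inverse_dynamics(st, LP)
        assert tau[0] == pytest.approx(
            (LP.m1 * LP.r1 + LP.m2 * LP.L1 + LP.m2 * LP.r2) * LP.g)
        assert tau[1] == pytest.approx(LP.m2 * LP.r2 * LP.g)

    def test_matches_finite_difference_euler_lagrange(self, rng):
        """50 random states: generalized forces match the variational oracle
        to 1e-6 relative."""
        for _ in range(50):
            q = rng.uniform(-np.pi, np.pi, 2)
            qd = rng.uniform(-3, 3, 2)
            qdd = rng.uniform(-10, 10, 2)
            Q = generalized_forces(LegState(q, qd, qdd), LP)
            Q_oracle = euler_lagrange_oracle(q, qd, qdd, LP)
            scale = max(np.abs(Q_oracle).max(), 1.0)
            assert np.abs(Q - Q_oracle).max() <= 1e-6 * scale
            tau = inverse_dynamics(LegState(q, qd, qdd), LP)
            assert np.allclose(tau, joint_torques_from_generalized(Q_oracle),
                               atol=1e-5 * scale)


class TestMassMatrix:
    def test_symmetric_positive_definite(self, rng):
        for _ in range(20):
            M = mass_matrix(rng.uniform(-np.pi, np.pi, 2), LP)
            assert np.allclose(M, M.T)
            assert (np.linalg.eigvalsh(M) > 0).all()

    def test_zero_velocity_kills_coriolis(self, rng):
        q = rng.uniform(-np.pi, np.pi, 2)
        assert np.allclose(coriolis_vector(q, np.zeros(2), LP), 0.0)

    def test_unit_acceleration_probing_recovers_M(self, rng):
        q = rng.uniform(-np.pi, np.pi, 2)
        weightless = dataclasses.replace(LP, g=0.0)
        cols = [generalized_forces(LegState(q, np.zeros(2), e), weightless)
                for e in np.eye(2)]
        assert np.allclose(np.array(cols).T, mass_matrix(q, LP), atol=1e-12)

    def test_mdot_minus_2C_skew_symmetric(self, rng):
        h = 1e-7
        for _ in range(10):
            q = rng.uniform(-np.pi, np.pi, 2)
            qd = rng.uniform(-3, 3, 2)
            Mdot = (mass_matrix(q + h * qd, LP)
                    - mass_matrix(q - h * qd, LP)) / (2 * h)
            S = Mdot - 2 * coriolis_matrix(q, qd, LP)
            assert np.allclose(S, -S.T, atol=1e-6)


class TestPassiveSimulation:
    def test_stable_equilibrium_is_fixed_point(self):
        res = passive_simulate(LegState([0.0, 0.0]), 1.0, 1e-3, LP)
        assert np.abs(res["q"]).max() <= 1e-12
        assert np.abs(res["qd"]).max() <= 1e-12

    def test_energy_conservation_five_seconds(self):
        res = passive_simulate(LegState([0.4, -0.2]), 5.0, 1e-3, LP)
        E = res["energy"]
        assert abs(E[-1] - E[0]) / abs(E[0]) <= 1e-6

    def test_small_oscillation_matches_linearized_eigenfrequency(self):
        """Release along one eigenmode of the linearization: the simulated
        period equals 2π/ω of that mode."""
        import scipy.linalg

        M0 = mass_matrix(np.zeros(2), LP)
        G = np.diag([(LP.m1 * LP.r1 + LP.m2 * LP.L1) * LP.g,
                     LP.m2 * LP.r2 * LP.g])
        w2, vecs = scipy.linalg.eigh(G, M0)
        omega = np.sqrt(w2[0])
        mode = vecs[:, 0]
        amp = 1e-4
        res = passive_simulate(LegState(amp * mode), 3 * 2 * np.pi / omega,
                               1e-4, LP)
        x = res["q"][:, 0] - 0.0
        # period from zero crossings of the first joint
        signs = np.sign(x)
        crossings = np.where(np.diff(signs) != 0)[0]
        periods = np.diff(res["t"][crossings])[::1]
        period = 2 * np.mean(periods)
        assert period == pytest.approx(2 * np.pi / omega, rel=1e-3)

    def test_divergence_reported_with_step(self):
        huge = LegState([0.0, 0.0], [1e8, -1e8])
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(FloatingPointError, match="step"):
                passive_simulate(huge, 1.0, 0.5, LP)
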