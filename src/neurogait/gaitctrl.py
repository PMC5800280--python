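"""Reference gait trajectories and PD computed-torque tracking control.

The reference is a smooth parametric stand-in for mean human hip/knee angle
curves over one stride: a truncated Fourier series with literature-typical
ranges (hip oscillating ±20° about a small forward offset; knee flexion a
two-harmonic profile peaking near 60° in swing). It is *not* a digitized
empirical curve; the coefficients are documented constants with analytic
first and second derivatives. The right leg runs 180° out of phase with the
left.

The controller is the classical computed-torque law (inverse-dynamics
control with PD error shaping and gravity compensation):

    Q = M(q) (q̈* + Kv (q̇* − q̇) + Kp (q* − q)) + b(q, q̇) + F(q̇) + g(q)

With an exact model the closed-loop error obeys ë + Kv ė + Kp e = 0 per
joint — linear, decoupled, configuration-independent — so for diagonal
critically damped gains Kp = ω²I, Kv = 2ωI the error decays as
e(t) = (e0 + (ė0 + ω e0) t) e^{−ωt}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .legmodel import (
    LegParams,
    LegState,
    coriolis_vector,
    dh_forward_kinematics,
    forward_dynamics,
    gravity_vector,
    mass_matrix,
    rk4_step,
)

__all__ = ["GaitTrajectory", "ControllerGains", "TrackingResult",
           "reference_gait", "ctc_torque", "simulate_tracking",
           "settling_time", "bci_gait_session"]

_DEG = np.pi / 180.0

# hip: mean offset + single harmonic; knee flexion: two harmonics, peak ~60°
# in swing. Coefficients are the package's documented stand-in constants.
_HIP_OFFSET = 5.0 * _DEG
_HIP_AMP = 20.0 * _DEG
_KNEE_A0 = 25.0 * _DEG
_KNEE_A1 = 15.0 * _DEG
_KNEE_A2 = 15.0 * _DEG
_KNEE_PH1 = 4.0 * np.pi / 3.0
_KNEE_PH2 = np.pi / 3.0


@dataclass(frozen=True)
class GaitTrajectory:
    """Periodic hip/knee reference with analytic derivatives."""

    stride_period_s: float = 1.2
    phase_offset_rad: float = 0.0      # 0 left leg, π right leg

    def __post_init__(self) -> None:
        if self.stride_period_s <= 0:
            raise ValueError("stride period must be positive")

    def angles(self, t: float | np.ndarray) -> np.ndarray:
        """Absolute link angles q* = (θ1*, θ2*) at time(s) t."""
        hip, knee = self._hip_knee(t, 0)
        return np.stack([hip, hip - knee], axis=-1)

    def velocities(self, t: float | np.ndarray) -> np.ndarray:
        hip, knee = self._hip_knee(t, 1)
        return np.stack([hip, hip - knee], axis=-1)

    def accelerations(self, t: float | np.ndarray) -> np.ndarray:
        hip, knee = self._hip_knee(t, 2)
        return np.stack([hip, hip - knee], axis=-1)

    def _hip_knee(self, t, deriv: int):
        """Hip angle and knee *flexion* (relative), or their derivatives."""
        w = 2.0 * np.pi / self.stride_period_s
        ph = w * np.asarray(t, dtype=float) + self.phase_offset_rad

        def harm(amp, k, phase, d):
            # d-th derivative of amp*cos(k*ph + phase)
            return amp * (k * w) ** d * np.cos(k * ph + phase + d * np.pi / 2)

        if deriv == 0:
            hip = _HIP_OFFSET + harm(_HIP_AMP, 1, 0.0, 0)
            knee = (_KNEE_A0 + harm(_KNEE_A1, 1, _KNEE_PH1, 0)
                    + harm(_KNEE_A2, 2, _KNEE_PH2, 0))
        else:
            hip = harm(_HIP_AMP, 1, 0.0, deriv)
            knee = (harm(_KNEE_A1, 1, _KNEE_PH1, deriv)
                    + harm(_KNEE_A2, 2, _KNEE_PH2, deriv))
        return hip, knee


def reference_gait(t: float | np.ndarray, traj: GaitTrajectory | None = None,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(q*, q̇*, q̈*) of the reference trajectory at time(s) ``t``."""
    if traj is None:
        traj = GaitTrajectory()
    return traj.angles(t), traj.velocities(t), traj.accelerations(t)


@dataclass(frozen=True)
class ControllerGains:
    """Diagonal PD gains; critical damping when Kv = 2 sqrt(Kp)."""

    Kp: np.ndarray = field(default_factory=lambda: 100.0 * np.eye(2))
    Kv: np.ndarray = field(default_factory=lambda: 20.0 * np.eye(2))

    def __post_init__(self) -> None:
        for name, m in (("Kp", self.Kp), ("Kv", self.Kv)):
            m = np.asarray(m, dtype=float)
            if m.shape != (2, 2) or not np.allclose(m, m.T):
                raise ValueError(f"{name} must be a symmetric 2x2 matrix")
            if np.any(np.linalg.eigvalsh(m) <= 0):
                raise ValueError(f"{name} must be positive-definite")
            object.__setattr__(self, name, m)

    @staticmethod
    def critically_damped(omega: float) -> "ControllerGains":
        return ControllerGains(Kp=omega ** 2 * np.eye(2),
                               Kv=2.0 * omega * np.eye(2))


def ctc_torque(state: LegState, ref: tuple[np.ndarray, np.ndarray, np.ndarray],
               gains: ControllerGains | None = None,
               params: LegParams | None = None,
               viscous_friction: float = 0.0) -> np.ndarray:
    """Computed-torque generalized forces for the current state and reference.

    Identical to evaluating the inverse dynamics at the PD-shaped
    acceleration q̈* + Kv(q̇* − q̇) + Kp(q* − q); viscous friction
    compensation is included when configured (default zero).
    """
    if gains is None:
        gains = ControllerGains()
    if params is None:
        params = LegParams()
    q_ref, qd_ref, qdd_ref = (np.asarray(a, dtype=float) for a in ref)
    e = q_ref - state.q
    ed = qd_ref - state.qd
    a_cmd = qdd_ref + gains.Kv @ ed + gains.Kp @ e
    return (mass_matrix(state.q, params) @ a_cmd
            + coriolis_vector(state.q, state.qd, params)
            + viscous_friction * state.qd
            + gravity_vector(state.q, params))


@dataclass
class TrackingResult:
    """Closed-loop tracking log."""

    t: np.ndarray
    q: np.ndarray
    q_ref: np.ndarray
    qd: np.ndarray
    torques: np.ndarray            # generalized CTC forces per step
    foot_error: np.ndarray         # Euclidean foot-tip position error
    settling_time_s: float | None  # None = never settled
    settling_tolerance: float

    @property
    def error(self) -> np.ndarray:
        return self.q_ref - self.q

    @property
    def settled(self) -> bool:
        return self.settling_time_s is not None


def settling_time(t: np.ndarray, error_norm: np.ndarray,
                  tolerance: float) -> float | None:
    """First time after which ‖e‖ stays below ``tolerance`` for good."""
    below = error_norm < tolerance
    if not below[-1]:
        return None
    # last index where the error is still at/above tolerance
    above = np.where(~below)[0]
    if above.size == 0:
        return float(t[0])
    idx = above[-1] + 1
    return float(t[idx]) if idx < t.size else None


def simulate_tracking(traj: GaitTrajectory, gains: ControllerGains | None = None,
                      params: LegParams | None = None,
                      duration_s: float = 5.0, dt: float = 1e-3,
                      initial_error: np.ndarray | float = 0.3,
                      initial_error_rate: np.ndarray | float = 0.0,
                      settle_fraction: float = 0.02,
                      plant_params: LegParams | None = None) -> TrackingResult:
    """Closed-loop RK4 simulation of the leg under the computed-torque law.

    The plant starts offset from the reference by ``initial_error`` (rad,
    scalar or per-joint). ``plant_params`` lets the simulated plant differ
    from the controller's model (parameter-mismatch studies); by default
    they are identical and the tracking error follows the exact linear
    error dynamics. Settling time is the first time the error norm stays
    below ``settle_fraction`` of its initial norm.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if gains is None:
        gains = ControllerGains()
    if params is None:
        params = LegParams()
    plant = params if plant_params is None else plant_params

    e0 = np.broadcast_to(np.asarray(initial_error, dtype=float), (2,)).copy()
    ed0 = np.broadcast_to(np.asarray(initial_error_rate, dtype=float), (2,)).copy()

    n = int(round(duration_s / dt))
    t = np.arange(n + 1) * dt
    q_ref_all, qd_ref_all, qdd_ref_all = reference_gait(t, traj)

    q = q_ref_all[0] - e0
    v = qd_ref_all[0] - ed0
    qs = np.empty((n + 1, 2)); qs[0] = q
    vs = np.empty((n + 1, 2)); vs[0] = v
    taus = np.empty((n + 1, 2))
    foot_err = np.empty(n + 1)

    def foot(qq):
        return dh_forward_kinematics(qq, plant)["ankle"]

    foot_err[0] = np.linalg.norm(foot(q) - foot(q_ref_all[0]))
    taus[0] = ctc_torque(LegState(q, v), (q_ref_all[0], qd_ref_all[0],
                                          qdd_ref_all[0]), gains, params)

    for i in range(1, n + 1):
        # the reference is re-evaluated analytically at the RK4 substep
        # times; a zero-order hold would forfeit 4th-order accuracy
        q, v = _rk4_tracking_step(q, v, t[i - 1], dt, traj, gains, params, plant)
        if not (np.isfinite(q).all() and np.isfinite(v).all()):
            raise FloatingPointError(f"tracking diverged at step {i}")
        qs[i], vs[i] = q, v
        taus[i] = ctc_torque(LegState(q, v), (q_ref_all[i], qd_ref_all[i],
                                              qdd_ref_all[i]), gains, params)
        foot_err[i] = np.linalg.norm(foot(q) - foot(q_ref_all[i]))

    err_norm = np.linalg.norm(q_ref_all - qs, axis=1)
    tol = settle_fraction * max(err_norm[0], np.finfo(float).tiny)
    ts = settling_time(t, err_norm, tol)
    return TrackingResult(t=t, q=qs, q_ref=q_ref_all, qd=vs, torques=taus,
                          foot_error=foot_err, settling_time_s=ts,
                          settling_tolerance=tol)


def _rk4_tracking_step(q, v, t0, dt, traj, gains, params, plant):
    def accel_at(qq, vv, tt):
        Q = ctc_torque(LegState(qq, vv), reference_gait(tt, traj), gains, params)
        return forward_dynamics(qq, vv, Q, plant)

    y0 = np.concatenate([q, v])

    def f(y, tt):
        return np.concatenate([y[2:], accel_at(y[:2], y[2:], tt)])

    k1 = f(y0, t0)
    k2 = f(y0 + 0.5 * dt * k1, t0 + 0.5 * dt)
    k3 = f(y0 + 0.5 * dt * k2, t0 + 0.5 * dt)
    k4 = f(y0 + dt * k3, t0 + dt)
    y1 = y0 + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y1[:2], y1[2:]


def bci_gait_session(commands: list[tuple[float, str]],
                     traj: GaitTrajectory | None = None,
                     gains: ControllerGains | None = None,
                     params: LegParams | None = None,
                     duration_s: float | None = None,
                     dt: float = 1e-3) -> dict[str, np.ndarray]:
    """Drive the leg from a timestamped command stream.

    On ``start_gait`` the reference plays the gait cycle forward; on ``hold``
    it freezes at the last reference pose (gravity-compensated hold) while
    the gait phase is retained, so a later walk command resumes where the
    cycle stopped. Commands must be time-ordered.
    """
    from .trigger import HOLD, START_GAIT

    if traj is None:
        traj = GaitTrajectory()
    if gains is None:
        gains = ControllerGains()
    if params is None:
        params = LegParams()
    times = [c[0] for c in commands]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("commands must be in non-decreasing time order")
    for _, cmd in commands:
        if cmd not in (START_GAIT, HOLD):
            raise ValueError(f"unknown command {cmd!r}")
    if duration_s is None:
        duration_s = (times[-1] if times else 0.0) + 2.0 * traj.stride_period_s

    n = int(round(duration_s / dt))
    t = np.arange(n + 1) * dt
    phase = 0.0            # accumulated gait time
    walking = False
    cmd_iter = iter(commands)
    next_cmd = next(cmd_iter, None)

    q0, _, _ = reference_gait(0.0, traj)
    q, v = q0.copy(), np.zeros(2)
    qs = np.empty((n + 1, 2)); qs[0] = q
    phases = np.empty(n + 1); phases[0] = phase
    walk_flags = np.zeros(n + 1, dtype=bool)
    refs = np.empty((n + 1, 2)); refs[0] = q0

    frozen_traj_time = 0.0
    for i in range(1, n + 1):
        while next_cmd is not None and next_cmd[0] <= t[i - 1]:
            walking = next_cmd[1] == START_GAIT
            next_cmd = next(cmd_iter, None)
        if walking:
            phase += dt
            frozen_traj_time = phase

        def accel(qq, vv):
            if walking:
                ref = reference_gait(frozen_traj_time, traj)
            else:
                qr, _, _ = reference_gait(frozen_traj_time, traj)
                ref = (qr, np.zeros(2), np.zeros(2))
            Q = ctc_torque(LegState(qq, vv), ref, gains, params)
            return forward_dynamics(qq, vv, Q, params)

        q, v = rk4_step(q, v, dt, accel)
        qs[i] = q
        phases[i] = phase
        walk_flags[i] = walking
        refs[i], _, _ = reference_gait(frozen_traj_time, traj)

    return {"t": t, "q": qs, "q_ref": refs, "phase": phases,
            "walking": walk_flags}
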