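"""Planar 2-DOF prosthetic-leg model: kinematics and Lagrangian dynamics.

The leg is a serial chain hanging from a fixed pelvic anchor: thigh (length
L1) and shank (L2), with the ankle fixed. Joint configuration is described
by absolute link angles ``q = (θ1, θ2)`` measured from the downward
vertical, positive forward, matching the center-of-mass coordinates

    x1 = xa + r1 sin θ1,            y1 = ya − r1 cos θ1
    x2 = xa + L1 sin θ1 + r2 sin θ2, y2 = ya − L1 cos θ1 − r2 cos θ2.

From the Lagrangian L = T − V of the two links the equations of motion are

    M(q) q̈ + b(q, q̇) + g(q) = Q

with the symmetric positive-definite inertia matrix

    M = [[m1 r1² + m2 L1² + I1,  m2 L1 r2 cos(θ1−θ2)],
         [m2 L1 r2 cos(θ1−θ2),   m2 r2² + I2       ]],

velocity terms b = (m2 L1 r2 sin(θ1−θ2)) · (θ̇2², −θ̇1²) and gravity
g = ((m1 r1 + m2 L1) g sinθ1, m2 r2 g sinθ2). ``Q`` are generalized forces
conjugate to the absolute angles; the physical actuator torques at the hip
and knee joints relate to them through the virtual-work map
τ_hip = Q1 + Q2, τ_knee = Q2 (a hip actuator must also carry every moment
transmitted through the knee). Prescribed anchor accelerations and an
external force at the foot tip enter as additional generalized forces.

The leg geometry fixes only the link lengths; masses and inertias default to
standard anthropometric segment ratios scaled to a 10 kg leg budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LegParams", "LegState", "dh_forward_kinematics",
           "link_com_positions", "mass_matrix", "coriolis_matrix",
           "coriolis_vector", "gravity_vector", "generalized_forces",
           "inverse_dynamics", "joint_torques_from_generalized",
           "generalized_from_joint_torques", "forward_dynamics",
           "passive_simulate", "total_energy", "rk4_step"]

_G_DEFAULT = 9.81

# anthropometric segment ratios (COM at 0.433 of length from proximal end,
# radius of gyration 0.323 of length about the COM)
_COM_RATIO = 0.433
_GYRATION_RATIO = 0.323


@dataclass(frozen=True)
class LegParams:
    """Geometry, inertia and environment of the 2-link leg."""

    L1: float = 0.2            # thigh length, m
    L2: float = 0.2            # shank length, m
    L3: float = 0.03           # pelvic link, m (cosmetic offset)
    m1: float = 4.5            # thigh mass, kg
    m2: float = 2.5            # shank(+foot) mass, kg
    r1: float = _COM_RATIO * 0.2
    r2: float = _COM_RATIO * 0.2
    I1: float = 4.5 * (_GYRATION_RATIO * 0.2) ** 2
    I2: float = 2.5 * (_GYRATION_RATIO * 0.2) ** 2
    g: float = _G_DEFAULT
    anchor: tuple[float, float] = (0.0, 0.0)
    anchor_accel: tuple[float, float] = (0.0, 0.0)
    foot_force: tuple[float, float] = (0.0, 0.0)   # (F1 horizontal, F2 vertical)

    def __post_init__(self) -> None:
        if min(self.L1, self.L2, self.L3) <= 0:
            raise ValueError("link lengths must be positive")
        if min(self.m1, self.m2) <= 0:
            raise ValueError("masses must be positive")
        if not (0 < self.r1 <= self.L1 and 0 < self.r2 <= self.L2):
            raise ValueError("COM distances must lie within the links")
        if min(self.I1, self.I2) < 0:
            raise ValueError("inertias must be non-negative")


@dataclass
class LegState:
    """Absolute link angles (rad, 0 = hanging down, positive = forward),
    velocities and optional accelerations."""

    q: np.ndarray
    qd: np.ndarray = field(default_factory=lambda: np.zeros(2))
    qdd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float).reshape(2)
        self.qd = np.asarray(self.qd, dtype=float).reshape(2)
        if self.qdd is not None:
            self.qdd = np.asarray(self.qdd, dtype=float).reshape(2)
        if not (np.isfinite(self.q).all() and np.isfinite(self.qd).all()):
            raise ValueError("non-finite leg state")


# ------------------------------------------------------------- kinematics

def dh_forward_kinematics(q: np.ndarray, params: LegParams | None = None,
                          ) -> dict[str, np.ndarray]:
    """Positions of the knee, ankle and foot tip for absolute angles ``q``.

    Planar zero-twist chain (all D-H link twists zero, offsets zero): each
    link rotates in the sagittal plane about its proximal joint.
    """
    if params is None:
        params = LegParams()
    q = np.asarray(q, dtype=float).reshape(-1)
    th1, th2 = q[0], q[1]
    xa, ya = params.anchor
    knee = np.array([xa + params.L1 * np.sin(th1),
                     ya - params.L1 * np.cos(th1)])
    ankle = knee + np.array([params.L2 * np.sin(th2),
                             -params.L2 * np.cos(th2)])
    th3 = q[2] if q.size > 2 else th2
    foot = ankle + np.array([params.L3 * np.sin(th3),
                             -params.L3 * np.cos(th3)])
    return {"knee": knee, "ankle": ankle, "foot": foot}


def link_com_positions(state: LegState, params: LegParams | None = None,
                       ) -> tuple[float, float, float, float]:
    """Centers of mass (x1, y1, x2, y2) of thigh and shank."""
    if params is None:
        params = LegParams()
    th1, th2 = state.q
    xa, ya = params.anchor
    x1 = xa + params.r1 * np.sin(th1)
    y1 = ya - params.r1 * np.cos(th1)
    x2 = xa + params.L1 * np.sin(th1) + params.r2 * np.sin(th2)
    y2 = ya - params.L1 * np.cos(th1) - params.r2 * np.cos(th2)
    return (float(x1), float(y1), float(x2), float(y2))


# --------------------------------------------------------------- dynamics

def mass_matrix(q: np.ndarray, params: LegParams | None = None) -> np.ndarray:
    """Symmetric positive-definite inertia matrix M(q)."""
    if params is None:
        params = LegParams()
    th1, th2 = np.asarray(q, dtype=float)
    k = params.m2 * params.L1 * params.r2
    m11 = params.m1 * params.r1 ** 2 + params.m2 * params.L1 ** 2 + params.I1
    m22 = params.m2 * params.r2 ** 2 + params.I2
    m12 = k * np.cos(th1 - th2)
    return np.array([[m11, m12], [m12, m22]])


def coriolis_matrix(q: np.ndarray, qd: np.ndarray,
                    params: LegParams | None = None) -> np.ndarray:
    """Christoffel-symbol factorization C(q, q̇) with Ṁ − 2C skew-symmetric."""
    if params is None:
        params = LegParams()
    th1, th2 = np.asarray(q, dtype=float)
    d1, d2 = np.asarray(qd, dtype=float)
    ks = params.m2 * params.L1 * params.r2 * np.sin(th1 - th2)
    return np.array([[0.0, ks * d2], [-ks * d1, 0.0]])


def coriolis_vector(q: np.ndarray, qd: np.ndarray,
                    params: LegParams | None = None) -> np.ndarray:
    """b(q, q̇) = C(q, q̇) q̇ (quadratic in the velocities)."""
    return coriolis_matrix(q, qd, params) @ np.asarray(qd, dtype=float)


def gravity_vector(q: np.ndarray, params: LegParams | None = None) -> np.ndarray:
    if params is None:
        params = LegParams()
    th1, th2 = np.asarray(q, dtype=float)
    return np.array([
        (params.m1 * params.r1 + params.m2 * params.L1) * params.g * np.sin(th1),
        params.m2 * params.r2 * params.g * np.sin(th2),
    ])


def _anchor_terms(q: np.ndarray, params: LegParams) -> np.ndarray:
    """Generalized forces required by prescribed anchor accelerations."""
    ax, ay = params.anchor_accel
    if ax == 0.0 and ay == 0.0:
        return np.zeros(2)
    th1, th2 = np.asarray(q, dtype=float)
    return np.array([
        (params.m1 * params.r1 + params.m2 * params.L1)
        * (ax * np.cos(th1) + ay * np.sin(th1)),
        params.m2 * params.r2 * (ax * np.cos(th2) + ay * np.sin(th2)),
    ])


def _foot_force_terms(q: np.ndarray, params: LegParams) -> np.ndarray:
    """Generalized forces of an external force applied at the foot tip
    (Jacobian-transpose map of the ankle-point Jacobian)."""
    f1, f2 = params.foot_force
    if f1 == 0.0 and f2 == 0.0:
        return np.zeros(2)
    th1, th2 = np.asarray(q, dtype=float)
    return np.array([
        params.L1 * (f1 * np.cos(th1) + f2 * np.sin(th1)),
        params.L2 * (f1 * np.cos(th2) + f2 * np.sin(th2)),
    ])


def generalized_forces(state: LegState, params: LegParams | None = None,
                       ) -> np.ndarray:
    """Q = M(q) q̈ + b(q, q̇) + g(q) + anchor terms − foot-force terms."""
    if params is None:
        params = LegParams()
    if state.qdd is None:
        raise ValueError("inverse dynamics needs accelerations (state.qdd)")
    return (mass_matrix(state.q, params) @ state.qdd
            + coriolis_vector(state.q, state.qd, params)
            + gravity_vector(state.q, params)
            + _anchor_terms(state.q, params)
            - _foot_force_terms(state.q, params))


_JOINT_MAP = np.array([[1.0, 1.0], [0.0, 1.0]])       # τ = A Q
_JOINT_MAP_INV = np.array([[1.0, -1.0], [0.0, 1.0]])  # Q = A⁻¹ τ


def joint_torques_from_generalized(Q: np.ndarray) -> np.ndarray:
    """(τ_hip, τ_knee) from generalized forces of the absolute angles."""
    return _JOINT_MAP @ np.asarray(Q, dtype=float)


def generalized_from_joint_torques(tau: np.ndarray) -> np.ndarray:
    return _JOINT_MAP_INV @ np.asarray(tau, dtype=float)


def inverse_dynamics(state: LegState, params: LegParams | None = None,
                     ) -> np.ndarray:
    """Hip and knee actuator torques realizing the state's accelerations.

    Euler-Lagrange generalized forces mapped to joint torques:
    τ_hip = Q1 + Q2, τ_knee = Q2.
    """
    return joint_torques_from_generalized(generalized_forces(state, params))


def forward_dynamics(q: np.ndarray, qd: np.ndarray, Q: np.ndarray,
                     params: LegParams | None = None) -> np.ndarray:
    """q̈ = M(q)⁻¹ (Q − b − g − anchor + foot terms), Q generalized."""
    if params is None:
        params = LegParams()
    rhs = (np.asarray(Q, dtype=float)
           - coriolis_vector(q, qd, params)
           - gravity_vector(q, params)
           - _anchor_terms(q, params)
           + _foot_force_terms(q, params))
    return np.linalg.solve(mass_matrix(q, params), rhs)


def total_energy(state: LegState, params: LegParams | None = None) -> float:
    """Kinetic plus gravitational potential energy (anchor at rest)."""
    if params is None:
        params = LegParams()
    T = 0.5 * state.qd @ mass_matrix(state.q, params) @ state.qd
    th1, th2 = state.q
    V = (-(params.m1 * params.r1 + params.m2 * params.L1) * params.g * np.cos(th1)
         - params.m2 * params.r2 * params.g * np.cos(th2))
    return float(T + V)


def rk4_step(q: np.ndarray, qd: np.ndarray, dt: float, accel) -> tuple[np.ndarray, np.ndarray]:
    """One fixed-step classical Runge-Kutta step of q̈ = accel(q, q̇)."""
    def f(y):
        qq, vv = y[:2], y[2:]
        return np.concatenate([vv, accel(qq, vv)])

    y0 = np.concatenate([q, qd])
    k1 = f(y0)
    k2 = f(y0 + 0.5 * dt * k1)
    k3 = f(y0 + 0.5 * dt * k2)
    k4 = f(y0 + dt * k3)
    y1 = y0 + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y1[:2], y1[2:]


def passive_simulate(initial: LegState, duration_s: float, dt: float = 1e-3,
                     params: LegParams | None = None,
                     Q: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Integrate the free (or constant-generalized-force) dynamics by RK4.

    Returns a trajectory log with per-step total energy so conservation can
    be audited; raises on divergence, naming the failing step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if params is None:
        params = LegParams()
    Qc = np.zeros(2) if Q is None else np.asarray(Q, dtype=float)

    def accel(qq, vv):
        return forward_dynamics(qq, vv, Qc, params)

    n = int(round(duration_s / dt))
    t = np.arange(n + 1) * dt
    qs = np.empty((n + 1, 2))
    vs = np.empty((n + 1, 2))
    es = np.empty(n + 1)
    q, v = initial.q.copy(), initial.qd.copy()
    qs[0], vs[0] = q, v
    es[0] = total_energy(LegState(q, v), params)
    for i in range(1, n + 1):
        q, v = rk4_step(q, v, dt, accel)
        if not (np.isfinite(q).all() and np.isfinite(v).all()):
            raise FloatingPointError(f"simulation diverged at step {i}")
        qs[i], vs[i] = q, v
        es[i] = total_energy(LegState(q, v), params)
    return {"t": t, "q": qs, "qd": vs, "energy": es}
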