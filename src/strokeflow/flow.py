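"""Kernel-parameterized diffeomorphic flows.

A deformation is generated by momentum vectors alpha_k(t) attached to control points
x_k(t) (the face centers of the baseline lesion surface). The velocity field at any
point x is the kernel convolution

    v_t(x) = sum_k exp(-|x_k(t) - x|^2 / lambda_v^2) * alpha_k(t),

an element of an RKHS of smooth vector fields with Gaussian scale lambda_v; points
further apart than lambda_v move in an essentially uncorrelated way. Integrating
dx/dt = v_t(x) with explicit Euler steps on the dt grid advects the control points
themselves together with any passive tracer points (mesh vertices), which is what
makes the resulting map a diffeomorphism proxy: connectivity never changes and, for
stable momenta magnitudes, triangles never fold.

Internal units: positions mm, time hours, momenta and velocities mm/hour.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "MomentaField",
    "FlowResult",
    "velocity_at",
    "flow_forward",
    "flow_inverse",
    "kinetic_energy",
]


def _kv(a: np.ndarray, b: np.ndarray, lambda_v: float) -> np.ndarray:
    return np.exp(-cdist(a, b, "sqeuclidean") / lambda_v**2)


@dataclasses.dataclass
class MomentaField:
    """Time-indexed momenta on advected control points; parameterizes one flow.

    momenta_t        : (S, N, 3) momentum vectors per Euler step, mm/h
    control_points_t : (S+1, N, 3) control point trajectories; row 0 is the baseline
                       configuration (face centers of the baseline shape)
    lambda_v         : deformation kernel scale, mm
    dt_hours         : Euler step, hours
    t0_hours         : time of the first frame, hours from onset
    """

    momenta_t: np.ndarray
    control_points_t: np.ndarray
    lambda_v: float
    dt_hours: float
    t0_hours: float = 0.0

    def __post_init__(self):
        self.momenta_t = np.asarray(self.momenta_t, dtype=float)
        self.control_points_t = np.asarray(self.control_points_t, dtype=float)
        if self.momenta_t.ndim != 3 or self.momenta_t.shape[2] != 3:
            raise ValueError("momenta_t must be (S, N, 3)")
        s, n, _ = self.momenta_t.shape
        if self.control_points_t.shape != (s + 1, n, 3):
            raise ValueError(
                f"control_points_t must be (S+1, N, 3) = {(s + 1, n, 3)}, got {self.control_points_t.shape}"
            )
        if self.lambda_v <= 0 or self.dt_hours <= 0:
            raise ValueError("lambda_v and dt_hours must be > 0")
        self.lambda_v = float(self.lambda_v)
        self.dt_hours = float(self.dt_hours)
        self.t0_hours = float(self.t0_hours)

    @property
    def n_steps(self) -> int:
        return self.momenta_t.shape[0]

    @property
    def n_control_points(self) -> int:
        return self.momenta_t.shape[1]

    @property
    def times_hours(self) -> np.ndarray:
        return self.t0_hours + self.dt_hours * np.arange(self.n_steps + 1)

    @classmethod
    def from_momenta(
        cls,
        control_points0: np.ndarray,
        momenta_t: np.ndarray,
        lambda_v: float,
        dt_hours: float,
        t0_hours: float = 0.0,
    ) -> "MomentaField":
        """Shoot the control points forward under their own momenta and build the field."""
        momenta_t = np.asarray(momenta_t, dtype=float)
        x = np.asarray(control_points0, dtype=float).copy()
        traj = [x.copy()]
        for step in range(momenta_t.shape[0]):
            v = _kv(x, x, lambda_v) @ momenta_t[step]
            disp = dt_hours * v
            _check_step(disp, lambda_v, step)
            x = x + disp
            traj.append(x.copy())
        return cls(momenta_t, np.stack(traj), lambda_v, dt_hours, t0_hours)

    @classmethod
    def zero(
        cls, control_points0: np.ndarray, n_steps: int, lambda_v: float, dt_hours: float, t0_hours: float = 0.0
    ) -> "MomentaField":
        x0 = np.asarray(control_points0, dtype=float)
        momenta = np.zeros((n_steps,) + x0.shape)
        traj = np.broadcast_to(x0, (n_steps + 1,) + x0.shape).copy()
        return cls(momenta, traj, lambda_v, dt_hours, t0_hours)


@dataclasses.dataclass
class FlowResult:
    """Tracked point trajectories on the uniform time grid.

    point_trajectories : (S+1, P, 3); first frame equals the input points
    times_hours        : length S+1; uniformly spaced (descending for inverse flows)
    """

    point_trajectories: np.ndarray
    times_hours: np.ndarray

    @property
    def final(self) -> np.ndarray:
        return self.point_trajectories[-1]


def _check_step(disp: np.ndarray, lambda_v: float, step: int) -> None:
    if not np.all(np.isfinite(disp)):
        raise FloatingPointError(f"non-finite displacement at step {step}")
    m = float(np.linalg.norm(disp, axis=-1).max()) if disp.size else 0.0
    if m > lambda_v:
        raise FloatingPointError(
            f"flow step {step} moves a point by {m:.2f} mm > lambda_v = {lambda_v:.2f} mm; "
            "momenta magnitude is unstable for the Euler step"
        )


def velocity_at(query: np.ndarray, step: int, mom: MomentaField) -> np.ndarray:
    """Velocity field (mm/h) at arbitrary query points for a given time step index."""
    if not 0 <= step < mom.n_steps:
        raise IndexError(f"step {step} out of range [0, {mom.n_steps})")
    query = np.atleast_2d(np.asarray(query, dtype=float))
    return _kv(query, mom.control_points_t[step], mom.lambda_v) @ mom.momenta_t[step]


def flow_forward(points: np.ndarray, mom: MomentaField, *, integrator: str = "euler") -> FlowResult:
    """Advect passive tracer points through the flow, frame by frame.

    `integrator` is "euler" (the scheme the momenta were estimated under) or
    "midpoint" (2nd-order, for convergence checks; uses the stored control-point
    trajectories at the nearest frames).
    """
    q = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    frames = [q.copy()]
    dt, lv = mom.dt_hours, mom.lambda_v
    for step in range(mom.n_steps):
        if integrator == "euler":
            v = _kv(q, mom.control_points_t[step], lv) @ mom.momenta_t[step]
            disp = dt * v
        elif integrator == "midpoint":
            v1 = _kv(q, mom.control_points_t[step], lv) @ mom.momenta_t[step]
            q_half = q + 0.5 * dt * v1
            x_half = 0.5 * (mom.control_points_t[step] + mom.control_points_t[step + 1])
            disp = dt * (_kv(q_half, x_half, lv) @ mom.momenta_t[step])
        else:
            raise ValueError(f"unknown integrator '{integrator}'")
        _check_step(disp, lv, step)
        q = q + disp
        frames.append(q.copy())
    return FlowResult(np.stack(frames), mom.t0_hours + dt * np.arange(mom.n_steps + 1))


def flow_inverse(points: np.ndarray, mom: MomentaField, *, n_fixed_point: int = 5) -> FlowResult:
    """Map points at the final time back to the baseline frame.

    Integrates the negated velocity field backward along the stored control-point
    trajectories. Each backward step solves q_t = q_{t+1} - dt * v_t(q_t) by
    fixed-point iteration (initialized with the negated field at q_{t+1}), which
    inverts the forward explicit-Euler step essentially exactly for stable flows.
    """
    q = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    frames = [q.copy()]
    dt, lv = mom.dt_hours, mom.lambda_v
    for step in range(mom.n_steps - 1, -1, -1):
        x, a = mom.control_points_t[step], mom.momenta_t[step]
        prev = q
        for _ in range(max(1, n_fixed_point)):
            v = _kv(prev, x, lv) @ a
            prev = q - dt * v
        _check_step(prev - q, lv, step)
        q = prev
        frames.append(q.copy())
    times = mom.t0_hours + dt * np.arange(mom.n_steps, -1, -1)
    return FlowResult(np.stack(frames), times)


def kinetic_energy(mom: MomentaField) -> float:
    """Deformation (kinetic) energy sum_t dt * sum_ij K_V(x_i(t), x_j(t)) alpha_i(t).alpha_j(t).

    This is the regularity term of the regression functional; it is the squared RKHS
    norm of the velocity field integrated over the deformation time span.
    """
    e = 0.0
    for step in range(mom.n_steps):
        x = mom.control_points_t[step]
        a = mom.momenta_t[step]
        e += mom.dt_hours * float(np.einsum("ij,ij->", _kv(x, x, mom.lambda_v), a @ a.T))
    return max(e, 0.0)
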