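"""Biomechanical eye plant: a rigid sphere driven by six muscle channels.

The eyeball is a sphere of uniform mass (inertia 2/5 m R^2) actuated by
six linear path actuators (the extraocular muscles) and restrained by a
passive orbital torque t = -K R - C U acting like a rotational
spring-damper, where R is the eye's orientation (rotation vector) and U
its angular velocity.  Muscle torque axes are fixed in the head frame
(a first approximation to the pulley system): the rectus pairs rotate
the eye about +/-x (up/down) and +/-y (left/right); the obliques about
-/+z.  Channel order follows the motoneuron convention
(up, down, left, right, z_plus, z_minus); z_plus is the superior
oblique, z_minus the inferior oblique (left eye).

Orientation is held internally as a unit quaternion and reported as
intrinsic x->y->z Euler angles in degrees.  Rigid-body dynamics are
integrated with a classical fixed-step 4th-order Runge-Kutta scheme,
inputs held constant over each step (zero-order hold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["PlantParams", "EyePlant", "couple_plant"]

DT_PLANT = 0.025  # s; the biomechanical solver timestep


def _default_axes() -> np.ndarray:
    # Columns: up, down, left, right, z_plus, z_minus (unit torque axes).
    return np.array(
        [
            [1.0, -1.0, 0.0, 0.0, 0.0, 0.0],   # x
            [0.0, 0.0, 1.0, -1.0, 0.0, 0.0],   # y
            [0.0, 0.0, 0.0, 0.0, -1.0, 1.0],   # z
        ]
    )


@dataclass
class PlantParams:
    """Physical parameters of the eye plant (SI units)."""

    mass: float = 7.5e-3        # kg
    diameter: float = 24e-3     # m
    K: float = 1.0e-3           # N m / rad, orbital stiffness
    C: float = 5.0e-5           # N m s / rad, orbital damping
    F_max: float = 0.1          # N, per-muscle maximum force
    substeps: int = 5           # internal RK4 substeps per plant step
    moment_arm: float | None = None  # m; defaults to the eye radius
    torque_axes: np.ndarray = field(default_factory=_default_axes)

    def __post_init__(self) -> None:
        if self.K <= 0 or self.C <= 0:
            raise ValueError("K and C must be positive")
        if self.moment_arm is None:
            self.moment_arm = self.diameter / 2.0
        self.torque_axes = np.asarray(self.torque_axes, dtype=float)
        if self.torque_axes.shape != (3, 6):
            raise ValueError("torque_axes must have shape (3, 6)")

    @property
    def inertia(self) -> float:
        """Moment of inertia of the uniform sphere, kg m^2."""
        return 0.4 * self.mass * (self.diameter / 2.0) ** 2

    @property
    def torque_scale(self) -> float:
        """Maximum torque per muscle, N m."""
        return self.F_max * self.moment_arm


class EyePlant:
    """Rigid-body eye with passive spring-damper orbit and six muscles."""

    def __init__(self, params: PlantParams | None = None) -> None:
        self.params = params or PlantParams()
        self.reset()

    def reset(self, euler_deg=(0.0, 0.0, 0.0)) -> None:
        self._q = Rotation.from_euler("XYZ", euler_deg, degrees=True)
        self.omega = np.zeros(3)  # rad/s, head frame

    @property
    def rotvec(self) -> np.ndarray:
        return self._q.as_rotvec()

    @property
    def euler_deg(self) -> np.ndarray:
        """Euler angles (theta_x, theta_y, theta_z) in degrees."""
        return self._q.as_euler("XYZ", degrees=True)

    @property
    def omega_deg(self) -> np.ndarray:
        return np.degrees(self.omega)

    def _torque(self, rotvec: np.ndarray, omega: np.ndarray, mn: np.ndarray) -> np.ndarray:
        p = self.params
        muscle = p.torque_axes @ (p.torque_scale * mn)
        return muscle - p.K * rotvec - p.C * omega

    def _deriv(self, q: np.ndarray, omega: np.ndarray, mn: np.ndarray):
        # q = (x, y, z, w) scalar-last; dq/dt = 0.5 * q (x) omega_quat
        rotvec = Rotation.from_quat(q).as_rotvec()
        torque = self._torque(rotvec, omega, mn)
        domega = torque / self.params.inertia
        ox, oy, oz = omega
        x, y, z, w = q
        dq = 0.5 * np.array(
            [
                w * ox + y * oz - z * oy,
                w * oy + z * ox - x * oz,
                w * oz + x * oy - y * ox,
                -x * ox - y * oy - z * oz,
            ]
        )
        return dq, domega

    def step(self, mn, dt: float = DT_PLANT) -> None:
        """Advance one plant step with motoneuron activations held constant."""
        mn = np.asarray(mn, dtype=float)
        if mn.shape != (6,):
            raise ValueError("mn must be a 6-vector")
        if np.any(mn < -1e-12) or np.any(mn > 1.0 + 1e-12):
            warnings.warn("motoneuron activations clamped to [0, 1]", stacklevel=2)
        mn = np.clip(mn, 0.0, 1.0)
        q = self._q.as_quat()
        w = self.omega
        h = dt / self.params.substeps
        for _ in range(self.params.substeps):
            k1q, k1w = self._deriv(q, w, mn)
            k2q, k2w = self._deriv(q + 0.5 * h * k1q, w + 0.5 * h * k1w, mn)
            k3q, k3w = self._deriv(q + 0.5 * h * k2q, w + 0.5 * h * k2w, mn)
            k4q, k4w = self._deriv(q + h * k3q, w + h * k3w, mn)
            q = q + (h / 6.0) * (k1q + 2 * k2q + 2 * k3q + k4q)
            q /= np.linalg.norm(q)
            w = w + (h / 6.0) * (k1w + 2 * k2w + 2 * k3w + k4w)
        self._q = Rotation.from_quat(q)
        self.omega = w

    def energy(self) -> float:
        """Rotational kinetic plus orbital elastic energy (J)."""
        p = self.params
        return 0.5 * p.inertia * float(self.omega @ self.omega) + 0.5 * p.K * float(
            self.rotvec @ self.rotvec
        )


def couple_plant(plant: EyePlant, mn_stream, dt_neural: float = 0.001,
                 dt_plant: float = DT_PLANT):
    """Couple a 1 ms motoneuron stream to the 25 ms plant solver.

    The plant advances one ``dt_plant`` step whenever the neural clock
    crosses a plant-step boundary, consuming the most recent motoneuron
    values (zero-order hold); between plant steps the reported eye state
    is the last computed one.  Returns an array of rows
    (t, theta_x, theta_y, theta_z, omega_x, omega_y, omega_z).
    """
    ratio = int(round(dt_plant / dt_neural))
    rows = []
    mn_latest = np.zeros(6)
    for k, mn in enumerate(mn_stream):
        mn_latest = np.asarray(mn, dtype=float)
        if (k + 1) % ratio == 0:
            plant.step(mn_latest, dt_plant)
        rows.append(np.concatenate(([(k + 1) * dt_neural], plant.euler_deg,
                                    plant.omega_deg)))
    return np.asarray(rows)
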