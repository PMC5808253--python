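"""World geometry: luminances on a spherical screen and their retinotopic image.

The eye sits at the origin of a right-handed world frame with its fovea
initially directed along -z; +x is to the subject's right and +y is up.
A luminance is placed by two Euler rotations: ``theta_x`` (about x,
positive above the horizon) and ``theta_y`` (about y, positive to the
left of the meridian).  Given the eye's rotational state the luminances
are transformed into the eye frame and rasterized onto a 50x50 log-polar
grid whose axes are eccentricity ``r`` and direction ``phi``.

The log-polar mapping uses a first-order cortical magnification model
M(eps) = M_f / (1 + eps/E2), which integrates to

    r(eps) = M_f * E2 * ln(eps/E2 + 1)

with the foveal magnification M_f fixed by requiring that the edge of
the field of view (eccentricity W_fov/2) maps exactly onto the edge of
the neural field (r = W_nfs).

Grid convention (1-based): ``phi = 1`` encodes upward movement, 13.5
left, 26 down, 38.5 right; the phi axis wraps (phi = 51 is phi = 1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.transform import Rotation

__all__ = [
    "MappingParams",
    "EyeRotation",
    "Luminance",
    "load_luminances",
    "rotation_matrix",
    "direction_from_angles",
    "angles_from_direction",
    "eye_frame_transform",
    "forward_map",
    "inverse_map",
    "WorldRenderer",
]


@dataclass(frozen=True)
class MappingParams:
    """Parameters of the log-polar retinotopic mapping.

    Attributes
    ----------
    W_nfs : side length of the square neural field (grid units).
    W_fov : width of the field of view (degrees).
    E2 : eccentricity at which retinal cell density has halved (degrees).
    """

    W_nfs: float = 50.0
    W_fov: float = 61.0
    E2: float = 2.5

    @property
    def M_f(self) -> float:
        """Foveal magnification (grid units per degree).

        Fixed by the closure condition r(W_fov / 2) = W_nfs.
        """
        return self.W_nfs / (self.E2 * math.log(self.W_fov / (2.0 * self.E2) + 1.0))

    def magnification(self, eccentricity):
        """M(eps) = M_f / (1 + eps/E2), eps in degrees."""
        return self.M_f / (1.0 + np.asarray(eccentricity, dtype=float) / self.E2)

    def eccentricity_of_r(self, r):
        """Inverse of the radial mapping: eps(r) in degrees."""
        return self.E2 * (np.exp(np.asarray(r, dtype=float) / (self.M_f * self.E2)) - 1.0)


@dataclass
class EyeRotation:
    """Euler rotational state of the eye in the world frame (degrees).

    The composition order is intrinsic x -> y -> z; the world-from-eye
    matrix is Rx(theta_x) @ Ry(theta_y) @ Rz(theta_z).
    """

    theta_x: float = 0.0
    theta_y: float = 0.0
    theta_z: float = 0.0
    omega: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def matrix(self) -> np.ndarray:
        return rotation_matrix(self.theta_x, self.theta_y, self.theta_z)


def rotation_matrix(theta_x: float, theta_y: float, theta_z: float = 0.0) -> np.ndarray:
    """World-from-rotated-frame matrix for intrinsic x->y->z Euler angles."""
    return Rotation.from_euler("XYZ", [theta_x, theta_y, theta_z], degrees=True).as_matrix()


@dataclass
class Luminance:
    """A cross-shaped luminous target on the spherical screen.

    The cross is an upright "+": a vertical bar aligned with the meridian
    and a horizontal bar aligned with the horizon, each arm extending
    ``span`` degrees from the centre and ``bar_width`` degrees thick.
    """

    theta_x: float
    theta_y: float
    span: float = 3.0
    bar_width: float = 2.0
    magnitude: float = 1.0
    t_on: float = 0.0
    t_off: float = math.inf
    shape: str = "cross"

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("luminance magnitude must be >= 0")
        if self.t_on > self.t_off:
            raise ValueError("t_on must not exceed t_off")
        if self.shape not in ("cross", "rect"):
            raise ValueError(f"unsupported luminance shape {self.shape!r}")

    def active(self, t: float) -> bool:
        return self.t_on <= t < self.t_off


def load_luminances(source) -> list[Luminance]:
    """Read a world-configuration (``luminances.json`` dialect).

    The file holds a JSON list of objects with keys ``thetaX``, ``thetaY``,
    ``shape``, ``span``, ``barWidth``, ``magnitude``, ``tOn`` and ``tOff``
    (all but the angles optional).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            entries = json.load(fh)
    else:
        entries = json.load(source)
    out = []
    for e in entries:
        out.append(
            Luminance(
                theta_x=float(e["thetaX"]),
                theta_y=float(e["thetaY"]),
                span=float(e.get("span", 3.0)),
                bar_width=float(e.get("barWidth", 2.0)),
                magnitude=float(e.get("magnitude", 1.0)),
                t_on=float(e.get("tOn", 0.0)),
                t_off=float(e.get("tOff", math.inf)),
                shape=str(e.get("shape", "cross")),
            )
        )
    return out


def direction_from_angles(theta_x, theta_y) -> np.ndarray:
    """Unit gaze-direction vector(s) for world angles in degrees.

    v = Rx(theta_x) @ Ry(theta_y) @ (0, 0, -1); shape (..., 3).
    """
    tx = np.deg2rad(np.asarray(theta_x, dtype=float))
    ty = np.deg2rad(np.asarray(theta_y, dtype=float))
    vx = -np.sin(ty)
    vy = np.sin(tx) * np.cos(ty)
    vz = -np.cos(tx) * np.cos(ty)
    return np.stack(np.broadcast_arrays(vx, vy, vz), axis=-1)


def angles_from_direction(v) -> tuple[np.ndarray, np.ndarray]:
    """Recover (theta_x, theta_y) in degrees from direction vectors.

    Valid for directions within the frontal hemisphere (|theta_y| < 90).
    """
    v = np.asarray(v, dtype=float)
    theta_x = np.degrees(np.arctan2(v[..., 1], -v[..., 2]))
    theta_y = np.degrees(np.arctan2(-v[..., 0], np.hypot(v[..., 1], v[..., 2])))
    return theta_x, theta_y


def eye_frame_transform(targets, eye: EyeRotation):
    """Transform world-frame target angles into the eye's frame.

    Parameters
    ----------
    targets : sequence of (theta_x, theta_y) pairs, degrees, world frame.
    eye : the eye's rotational state.

    Returns
    -------
    ndarray of shape (n, 2) with eye-frame (theta_x, theta_y); a target
    antipodal to the gaze direction (undefined azimuth) yields NaNs.
    """
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    v_world = direction_from_angles(targets[:, 0], targets[:, 1])
    R = eye.matrix()
    v_eye = v_world @ R  # R.T applied to rows
    tx, ty = angles_from_direction(v_eye)
    out = np.stack([tx, ty], axis=-1)
    antipodal = v_eye[:, 2] > 1.0 - 1e-12
    out[antipodal] = np.nan
    return out


def forward_map(theta_x, theta_y, params: MappingParams = MappingParams()):
    """Map eye-frame angles (degrees) to collicular coordinates (r, phi).

    r = M_f * E2 * ln(ecc/E2 + 1) with ecc = sqrt(tx^2 + ty^2); phi is the
    1-based direction index: up (tx>0, ty=0) at phi=1, increasing towards
    left (ty>0, phi=13.5), down (phi=26) and right (phi=38.5).

    Out-of-view targets (ecc > W_fov/2) map to (nan, nan).  The origin
    maps to r=0 with phi fixed at 1 (the direction is undefined there).
    """
    tx = np.asarray(theta_x, dtype=float)
    ty = np.asarray(theta_y, dtype=float)
    ecc = np.hypot(tx, ty)
    r = params.M_f * params.E2 * np.log1p(ecc / params.E2)
    ang = np.mod(np.arctan2(ty, tx), 2.0 * np.pi)
    phi = 1.0 + params.W_nfs * ang / (2.0 * np.pi)
    phi = np.where(ecc == 0.0, 1.0, phi)
    oov = ecc > params.W_fov / 2.0 + 1e-12
    r = np.where(oov, np.nan, r)
    phi = np.where(oov, np.nan, phi)
    if np.ndim(theta_x) == 0 and np.ndim(theta_y) == 0:
        return float(r), float(phi)
    return r, phi


def inverse_map(r, phi, params: MappingParams = MappingParams()):
    """Map collicular coordinates back to eye-frame angles (degrees)."""
    r = np.asarray(r, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    ecc = params.eccentricity_of_r(r)
    ang = 2.0 * np.pi * (phi - 1.0) / params.W_nfs
    tx = ecc * np.cos(ang)
    ty = ecc * np.sin(ang)
    if np.ndim(r) == 0 and np.ndim(phi) == 0:
        return float(tx), float(ty)
    return tx, ty


class WorldRenderer:
    """Rasterizes the visible world onto the retinotopic grid.

    Grid cells are placed at integer (r, phi) in [1, 50] x [1, 50].  For
    each cell the eye-frame angles are precomputed once via the inverse
    mapping; rendering then tests membership of each cell in each active
    cross (in eye-frame angular coordinates), takes the maximum magnitude
    over overlapping crosses (configurable to sum), blurs with a 2-D
    Gaussian (wrapping along phi) and finally zeroes the foveal mask.
    """

    def __init__(
        self,
        params: MappingParams = MappingParams(),
        blur_sigma: float = 1.0,
        fovea_mask_deg: float = 1.5,
        combine: str = "max",
        supersample: int = 2,
    ) -> None:
        if combine not in ("max", "sum"):
            raise ValueError("combine must be 'max' or 'sum'")
        if supersample < 1:
            raise ValueError("supersample must be >= 1")
        self.params = params
        self.blur_sigma = float(blur_sigma)
        self.fovea_mask_deg = float(fovea_mask_deg)
        self.combine = combine
        self.supersample = int(supersample)
        n = int(params.W_nfs)
        r_idx, phi_idx = np.meshgrid(
            np.arange(1, n + 1, dtype=float), np.arange(1, n + 1, dtype=float), indexing="ij"
        )
        self.cell_tx, self.cell_ty = inverse_map(r_idx, phi_idx, params)
        self.cell_ecc = np.hypot(self.cell_tx, self.cell_ty)
        self._fovea = self.cell_ecc < self.fovea_mask_deg
        # sub-cell sample angles for anti-aliased rasterization
        ss = self.supersample
        offs = (np.arange(ss) + 0.5) / ss - 0.5
        sub_r, sub_phi = [], []
        for dr in offs:
            for dp in offs:
                sub_r.append(np.maximum(r_idx + dr, 0.0))
                sub_phi.append(phi_idx + dp)
        tx, ty = inverse_map(np.stack(sub_r), np.stack(sub_phi), params)
        self._sub_tx, self._sub_ty = tx, ty

    def render(
        self,
        luminances: list[Luminance],
        eye: EyeRotation,
        t: float,
        mask_fovea: bool = True,
        blur: bool = True,
    ) -> np.ndarray:
        """Return the 50x50 grid of non-negative activities at time t."""
        if t < 0:
            raise ValueError("t must be >= 0")
        active = [lum for lum in luminances if lum.active(t)]
        n = int(self.params.W_nfs)
        grid = np.zeros((n, n))
        if active:
            centres = eye_frame_transform([(l.theta_x, l.theta_y) for l in active], eye)
            for lum, (cx, cy) in zip(active, centres):
                if not np.isfinite(cx):
                    continue
                dx = np.abs(self._sub_tx - cx)
                dy = np.abs(self._sub_ty - cy)
                half = lum.bar_width / 2.0
                if lum.shape == "cross":
                    inside = ((dx <= lum.span) & (dy <= half)) | ((dy <= lum.span) & (dx <= half))
                else:  # axis-aligned rectangle: span tall, bar_width wide
                    inside = (dx <= lum.span) & (dy <= half)
                contrib = lum.magnitude * inside.mean(axis=0)
                if self.combine == "max":
                    np.maximum(grid, contrib, out=grid)
                else:
                    grid += contrib
        if blur and self.blur_sigma > 0:
            grid = gaussian_filter(grid, self.blur_sigma, mode=["nearest", "wrap"])
        if mask_fovea:
            grid = np.where(self._fovea, 0.0, grid)
        return grid
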