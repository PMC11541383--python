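"""Virtualized electromagnetic tracking.

The physical benchmark tool carries three 5-DoF EM sensors glued along a
catheter at 0.5, 10.5 and 17.5 cm from the tip.  Only sensor positions are
used here (the selection error is position-based), so sensors are modeled
as points sampled on the simulated rod at fixed arc-length offsets from the
tip, measured along the deformed rod — matching sensors glued to a bent
catheter.  Readings are synthesized with isotropic Gaussian noise, and the
image and physical frames are related by a landmark-based rigid (Kabsch)
registration with its fiducial registration error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FrameMismatchError, ValidationError

DEFAULT_SENSOR_OFFSETS = (5.0, 105.0, 175.0)  # mm from the tip


@dataclass
class VirtualSensorSet:
    """Simulated sensor positions at one insertion step."""

    step: str
    positions: np.ndarray                  # (3, 3) mm, sensor 1 = closest to tip
    offsets: tuple[float, float, float] = DEFAULT_SENSOR_OFFSETS
    frame: str = "image"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (3, 3):
            raise ValidationError("need exactly three 3D sensor positions")
        if not np.all(np.diff(self.offsets) > 0):
            raise ValidationError("sensor offsets must be strictly increasing")


@dataclass
class SensorReading:
    """One measured sensor position (synthetic stand-in for an EM acquisition)."""

    step: str
    sensor: int           # 1, 2 or 3 (1 = closest to tip)
    position: np.ndarray  # (3,) mm
    frame: str = "physical"

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.sensor not in (1, 2, 3):
            raise ValidationError("sensor index must be 1, 2 or 3")
        if self.position.shape != (3,):
            raise ValidationError("position must be a 3-vector")


@dataclass
class RigidTransform:
    """Rotation + translation mapping moving -> fixed frame (no scaling)."""

    rotation: np.ndarray     # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,) mm
    fre: float = 0.0         # fiducial registration error, mm RMS

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if np.linalg.norm(self.rotation.T @ self.rotation - np.eye(3)) > 1e-9:
            raise ValidationError("rotation matrix is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValidationError("reflection is not a rigid transform")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation,
                              fre=self.fre)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))

    @classmethod
    def from_params(cls, axis, angle_deg: float, translation) -> "RigidTransform":
        from scipy.spatial.transform import Rotation

        axis = np.asarray(axis, dtype=float)
        rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / np.linalg.norm(axis))
        return cls(rotation=rot.as_matrix(), translation=np.asarray(translation, float))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _arc_interpolate_from_tip(positions: np.ndarray, offsets) -> np.ndarray:
    """Points at given arc lengths from the tip along a polyline.

    The tip is the last point of ``positions``; arc length is accumulated
    backwards along the (possibly bent) polyline and each offset is resolved
    by linear interpolation within its containing segment.
    """
    pts = positions[::-1]  # tip first
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    out = np.empty((len(offsets), 3))
    for k, s in enumerate(offsets):
        if s < 0 or s > arc[-1] + 1e-9:
            raise ValidationError(
                f"sensor offset {s} mm exceeds rod length {arc[-1]:.1f} mm"
            )
        out[k] = np.array([np.interp(s, arc, pts[:, d]) for d in range(3)])
    return out


def virtual_sensor_positions(rod, offsets=DEFAULT_SENSOR_OFFSETS,
                             step: str = "") -> VirtualSensorSet:
    """Sample the three virtual sensors on the rod at arc offsets from the tip."""
    offsets = tuple(float(o) for o in offsets)
    if len(offsets) != 3 or not np.all(np.diff(offsets) > 0):
        raise ValidationError("offsets must be three strictly increasing values")
    pos = _arc_interpolate_from_tip(np.asarray(rod.positions, dtype=float), offsets)
    return VirtualSensorSet(step=step, positions=pos, offsets=offsets)


def synthesize_readings(sensors: VirtualSensorSet, noise_sigma: float = 0.5,
                        seed: int = 0,
                        transform: RigidTransform | None = None) -> list[SensorReading]:
    """Noisy 'experimental' readings from virtual sensor positions.

    Isotropic Gaussian noise with standard deviation ``noise_sigma`` (mm) is
    added per coordinate; an optional rigid transform maps the simulation
    frame into the physical (tracker) frame first.  Seeded and deterministic.
    """
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    pos = sensors.positions
    if transform is not None:
        pos = transform.apply(pos)
    noisy = pos + rng.normal(0.0, noise_sigma, size=pos.shape)
    return [SensorReading(step=sensors.step, sensor=i + 1,
                          position=noisy[i], frame="physical")
            for i in range(3)]


def register_rigid(moving_landmarks: np.ndarray,
                   fixed_landmarks: np.ndarray) -> RigidTransform:
    """Landmark-based rigid registration (least-squares, Kabsch).

    Finds the rotation + translation (no scaling, reflection guarded out)
    minimizing the RMS distance from transformed moving landmarks to fixed
    landmarks, and reports that residual as the fiducial registration error.
    """
    mov = np.asarray(moving_landmarks, dtype=float)
    fix = np.asarray(fixed_landmarks, dtype=float)
    if mov.shape != fix.shape or mov.ndim != 2 or mov.shape[1] != 3:
        raise ValidationError("landmark sets must be equal-length (N, 3) arrays")
    if len(mov) < 3:
        raise ValidationError("need at least 3 landmarks")
    mc, fc = mov.mean(axis=0), fix.mean(axis=0)
    a, b = mov - mc, fix - fc
    s = np.linalg.svd(a, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValidationError("landmarks are collinear; registration is degenerate")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = fc - rot @ mc
    res = mov @ rot.T + trans - fix
    fre = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return RigidTransform(rotation=rot, translation=trans, fre=fre)


def sensor_error(experimental: list[SensorReading],
                 simulated: VirtualSensorSet) -> float:
    """Mean Euclidean distance (mm) between measured and simulated sensors.

    e = (1/3) * sum_i || s_exp,i - s_sim,i ||, the position-matching error
    used to rank candidate simulations.  Both point sets must be expressed in
    the same frame.
    """
    by_index = {}
    for r in experimental:
        if r.frame != simulated.frame:
            raise FrameMismatchError(
                f"reading frame {r.frame!r} != simulation frame {simulated.frame!r}; "
                "register the readings first"
            )
        by_index[r.sensor] = r.position
    missing = {1, 2, 3} - set(by_index)
    if missing:
        raise ValidationError(f"missing sensor(s): {sorted(missing)}")
    d = [np.linalg.norm(by_index[i + 1] - simulated.positions[i]) for i in range(3)]
    return float(np.mean(d))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

READINGS_COLUMNS = ["step", "sensor", "x_mm", "y_mm", "z_mm", "frame"]


def readings_to_frame(readings: list[SensorReading]) -> pd.DataFrame:
    rows = [
        {"step": r.step, "sensor": r.sensor, "x_mm": r.position[0],
         "y_mm": r.position[1], "z_mm": r.position[2], "frame": r.frame}
        for r in readings
    ]
    return pd.DataFrame(rows, columns=READINGS_COLUMNS)


def save_readings(readings: list[SensorReading], path) -> None:
    path = str(path)
    df = readings_to_frame(readings)
    if path.endswith(".json"):
        df.to_json(path, orient="records", indent=2)
    else:
        df.to_csv(path, index=False)


def load_readings(path) -> list[SensorReading]:
    path = str(path)
    df = pd.read_json(path) if path.endswith(".json") else pd.read_csv(path)
    missing = set(READINGS_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"readings file missing columns: {sorted(missing)}")
    return [
        SensorReading(step=str(row.step), sensor=int(row.sensor),
                      position=np.array([row.x_mm, row.y_mm, row.z_mm]),
                      frame=str(row.frame))
        for row in df.itertuples()
    ]


def transform_readings(readings: list[SensorReading], transform: RigidTransform,
                       frame: str) -> list[SensorReading]:
    """Map readings into another frame (e.g. physical -> image after registration)."""
    return [
        SensorReading(step=r.step, sensor=r.sensor,
                      position=transform.apply(r.position), frame=frame)
        for r in readings
    ]


def save_landmarks(names, points, path) -> None:
    pts = np.asarray(points, dtype=float)
    pd.DataFrame({"name": list(names), "x_mm": pts[:, 0], "y_mm": pts[:, 1],
                  "z_mm": pts[:, 2]}).to_csv(path, index=False)


def load_landmarks(path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path)
    return list(df["name"]), df[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
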