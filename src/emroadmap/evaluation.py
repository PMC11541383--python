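"""Roadmap accuracy metrics.

Quantifies how well a predicted (simulated) deformed vessel matches the
ground-truth deformed one, and how much better that is than using the
undeformed baseline:

* surface mismatch as nearest-neighbor distance fields between area-uniform
  surface samples, summarized by the symmetric Hausdorff maximum and
  percentiles (u_gt: baseline vs ground-truth deformed; u_p: baseline vs
  predicted; e_aorta: predicted vs ground-truth deformed);
* a three-region partition of the model by the two mid-planes between
  consecutive EM sensors (region I at the tip);
* normalized lumen-volume overlaps per region,
  OV = 100 * |Va ∩ Vb| / min(va, vb), applied as OV_P (predicted vs deformed)
  and OV_GT (undeformed vs deformed), and the roadmap improvement
  delta_OV = OV_P - OV_GT.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial import cKDTree

from .errors import ValidationError
from .vesselgen import LabelVolume, VesselMesh

__all__ = [
    "SurfaceDistanceReport",
    "RegionPartition",
    "OverlapReport",
    "EvaluationReport",
    "surface_distance",
    "partition_regions",
    "overlap_percent",
    "delta_ov",
    "evaluate_roadmap",
]

REGIONS = ("I", "II", "III")


# ---------------------------------------------------------------------------
# surface distances
# ---------------------------------------------------------------------------

@dataclass
class SurfaceDistanceReport:
    """Bidirectional nearest-neighbor distances between two sampled surfaces."""

    distances_ab: np.ndarray  # samples of A -> nearest sample of B (mm)
    distances_ba: np.ndarray
    role: str = ""            # e.g. "u_gt", "u_p", "e_aorta"

    @property
    def directed_max_ab(self) -> float:
        return float(self.distances_ab.max())

    @property
    def directed_max_ba(self) -> float:
        return float(self.distances_ba.max())

    @property
    def hausdorff(self) -> float:
        """Symmetric Hausdorff maximum (mm)."""
        return max(self.directed_max_ab, self.directed_max_ba)

    def percentile(self, q) -> float:
        return float(np.percentile(self._pooled(), q))

    @property
    def median(self) -> float:
        return self.percentile(50)

    def fraction_below(self, threshold_mm: float) -> float:
        """Fraction of sampled points with mismatch below a threshold."""
        pooled = self._pooled()
        return float(np.mean(pooled < threshold_mm))

    def _pooled(self) -> np.ndarray:
        return np.concatenate([self.distances_ab, self.distances_ba])

    def summary(self) -> dict:
        return {
            "role": self.role,
            "hausdorff_mm": self.hausdorff,
            "median_mm": self.median,
            "p90_mm": self.percentile(90),
            "p95_mm": self.percentile(95),
            "mean_mm": float(self._pooled().mean()),
            "n_samples": int(len(self.distances_ab) + len(self.distances_ba)),
        }


def _as_trimesh(surface) -> trimesh.Trimesh | None:
    if isinstance(surface, VesselMesh):
        return surface.as_trimesh()
    if isinstance(surface, trimesh.Trimesh):
        return surface
    return None


def _as_points(surface, sample_density: float, seed: int) -> np.ndarray:
    """Area-uniform samples of a surface (or pass point arrays through)."""
    tm = _as_trimesh(surface)
    if tm is None:
        pts = np.atleast_2d(np.asarray(surface, dtype=float))
        if pts.size == 0:
            raise ValidationError("empty surface")
        return pts
    if len(tm.faces) == 0:
        raise ValidationError("empty mesh")
    n = max(int(np.ceil(tm.area * sample_density)), 100)
    samples, _ = trimesh.sample.sample_surface(tm, n, seed=seed)
    return np.asarray(samples, dtype=float)


def _point_to_surface_distance(points: np.ndarray, tm: trimesh.Trimesh) -> np.ndarray:
    """Exact distance to the nearest triangle (candidates from nearest vertices)."""
    from .rodsim import _closest_point_triangles

    verts = np.asarray(tm.vertices)
    faces = np.asarray(tm.faces)
    vertex_faces: list[list[int]] = [[] for _ in range(len(verts))]
    for f, t in enumerate(faces):
        for v in t:
            vertex_faces[int(v)].append(f)
    max_deg = max(len(fs) for fs in vertex_faces)
    table = np.full((len(verts), max_deg), -1, dtype=int)
    for v, fs in enumerate(vertex_faces):
        table[v, :len(fs)] = fs
    _, nearest = cKDTree(verts).query(points, k=min(3, len(verts)))
    centroids = verts[faces].mean(axis=1)
    _, near_faces = cKDTree(centroids).query(points, k=min(8, len(centroids)))
    parts = [table[np.atleast_2d(nearest)].reshape(len(points), -1),
             np.atleast_2d(near_faces)]
    # a few long faces (junction strips) can be closest while their vertices
    # and centroid are all far: always include them
    edge_len = np.linalg.norm(verts[faces] - verts[np.roll(faces, 1, axis=1)],
                              axis=2).max(axis=1)
    big = np.flatnonzero(edge_len > max(3.0 * np.median(edge_len), 6.0))
    if len(big):
        parts.append(np.tile(big, (len(points), 1)))
    cand = np.hstack(parts)
    owner = np.repeat(np.arange(len(points)), cand.shape[1])
    flat = cand.ravel()
    keep = flat >= 0
    owner, flat = owner[keep], flat[keep]
    cp, _ = _closest_point_triangles(points[owner], verts[faces[flat]])
    d2 = np.sum((cp - points[owner]) ** 2, axis=1)
    out = np.full(len(points), np.inf)
    np.minimum.at(out, owner, d2)
    return np.sqrt(out)


def surface_distance(surface_a, surface_b, sample_density: float = 1.0,
                     role: str = "", seed: int = 0) -> SurfaceDistanceReport:
    """Bidirectional nearest-neighbor distance between two sampled surfaces.

    Surfaces are sampled uniformly by area at ``sample_density`` (samples per
    mm^2, seeded for reproducibility); samples are measured against the other
    surface's triangles (exact nearest-triangle distance).  Raw point arrays
    are accepted as-is and measured point-to-point.
    """
    if sample_density <= 0:
        raise ValidationError("sample_density must be > 0")
    pa = _as_points(surface_a, sample_density, seed)
    pb = _as_points(surface_b, sample_density, seed + 1)
    tma, tmb = _as_trimesh(surface_a), _as_trimesh(surface_b)
    d_ab = (_point_to_surface_distance(pa, tmb) if tmb is not None
            else cKDTree(pb).query(pa)[0])
    d_ba = (_point_to_surface_distance(pb, tma) if tma is not None
            else cKDTree(pa).query(pb)[0])
    return SurfaceDistanceReport(distances_ab=d_ab, distances_ba=d_ba, role=role)


# ---------------------------------------------------------------------------
# sensor mid-plane regions
# ---------------------------------------------------------------------------

@dataclass
class RegionPartition:
    """Partition of points by the mid-planes between consecutive sensors.

    Plane k passes through the midpoint of sensors k, k+1 with normal along
    their chord.  Region I is the tip side of plane 1, region III the far
    side of plane 2, region II between.  Points that test on the tip side of
    plane 1 *and* the far side of plane 2 simultaneously (possible when the
    planes intersect inside a bent model) are assigned to the region of the
    nearest sensor and counted.
    """

    plane_points: np.ndarray    # (2, 3)
    plane_normals: np.ndarray   # (2, 3) unit
    labels: np.ndarray          # (N,) values in {"I", "II", "III"}
    sensors: np.ndarray         # (3, 3)
    n_ambiguous: int = 0

    def mask(self, region: str) -> np.ndarray:
        if region not in REGIONS:
            raise ValidationError(f"unknown region {region!r}")
        return self.labels == region


def partition_regions(points: np.ndarray, sensor_positions: np.ndarray
                      ) -> RegionPartition:
    """Classify points into sensor regions I/II/III (see RegionPartition)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    sens = np.asarray(sensor_positions, dtype=float)
    if sens.shape != (3, 3):
        raise ValidationError("need exactly three sensor positions")
    if (np.linalg.norm(sens[1] - sens[0]) < 1e-9
            or np.linalg.norm(sens[2] - sens[1]) < 1e-9):
        raise ValidationError("coincident sensors cannot define mid-planes")

    mids = np.array([(sens[0] + sens[1]) / 2, (sens[1] + sens[2]) / 2])
    normals = np.array([sens[1] - sens[0], sens[2] - sens[1]])
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)

    s1 = (pts - mids[0]) @ normals[0]  # < 0: tip side of plane 1
    s2 = (pts - mids[1]) @ normals[1]  # > 0: far side of plane 2
    labels = np.full(len(pts), "II", dtype=object)
    labels[s1 < 0] = "I"
    labels[s2 > 0] = "III"
    ambiguous = (s1 < 0) & (s2 > 0)
    if ambiguous.any():
        d = np.linalg.norm(pts[ambiguous, None, :] - sens[None, :, :], axis=2)
        nearest = np.argmin(d, axis=1)
        labels[np.flatnonzero(ambiguous)] = np.array(REGIONS)[nearest]
    return RegionPartition(plane_points=mids, plane_normals=normals,
                           labels=labels.astype(str), sensors=sens,
                           n_ambiguous=int(ambiguous.sum()))


# ---------------------------------------------------------------------------
# volume overlaps
# ---------------------------------------------------------------------------

def _check_same_grid(va: LabelVolume, vb: LabelVolume) -> None:
    if not va.same_grid(vb):
        raise ValidationError(
            "label volumes are on different grids: "
            f"{va.grid_header()} vs {vb.grid_header()}")


def overlap_percent(va: LabelVolume, vb: LabelVolume,
                    mask: np.ndarray | None = None) -> float:
    """Normalized overlap 100 * |Va ∩ Vb| / min(va, vb), in percent.

    Symmetric in its arguments; requires identical grids.  ``mask`` (same
    shape) restricts the computation to one region; an empty region yields
    NaN rather than a fake 0 or 100.
    """
    _check_same_grid(va, vb)
    a, b = va.data, vb.data
    if mask is not None:
        if mask.shape != a.shape:
            raise ValidationError("region mask shape does not match the grid")
        a, b = a & mask, b & mask
    ca, cb = int(a.sum()), int(b.sum())
    if mask is None and ca == 0 and cb == 0:
        raise ValidationError("both label volumes are empty")
    denom = min(ca, cb)
    if denom == 0:
        return float("nan")
    inter = int((a & b).sum())
    return 100.0 * inter / denom


def delta_ov(ov_p: float, ov_gt: float) -> float:
    """Roadmap improvement delta_OV = OV_P - OV_GT (percentage points).

    Positive when the predicted deformed roadmap overlaps the ground-truth
    deformed lumen better than the undeformed baseline does; may be negative.
    """
    for name, v in (("ov_p", ov_p), ("ov_gt", ov_gt)):
        if not (np.isnan(v) or 0.0 <= v <= 100.0):
            raise ValidationError(f"{name} = {v} outside [0, 100]")
    return float(ov_p - ov_gt)


@dataclass
class OverlapReport:
    """Regional overlap metrics for one insertion position.

    ``per_region`` maps region -> dict with ov_p, ov_gt, delta_ov (percent)
    and the underlying voxel counts.  The position average is the arithmetic
    mean of the three regional values (NaN regions excluded).
    """

    position: str
    per_region: dict[str, dict] = field(default_factory=dict)

    def average(self, key: str = "delta_ov") -> float:
        vals = [r[key] for r in self.per_region.values() if not np.isnan(r[key])]
        return float(np.mean(vals)) if vals else float("nan")

    def table_row(self) -> dict:
        row = {f"{reg}": round(self.per_region[reg]["delta_ov"], 1)
               for reg in REGIONS if reg in self.per_region}
        row["Avg"] = round(self.average(), 1)
        return row


# ---------------------------------------------------------------------------
# end-to-end evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Full accuracy report across insertion positions."""

    surface: dict[str, dict[str, SurfaceDistanceReport]]  # position -> role -> report
    overlap: dict[str, OverlapReport]                     # position -> report
    n_ambiguous: dict[str, int] = field(default_factory=dict)

    def delta_ov_table(self) -> pd.DataFrame:
        """Regions I/II/III + Avg per position, one decimal (export style)."""
        return pd.DataFrame({pos: rep.table_row()
                             for pos, rep in self.overlap.items()}).T

    def to_json(self, path=None) -> str:
        payload = {
            "surface": {pos: {role: rep.summary() for role, rep in roles.items()}
                        for pos, roles in self.surface.items()},
            "overlap": {pos: {"per_region": rep.per_region,
                              "avg_delta_ov": rep.average(),
                              "avg_ov_p": rep.average("ov_p"),
                              "avg_ov_gt": rep.average("ov_gt")}
                        for pos, rep in self.overlap.items()},
            "ambiguous_region_points": self.n_ambiguous,
        }
        text = json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _region_masks(volume: LabelVolume, sensors: np.ndarray
                  ) -> tuple[dict[str, np.ndarray], int]:
    centers = volume.voxel_centers().reshape(-1, 3)
    part = partition_regions(centers, sensors)
    labels = part.labels.reshape(volume.shape)
    return ({reg: labels == reg for reg in REGIONS}, part.n_ambiguous)


def evaluate_roadmap(predicted: dict[str, tuple[VesselMesh, LabelVolume]],
                     ground_truth: dict[str, tuple[VesselMesh, LabelVolume]],
                     baseline: tuple[VesselMesh, LabelVolume],
                     sensors: dict[str, np.ndarray],
                     sample_density: float = 1.0,
                     seed: int = 0) -> EvaluationReport:
    """Evaluate a predicted roadmap against ground truth at each position.

    Per position: the three surface-distance fields (baseline vs ground
    truth, baseline vs predicted, predicted vs ground truth), the sensor
    mid-plane region partition, and regional OV_P / OV_GT / delta_OV with
    per-position averages.  All label volumes must share one grid.
    """
    base_mesh, base_vol = baseline
    missing = [p for p in ground_truth if p not in predicted]
    if missing:
        raise ValidationError(f"prediction missing position(s): {missing}")

    surface: dict[str, dict[str, SurfaceDistanceReport]] = {}
    overlap: dict[str, OverlapReport] = {}
    ambiguous: dict[str, int] = {}
    for pos, (gt_mesh, gt_vol) in ground_truth.items():
        pred_mesh, pred_vol = predicted[pos]
        _check_same_grid(base_vol, gt_vol)
        _check_same_grid(base_vol, pred_vol)
        surface[pos] = {
            "u_gt": surface_distance(base_mesh, gt_mesh, sample_density,
                                     role="u_gt", seed=seed),
            "u_p": surface_distance(base_mesh, pred_mesh, sample_density,
                                    role="u_p", seed=seed + 1),
            "e_aorta": surface_distance(pred_mesh, gt_mesh, sample_density,
                                        role="e_aorta", seed=seed + 2),
        }
        masks, n_amb = _region_masks(base_vol, np.asarray(sensors[pos]))
        ambiguous[pos] = n_amb
        rep = OverlapReport(position=pos)
        for reg in REGIONS:
            ov_p = overlap_percent(pred_vol, gt_vol, mask=masks[reg])
            ov_gt = overlap_percent(base_vol, gt_vol, mask=masks[reg])
            rep.per_region[reg] = {
                "ov_p": ov_p,
                "ov_gt": ov_gt,
                "delta_ov": delta_ov(ov_p, ov_gt) if not (np.isnan(ov_p)
                                                          or np.isnan(ov_gt))
                else float("nan"),
                "voxels_pred": int((pred_vol.data & masks[reg]).sum()),
                "voxels_gt_def": int((gt_vol.data & masks[reg]).sum()),
                "voxels_baseline": int((base_vol.data & masks[reg]).sum()),
                "voxels_intersection_pred": int(
                    (pred_vol.data & gt_vol.data & masks[reg]).sum()),
                "voxels_intersection_baseline": int(
                    (base_vol.data & gt_vol.data & masks[reg]).sum()),
            }
        overlap[pos] = rep
    return EvaluationReport(surface=surface, overlap=overlap,
                            n_ambiguous=ambiguous)


def export_distance_map(mesh: VesselMesh, reference_points: np.ndarray,
                        path) -> np.ndarray:
    """Per-vertex distance to a reference point set, exported as a colored PLY.

    Returns the per-vertex distances; the PLY encodes them as a grayscale
    vertex-color ramp for quick visual inspection of local mismatch.
    """
    d = cKDTree(np.asarray(reference_points)).query(mesh.vertices)[0]
    tm = mesh.as_trimesh()
    dmax = d.max() if d.max() > 0 else 1.0
    ramp = (255 * d / dmax).astype(np.uint8)
    tm.visual.vertex_colors = np.column_stack(
        [ramp, ramp, 255 - ramp, np.full_like(ramp, 255)])
    tm.export(path)
    return d
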