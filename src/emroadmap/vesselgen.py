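"""Synthetic aorto-iliac phantom generation.

Builds desk-scale stand-ins for a manufactured patient-specific aneurysm
model: a bifurcated centerline tree (aneurysmatic trunk splitting into two
tortuous iliac arteries), a swept triangulated lumen surface fixed at its
connector rings, and a binary voxel label map of the lumen.

Coordinate convention (right-handed, millimetres):
    +x  patient-left -> patient-right
    +y  posterior   -> anterior
    +z  caudal      -> cranial
The frontal plane is x-z, the sagittal plane is y-z.  The aortic bifurcation
sits at the origin; the trunk extends cranially (+z) and the iliac branches
run caudally from it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import shapely
import trimesh

from .errors import GeometryError, ValidationError

__all__ = [
    "Branch",
    "CenterlineTree",
    "VesselMesh",
    "LabelVolume",
    "PhantomParams",
    "make_bifurcated_centerline",
    "sweep_tube_surface",
    "voxelize_lumen",
]


# ---------------------------------------------------------------------------
# centerline tree
# ---------------------------------------------------------------------------

@dataclass
class Branch:
    """One branch of the centerline tree: ordered 3D points with local lumen radii."""

    name: str
    points: np.ndarray  # (N, 3) mm
    radii: np.ndarray   # (N,) mm
    parent: str | None = None  # branch whose point this branch starts on

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValidationError(f"branch {self.name!r}: points must be (N, 3)")
        if len(self.points) < 2:
            raise ValidationError(f"branch {self.name!r}: need at least 2 points")
        if len(self.radii) != len(self.points):
            raise ValidationError(f"branch {self.name!r}: radii/points length mismatch")
        if np.any(self.radii <= 0):
            raise ValidationError(f"branch {self.name!r}: all radii must be > 0")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValidationError(f"branch {self.name!r}: zero-length segment")

    @property
    def arc_length(self) -> np.ndarray:
        """Cumulative arc length per point (mm), strictly increasing from 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def tangents(self) -> np.ndarray:
        """Unit tangent per point (central differences, one-sided at the ends)."""
        t = np.gradient(self.points, self.arc_length, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    def curvature(self) -> np.ndarray:
        """Discrete curvature (1/mm) per point."""
        t = self.tangents()
        dt = np.gradient(t, self.arc_length, axis=0)
        return np.linalg.norm(dt, axis=1)

    def max_curvature(self) -> float:
        """Maximum discrete curvature (1/mm) along the branch."""
        return float(np.max(self.curvature()))


@dataclass
class CenterlineTree:
    """Named branches; children attach (first point) onto a parent point."""

    branches: dict[str, Branch]

    def __post_init__(self):
        for name, br in self.branches.items():
            if br.name != name:
                raise ValidationError(f"branch key {name!r} != branch.name {br.name!r}")
            if br.parent is not None:
                if br.parent not in self.branches:
                    raise ValidationError(f"branch {name!r}: unknown parent {br.parent!r}")
                parent_pts = self.branches[br.parent].points
                d = np.linalg.norm(parent_pts - br.points[0], axis=1)
                if d.min() > 1e-9:
                    raise ValidationError(
                        f"branch {name!r}: first point does not coincide with a "
                        f"parent point (min distance {d.min():.3g} mm)"
                    )

    def __getitem__(self, name: str) -> Branch:
        return self.branches[name]

    @property
    def names(self) -> list[str]:
        return list(self.branches)


# ---------------------------------------------------------------------------
# vessel surface mesh
# ---------------------------------------------------------------------------

@dataclass
class VesselMesh:
    """Deformable triangulated lumen surface.

    ``vertices`` hold the current (possibly deformed) configuration;
    ``reference_vertices`` the undeformed one.  ``fixed_vertex_ids`` are the
    Dirichlet set: the open connector rings where the physical model is tied
    to its box, which never move.  ``rings`` maps ring names (``inlet``,
    ``<branch>_outlet``) to the ordered vertex ids of each open ring.
    """

    vertices: np.ndarray            # (V, 3) mm
    triangles: np.ndarray           # (F, 3) int
    reference_vertices: np.ndarray  # (V, 3) mm
    wall_thickness: float = 2.0     # mm
    fixed_vertex_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    rings: dict[str, np.ndarray] = field(default_factory=dict)
    local_radius: np.ndarray | None = None  # (V,) mm, lumen radius at each vertex

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.reference_vertices = np.asarray(self.reference_vertices, dtype=float)
        self.fixed_vertex_ids = np.asarray(self.fixed_vertex_ids, dtype=np.int64)
        if len(self.vertices) != len(self.reference_vertices):
            raise ValidationError("vertices and reference_vertices differ in length")
        if self.wall_thickness <= 0:
            raise ValidationError("wall_thickness must be > 0")
        if len(self.fixed_vertex_ids) and (
            self.fixed_vertex_ids.min() < 0
            or self.fixed_vertex_ids.max() >= len(self.vertices)
        ):
            raise ValidationError("fixed_vertex_ids out of range")

    # -- derived geometry ---------------------------------------------------

    def as_trimesh(self, reference: bool = False) -> trimesh.Trimesh:
        v = self.reference_vertices if reference else self.vertices
        return trimesh.Trimesh(vertices=v, faces=self.triangles, process=False)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        c = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return 0.5 * np.linalg.norm(c, axis=1)

    def boundary_edges(self) -> np.ndarray:
        """Edges used by exactly one triangle, as (E, 2) sorted vertex pairs."""
        e = np.vstack([self.triangles[:, [0, 1]],
                       self.triangles[:, [1, 2]],
                       self.triangles[:, [2, 0]]])
        e = np.sort(e, axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts == 1]

    def boundary_loops(self) -> list[np.ndarray]:
        """Connected components of the boundary, each as an array of vertex ids."""
        import networkx as nx  # stdlib-adjacent; used only for loop grouping

        g = nx.Graph()
        g.add_edges_from(map(tuple, self.boundary_edges()))
        return [np.fromiter(c, dtype=np.int64) for c in nx.connected_components(g)]

    def validate(self) -> None:
        """Check the structural invariants; raise ValidationError on failure."""
        if np.any(self.triangle_areas() <= 0):
            raise ValidationError("degenerate (zero-area) triangle in mesh")
        ring_ids = set()
        for ids in self.rings.values():
            ring_ids.update(int(i) for i in ids)
        bverts = set(int(i) for i in np.unique(self.boundary_edges()))
        if not bverts <= ring_ids:
            raise ValidationError(
                f"{len(bverts - ring_ids)} boundary vertices outside declared rings"
            )

    def displacements(self) -> np.ndarray:
        return self.vertices - self.reference_vertices

    def copy(self) -> "VesselMesh":
        return VesselMesh(
            vertices=self.vertices.copy(),
            triangles=self.triangles.copy(),
            reference_vertices=self.reference_vertices.copy(),
            wall_thickness=self.wall_thickness,
            fixed_vertex_ids=self.fixed_vertex_ids.copy(),
            rings={k: np.asarray(v).copy() for k, v in self.rings.items()},
            local_radius=None if self.local_radius is None else self.local_radius.copy(),
        )

    def with_vertices(self, vertices: np.ndarray) -> "VesselMesh":
        out = self.copy()
        out.vertices = np.asarray(vertices, dtype=float)
        return out

    def content_hash(self) -> str:
        """SHA-256 over the reference geometry; identifies the phantom."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.reference_vertices).tobytes())
        h.update(np.ascontiguousarray(self.triangles).tobytes())
        return h.hexdigest()

    # -- I/O ----------------------------------------------------------------

    def save(self, path) -> None:
        """Write current configuration as STL or PLY (binary, by extension)."""
        self.as_trimesh().export(path)

    @classmethod
    def load(cls, path, wall_thickness: float = 2.0) -> "VesselMesh":
        """Read a surface mesh (STL/PLY); reference set to the loaded geometry."""
        m = trimesh.load_mesh(path, process=False)
        mesh = cls(
            vertices=np.asarray(m.vertices, dtype=float),
            triangles=np.asarray(m.faces, dtype=np.int64),
            reference_vertices=np.asarray(m.vertices, dtype=float).copy(),
            wall_thickness=wall_thickness,
        )
        # declare whatever open boundary exists as rings so validate() passes
        for i, loop in enumerate(mesh.boundary_loops()):
            mesh.rings[f"ring_{i}"] = loop
        mesh.fixed_vertex_ids = (
            np.unique(np.concatenate([v for v in mesh.rings.values()]))
            if mesh.rings else np.empty(0, dtype=np.int64)
        )
        return mesh


# ---------------------------------------------------------------------------
# label volume
# ---------------------------------------------------------------------------

@dataclass
class LabelVolume:
    """Binary voxel occupancy on an isotropic grid (1 = lumen)."""

    origin: np.ndarray   # (3,) mm, corner of voxel (0,0,0)
    spacing: float       # mm, isotropic
    data: np.ndarray     # (nx, ny, nz) bool

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.data = np.asarray(self.data)
        if self.spacing <= 0:
            raise ValidationError("spacing must be > 0")
        if self.data.dtype != bool:
            if not np.isin(np.unique(self.data), [0, 1]).all():
                raise ValidationError("occupancy must be strictly binary")
            self.data = self.data.astype(bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.count * self.spacing**3

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of every voxel center, shape (nx, ny, nz, 3)."""
        idx = np.stack(np.meshgrid(*[np.arange(n) for n in self.shape],
                                   indexing="ij"), axis=-1)
        return self.origin + (idx + 0.5) * self.spacing

    def same_grid(self, other: "LabelVolume") -> bool:
        return (
            self.shape == other.shape
            and abs(self.spacing - other.spacing) < 1e-9
            and np.allclose(self.origin, other.origin, atol=1e-9)
        )

    def grid_header(self) -> dict:
        return {"origin": self.origin.tolist(), "spacing": self.spacing,
                "shape": list(self.shape)}

    # -- I/O ----------------------------------------------------------------

    def save(self, path) -> None:
        path = str(path)
        if path.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            affine = np.eye(4)
            affine[:3, :3] = np.eye(3) * self.spacing
            affine[:3, 3] = self.origin + 0.5 * self.spacing
            nib.save(nib.Nifti1Image(self.data.astype(np.uint8), affine), path)
        elif path.endswith(".mha"):
            import SimpleITK as sitk

            img = sitk.GetImageFromArray(
                np.ascontiguousarray(self.data.astype(np.uint8).transpose(2, 1, 0))
            )
            img.SetSpacing((self.spacing,) * 3)
            img.SetOrigin(tuple(self.origin + 0.5 * self.spacing))
            sitk.WriteImage(img, path)
        else:
            raise ValidationError(f"unsupported volume format: {path}")

    @classmethod
    def load(cls, path) -> "LabelVolume":
        path = str(path)
        if path.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            img = nib.load(path)
            spacing = float(img.affine[0, 0])
            origin = img.affine[:3, 3] - 0.5 * spacing
            return cls(origin=origin, spacing=spacing,
                       data=np.asarray(img.dataobj).astype(bool))
        if path.endswith(".mha"):
            import SimpleITK as sitk

            img = sitk.ReadImage(path)
            spacing = float(img.GetSpacing()[0])
            origin = np.array(img.GetOrigin()) - 0.5 * spacing
            data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(bool)
            return cls(origin=origin, spacing=spacing, data=data)
        raise ValidationError(f"unsupported volume format: {path}")


# ---------------------------------------------------------------------------
# centerline generation
# ---------------------------------------------------------------------------

@dataclass
class PhantomParams:
    """Geometry of the synthetic aorto-iliac phantom (mm / degrees).

    Defaults emulate the anatomy class of the physical benchmark: an
    aneurysmatic abdominal aorta (fusiform bulge on the trunk) bifurcating
    into two markedly tortuous iliac arteries, with the device inserted from
    one iliac access.
    """

    trunk_length: float = 120.0
    trunk_radius: float = 9.0
    aneurysm_amplitude: float = 9.0       # extra radius at bulge apex
    aneurysm_center_frac: float = 0.45    # bulge center, fraction of trunk length from inlet
    aneurysm_extent: float = 22.0         # Gaussian sigma of the bulge (mm)
    iliac_length: float = 160.0
    iliac_radius: float = 6.0
    branch_half_angle_deg: float = 25.0
    tortuosity_amplitude: float = 10.0    # lateral sinusoid amplitude (mm)
    tortuosity_wavelength: float = 100.0  # sinusoid wavelength (mm)
    point_spacing: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("trunk_length", "trunk_radius", "iliac_length",
                     "iliac_radius", "point_spacing", "aneurysm_extent",
                     "tortuosity_wavelength"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("aneurysm_amplitude", "tortuosity_amplitude"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 < self.branch_half_angle_deg < 90:
            raise ValidationError("branch_half_angle_deg must be in (0, 90)")


def _resample_count(length: float, spacing: float) -> int:
    return max(2, int(round(length / spacing)) + 1)


def make_bifurcated_centerline(params: PhantomParams) -> CenterlineTree:
    """Generate the aorto-iliac centerline tree.

    The trunk runs straight down the z-axis from the inlet at
    ``(0, 0, trunk_length)`` to the bifurcation at the origin, with a
    Gaussian radius bulge standing in for the aneurysm sac.  Each iliac
    leaves the bifurcation at ``branch_half_angle_deg`` from the trunk axis
    in the frontal plane and is perturbed by windowed sinusoids in two
    transverse directions (amplitude/wavelength configurable; zero amplitude
    gives a planar, straight-branch tree).  Deterministic for a fixed seed:
    the seed only draws the sinusoid phases.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    # trunk: inlet (cranial) -> bifurcation (origin), ordered along travel of flow
    n_t = _resample_count(params.trunk_length, params.point_spacing)
    s_t = np.linspace(0.0, params.trunk_length, n_t)
    trunk_pts = np.column_stack([np.zeros(n_t), np.zeros(n_t),
                                 params.trunk_length - s_t])
    s_c = params.aneurysm_center_frac * params.trunk_length
    trunk_radii = params.trunk_radius + params.aneurysm_amplitude * np.exp(
        -0.5 * ((s_t - s_c) / params.aneurysm_extent) ** 2
    )

    phi = np.deg2rad(params.branch_half_angle_deg)
    branches = {"trunk": Branch("trunk", trunk_pts, trunk_radii)}
    for name, side in (("left_iliac", -1.0), ("right_iliac", +1.0)):
        n_i = _resample_count(params.iliac_length, params.point_spacing)
        s = np.linspace(0.0, params.iliac_length, n_i)
        d = np.array([side * np.sin(phi), 0.0, -np.cos(phi)])
        pts = s[:, None] * d[None, :]
        if params.tortuosity_amplitude > 0:
            # transverse unit vectors: in-plane (frontal) and out-of-plane (sagittal)
            e1 = np.array([np.cos(phi) * side, 0.0, np.sin(phi)])
            e2 = np.array([0.0, 1.0, 0.0])
            window = np.sin(np.pi * s / params.iliac_length) ** 2
            ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
            a = params.tortuosity_amplitude
            w = 2 * np.pi / params.tortuosity_wavelength
            pts = (
                pts
                + (a * np.sin(w * s + ph1) * window)[:, None] * e1
                + (0.6 * a * np.sin(w * s * 1.4 + ph2) * window)[:, None] * e2
            )
        # blend from the trunk caliber at the root down to the iliac caliber
        blend = np.clip(s / (3 * params.iliac_radius), 0, 1)
        radii = trunk_radii[-1] + (params.iliac_radius - trunk_radii[-1]) * blend
        branches[name] = Branch(name, pts, radii, parent="trunk")

    return CenterlineTree(branches)


# ---------------------------------------------------------------------------
# surface sweep
# ---------------------------------------------------------------------------

def _transverse_frame(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Common junction frame from fixed global axes (Gram-Schmidt).

    Using projected +x / +y (rather than a tangent cross product) keeps the
    angular traversal direction of rings identical in space for branches
    whose tangents point in opposite z directions — required for the
    pair-of-pants junction strips to match geometrically.
    """
    ref1, ref2 = np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
    if abs(np.dot(ref1, tangent)) > 0.9:
        ref1, ref2 = np.array([0.0, 0.0, 1.0]), ref2
    e1 = ref1 - np.dot(ref1, tangent) * tangent
    e1 /= np.linalg.norm(e1)
    e2 = ref2 - np.dot(ref2, tangent) * tangent - np.dot(ref2, e1) * e1
    n = np.linalg.norm(e2)
    if n < 1e-9:  # tangent nearly parallel to ref2: fall back to cross product
        e2 = np.cross(tangent, e1)
    else:
        e2 = e2 / n
    return e1, e2


def _sweep_frames(points: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Rotation-minimizing frames along a polyline, seeded at its first point."""
    tans = np.gradient(points, axis=0)
    tans /= np.linalg.norm(tans, axis=1, keepdims=True)
    e1, e2 = _transverse_frame(tans[0])
    frames = [(e1, e2)]
    for i in range(1, len(points)):
        t_prev, t_new = tans[i - 1], tans[i]
        axis = np.cross(t_prev, t_new)
        s = np.linalg.norm(axis)
        c = np.clip(np.dot(t_prev, t_new), -1.0, 1.0)
        if s < 1e-12:
            frames.append(frames[-1])
            continue
        axis = axis / s
        ang = np.arctan2(s, c)
        rot = _axis_angle_matrix(axis, ang)
        frames.append((rot @ frames[-1][0], rot @ frames[-1][1]))
    return frames


def _axis_angle_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _ring_vertices(center, radius, e1, e2, n) -> np.ndarray:
    ang = 2 * np.pi * np.arange(n) / n
    return center + radius * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2)


def _ladder(poly_a: np.ndarray, poly_b: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate the strip between two equal-length vertex-id polylines."""
    faces = []
    for i in range(len(poly_a) - 1):
        a0, a1 = int(poly_a[i]), int(poly_a[i + 1])
        b0, b1 = int(poly_b[i]), int(poly_b[i + 1])
        faces.append((a0, b0, a1))
        faces.append((a1, b0, b1))
    return faces


def _ring_ladder(ring_a: np.ndarray, ring_b: np.ndarray) -> list[tuple[int, int, int]]:
    """Closed ladder between two rings (wraps around)."""
    return _ladder(np.append(ring_a, ring_a[0]), np.append(ring_b, ring_b[0]))


def _half_ring(ids: np.ndarray, n: int, which: str) -> np.ndarray:
    """Front-saddle(n/4) .. back-saddle(3n/4) through the right or left side."""
    q = n // 4
    if which == "right":  # decreasing index through 0 (the +x side)
        idx = np.concatenate([np.arange(q, -1, -1), np.arange(n - 1, 3 * q - 1, -1)])
    else:  # increasing index (the -x side)
        idx = np.arange(q, 3 * q + 1)
    return ids[idx]


def sweep_tube_surface(centerline: CenterlineTree,
                       circumferential_resolution: int = 16) -> VesselMesh:
    """Sweep the centerline tree into a triangulated lumen surface.

    Each branch is swept with rotation-minimizing frames; at the bifurcation
    the trunk's last ring is joined to the first ring of each iliac with a
    pair-of-pants triangulation (two outer half-strips, a saddle strip and
    two apex triangles), producing a surface that is watertight except for
    the open inlet/outlet rings.  All open-ring vertices become the Dirichlet
    set ``fixed_vertex_ids`` (the connector rings of the physical model).
    """
    n = int(circumferential_resolution)
    if n < 8:
        raise ValidationError("circumferential_resolution must be >= 8")
    n = 4 * ((n + 3) // 4)  # round up to a multiple of 4 so saddles fall on x=0

    for name, br in centerline.branches.items():
        prod = br.curvature() * br.radii  # pointwise kappa * r
        if np.any(prod >= 1.0):
            k = float(br.curvature()[np.argmax(prod)])
            raise GeometryError(
                f"branch {name!r}: centerline curvature radius "
                f"{1 / max(k, 1e-12):.1f} mm is below the local tube radius; "
                "the swept surface would self-intersect"
            )

    verts: list[np.ndarray] = []
    radii_per_vertex: list[float] = []
    faces: list[tuple[int, int, int]] = []
    rings: dict[str, np.ndarray] = {}

    def add_ring(center, radius, e1, e2) -> np.ndarray:
        start = len(verts)
        for p in _ring_vertices(center, radius, e1, e2, n):
            verts.append(p)
            radii_per_vertex.append(radius)
        return np.arange(start, start + n)

    def sweep_branch(points, radii, reverse_frames=False):
        """Rings along a branch; frames seeded at index 0 (junction side)."""
        pts = points[::-1] if reverse_frames else points
        rad = radii[::-1] if reverse_frames else radii
        frames = _sweep_frames(pts)
        ring_ids = [add_ring(pts[i], rad[i], *frames[i]) for i in range(len(pts))]
        return ring_ids[::-1] if reverse_frames else ring_ids

    is_bifurcated = {"left_iliac", "right_iliac"} <= set(centerline.names)

    if not is_bifurcated:
        # single-branch tube (used for straight/curved test vessels)
        for name, br in centerline.branches.items():
            ring_ids = sweep_branch(br.points, br.radii)
            for a, b in zip(ring_ids[:-1], ring_ids[1:]):
                faces.extend(_ring_ladder(a, b))
            rings["inlet"] = ring_ids[0]
            rings[f"{name}_outlet"] = ring_ids[-1]
    else:
        trunk = centerline["trunk"]
        # trunk rings, frames seeded at the bifurcation end for junction alignment
        trunk_rings = sweep_branch(trunk.points, trunk.radii, reverse_frames=True)
        for a, b in zip(trunk_rings[:-1], trunk_rings[1:]):
            faces.extend(_ring_ladder(a, b))
        rings["inlet"] = trunk_rings[0]
        ring_T = trunk_rings[-1]

        r_trunk_end = trunk.radii[-1]
        first_rings = {}
        for name in ("left_iliac", "right_iliac"):
            br = centerline[name]
            arc = br.arc_length
            phi = np.arccos(np.clip(
                -(br.points[1] - br.points[0])[2]
                / np.linalg.norm(br.points[1] - br.points[0]), -1, 1))
            # push the first ring far enough from the apex that the two iliac
            # rings clear each other and the trunk ring
            offset = max(1.2 * r_trunk_end,
                         1.15 * br.radii[0] / max(np.sin(phi), 0.2))
            offset = min(offset, 0.4 * br.length)
            i0 = int(np.searchsorted(arc, offset))
            i0 = min(max(i0, 1), len(arc) - 2)
            ring_ids = sweep_branch(br.points[i0:], br.radii[i0:])
            for a, b in zip(ring_ids[:-1], ring_ids[1:]):
                faces.extend(_ring_ladder(a, b))
            rings[f"{name}_outlet"] = ring_ids[-1]
            first_rings[name] = ring_ids[0]

        L, R = first_rings["left_iliac"], first_rings["right_iliac"]
        q = n // 4
        # outer strips: trunk half-rings to the matching iliac outer half-rings
        faces.extend(_ladder(_half_ring(ring_T, n, "right"), _half_ring(R, n, "right")))
        faces.extend(_ladder(_half_ring(ring_T, n, "left"), _half_ring(L, n, "left")))
        # saddle strip between the facing (inner) iliac half-rings
        faces.extend(_ladder(_half_ring(R, n, "left"), _half_ring(L, n, "right")))
        # apex triangles closing the junction at the two saddle vertices
        faces.append((int(ring_T[q]), int(R[q]), int(L[q])))
        faces.append((int(ring_T[3 * q]), int(R[3 * q]), int(L[3 * q])))

    vertices = np.array(verts)
    tri = np.array(faces, dtype=np.int64)

    # consistent winding with outward normals
    tm = trimesh.Trimesh(vertices=vertices, faces=tri, process=False)
    trimesh.repair.fix_normals(tm)
    tri = np.asarray(tm.faces, dtype=np.int64)
    # orient outward: test one mid-tube face against its ring's radial direction
    first_branch = next(iter(centerline.branches.values()))
    probe_center = first_branch.points[len(first_branch.points) // 2]
    fc = vertices[tri].mean(axis=1)
    j = int(np.argmin(np.linalg.norm(fc - probe_center, axis=1)))
    normal = np.cross(vertices[tri[j, 1]] - vertices[tri[j, 0]],
                      vertices[tri[j, 2]] - vertices[tri[j, 0]])
    radial = fc[j] - probe_center
    radial -= np.dot(radial, first_branch.tangents()[len(first_branch.points) // 2]) \
        * first_branch.tangents()[len(first_branch.points) // 2]
    if np.dot(normal, radial) < 0:
        tri = tri[:, ::-1]

    fixed = np.unique(np.concatenate(list(rings.values())))
    mesh = VesselMesh(
        vertices=vertices.copy(),
        triangles=tri,
        reference_vertices=vertices.copy(),
        fixed_vertex_ids=fixed,
        rings=rings,
        local_radius=np.array(radii_per_vertex),
    )
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def _capped_trimesh(mesh: VesselMesh) -> trimesh.Trimesh:
    """Close the open rings with centroid fans so the lumen becomes watertight."""
    verts = [mesh.vertices]
    faces = [mesh.triangles]
    n_v = len(mesh.vertices)
    loops = mesh.boundary_loops()
    if not loops:
        return mesh.as_trimesh()
    # order each loop by walking its boundary edges
    bedges = mesh.boundary_edges()
    adj: dict[int, list[int]] = {}
    for a, b in bedges:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    for loop in loops:
        start = int(loop[0])
        ordered = [start]
        prev = None
        cur = start
        while True:
            nxts = [v for v in adj[cur] if v != prev]
            if not nxts:
                break
            prev, cur = cur, nxts[0]
            if cur == start:
                break
            ordered.append(cur)
        if len(ordered) < 3:
            raise GeometryError("open ring with fewer than 3 vertices cannot be capped")
        centroid = mesh.vertices[ordered].mean(axis=0)
        cid = n_v
        verts.append(centroid[None, :])
        n_v += 1
        ring_faces = [(ordered[i], ordered[(i + 1) % len(ordered)], cid)
                      for i in range(len(ordered))]
        faces.append(np.array(ring_faces, dtype=np.int64))
    tm = trimesh.Trimesh(vertices=np.vstack(verts),
                         faces=np.vstack(faces), process=False)
    trimesh.repair.fix_normals(tm)
    if not tm.is_watertight:
        raise GeometryError("mesh could not be capped into a watertight lumen")
    return tm


def voxelize_lumen(mesh: VesselMesh, spacing: float = 1.0,
                   origin: np.ndarray | None = None,
                   shape: tuple[int, int, int] | None = None) -> LabelVolume:
    """Binary label map of the lumen: voxel = 1 iff its center is inside the
    capped surface.

    The open rings are capped with centroid fans, then each axial slice of the
    closed surface is converted to planar polygons and voxel centers are
    classified with a vectorized point-in-polygon test.  ``origin``/``shape``
    may be supplied to force a shared grid across volumes.
    """
    if spacing <= 0:
        raise ValidationError("spacing must be > 0")
    tm = _capped_trimesh(mesh)

    if origin is None:
        lo = tm.bounds[0] - 2 * spacing
        origin = np.floor(lo / spacing) * spacing
    origin = np.asarray(origin, dtype=float)
    if shape is None:
        hi = tm.bounds[1] + 2 * spacing
        shape = tuple(int(np.ceil((hi[k] - origin[k]) / spacing)) for k in range(3))

    nx, ny, nz = shape
    data = np.zeros(shape, dtype=bool)
    xs = origin[0] + (np.arange(nx) + 0.5) * spacing
    ys = origin[1] + (np.arange(ny) + 0.5) * spacing
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    flat_x, flat_y = gx.ravel(), gy.ravel()

    z_lo, z_hi = tm.bounds[0][2], tm.bounds[1][2]
    eps = 1e-6 * spacing  # dodge sections that coincide exactly with caps
    for iz in range(nz):
        z = origin[2] + (iz + 0.5) * spacing + eps
        if z <= z_lo or z >= z_hi:
            continue
        section = tm.section(plane_origin=[0.0, 0.0, z], plane_normal=[0.0, 0.0, 1.0])
        if section is None:
            continue
        # z-normal slice: loops live in the x-y plane, use coordinates directly.
        # Lumen cross-sections are simple disjoint loops (no holes), so the
        # union of per-loop polygons is the slice interior.
        inside = np.zeros(len(flat_x), dtype=bool)
        for loop in section.discrete:
            if len(loop) < 3:
                continue
            poly = shapely.Polygon(loop[:, :2])
            if not poly.is_valid:
                poly = poly.buffer(0)
            inside |= shapely.contains_xy(poly, flat_x, flat_y)
        data[:, :, iz] = inside.reshape(nx, ny)

    return LabelVolume(origin=origin, spacing=float(spacing), data=data)
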