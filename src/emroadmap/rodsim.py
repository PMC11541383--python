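"""Quasi-static guidewire-in-vessel mechanics.

The stiff-guidewire + sensorized-catheter assembly is modeled as a discrete
elastic rod (bending energy; exact inextensibility via a unit-tangent
parameterization of the inserted portion) pushed through a compliant vessel.
The vessel wall combines a weak per-vertex elastic foundation (springs to
the reference position, a scaled E_eff * thickness * area / R^2), edge
springs along reference edge directions, and an isotropic neighbor-coupling
term that stands in for shell bending; rod-wall coupling is a one-sided
quadratic penalty on the signed distance of rod nodes outside the lumen
surface, with the equal-and-opposite reaction spread barycentrically onto
the nearest triangle.

Insertion is quasi-static: instead of an imposed pushing velocity, the rod
is advanced in arc-length increments through a straight introducer channel
at the access, and full equilibrium is solved at every increment.  A
configuration is accepted only if a step-displacement-based pseudo-kinetic
proxy stays below 5% of the internal energy — the quasi-static counterpart
of the kinetic/internal energy check used with explicit dynamics solvers.

Units: mm, N, N*mm (energy), N*mm^2 (bending stiffness EI), MPa (N/mm^2).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.sparse
import scipy.sparse.linalg
from scipy.spatial import cKDTree

from . import emtrack
from .errors import ConvergenceError, ValidationError
from .vesselgen import VesselMesh

logger = logging.getLogger(__name__)

__all__ = [
    "BendingStiffness",
    "RodState",
    "InsertionAngles",
    "DepthSchedule",
    "EquilibriumDiagnostics",
    "SimulationRecord",
    "MechanicsParams",
    "ANGLE_PRESETS",
    "estimate_bending_stiffness",
    "build_rod",
    "solve_equilibrium",
    "run_insertion",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BendingStiffness:
    """Equivalent flexural rigidity EI calibrated from a four-point bending test."""

    ei: float                     # N*mm^2
    source: str = "assembled_tool"  # or "stiff_guidewire"
    fit_slope: float = 0.0        # N/mm
    fit_r2: float = 1.0

    def __post_init__(self):
        if self.ei <= 0:
            raise ValidationError("EI must be > 0")
        if not 0.0 <= self.fit_r2 <= 1.0 + 1e-12:
            raise ValidationError("R^2 must lie in [0, 1]")


@dataclass
class RodState:
    """Discrete elastic rod: node chain from pushed (proximal) end to tip."""

    positions: np.ndarray        # (N, 3) mm; index -1 is the tip
    h: float                     # segment rest length, mm
    segment_ei: np.ndarray       # (N-1,) N*mm^2
    floppy_tip_length: float = 0.0
    inserted_length: float = 0.0
    insertion_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    fixed_mask: np.ndarray | None = None  # True = prescribed (extracorporeal)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.segment_ei = np.asarray(self.segment_ei, dtype=float)
        if np.any(self.segment_ei <= 0):
            raise ValidationError("per-segment EI must be > 0")
        if len(self.segment_ei) != len(self.positions) - 1:
            raise ValidationError("segment_ei must have N-1 entries")
        if self.fixed_mask is None:
            self.fixed_mask = np.ones(len(self.positions), dtype=bool)

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def total_length(self) -> float:
        return self.h * (self.n_nodes - 1)

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)

    def arc_from_tip(self) -> np.ndarray:
        """Rest arc length of each node measured from the tip (material coordinate)."""
        n = self.n_nodes
        return self.h * (n - 1 - np.arange(n))

    def max_segment_strain(self) -> float:
        return float(np.max(np.abs(self.segment_lengths() - self.h)) / self.h)

    def copy(self) -> "RodState":
        return RodState(
            positions=self.positions.copy(), h=self.h,
            segment_ei=self.segment_ei.copy(),
            floppy_tip_length=self.floppy_tip_length,
            inserted_length=self.inserted_length,
            insertion_dir=self.insertion_dir.copy(),
            fixed_mask=self.fixed_mask.copy(),
        )


@dataclass
class InsertionAngles:
    """Access attitude: frontal-plane (x-z) and sagittal-plane (y-z) angles, degrees."""

    theta_f: float
    theta_s: float
    bound: float = 60.0  # anatomical bound on either angle

    def __post_init__(self):
        if abs(self.theta_f) > self.bound or abs(self.theta_s) > self.bound:
            raise ValidationError(
                f"insertion angles ({self.theta_f}, {self.theta_s}) exceed "
                f"the anatomical bound of +/-{self.bound} deg"
            )

    def direction(self) -> np.ndarray:
        """Unit insertion direction: +z (cranial) tilted by the two plane angles."""
        d = np.array([np.tan(np.deg2rad(self.theta_f)),
                      np.tan(np.deg2rad(self.theta_s)), 1.0])
        return d / np.linalg.norm(d)

    def as_tuple(self) -> tuple[float, float]:
        return (self.theta_f, self.theta_s)


# named angle presets spanning plausible access attitudes in the two planes
ANGLE_PRESETS: dict[str, InsertionAngles] = {
    "alpha": InsertionAngles(4.0, 13.0),
    "beta": InsertionAngles(4.0, 38.0),
    "gamma": InsertionAngles(23.0, 30.0),
}


@dataclass
class DepthSchedule:
    """Named insertion depths (mm of inserted arc length), strictly increasing."""

    names: list[str]
    depths: list[float]

    def __post_init__(self):
        if len(self.names) != len(self.depths) or len(self.names) == 0:
            raise ValidationError("schedule needs >= 1 named depth")
        if not np.all(np.diff(self.depths) > 0):
            raise ValidationError("scheduled depths must be strictly increasing")

    @classmethod
    def two_position(cls, pos1: float, pos2: float) -> "DepthSchedule":
        return cls(names=["Pos1", "Pos2"], depths=[pos1, pos2])

    def items(self):
        return zip(self.names, self.depths)


@dataclass
class EquilibriumDiagnostics:
    """Audit trail of one quasi-static solve."""

    iterations: int
    gradient_norm: float
    energies: dict[str, float]
    pseudo_kinetic_ratio: float
    converged: bool
    energy_trace: list[float] = field(default_factory=list)

    @property
    def total_energy(self) -> float:
        return float(sum(self.energies.values()))


@dataclass
class InsertionStep:
    """Stored state at one scheduled depth."""

    name: str
    depth: float
    rod: RodState
    vessel: VesselMesh
    sensors: "emtrack.VirtualSensorSet"
    diagnostics: EquilibriumDiagnostics


@dataclass
class SimulationRecord:
    """One angle-parameterized insertion run at its scheduled depths."""

    label: str
    angles: InsertionAngles
    schedule: DepthSchedule
    steps: list[InsertionStep]
    valid: bool = True
    failure_reason: str | None = None

    def step(self, name: str) -> InsertionStep:
        for s in self.steps:
            if s.name == name:
                return s
        raise KeyError(f"no stored step named {name!r}")

    @property
    def step_names(self) -> list[str]:
        return [s.name for s in self.steps]

    # -- directory serialization -------------------------------------------

    def save(self, directory) -> None:
        """Write the record as a directory: JSON index, per-depth deformed
        PLY meshes, rod-node CSVs and virtual-sensor CSVs."""
        import json
        import os

        import pandas as pd

        os.makedirs(directory, exist_ok=True)
        index = {
            "label": self.label,
            "angles": {"theta_f": self.angles.theta_f,
                       "theta_s": self.angles.theta_s},
            "schedule": {"names": self.schedule.names,
                         "depths": self.schedule.depths},
            "valid": self.valid,
            "failure_reason": self.failure_reason,
            "steps": [],
        }
        if self.steps:
            ref = self.steps[0].vessel
            np.savetxt(os.path.join(directory, "reference_vertices.csv"),
                       ref.reference_vertices, delimiter=",")
            np.savetxt(os.path.join(directory, "triangles.csv"),
                       ref.triangles, fmt="%d", delimiter=",")
            index["rings"] = {k: np.asarray(v).tolist()
                              for k, v in ref.rings.items()}
            index["wall_thickness"] = ref.wall_thickness
        for s in self.steps:
            s.vessel.save(os.path.join(directory, f"{s.name}_vessel.ply"))
            pd.DataFrame(s.rod.positions, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
                os.path.join(directory, f"{s.name}_rod.csv"), index=False)
            pd.DataFrame(
                s.sensors.positions, columns=["x_mm", "y_mm", "z_mm"]
            ).assign(sensor=[1, 2, 3], offset_mm=list(s.sensors.offsets)).to_csv(
                os.path.join(directory, f"{s.name}_sensors.csv"), index=False)
            index["steps"].append({
                "name": s.name,
                "depth": s.depth,
                "rod_h": s.rod.h,
                "sensor_offsets": list(s.sensors.offsets),
                "diagnostics": {
                    "iterations": s.diagnostics.iterations,
                    "gradient_norm": s.diagnostics.gradient_norm,
                    "energies": s.diagnostics.energies,
                    "pseudo_kinetic_ratio": s.diagnostics.pseudo_kinetic_ratio,
                    "converged": s.diagnostics.converged,
                },
            })
        with open(os.path.join(directory, "index.json"), "w") as fh:
            json.dump(index, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, directory) -> "SimulationRecord":
        import json
        import os

        import pandas as pd
        import trimesh as _trimesh

        from .vesselgen import VesselMesh

        with open(os.path.join(directory, "index.json")) as fh:
            index = json.load(fh)
        angles = InsertionAngles(index["angles"]["theta_f"],
                                 index["angles"]["theta_s"])
        schedule = DepthSchedule(names=index["schedule"]["names"],
                                 depths=index["schedule"]["depths"])
        steps = []
        if index["steps"]:
            ref_v = np.loadtxt(os.path.join(directory, "reference_vertices.csv"),
                               delimiter=",")
            tri = np.loadtxt(os.path.join(directory, "triangles.csv"),
                             delimiter=",").astype(np.int64)
            rings = {k: np.asarray(v, dtype=np.int64)
                     for k, v in index.get("rings", {}).items()}
            fixed = (np.unique(np.concatenate(list(rings.values())))
                     if rings else np.empty(0, dtype=np.int64))
        for meta in index["steps"]:
            name = meta["name"]
            tm = _trimesh.load_mesh(os.path.join(directory, f"{name}_vessel.ply"),
                                    process=False)
            vessel = VesselMesh(
                vertices=np.asarray(tm.vertices, dtype=float),
                triangles=tri, reference_vertices=ref_v,
                wall_thickness=index.get("wall_thickness", 2.0),
                fixed_vertex_ids=fixed, rings=rings)
            rod_pos = pd.read_csv(
                os.path.join(directory, f"{name}_rod.csv")).to_numpy(float)
            h = meta["rod_h"]
            rod = RodState(positions=rod_pos, h=h,
                           segment_ei=np.ones(len(rod_pos) - 1),
                           inserted_length=meta["depth"])
            sens_df = pd.read_csv(os.path.join(directory, f"{name}_sensors.csv"))
            sensors = emtrack.VirtualSensorSet(
                step=name,
                positions=sens_df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
                offsets=tuple(meta["sensor_offsets"]))
            diag = meta["diagnostics"]
            steps.append(InsertionStep(
                name=name, depth=meta["depth"], rod=rod, vessel=vessel,
                sensors=sensors,
                diagnostics=EquilibriumDiagnostics(
                    iterations=diag["iterations"],
                    gradient_norm=diag["gradient_norm"],
                    energies=diag["energies"],
                    pseudo_kinetic_ratio=diag["pseudo_kinetic_ratio"],
                    converged=diag["converged"])))
        return cls(label=index["label"], angles=angles, schedule=schedule,
                   steps=steps, valid=index["valid"],
                   failure_reason=index["failure_reason"])


@dataclass
class MechanicsParams:
    """Mechanical configuration of the rod-vessel system.

    ``wall_e_eff`` is a free calibration parameter of the simplified
    foundation wall (it is not a measured material modulus); the default is
    chosen so that a stiff-guidewire insertion deforms the tortuous phantom
    by a few tens of millimetres, the clinically reported scale.
    """

    wall_e_eff: float = 0.05          # MPa, effective wall modulus
    wall_thickness: float = 2.0       # mm
    foundation_per_area: float | None = None  # N/mm^3 override; else E*t/R^2
    foundation_factor: float = 0.01   # scales the tie-to-reference springs;
    # small by default: the physical model hangs between its connector rings
    # and deforms mostly by global tube bending, which the (stronger)
    # membrane + neighbor coupling represents, not by local wall stretching
    membrane_factor: float = 1.0      # multiplier on edge-spring stiffness
    laplacian_factor: float = 4.0     # isotropic neighbor coupling vs k_edge
    contact_penalty: float = 60.0     # N/mm per rod node
    axial_stiffness: float = 300.0    # N (inextensibility penalty EA)
    friction_mu: float = 0.0          # only frictionless contact is implemented
    increment: float = 5.0            # mm of arc length per insertion step
    tol_energy: float = 2e-4          # relative energy change at convergence
    tol_window: int = 3               # consecutive below-tol iterations required
    max_outer: int = 250
    rod_maxiter: int = 300

    def __post_init__(self):
        if self.friction_mu != 0.0:
            raise ValidationError(
                "only frictionless contact (friction_mu = 0) is implemented"
            )
        for name in ("wall_e_eff", "wall_thickness", "contact_penalty",
                     "axial_stiffness", "increment"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")


# ---------------------------------------------------------------------------
# bending stiffness from four-point bending
# ---------------------------------------------------------------------------

def four_point_midspan_deflection(force: float, ei: float, support_span: float,
                                  load_span: float) -> float:
    """Euler-Bernoulli midspan deflection of a simply supported beam under
    four-point bending: total load F split at two points a = (L - l)/2 from
    the supports, delta = F a (3 L^2 - 4 a^2) / (48 EI)."""
    a = 0.5 * (support_span - load_span)
    return force * a * (3 * support_span**2 - 4 * a**2) / (48.0 * ei)


def estimate_bending_stiffness(force_displacement_records, support_span: float,
                               load_span: float, fit_fraction: float = 0.5,
                               source: str = "assembled_tool") -> BendingStiffness:
    """Calibrate EI from a four-point-bending force-deflection record.

    A least-squares line is fitted to the initial ``fit_fraction`` of the
    F-delta curve (by deflection) and its slope k = dF/d(delta) is converted
    to EI with the Euler-Bernoulli closed form above:
    EI = k * a * (3 L^2 - 4 a^2) / 48, with a = (L - l)/2.
    """
    rec = np.asarray(force_displacement_records, dtype=float)
    if rec.ndim != 2 or rec.shape[1] != 2 or len(rec) < 3:
        raise ValidationError("need >= 3 (force, displacement) records")
    if support_span <= 0 or load_span <= 0 or load_span >= support_span:
        raise ValidationError("need 0 < load_span < support_span")
    if not 0 < fit_fraction <= 1:
        raise ValidationError("fit_fraction must be in (0, 1]")
    force, disp = rec[:, 0], rec[:, 1]
    if np.any(np.diff(disp) <= 0):
        raise ValidationError("displacement record must be strictly increasing")
    cutoff = disp[0] + fit_fraction * (disp[-1] - disp[0])
    mask = disp <= cutoff + 1e-12
    if mask.sum() < 3:
        mask = np.zeros(len(disp), dtype=bool)
        mask[:3] = True
    slope, intercept = np.polyfit(disp[mask], force[mask], 1)
    if slope <= 0:
        raise ValidationError("non-positive fitted slope; record is not a bending curve")
    pred = slope * disp[mask] + intercept
    ss_res = float(np.sum((force[mask] - pred) ** 2))
    ss_tot = float(np.sum((force[mask] - force[mask].mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    a = 0.5 * (support_span - load_span)
    ei = slope * a * (3 * support_span**2 - 4 * a**2) / 48.0
    return BendingStiffness(ei=float(ei), source=source,
                            fit_slope=float(slope), fit_r2=r2)


# ---------------------------------------------------------------------------
# rod construction
# ---------------------------------------------------------------------------

def build_rod(total_length: float, h: float, stiffness: BendingStiffness,
              floppy_tip_length: float = 30.0,
              floppy_ei_factor: float = 0.01) -> RodState:
    """Discretize the tool into a straight rod with a compliant distal tip.

    The distal ``floppy_tip_length`` (mm) of segments has EI scaled by
    ``floppy_ei_factor``; the rest carries the calibrated EI.
    """
    if h >= total_length:
        raise ValidationError("segment length h must be < total_length")
    if not 0 <= floppy_tip_length < total_length:
        raise ValidationError("need 0 <= floppy_tip_length < total_length")
    if not 0 < floppy_ei_factor <= 1:
        raise ValidationError("floppy_ei_factor must be in (0, 1]")
    n_seg = int(round(total_length / h))
    positions = np.zeros((n_seg + 1, 3))
    positions[:, 2] = np.arange(n_seg + 1) * h
    ei = np.full(n_seg, stiffness.ei)
    n_floppy = int(np.ceil(floppy_tip_length / h)) if floppy_tip_length > 0 else 0
    if n_floppy:
        ei[n_seg - n_floppy:] *= floppy_ei_factor
    return RodState(positions=positions, h=h, segment_ei=ei,
                    floppy_tip_length=floppy_tip_length)


# ---------------------------------------------------------------------------
# wall model
# ---------------------------------------------------------------------------

class WallModel:
    """Linearized elastic-foundation + membrane wall on a reference mesh.

    Foundation: per-vertex spring to the reference position, stiffness
    k_i = kappa_i * A_i with kappa_i = E_eff * t / R_i^2 (or an explicit
    per-area override) and A_i the barycentric vertex area.  Membrane:
    linear springs along each reference edge, k_e = factor * E_eff * t *
    A_e / L0^2.  Fixed (connector-ring) vertices are eliminated from the
    system; the stiffness matrix is prefactorized once per vessel.
    """

    def __init__(self, vessel: VesselMesh, params: MechanicsParams):
        self.vessel = vessel
        ref = vessel.reference_vertices
        tri = vessel.triangles
        nv = len(ref)

        # barycentric vertex areas on the reference surface
        c = np.cross(ref[tri[:, 1]] - ref[tri[:, 0]], ref[tri[:, 2]] - ref[tri[:, 0]])
        f_area = 0.5 * np.linalg.norm(c, axis=1)
        v_area = np.zeros(nv)
        for k in range(3):
            np.add.at(v_area, tri[:, k], f_area / 3.0)

        if vessel.local_radius is not None:
            r_local = np.maximum(vessel.local_radius, 1e-6)
        else:
            # fallback for user-supplied meshes: mean tube radius ~ 2 V / A
            tm = vessel.as_trimesh(reference=True)
            r_est = max(2.0 * abs(tm.volume) / max(tm.area, 1e-9), 1.0)
            r_local = np.full(nv, r_est)

        if params.foundation_per_area is not None:
            kappa = np.full(nv, params.foundation_per_area)
        else:
            kappa = params.foundation_factor * params.wall_e_eff \
                * params.wall_thickness / r_local**2
        self.k_found = kappa * v_area  # N/mm per vertex

        # unique edges with adjacent-area weights
        e = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
        e = np.sort(e, axis=1)
        e_area = np.concatenate([f_area / 3.0] * 3)  # one third of each face per edge slot
        edges, inv = np.unique(e, axis=0, return_inverse=True)
        a_e = np.zeros(len(edges))
        np.add.at(a_e, inv, e_area)
        vec = ref[edges[:, 1]] - ref[edges[:, 0]]
        l0 = np.linalg.norm(vec, axis=1)
        ehat = vec / l0[:, None]
        self.k_edge = params.membrane_factor * params.wall_e_eff \
            * params.wall_thickness * a_e / l0**2 * l0  # N/mm  (=E t a_e / l0)
        # isotropic neighbor coupling (graph Laplacian): stands in for the
        # shell's bending stiffness, spreading point loads into segment-scale
        # deformation instead of local dimples
        self.k_lap = params.laplacian_factor * self.k_edge
        self.edges = edges
        self.ehat = ehat

        free = np.ones(nv, dtype=bool)
        free[vessel.fixed_vertex_ids] = False
        self.free = free
        self.nv = nv

        k = self._assemble()
        idx = np.repeat(np.flatnonzero(free) * 3, 3) + np.tile([0, 1, 2], free.sum())
        self.free_dof = idx
        kff = k[np.ix_(idx, idx)]
        self.solver = scipy.sparse.linalg.factorized(
            scipy.sparse.csc_matrix(kff))
        self._k = k

    def _assemble(self):
        nv = self.nv
        rows, cols, vals = [], [], []
        # foundation: isotropic diagonal blocks
        for d in range(3):
            rows.append(np.arange(nv) * 3 + d)
            cols.append(np.arange(nv) * 3 + d)
            vals.append(self.k_found)
        # membrane: k_e (e e^T) + k_lap I blocks per edge
        i, j = self.edges[:, 0], self.edges[:, 1]
        for a in range(3):
            for b in range(3):
                block = self.k_edge * self.ehat[:, a] * self.ehat[:, b]
                if a == b:
                    block = block + self.k_lap
                rows.extend([i * 3 + a, j * 3 + a, i * 3 + a, j * 3 + a])
                cols.extend([i * 3 + b, j * 3 + b, j * 3 + b, i * 3 + b])
                vals.extend([block, block, -block, -block])
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        return scipy.sparse.coo_matrix((vals, (rows, cols)),
                                       shape=(3 * nv, 3 * nv)).tocsr()

    def solve(self, load: np.ndarray) -> np.ndarray:
        """Displacement field (nv, 3) under a vertex load field (nv, 3)."""
        u = np.zeros(3 * self.nv)
        u[self.free_dof] = self.solver(load.ravel()[self.free_dof])
        return u.reshape(self.nv, 3)

    def energy(self, u: np.ndarray) -> tuple[float, float]:
        """(foundation, membrane) energies of a displacement field."""
        e_found = 0.5 * float(np.sum(self.k_found[:, None] * u**2))
        du = u[self.edges[:, 1]] - u[self.edges[:, 0]]
        stretch = np.einsum("ij,ij->i", du, self.ehat)
        e_mem = 0.5 * float(np.sum(self.k_edge * stretch**2))
        e_mem += 0.5 * float(np.sum(self.k_lap[:, None] * du**2))
        return e_found, e_mem


# ---------------------------------------------------------------------------
# contact queries
# ---------------------------------------------------------------------------

def _closest_point_triangles(p: np.ndarray, tri_pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest points on a batch of triangles, row-aligned with query points.

    ``p`` is (m, 3) (or (3,) broadcast), ``tri_pts`` is (m, 3, 3).  Returns
    (points (m, 3), barycentric (m, 3)).  Standard region-based projection
    (Ericson, Real-Time Collision Detection).
    """
    p = np.broadcast_to(np.atleast_2d(p), (len(tri_pts), 3))
    a, b, c = tri_pts[:, 0], tri_pts[:, 1], tri_pts[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    m = len(tri_pts)
    bary = np.zeros((m, 3))
    out = np.zeros((m, 3))
    done = np.zeros(m, dtype=bool)

    reg = (d1 <= 0) & (d2 <= 0)  # vertex a
    out[reg] = a[reg]
    bary[reg] = [1, 0, 0]
    done |= reg
    reg = (~done) & (d3 >= 0) & (d4 <= d3)  # vertex b
    out[reg] = b[reg]
    bary[reg] = [0, 1, 0]
    done |= reg
    reg = (~done) & (d6 >= 0) & (d5 <= d6)  # vertex c
    out[reg] = c[reg]
    bary[reg] = [0, 0, 1]
    done |= reg

    vc = d1 * d4 - d3 * d2
    reg = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    v = np.where(np.abs(d1 - d3) > 1e-30, d1 / (d1 - d3 + 1e-300), 0.0)
    out[reg] = a[reg] + v[reg, None] * ab[reg]
    bary[reg, 0] = 1 - v[reg]
    bary[reg, 1] = v[reg]
    done |= reg
    vb = d5 * d2 - d1 * d6
    reg = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    w = np.where(np.abs(d2 - d6) > 1e-30, d2 / (d2 - d6 + 1e-300), 0.0)
    out[reg] = a[reg] + w[reg, None] * ac[reg]
    bary[reg, 0] = 1 - w[reg]
    bary[reg, 2] = w[reg]
    done |= reg
    va = d3 * d6 - d5 * d4
    reg = (~done) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)  # edge bc
    w = (d4 - d3) / (d4 - d3 + (d5 - d6) + 1e-300)
    out[reg] = b[reg] + w[reg, None] * (c[reg] - b[reg])
    bary[reg, 1] = 1 - w[reg]
    bary[reg, 2] = w[reg]
    done |= reg

    inside = ~done
    denom = va + vb + vc
    v = vb / np.where(np.abs(denom) > 1e-30, denom, 1e-300)
    w = vc / np.where(np.abs(denom) > 1e-30, denom, 1e-300)
    out[inside] = a[inside] + v[inside, None] * ab[inside] + w[inside, None] * ac[inside]
    bary[inside, 0] = 1 - v[inside] - w[inside]
    bary[inside, 1] = v[inside]
    bary[inside, 2] = w[inside]
    return out, bary


class _ContactQuery:
    """Nearest-surface-point queries against the (deforming) vessel mesh."""

    def __init__(self, vessel: VesselMesh):
        self.tri = vessel.triangles
        nv = len(vessel.vertices)
        vertex_faces: list[list[int]] = [[] for _ in range(nv)]
        for f, t in enumerate(self.tri):
            for v in t:
                vertex_faces[int(v)].append(f)
        # padded (nv, max_deg) candidate-face table for vectorized queries
        max_deg = max(len(fs) for fs in vertex_faces)
        table = np.full((nv, max_deg), -1, dtype=int)
        for v, fs in enumerate(vertex_faces):
            table[v, :len(fs)] = fs
        self.face_table = table

    def query(self, points: np.ndarray, vertices: np.ndarray):
        """For each point: closest surface point, outward normal, face id, barycentric.

        Candidates are the faces incident to the 3 nearest mesh vertices plus
        the faces with the 8 nearest centroids — the latter catch long
        triangles (e.g. at the bifurcation junction) whose interior lies far
        from every vertex.
        """
        points = np.atleast_2d(points)
        tree = cKDTree(vertices)
        _, nearest = tree.query(points, k=min(3, len(vertices)))
        nearest = np.atleast_2d(nearest)
        centroids = vertices[self.tri].mean(axis=1)
        _, near_faces = cKDTree(centroids).query(
            points, k=min(8, len(centroids)))
        near_faces = np.atleast_2d(near_faces)
        # long faces (junction strips) can be closest while all their vertices
        # and centroid are far; there are few, so always consider them
        edge_len = np.linalg.norm(
            vertices[self.tri] - vertices[np.roll(self.tri, 1, axis=1)],
            axis=2).max(axis=1)
        big = np.flatnonzero(edge_len > max(3.0 * np.median(edge_len), 6.0))
        parts = [self.face_table[nearest].reshape(len(points), -1), near_faces]
        if len(big):
            parts.append(np.tile(big, (len(points), 1)))
        cand = np.hstack(parts)
        owner = np.repeat(np.arange(len(points)), cand.shape[1])
        flat = cand.ravel()
        keep = flat >= 0
        owner, flat = owner[keep], flat[keep]
        cp, bary = _closest_point_triangles(points[owner], vertices[self.tri[flat]])
        d2 = np.sum((cp - points[owner]) ** 2, axis=1)
        # per-point argmin over its candidate rows (rows are grouped by owner)
        best = np.full(len(points), -1, dtype=np.int64)
        order = np.lexsort((d2, owner))
        first = np.searchsorted(owner[order], np.arange(len(points)), side="left")
        best = order[first]
        q = cp[best]
        barys = bary[best]
        face_ids = flat[best]
        t = self.tri[face_ids]
        n = np.cross(vertices[t[:, 1]] - vertices[t[:, 0]],
                     vertices[t[:, 2]] - vertices[t[:, 0]])
        nrm = n / np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-300)
        return q, nrm, face_ids, barys


# ---------------------------------------------------------------------------
# rod energies
# ---------------------------------------------------------------------------

def _rod_elastic_energy_grad(x: np.ndarray, h: float, seg_ei: np.ndarray,
                             ea: float) -> tuple[float, np.ndarray]:
    """Bending + axial-penalty energy of the whole rod with analytic gradient."""
    e = np.diff(x, axis=0)
    le = np.linalg.norm(e, axis=1)
    u = e / le[:, None]
    grad = np.zeros_like(x)

    # axial penalty: sum 0.5 (EA/h) (l - h)^2
    f_ax = (ea / h) * (le - h)
    e_ax = 0.5 * float(np.sum(f_ax * (le - h)))
    grad[:-1] -= f_ax[:, None] * u
    grad[1:] += f_ax[:, None] * u

    # bending: at each interior node, k (1 - u_j . u_{j+1}), k = mean EI / h
    uj, uk = u[:-1], u[1:]
    cosang = np.einsum("ij,ij->i", uj, uk)
    k = 0.5 * (seg_ei[:-1] + seg_ei[1:]) / h
    e_bend = float(np.sum(k * (1.0 - cosang)))
    dce1 = (uk - cosang[:, None] * uj) / le[:-1, None]  # d(cos)/d e1
    dce2 = (uj - cosang[:, None] * uk) / le[1:, None]   # d(cos)/d e2
    g1 = -k[:, None] * dce1  # dE/d e1
    g2 = -k[:, None] * dce2
    grad[0:-2] -= g1
    grad[1:-1] += g1 - g2
    grad[2:] += g2
    return e_bend + e_ax, grad, {"bending": e_bend, "axial": e_ax}


def _free_chain(fixed_mask: np.ndarray) -> tuple[int, np.ndarray]:
    """Anchor index and free-node ids; free nodes must trail contiguously."""
    fidx = np.flatnonzero(~fixed_mask)
    if len(fidx) == 0:
        return len(fixed_mask) - 1, fidx
    if fidx[-1] != len(fixed_mask) - 1 or np.any(np.diff(fidx) != 1):
        raise ValidationError(
            "free rod nodes must form a contiguous block ending at the tip")
    if fidx[0] == 0:  # fully free rod: pin the proximal node as the anchor
        fidx = fidx[1:]
    return int(fidx[0]) - 1 if len(fidx) else 0, fidx


def _project_chain(x: np.ndarray, fixed_mask: np.ndarray, h: float) -> np.ndarray:
    """Rebuild the free suffix as an exactly inextensible chain (lengths = h)."""
    anchor_i, fidx = _free_chain(fixed_mask)
    if len(fidx) == 0:
        return x
    out = x.copy()
    prev = x[anchor_i]
    for i in fidx:
        t = x[i] - prev
        nt = np.linalg.norm(t)
        t = t / nt if nt > 1e-12 else np.array([0.0, 0.0, 1.0])
        prev = prev + h * t
        out[i] = prev
    return out


def _minimize_rod(rod: RodState, q, n, k_c: float,
                  maxiter: int) -> tuple[np.ndarray, float]:
    """Equilibrate the rod's free suffix against frozen contact planes.

    The free portion is parameterized by its segment unit tangents (exact
    inextensibility, no stiff axial penalty), which keeps the problem
    well-conditioned; positions follow by cumulative summation from the last
    prescribed node.
    """
    x0 = rod.positions
    anchor_i, fidx = _free_chain(rod.fixed_mask)
    m = len(fidx)
    if m == 0:
        return x0.copy(), 0.0
    h = rod.h
    ei = rod.segment_ei
    anchor = x0[anchor_i]
    seg_ids = np.arange(anchor_i, anchor_i + m)  # global segment per free segment
    kj = 0.5 * (ei[seg_ids[:-1]] + ei[seg_ids[1:]]) / h
    if anchor_i >= 1:
        prev_t = x0[anchor_i] - x0[anchor_i - 1]
        prev_t = prev_t / np.linalg.norm(prev_t)
        k0 = 0.5 * (ei[seg_ids[0] - 1] + ei[seg_ids[0]]) / h \
            if seg_ids[0] >= 1 else ei[seg_ids[0]] / h
    else:
        prev_t, k0 = None, 0.0
    qf = q[-m:] if len(q) > m else q
    nf = n[-m:] if len(n) > m else n
    k_arr = np.broadcast_to(np.asarray(k_c, dtype=float),
                            (len(qf),)) if np.ndim(k_c) == 0 else np.asarray(k_c)
    kf = k_arr[-m:] if len(k_arr) > m else k_arr

    def fun(vflat):
        v = vflat.reshape(m, 3)
        nv = np.linalg.norm(v, axis=1, keepdims=True)
        t = v / nv
        x = anchor + h * np.cumsum(t, axis=0)
        cosj = np.einsum("ij,ij->i", t[:-1], t[1:])
        e_b = float(np.sum(kj * (1.0 - cosj)))
        gt = np.zeros((m, 3))
        gt[:-1] -= kj[:, None] * t[1:]
        gt[1:] -= kj[:, None] * t[:-1]
        if prev_t is not None:
            e_b += k0 * (1.0 - float(prev_t @ t[0]))
            gt[0] -= k0 * prev_t
        g = np.einsum("ij,ij->i", x - qf, nf)
        act = g > 0
        e_c = 0.5 * float(np.sum(kf[act] * g[act] ** 2))
        f = np.zeros((m, 3))
        f[act] = (kf[act] * g[act])[:, None] * nf[act]
        gt += h * np.cumsum(f[::-1], axis=0)[::-1]
        gv = (gt - np.einsum("ij,ij->i", gt, t)[:, None] * t) / nv
        return e_b + e_c, gv.ravel()

    v0 = np.diff(np.vstack([anchor[None, :], x0[fidx]]), axis=0)
    norms = np.linalg.norm(v0, axis=1, keepdims=True)
    v0 = np.where(norms > 1e-12, v0 / np.maximum(norms, 1e-300),
                  np.array([0.0, 0.0, 1.0]))
    res = scipy.optimize.minimize(fun, v0.ravel(), jac=True, method="L-BFGS-B",
                                  options={"maxiter": maxiter, "ftol": 1e-14,
                                           "gtol": 1e-9})
    v = res.x.reshape(m, 3)
    t = v / np.linalg.norm(v, axis=1, keepdims=True)
    x = x0.copy()
    x[fidx] = anchor + h * np.cumsum(t, axis=0)
    return x, float(np.max(np.abs(res.jac))) if np.size(res.jac) else 0.0


# ---------------------------------------------------------------------------
# coupled equilibrium
# ---------------------------------------------------------------------------

def _total_energy(x, rod, vessel_ref, u, wall: WallModel, contact: _ContactQuery,
                  k_c: float, ea: float):
    """Total elastic energy with contact re-evaluated on the current surface."""
    e_rod, _, parts = _rod_elastic_energy_grad(x, rod.h, rod.segment_ei, ea)
    e_found, e_mem = wall.energy(u)
    free = ~rod.fixed_mask
    if free.sum():
        verts = vessel_ref + u
        q, n, _, _ = contact.query(x[free], verts)
        g = np.einsum("ij,ij->i", x[free] - q, n)
        e_c = 0.5 * k_c * float(np.sum(np.maximum(g, 0.0) ** 2))
        max_pen = float(np.max(g)) if len(g) else 0.0
    else:
        e_c, max_pen = 0.0, 0.0
    parts = {"bending": parts["bending"], "axial": parts["axial"],
             "wall_foundation": e_found, "wall_membrane": e_mem, "contact": e_c}
    return sum(parts.values()), parts, max_pen


def solve_equilibrium(rod: RodState, vessel: VesselMesh,
                      params: MechanicsParams | None = None,
                      wall: WallModel | None = None,
                      contact: _ContactQuery | None = None,
                      ) -> tuple[RodState, VesselMesh, EquilibriumDiagnostics]:
    """Quasi-static equilibrium of the rod-vessel system.

    Alternates rod equilibration (against frozen contact planes on the
    current deformed surface) with a linear wall solve under the barycentric
    contact reactions, damping each combined update so that total energy is
    non-increasing across accepted iterates.  Succeeds when the relative
    energy change falls below tolerance and the pseudo-kinetic ratio (step
    displacement proxy over internal energy) is below 5%.
    """
    params = params or MechanicsParams()
    if len(vessel.fixed_vertex_ids) == 0:
        raise ValidationError("vessel has no fixed vertices (connector rings)")
    wall = wall or WallModel(vessel, params)
    contact = contact or _ContactQuery(vessel)
    k_c, ea = params.contact_penalty, params.axial_stiffness

    x = _project_chain(rod.positions.copy(), rod.fixed_mask, rod.h)
    u = vessel.vertices - vessel.reference_vertices
    ref = vessel.reference_vertices
    free = ~rod.fixed_mask

    e_prev, parts, _ = _total_energy(x, rod, ref, u, wall, contact, k_c, ea)
    trace = [e_prev]
    grad_norm = np.inf
    ratio = np.inf
    converged = False
    it = 0

    def true_energy(xc, uc):
        return _total_energy(xc, rod, ref, uc, wall, contact, k_c, ea)

    def backtrack(x_old, u_old, x_cand, u_cand, e_old, project_rod):
        """Largest halving step along the block update that does not raise energy."""
        alpha = 1.0
        while alpha >= 1.0 / 64:
            xa = x_old + alpha * (x_cand - x_old)
            if project_rod:
                xa = _project_chain(xa, rod.fixed_mask, rod.h)
            ua = u_old + alpha * (u_cand - u_old)
            e_new, parts_new, pen = true_energy(xa, ua)
            if e_new <= e_old + 1e-10 * (1.0 + abs(e_old)):
                return xa, ua, e_new, parts_new, pen, True
            alpha *= 0.5
        e_new, parts_new, pen = true_energy(x_old, u_old)
        return x_old, u_old, e_new, parts_new, pen, False

    nfree_dof = len(wall.free_dof)
    dof_index = -np.ones(3 * wall.nv, dtype=int)
    dof_index[wall.free_dof] = np.arange(nfree_dof)
    # wall stiffness seen by each contacting rod node (N/mm along the normal),
    # refreshed after every wall solve and condensed into the rod block as a
    # series spring — the standard cure for slow stiff-contact/soft-wall
    # interface zigzagging
    k_wall_est: dict[int, float] = {}

    def rod_block(x_in, u_in, k_arr):
        verts = ref + u_in
        if free.sum():
            q, n, _, _ = contact.query(x_in[free], verts)
        else:
            q = n = np.zeros((0, 3))
        return _minimize_rod(
            RodState(positions=x_in, h=rod.h, segment_ei=rod.segment_ei,
                     floppy_tip_length=rod.floppy_tip_length,
                     inserted_length=rod.inserted_length,
                     insertion_dir=rod.insertion_dir, fixed_mask=rod.fixed_mask),
            q, n, k_arr, params.rod_maxiter)

    def wall_block(x_in, u_in):
        """Exact minimizer of the wall quadratic with contact linearized as
        g_i(u) = c_i + a_i^T u (Woodbury update on the prefactored K)."""
        if free.sum():
            q2, n2, faces2, barys2 = contact.query(x_in[free], ref + u_in)
            g = np.einsum("ij,ij->i", x_in[free] - q2, n2)
            act = np.flatnonzero(g > -0.25)  # include near-contact nodes
        else:
            act = np.zeros(0, dtype=int)
        if not len(act):
            return np.zeros_like(u_in)
        a_cols = np.zeros((nfree_dof, len(act)))
        c_vec = np.empty(len(act))
        u_flat = u_in.ravel()[wall.free_dof]
        for col, i in enumerate(act):
            tri_v = contact.tri[faces2[i]]
            for k in range(3):
                rows = dof_index[tri_v[k] * 3 + np.arange(3)]
                ok = rows >= 0
                a_cols[rows[ok], col] += -barys2[i, k] * n2[i][ok]
            c_vec[col] = g[i] - a_cols[:, col] @ u_flat
        y = np.column_stack([wall.solver(a_cols[:, j]) for j in range(len(act))])
        gmat = a_cols.T @ y
        comp = np.maximum(np.diag(gmat), 1e-12)  # mm/N compliance per contact
        for i, cmpl in zip(act, comp):
            k_wall_est[int(i)] = 1.0 / cmpl
        s = np.linalg.solve(np.eye(len(act)) + k_c * gmat, -k_c * gmat @ c_vec)
        u_free = -k_c * (y @ (c_vec + s))
        u_out = np.zeros(3 * wall.nv)
        u_out[wall.free_dof] = u_free
        return u_out.reshape(wall.nv, 3)

    for it in range(1, params.max_outer + 1):
        x_before, u_before, e_start = x, u, e_prev

        # accelerated pass: rod feels the condensed wall compliance
        k_arr = np.full(free.sum(), k_c)
        for i, kw in k_wall_est.items():
            if i < len(k_arr):
                k_arr[i] = k_c * kw / (k_c + kw)
        x_new, grad_norm = rod_block(x, u, k_arr)
        u_new = wall_block(x_new, u)
        e_end, parts_e, _ = true_energy(x_new, u_new)
        if e_end <= e_start + 1e-10 * (1.0 + abs(e_start)):
            x, u, e_prev, parts = x_new, u_new, e_end, parts_e
        else:
            # safe monotone fallback: exact blocks with backtracking
            x_ex, grad_norm = rod_block(x, u, np.full(free.sum(), k_c))
            x, _, e_prev, parts, _, _ = backtrack(x, u, x_ex, u, e_prev, True)
            u_ex = wall_block(x, u)
            _, u, e_prev, parts, _, _ = backtrack(x, u, x, u_ex, e_prev, False)

        step2 = float(np.sum((x - x_before) ** 2) + np.sum((u - u_before) ** 2))
        trace.append(e_prev)
        # pseudo-kinetic proxy: (1/2) k_ref ||step||^2 with k_ref = 1 N/mm
        ratio = 0.5 * step2 / max(e_prev, 1e-9)
        # robust stop: several consecutive iterations with a small relative
        # energy change (a single stalled iteration does not count) and the
        # 5% pseudo-kinetic acceptance satisfied
        w = params.tol_window
        if len(trace) > w and ratio < 0.05:
            recent = np.abs(np.diff(trace[-(w + 1):]))
            if np.all(recent <= params.tol_energy * (1.0 + abs(e_prev))):
                converged = True
                break

    diags = EquilibriumDiagnostics(
        iterations=it, gradient_norm=grad_norm, energies=parts,
        pseudo_kinetic_ratio=float(ratio), converged=converged,
        energy_trace=[float(t) for t in trace],
    )
    if not converged:
        raise ConvergenceError(
            f"no equilibrium within {params.max_outer} outer iterations "
            f"(pseudo-kinetic ratio {ratio:.3g})",
            energy_trace=diags.energy_trace, diagnostics=diags)
    _, _, max_pen = _total_energy(x, rod, ref, u, wall, contact, k_c, ea)
    if max_pen > params.wall_thickness:
        raise ConvergenceError(
            f"rod penetrates {max_pen:.2f} mm beyond the lumen surface, more "
            f"than the wall thickness {params.wall_thickness} mm",
            energy_trace=diags.energy_trace, diagnostics=diags)

    rod_out = rod.copy()
    rod_out.positions = x
    vessel_out = vessel.with_vertices(ref + u)
    return rod_out, vessel_out, diags


# ---------------------------------------------------------------------------
# incremental insertion
# ---------------------------------------------------------------------------

def _warm_start_positions(rod: RodState, access: np.ndarray, direction: np.ndarray,
                          new_length: float) -> tuple[np.ndarray, np.ndarray]:
    """Advance the rod along its own current path to a new inserted length.

    Material nodes are re-placed at their new arc coordinate along the
    previous centerline path (extrapolated past the old tip along the tip
    tangent); extracorporeal nodes are pinned on the introducer line.
    Returns (positions, fixed_mask).
    """
    a = rod.arc_from_tip()
    s_new = new_length - a  # arc coordinate past the access point (per node)
    fixed = s_new <= 1e-12
    pos = np.empty_like(rod.positions)
    pos[fixed] = access + s_new[fixed, None] * direction

    inside_old = rod.inserted_length - a > 1e-12
    if inside_old.sum() >= 1:
        path = np.vstack([access[None, :], rod.positions[inside_old]])
    else:
        path = access[None, :]
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1) if len(path) > 1 else np.array([])
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    tip_tan = (path[-1] - path[-2]) / max(np.linalg.norm(path[-1] - path[-2]), 1e-12) \
        if len(path) > 1 else direction
    for i in np.flatnonzero(~fixed):
        s = s_new[i]
        if s <= arc[-1]:
            pos[i] = np.array([np.interp(s, arc, path[:, d]) for d in range(3)])
        else:
            pos[i] = path[-1] + (s - arc[-1]) * tip_tan
    return pos, fixed


def run_insertion(vessel: VesselMesh, angles: InsertionAngles,
                  schedule: DepthSchedule, rod: RodState | None = None,
                  params: MechanicsParams | None = None,
                  access_ring: str = "left_iliac_outlet",
                  sensor_offsets=emtrack.DEFAULT_SENSOR_OFFSETS,
                  label: str = "") -> SimulationRecord:
    """Advance the rod into the vessel and record states at scheduled depths.

    The rod enters at the center of ``access_ring`` along the direction set
    by the two insertion-plane angles; its extracorporeal portion is pinned
    to that line (the straight introducer channel).  The inserted length
    grows in ``params.increment`` steps (plus exact stops at every scheduled
    depth), with a full equilibrium solve per increment.  Each stored step
    keeps the rod, the deformed vessel, the virtual sensors and the
    equilibrium diagnostics; every stored state satisfies the 5%
    pseudo-kinetic check by construction.
    """
    params = params or MechanicsParams()
    if rod is None:
        # default tool: stiff 0.035" steel-core guidewire + catheter assembly;
        # EI ~ E * pi d^4 / 64 for the core alone is already ~6e3 N*mm^2
        rod = build_rod(total_length=max(schedule.depths) + max(sensor_offsets) + 60.0,
                        h=3.0, stiffness=BendingStiffness(ei=6000.0))
    if max(schedule.depths) > rod.total_length:
        raise ValidationError(
            f"scheduled depth {max(schedule.depths)} mm exceeds rod length "
            f"{rod.total_length} mm")
    if access_ring not in vessel.rings:
        raise ValidationError(
            f"unknown access ring {access_ring!r}; available: {list(vessel.rings)}")

    access = vessel.reference_vertices[vessel.rings[access_ring]].mean(axis=0)
    direction = angles.direction()

    wall = WallModel(vessel, params)
    contact = _ContactQuery(vessel)

    depths = np.unique(np.concatenate([
        np.arange(params.increment, max(schedule.depths), params.increment),
        np.asarray(schedule.depths, dtype=float)]))
    scheduled = {float(d): n for n, d in zip(schedule.names, schedule.depths)}

    state = rod.copy()
    state.insertion_dir = direction
    state.positions, state.fixed_mask = _warm_start_positions(
        state, access, direction, 0.0)
    state.inserted_length = 0.0
    work_vessel = vessel.copy()
    steps: list[InsertionStep] = []

    for depth in depths:
        state.positions, state.fixed_mask = _warm_start_positions(
            state, access, direction, float(depth))
        state.inserted_length = float(depth)
        # keep the warm start inside the lumen: extrapolating past the old tip
        # can overshoot through the wall near bends and the bifurcation apex
        free_idx = np.flatnonzero(~state.fixed_mask)
        if len(free_idx):
            q, n, _, _ = contact.query(state.positions[free_idx],
                                       work_vessel.vertices)
            g = np.einsum("ij,ij->i", state.positions[free_idx] - q, n)
            out = g > 0
            state.positions[free_idx[out]] = q[out] - 0.5 * n[out]
        try:
            state, work_vessel, diags = solve_equilibrium(
                state, work_vessel, params, wall=wall, contact=contact)
        except ConvergenceError as err:
            record = SimulationRecord(
                label=label, angles=angles, schedule=schedule, steps=steps,
                valid=False,
                failure_reason=f"equilibrium failed at depth {depth:.1f} mm: {err}")
            err.partial_record = record
            raise
        for d, name in scheduled.items():
            if abs(d - depth) < 1e-9:
                sensors = emtrack.virtual_sensor_positions(
                    state, offsets=sensor_offsets, step=name)
                outside = [i + 1 for i, off in enumerate(sensor_offsets)
                           if off > depth]
                if outside:
                    # selection still weights all sensors equally, but an
                    # extracorporeal sensor carries no vessel information
                    logger.warning(
                        "step %s (depth %.0f mm): sensor(s) %s lie outside "
                        "the model", name, depth, outside)
                steps.append(InsertionStep(
                    name=name, depth=float(depth), rod=state.copy(),
                    vessel=work_vessel.copy(), sensors=sensors,
                    diagnostics=copy.deepcopy(diags)))

    return SimulationRecord(label=label, angles=angles, schedule=schedule,
                            steps=steps)
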