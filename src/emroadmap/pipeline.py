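"""End-to-end workflow: phantom -> database -> synthetic acquisition ->
best-fit selection -> accuracy evaluation.

The synthetic acquisition stands in for the intra-operative side of the
workflow: one database record is designated the "truth", its virtual sensor
positions are mapped into a physical (tracker) frame by a known rigid pose,
perturbed with Gaussian noise and handed to the selection step, which must
recover the generating record after registering the frames from fiducial
landmarks.  The evaluation step then scores the selected roadmap against the
truth deformation.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np

from . import emtrack, evaluation, rodsim, selection, vesselgen
from .config import RunConfig
from .errors import EmroadmapError

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "build_phantom", "derive_schedule",
           "synthesize_experiment", "run_pipeline", "generate_fixture",
           "fiducial_landmarks"]


@dataclass
class PipelineResult:
    """In-memory results of one pipeline run (artifacts also on disk)."""

    config: RunConfig
    phantom: vesselgen.VesselMesh
    centerline: vesselgen.CenterlineTree
    database: selection.SimulationDatabase
    readings: list[emtrack.SensorReading]          # image frame, registered
    registration: emtrack.RigidTransform
    selection: selection.SelectionResult
    evaluation: evaluation.EvaluationReport | None = None
    timings: dict[str, float] = field(default_factory=dict)


def build_phantom(cfg: RunConfig):
    """Centerline tree + swept surface from the phantom block."""
    p = cfg.phantom
    params = vesselgen.PhantomParams(
        trunk_length=p.trunk_length, trunk_radius=p.trunk_radius,
        aneurysm_amplitude=p.aneurysm_amplitude,
        aneurysm_center_frac=p.aneurysm_center_frac,
        aneurysm_extent=p.aneurysm_extent, iliac_length=p.iliac_length,
        iliac_radius=p.iliac_radius,
        branch_half_angle_deg=p.branch_half_angle_deg,
        tortuosity_amplitude=p.tortuosity_amplitude,
        tortuosity_wavelength=p.tortuosity_wavelength,
        point_spacing=p.point_spacing, seed=p.seed)
    tree = vesselgen.make_bifurcated_centerline(params)
    mesh = vesselgen.sweep_tube_surface(tree, p.circumferential_resolution)
    mesh.wall_thickness = cfg.mechanics.wall_thickness
    return tree, mesh


def derive_schedule(cfg: RunConfig,
                    tree: vesselgen.CenterlineTree) -> rodsim.DepthSchedule:
    """Scheduled depths: explicit, or derived from the phantom geometry
    (first stop just past the aortic bifurcation, final stop near full
    insertion of the trunk)."""
    if cfg.schedule.depths is not None:
        return rodsim.DepthSchedule(names=cfg.schedule.names,
                                    depths=cfg.schedule.depths)
    iliac = tree["left_iliac"].length
    trunk = tree["trunk"].length
    depths = [iliac + 10.0, iliac + trunk - 15.0][:len(cfg.schedule.names)]
    return rodsim.DepthSchedule(names=cfg.schedule.names, depths=depths)


def _mechanics(cfg: RunConfig) -> rodsim.MechanicsParams:
    m = cfg.mechanics
    return rodsim.MechanicsParams(
        wall_e_eff=m.wall_e_eff, wall_thickness=m.wall_thickness,
        contact_penalty=m.contact_penalty, increment=m.increment,
        tol_energy=m.tol_energy, max_outer=m.max_outer)


def _rod(cfg: RunConfig, schedule: rodsim.DepthSchedule) -> rodsim.RodState:
    t = cfg.tool
    total = max(schedule.depths) + max(t.sensor_offsets) + 60.0
    return rodsim.build_rod(total_length=total, h=t.h,
                            stiffness=rodsim.BendingStiffness(ei=t.ei),
                            floppy_tip_length=t.floppy_tip_length,
                            floppy_ei_factor=t.floppy_ei_factor)


def fiducial_landmarks(mesh: vesselgen.VesselMesh) -> np.ndarray:
    """Seven reproducible fiducials on the phantom's bounding box.

    Six box corners plus one asymmetric point (to break any residual
    symmetry), mimicking radiopaque markers fixed to the mounting box.
    """
    lo, hi = mesh.vertices.min(axis=0) - 20.0, mesh.vertices.max(axis=0) + 20.0
    c = lambda ix, iy, iz: np.array(
        [lo[0] if ix == 0 else hi[0], lo[1] if iy == 0 else hi[1],
         lo[2] if iz == 0 else hi[2]])
    pts = [c(0, 0, 0), c(1, 0, 0), c(0, 1, 0), c(0, 0, 1), c(1, 1, 0),
           c(1, 0, 1), (0.7 * lo + 0.3 * hi)]
    return np.array(pts)


def synthesize_experiment(cfg: RunConfig, db: selection.SimulationDatabase,
                          phantom: vesselgen.VesselMesh,
                          truth: rodsim.SimulationRecord | None = None,
                          noise_seed: int | None = None):
    """Physical-frame noisy readings from the truth record + registration.

    Returns (readings in image frame, registration transform, raw physical
    readings, truth record).
    """
    truth = truth or db.record(cfg.experiment.truth_label)
    t = cfg.experiment.transform
    pose = emtrack.RigidTransform.from_params(t.axis, t.angle_deg, t.translation)
    seed0 = cfg.noise.seed if noise_seed is None else noise_seed

    physical: list[emtrack.SensorReading] = []
    for k, step in enumerate(truth.steps):
        physical.extend(emtrack.synthesize_readings(
            step.sensors, noise_sigma=cfg.noise.sigma,
            seed=seed0 * 1000 + k, transform=pose))

    image_lm = fiducial_landmarks(phantom)
    physical_lm = pose.apply(image_lm)
    if cfg.noise.fiducial_sigma > 0:
        rng = np.random.default_rng(seed0 * 1000 + 999)
        physical_lm = physical_lm + rng.normal(
            0, cfg.noise.fiducial_sigma, physical_lm.shape)
    registration = emtrack.register_rigid(physical_lm, image_lm)
    readings = emtrack.transform_readings(physical, registration, frame="image")
    return readings, registration, physical, truth


def _voxelize_steps(record: rodsim.SimulationRecord, spacing: float,
                    origin, shape):
    return {s.name: (s.vessel,
                     vesselgen.voxelize_lumen(s.vessel, spacing,
                                              origin=origin, shape=shape))
            for s in record.steps}


def run_pipeline(cfg: RunConfig, outdir: str | None = None) -> PipelineResult:
    """Execute the full workflow, serializing every intermediate artifact.

    Raises on the first failing stage with a stage-named error; artifacts
    produced up to that point are kept on disk.
    """
    outdir = outdir or cfg.output.directory
    os.makedirs(outdir, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        logger.info("stage %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = time.perf_counter() - timings[name]
        logger.info("stage %s done in %.1f s", name, timings[name])

    try:
        stage("phantom")
        tree, mesh = build_phantom(cfg)
        mesh.save(os.path.join(outdir, "phantom.ply"))
        mesh.save(os.path.join(outdir, "phantom.stl"))
        schedule = derive_schedule(cfg, tree)
        # one shared grid large enough for deformed configurations
        spacing = cfg.evaluation.spacing
        lo = mesh.vertices.min(axis=0) - 15.0
        hi = mesh.vertices.max(axis=0) + 15.0
        origin = np.floor(lo / spacing) * spacing
        shape = tuple(int(np.ceil((hi[k] - origin[k]) / spacing))
                      for k in range(3))
        baseline_vol = vesselgen.voxelize_lumen(mesh, spacing,
                                                origin=origin, shape=shape)
        baseline_vol.save(os.path.join(outdir, "phantom_lumen.nii.gz"))
        cfg.to_yaml(os.path.join(outdir, "config.yaml"))
        done("phantom")
    except EmroadmapError as err:
        raise EmroadmapError(f"stage 'phantom' failed: {err}") from err

    try:
        stage("database")
        angle_map = {a.label: rodsim.InsertionAngles(a.theta_f, a.theta_s)
                     for a in cfg.angles}
        db = selection.build_database(
            mesh, angle_map, schedule, rod=_rod(cfg, schedule),
            params=_mechanics(cfg), sensor_offsets=cfg.tool.sensor_offsets)
        for rec in db.records:
            rec.save(os.path.join(outdir, "database", rec.label))
        done("database")
    except EmroadmapError as err:
        raise EmroadmapError(f"stage 'database' failed: {err}") from err

    try:
        stage("acquisition")
        readings, registration, physical, truth = synthesize_experiment(
            cfg, db, mesh)
        emtrack.save_readings(physical,
                              os.path.join(outdir, "readings_physical.csv"))
        emtrack.save_readings(readings,
                              os.path.join(outdir, "readings_image.csv"))
        lm = fiducial_landmarks(mesh)
        emtrack.save_landmarks([f"M{i+1}" for i in range(len(lm))], lm,
                               os.path.join(outdir, "landmarks_image.csv"))
        done("acquisition")
    except EmroadmapError as err:
        raise EmroadmapError(f"stage 'acquisition' failed: {err}") from err

    try:
        stage("selection")
        sel = selection.select_best_fit(db, readings)
        sel.to_json(os.path.join(outdir, "selection.json"))
        done("selection")
    except EmroadmapError as err:
        raise EmroadmapError(f"stage 'selection' failed: {err}") from err

    try:
        stage("evaluation")
        best = db.record(sel.best_label)
        predicted = _voxelize_steps(best, spacing, origin, shape)
        gt = _voxelize_steps(truth, spacing, origin, shape)
        sensors = {s.name: s.sensors.positions for s in truth.steps}
        report = evaluation.evaluate_roadmap(
            predicted, gt, (mesh, baseline_vol), sensors,
            sample_density=cfg.evaluation.sample_density,
            seed=cfg.noise.seed)
        report.to_json(os.path.join(outdir, "evaluation.json"))
        report.delta_ov_table().to_csv(
            os.path.join(outdir, "delta_ov_table.csv"))
        done("evaluation")
    except EmroadmapError as err:
        raise EmroadmapError(f"stage 'evaluation' failed: {err}") from err

    summary = {
        "best": sel.best_label,
        "truth": truth.label,
        "registration_fre_mm": registration.fre,
        "e_sensor_mm": json.loads(sel.to_json())["e_sensor_mm"],
        "avg_delta_ov": {pos: rep.average()
                         for pos, rep in report.overlap.items()},
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
    }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    return PipelineResult(config=cfg, phantom=mesh, centerline=tree,
                          database=db, readings=readings,
                          registration=registration, selection=sel,
                          evaluation=report, timings=timings)


def fixture_config(seed: int = 0) -> RunConfig:
    """Miniature configuration for fast end-to-end checks (< 30 s)."""
    cfg = RunConfig()
    cfg = cfg.model_copy(update={})
    cfg.phantom.trunk_length = 60.0
    cfg.phantom.trunk_radius = 7.0
    cfg.phantom.aneurysm_amplitude = 4.0
    cfg.phantom.aneurysm_extent = 12.0
    cfg.phantom.iliac_length = 50.0
    cfg.phantom.iliac_radius = 5.0
    cfg.phantom.tortuosity_amplitude = 6.0
    cfg.phantom.tortuosity_wavelength = 45.0
    cfg.phantom.point_spacing = 2.5
    cfg.phantom.circumferential_resolution = 12
    cfg.phantom.seed = seed
    cfg.tool.sensor_offsets = (5.0, 30.0, 55.0)
    cfg.tool.floppy_tip_length = 15.0
    cfg.schedule.names = ["Pos1"]
    cfg.evaluation.spacing = 1.5
    cfg.noise.seed = seed
    cfg.angles = cfg.angles[:1] + cfg.angles[2:]  # alpha and gamma
    cfg.experiment.truth_label = "gamma"
    cfg.output.directory = "runs/fixture"
    return cfg


def generate_fixture(seed: int = 0, outdir: str | None = None):
    """Deterministic miniature assets: coarse phantom, 2-record database,
    noisy readings and a selection — the whole workflow at toy scale."""
    cfg = fixture_config(seed)
    tree, mesh = build_phantom(cfg)
    schedule = derive_schedule(cfg, tree)
    angle_map = {a.label: rodsim.InsertionAngles(a.theta_f, a.theta_s)
                 for a in cfg.angles}
    db = selection.build_database(
        mesh, angle_map, schedule, rod=_rod(cfg, schedule),
        params=_mechanics(cfg), sensor_offsets=cfg.tool.sensor_offsets)
    readings, registration, physical, truth = synthesize_experiment(cfg, db, mesh)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        mesh.save(os.path.join(outdir, "phantom.ply"))
        for rec in db.records:
            rec.save(os.path.join(outdir, "database", rec.label))
        emtrack.save_readings(readings, os.path.join(outdir, "readings_image.csv"))
    return {"config": cfg, "tree": tree, "mesh": mesh, "schedule": schedule,
            "database": db, "readings": readings, "registration": registration,
            "truth": truth}
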