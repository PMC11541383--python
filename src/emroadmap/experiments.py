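"""Reference parameter-recovery experiment.

The central claim of the workflow is that the insertion simulation
minimizing the EM sensor position error is also the most accurate roadmap.
This module runs that experiment end-to-end at the package's reference
study conditions: build the default phantom and the three-preset insertion
database, synthesize noisy sensor readings from one record treated as the
experimental truth, select the best-fitting record over seeded noise
replicates, and score every record's roadmap accuracy against the truth
deformation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import emtrack, evaluation, rodsim, selection, vesselgen
from .config import RunConfig
from .pipeline import build_phantom, derive_schedule, _mechanics, _rod

__all__ = ["ReferenceStudy", "build_reference_study", "recovery_experiment"]


@dataclass
class ReferenceStudy:
    """Default phantom + three-preset database + shared evaluation grid."""

    config: RunConfig
    mesh: vesselgen.VesselMesh
    tree: vesselgen.CenterlineTree
    schedule: rodsim.DepthSchedule
    database: selection.SimulationDatabase
    baseline_volume: vesselgen.LabelVolume
    volumes: dict[str, dict[str, vesselgen.LabelVolume]]  # label -> step -> vol
    grid: tuple = ()


def build_reference_study(config: RunConfig | None = None) -> ReferenceStudy:
    """Build the reference phantom, database and shared-grid label volumes."""
    cfg = config or RunConfig()
    tree, mesh = build_phantom(cfg)
    schedule = derive_schedule(cfg, tree)
    angle_map = {a.label: rodsim.InsertionAngles(a.theta_f, a.theta_s)
                 for a in cfg.angles}
    db = selection.build_database(
        mesh, angle_map, schedule, rod=_rod(cfg, schedule),
        params=_mechanics(cfg), sensor_offsets=cfg.tool.sensor_offsets)

    spacing = cfg.evaluation.spacing
    lo = mesh.vertices.min(axis=0) - 20.0
    hi = mesh.vertices.max(axis=0) + 20.0
    origin = np.floor(lo / spacing) * spacing
    shape = tuple(int(np.ceil((hi[k] - origin[k]) / spacing)) for k in range(3))
    baseline = vesselgen.voxelize_lumen(mesh, spacing, origin=origin,
                                        shape=shape)
    volumes = {
        rec.label: {s.name: vesselgen.voxelize_lumen(s.vessel, spacing,
                                                     origin=origin, shape=shape)
                    for s in rec.steps}
        for rec in db.records}
    return ReferenceStudy(config=cfg, mesh=mesh, tree=tree, schedule=schedule,
                          database=db, baseline_volume=baseline,
                          volumes=volumes, grid=(origin, spacing, shape))


def _noiseless_readings(record: rodsim.SimulationRecord):
    out = []
    for s in record.steps:
        for i in range(3):
            out.append(emtrack.SensorReading(step=s.name, sensor=i + 1,
                                             position=s.sensors.positions[i],
                                             frame="image"))
    return out


def _noisy_readings(record: rodsim.SimulationRecord, sigma: float, seed: int):
    out = []
    for k, s in enumerate(record.steps):
        rs = emtrack.synthesize_readings(s.sensors, noise_sigma=sigma,
                                         seed=seed * 100 + k)
        for r in rs:
            r.frame = "image"
        out.extend(rs)
    return out


@dataclass
class RecoveryResult:
    """Outcome of the reference recovery experiment."""

    noiseless_self_error: dict[str, float]      # label -> mean e_sensor (mm)
    noiseless_selected: dict[str, str]          # label -> selected label
    replicate_hits: dict[str, int]              # label -> correct selections
    n_replicates: int
    noisy_selected_from_truth: str              # selection for the truth run
    truth_label: str
    most_deformed_region: str
    final_position: str
    delta_ov_by_record: dict[str, float]        # in the most-deformed region
    avg_delta_ov_selected: float                # across regions, final position
    ov_gt_by_region: dict[str, float]
    e_sensor_table: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def recovery_rate(self) -> float:
        total = self.n_replicates * len(self.replicate_hits)
        return sum(self.replicate_hits.values()) / total if total else 0.0


def recovery_experiment(study: ReferenceStudy, seed: int = 1,
                        n_replicates: int = 20,
                        sigma: float = 0.5) -> RecoveryResult:
    """Noiseless self-selection, seeded noisy recovery, and roadmap scoring.

    For every database record: its own noiseless virtual-sensor readings must
    select it with zero error; over ``n_replicates`` seeded noisy replicates
    the generating record should be re-selected.  The record designated as
    the experimental truth is then used as ground-truth deformation, and each
    record's regional overlap improvement (delta_OV) is computed on the
    shared voxel grid; the most-deformed region is the one with the lowest
    ground-truth overlap at the final scheduled position.
    """
    db = study.database
    cfg = study.config
    truth_label = cfg.experiment.truth_label
    truth = db.record(truth_label)

    noiseless_err = {}
    noiseless_sel = {}
    hits = {}
    for rec in db.records:
        res = selection.select_best_fit(db, _noiseless_readings(rec))
        noiseless_err[rec.label] = float(res.table.loc[rec.label, "mean"])
        noiseless_sel[rec.label] = res.best_label
        n_hit = 0
        for rep in range(n_replicates):
            rep_seed = (seed * 10_000 + rep * 37
                        + db.labels.index(rec.label) * 7919) % (2**31 - 1)
            noisy = _noisy_readings(rec, sigma, rep_seed)
            if selection.select_best_fit(db, noisy).best_label == rec.label:
                n_hit += 1
        hits[rec.label] = n_hit

    sel_noisy_result = selection.select_best_fit(
        db, _noisy_readings(truth, sigma, seed))
    sel_noisy = sel_noisy_result.best_label

    # roadmap accuracy of every record against the truth deformation
    final_pos = study.schedule.names[-1]
    gt = {s.name: (s.vessel, study.volumes[truth_label][s.name])
          for s in truth.steps}
    sensors = {s.name: s.sensors.positions for s in truth.steps}
    reports = {}
    for rec in db.records:
        predicted = {s.name: (s.vessel, study.volumes[rec.label][s.name])
                     for s in rec.steps}
        reports[rec.label] = evaluation.evaluate_roadmap(
            predicted, gt, (study.mesh, study.baseline_volume), sensors,
            sample_density=0.5, seed=seed)

    ov_gt = {reg: reports[truth_label].overlap[final_pos].per_region[reg]["ov_gt"]
             for reg in evaluation.REGIONS}
    valid = [r for r in evaluation.REGIONS if not np.isnan(ov_gt[r])]
    most_deformed = min(valid, key=lambda r: ov_gt[r])
    delta = {lbl: reports[lbl].overlap[final_pos].per_region[most_deformed][
        "delta_ov"] for lbl in db.labels}

    return RecoveryResult(
        noiseless_self_error=noiseless_err,
        noiseless_selected=noiseless_sel,
        replicate_hits=hits,
        n_replicates=n_replicates,
        noisy_selected_from_truth=sel_noisy,
        truth_label=truth_label,
        most_deformed_region=most_deformed,
        final_position=final_pos,
        delta_ov_by_record=delta,
        avg_delta_ov_selected=float(
            reports[sel_noisy].overlap[final_pos].average()),
        ov_gt_by_region={k: float(v) for k, v in ov_gt.items()},
        # per-record errors against the noisy truth acquisition
        e_sensor_table={lbl: {c: float(v) for c, v in row.items()}
                        for lbl, row in sel_noisy_result.table.iterrows()},
    )
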