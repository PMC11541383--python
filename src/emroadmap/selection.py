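"""Simulation database and best-EM-fit selection.

The navigation workflow precomputes a database of insertion simulations over
candidate insertion-angle pairs; intra-operatively, the simulation whose
virtual sensors best match the measured EM sensor positions (smallest mean
position error across the scheduled insertion steps) is selected as the
deformed roadmap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import emtrack, rodsim
from .errors import ValidationError
from .vesselgen import VesselMesh

logger = logging.getLogger(__name__)

__all__ = ["SimulationDatabase", "SelectionResult", "build_database",
           "select_best_fit", "ANGLE_PRESETS"]

ANGLE_PRESETS = rodsim.ANGLE_PRESETS


@dataclass
class SimulationDatabase:
    """Insertion runs over unique angle pairs, sharing phantom and schedule."""

    records: list[rodsim.SimulationRecord]
    phantom_hash: str
    schedule: rodsim.DepthSchedule
    failures: dict[str, str] = field(default_factory=dict)  # label -> reason

    def __post_init__(self):
        pairs = [r.angles.as_tuple() for r in self.records]
        if len(set(pairs)) != len(pairs):
            raise ValidationError("duplicate insertion-angle pairs in database")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def record(self, label: str) -> rodsim.SimulationRecord:
        for r in self.records:
            if r.label == label:
                return r
        raise KeyError(f"no record labelled {label!r}")


@dataclass
class SelectionResult:
    """Ranking of database records by mean sensor error across steps."""

    best_label: str
    table: pd.DataFrame  # index: record label; columns: step names + "mean" (mm)
    tie: bool = False

    def to_json(self, path=None) -> str:
        payload = {
            "best": self.best_label,
            "tie": self.tie,
            "e_sensor_mm": {
                lbl: {c: float(v) for c, v in row.items()}
                for lbl, row in self.table.iterrows()
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def build_database(vessel: VesselMesh, angle_list, schedule: rodsim.DepthSchedule,
                   rod: rodsim.RodState | None = None,
                   params: rodsim.MechanicsParams | None = None,
                   access_ring: str = "left_iliac_outlet",
                   sensor_offsets=emtrack.DEFAULT_SENSOR_OFFSETS,
                   ) -> SimulationDatabase:
    """Run one insertion simulation per angle pair and index the results.

    ``angle_list`` is a mapping label -> InsertionAngles (or an iterable of
    (label, angles) pairs).  A run that fails to reach equilibrium is excluded
    and logged rather than fatal, so one diverging angle does not invalidate
    the database; an empty surviving set is an error.
    """
    if isinstance(angle_list, dict):
        items = list(angle_list.items())
    else:
        items = list(angle_list)
    if not items:
        raise ValidationError("angle list is empty")
    pairs = [ang.as_tuple() for _, ang in items]
    if len(set(pairs)) != len(pairs):
        raise ValidationError("duplicate insertion-angle pairs in angle list")

    records = []
    failures: dict[str, str] = {}
    for label, angles in items:
        try:
            rec = rodsim.run_insertion(
                vessel, angles, schedule, rod=None if rod is None else rod.copy(),
                params=params, access_ring=access_ring,
                sensor_offsets=sensor_offsets, label=label)
            records.append(rec)
        except Exception as err:  # failures recorded, not fatal
            failures[label] = str(err)
            logger.warning("database run %s excluded: %s", label, err)
    if not records:
        raise ValidationError(
            f"no database run reached equilibrium; failures: {failures}")
    return SimulationDatabase(records=records, phantom_hash=vessel.content_hash(),
                              schedule=schedule, failures=failures)


def _group_readings(readings: list[emtrack.SensorReading]) -> dict[str, list]:
    by_step: dict[str, list] = {}
    for r in readings:
        by_step.setdefault(r.step, []).append(r)
    return by_step


def select_best_fit(db: SimulationDatabase,
                    readings: list[emtrack.SensorReading],
                    tie_tol: float = 1e-9) -> SelectionResult:
    """Select the simulation minimizing the mean sensor error.

    For every record and scheduled step the three-sensor mean position error
    is computed; records are ranked by the unweighted mean across steps, and
    the argmin is returned.  Ties within ``tie_tol`` (mm) go to the first
    record in database order, with the tie flag set.
    """
    by_step = _group_readings(readings)
    missing = [s for s in db.schedule.names if s not in by_step]
    if missing:
        raise ValidationError(f"readings missing for scheduled step(s): {missing}")

    rows = {}
    for rec in db.records:
        errs = {}
        for step_name in db.schedule.names:
            sensors = rec.step(step_name).sensors
            errs[step_name] = emtrack.sensor_error(by_step[step_name], sensors)
        errs["mean"] = float(np.mean([errs[s] for s in db.schedule.names]))
        rows[rec.label] = errs
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table.loc[db.labels]  # preserve database order

    means = table["mean"].to_numpy()
    best_i = int(np.argmin(means))
    tie = bool(np.any(np.abs(np.delete(means, best_i) - means[best_i]) < tie_tol))
    # ties resolve to the first record in database order
    best_i = int(np.flatnonzero(means <= means.min() + tie_tol)[0])
    return SelectionResult(best_label=db.labels[best_i], table=table, tie=tie)
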