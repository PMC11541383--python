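import numpy as np
import pytest

from emroadmap.vesselgen import (
    Branch,
    CenterlineTree,
    PhantomParams,
    make_bifurcated_centerline,
    sweep_tube_surface,
)


def straight_tube_tree(length=150.0, radius=10.0, spacing=2.0):
    n = int(length / spacing) + 1
    pts = np.column_stack([np.zeros(n), np.zeros(n), np.linspace(length, 0, n)])
    return CenterlineTree({"trunk": Branch("trunk", pts, np.full(n, radius))})


def curved_tube_tree(arc_radius=80.0, arc_deg=60.0, tube_radius=6.0,
                     spacing=2.0):
    """Circular-arc tube in the x-z plane, access end at the bottom."""
    arc = np.deg2rad(arc_deg)
    n = int(arc_radius * arc / spacing) + 1
    t = np.linspace(arc, 0.0, n)
    pts = np.column_stack([arc_radius * (1 - np.cos(t)), np.zeros(n),
                           arc_radius * np.sin(t)])
    return CenterlineTree({"trunk": Branch("trunk", pts,
                                           np.full(n, tube_radius))})


@pytest.fixture(scope="session")
def straight_tube():
    return sweep_tube_surface(straight_tube_tree(), 16)


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse bifurcated phantom for geometry tests (fast to build)."""
    params = PhantomParams(trunk_length=80.0, iliac_length=70.0,
                           point_spacing=2.5, seed=3)
    tree = make_bifurcated_centerline(params)
    return tree, sweep_tube_surface(tree, 16)


@pytest.fixture(scope="session")
def fixture_run():
    """Miniature end-to-end workflow: phantom, 2-record database, readings."""
    from emroadmap.pipeline import generate_fixture

    return generate_fixture(seed=0)


def readings_from_sensors(sensors, frame="image"):
    """Noise-free readings aligned with a record's virtual sensors."""
    from emroadmap.emtrack import SensorReading

    return [SensorReading(step=sensors.step, sensor=i + 1,
                          position=sensors.positions[i].copy(), frame=frame)
            for i in range(3)]
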