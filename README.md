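# emroadmap

Simulation-backed aortic roadmapping driven by electromagnetic (EM)
tracking, at desk scale.

## The problem

During endovascular aneurysm repair (EVAR), stiff guidewires deform the
aorta and iliac arteries, so the static pre-operative 3D model overlaid on
live imaging (the *roadmap*) no longer matches the intra-operative anatomy.
One way to correct it without extra imaging: precompute a database of
guidewire-insertion simulations over plausible insertion conditions, track
a few EM sensors on the tool intra-operatively, and select the simulation
whose virtual sensors best match the measured ones — that simulation's
deformed vessel becomes the updated roadmap. This package implements and
tests that workflow end-to-end on synthetic aorto-iliac phantoms: phantom
generation, quasi-static guidewire–vessel mechanics, EM-sensor
virtualization, best-fit selection, and roadmap accuracy metrics. It is
written for researchers in image-guided intervention and vascular
biomechanics who want a runnable, inspectable desk-scale counterpart of
the hardware workflow.

## The quantities at its core

For three sensors at arc offsets 0.5 / 10.5 / 17.5 cm from the tool tip,
the selection error between experimental and simulated sensor positions is

    e_sensor = (1/3) Σ_{i=1..3} || s_EXP,i − s_SIM,i ||     [mm]

computed per scheduled insertion depth and averaged; the database record
minimizing it is the *best EM-fitting simulation*. Roadmap accuracy is
measured per sensor-defined region (mid-planes between consecutive
sensors split the model into regions I/II/III) as normalized lumen-volume
overlaps on a common voxel grid,

    OV_P  = 100 · |V_P ∩ V_def|   / min(v_P, v_def)     (prediction vs truth)
    OV_GT = 100 · |V_und ∩ V_def| / min(v_und, v_def)   (baseline vs truth)
    Δ_OV  = OV_P − OV_GT                                 [percentage points]

plus symmetric Hausdorff surface-distance fields (u_GT, u_P, e_aorta).
Δ_OV is the improvement gained by navigating on the simulated deformed
roadmap instead of the undeformed baseline.

The mechanics replaces full explicit finite-element simulation with a
discrete elastic rod (exact inextensibility, floppy tip) pushed in
arc-length increments into a linearized elastic-surface vessel through
frictionless penalty contact; every stored state passes a quasi-static
acceptance check (pseudo-kinetic ratio < 5%). See `docs/methods.md`.

## Worked example

```python
from emroadmap import generate_fixture
from emroadmap.selection import select_best_fit

fx = generate_fixture(seed=0)          # coarse phantom, 2-record database,
res = select_best_fit(fx["database"],  # noisy readings from record "gamma"
                      fx["readings"])
print(res.table.round(3))
print("selected:", res.best_label, " truth:", fx["truth"].label)
```

prints

```
        Pos1   mean
alpha  5.249  5.249
gamma  0.513  0.513
selected: gamma  truth: gamma
```

The generating record is recovered: its mean sensor error (0.513 mm) sits
at the 0.5 mm noise floor, while the wrong insertion angle is ten times
worse. Scoring both records against the truth deformation
(`examples/evaluate_roadmap.py`) gives

```
record alpha: e_aorta (Hausdorff)   3.31 mm, avg delta_OV   -2.3 %
record gamma: e_aorta (Hausdorff)   0.00 mm, avg delta_OV    9.8 %
```

— the best EM-fitting simulation is also the most accurate roadmap, the
workflow's central claim. Each script in `examples/` demonstrates one
capability (phantom generation, stiffness calibration, insertion
simulation, selection, evaluation, full pipeline); a thin CLI
(`emroadmap pipeline|phantom|simulate|database|select|evaluate|fixture`)
wraps the same API for shell use.

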