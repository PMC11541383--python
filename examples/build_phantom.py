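"""Generate a synthetic aorto-iliac phantom and its lumen label map.

Builds the default anatomy — an aneurysmatic trunk bifurcating into two
tortuous iliacs — then sweeps the surface mesh and voxelizes the lumen.
"""

import numpy as np

from emroadmap import (
    PhantomParams,
    make_bifurcated_centerline,
    sweep_tube_surface,
    voxelize_lumen,
)

params = PhantomParams(seed=0)
tree = make_bifurcated_centerline(params)
mesh = sweep_tube_surface(tree, circumferential_resolution=16)
volume = voxelize_lumen(mesh, spacing=1.0)

print("branches:", ", ".join(
    f"{name} ({tree[name].length:.0f} mm)" for name in tree.names))
print(f"surface: {len(mesh.vertices)} vertices, {len(mesh.triangles)} "
      f"triangles, {len(mesh.boundary_loops())} open rings")
print(f"lumen:   {volume.count} voxels at {volume.spacing} mm "
      f"= {volume.volume_mm3 / 1000:.1f} mL")
print(f"fixed connector-ring vertices: {len(mesh.fixed_vertex_ids)}")

# the rings are where the physical model would be tied to its mounting box;
# the lumen volume (in mL) is the quantity the overlap metrics count voxels of
mesh.save("phantom.ply")
volume.save("phantom_lumen.nii.gz")
print("wrote phantom.ply and phantom_lumen.nii.gz")
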