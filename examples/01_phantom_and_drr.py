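"""Build a synthetic spine volume and compute a digitally reconstructed
radiograph (DRR) of it.

The phantom is a stylized 5-vertebra spine (ellipsoidal bodies, posterior
rings, pedicle struts) inside a soft-tissue torso; each vertebra carries
two analytic landmarks (body center, left pedicle center).
"""

import numpy as np

import spinereg as sr

volume, vertebrae = sr.make_phantom(n_vertebrae=5, seed=1)
print(f"volume: {volume.shape} voxels, spacing {volume.spacing} mm")
for v in vertebrae:
    print(f"  {v.label}: body center {np.round(v.body_center, 1)} mm, "
          f"{int(v.mask.sum())} mask voxels")

# an anterior-posterior cone-beam view (source ventral, detector dorsal)
g = sr.carm_geometry(0.0, detector_shape=(256, 256))
drr = sr.forward_project(volume, g)
print(f"\nDRR {drr.values.shape}: line integrals 0..{drr.values.max():.2f} "
      "(dimensionless attenuation-length; bone paths are the bright ~0.5-1 values)")

# the projected body center of the middle vertebra falls on the spine shadow
rc = sr.project_points(g, vertebrae[2].body_center)
print(f"projected {vertebrae[2].label} body center -> pixel (row, col) = {np.round(rc, 1)}")
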