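"""Local matrix stiffness around a strongly contracting spheroid.

Converts a simulated deformation field into a map of radial strain and
local tangent stiffness: near the inclusion the radial tension drives the
collagen deep into its strain-stiffening regime.
"""

import numpy as np

import spherotfm as sp
from spherotfm.piv import ProjectedField

params = sp.get_preset("collagen-1.2")
prof = sp.solve_contraction(2000.0, sp.SphericalDomain(r0=100.0), params)

# sample the field on a tile-like Cartesian grid
ax = np.arange(-800.0, 801.0, 20.0)
xx, yy = np.meshgrid(ax, ax)
pos = np.column_stack([xx.ravel(), yy.ravel()])
d = np.linalg.norm(pos, axis=1)
keep = d > 105.0
fieldp = ProjectedField(
    positions=pos[keep], d=d[keep],
    u_proj=prof.interp_u(d[keep]), passes=np.ones(keep.sum(), bool),
    r0=100.0, centroid=np.zeros(2), meta={"window": 20, "pixel_size": 1.0})

smap = sp.local_stiffness(sp.radial_strain(fieldp, delta=20.0), params)
k0 = sp.tangent_stiffness(0.0, params)
dd = np.linalg.norm(smap.positions, axis=1)
for lo, hi in [(110, 200), (200, 400), (400, 800)]:
    sel = np.isfinite(smap.stiffness) & (dd >= lo) & (dd < hi)
    print(f"r in [{lo:3d}, {hi:3d}] um: median strain {np.median(smap.strain[sel]):+.4f}, "
          f"median stiffness {np.median(smap.stiffness[sel]):8.1f} Pa "
          f"({np.median(smap.stiffness[sel]) / k0:5.1f}x the zero-strain value)")
print(f"\nzero-strain gel stiffness: {k0:.1f} Pa; the stiffened shell next to")
print("the spheroid exceeds it many-fold and decays with distance.")
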