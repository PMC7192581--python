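"""Build a pressure lookup table and invert a deformation measurement.

The normalized curve family y(x; P) collapses over inclusion sizes, so a
single table converts any measured (deformation, distance) pair into a
contractile pressure.  Here a reduced table is built and used to invert a
simulation the table has never seen.
"""

import numpy as np

import spherotfm as sp

table = sp.build_lookup("collagen-1.2", p_min=1.0, p_max=1000.0, n=30)
print(f"lookup: {len(table.pressures)} pressures from {table.p_min} to "
      f"{table.p_max} Pa, x grid {table.x[0]:.2f}..{table.x[-1]:.0f}")

# forward: expected deformation at 2 radii for 100 Pa
y = sp.deformation_from_pressure(table, 100.0, 2.0)
print(f"at 100 Pa a tile 2 radii out deforms by u/r0 = {y:.4f}")

# inverse: a fresh simulation at an off-grid pressure
prof = sp.solve_contraction(300.0, sp.SphericalDomain(), sp.get_preset("collagen-1.2"))
n = prof.normalized()
sel = (n.x > 1.1) & (n.x < 45)
inverted = sp.pressure_from_deformation(table, n.y[sel], n.x[sel])
print(f"median inverted pressure of a 300 Pa simulation: "
      f"{np.nanmedian(inverted):.1f} Pa")
print("out-of-range measurements return NaN rather than a clamped value:",
      sp.pressure_from_deformation(table, 0.0, 5.0))
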