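"""Local matrix strain and tangent stiffness maps from measured deformations.

Strain stiffening makes the matrix stiffness around a contracting spheroid
strongly heterogeneous: radially stretched regions near the surface can
stiffen more than 20-fold while circumferentially compressed fibers
buckle.  From a projected deformation field the local radial strain is
estimated by a finite difference along the outward radial direction,

    eps(r) = (u(r) - u(r + delta * e_r)) / delta

with ``delta`` defaulting to the PIV window size, and converted to a local
tangent stiffness k = d sigma / d eps of the semi-affine fiber model
evaluated at that strain.  With the inward-positive sign convention and
deformations decaying with distance this yields eps > 0 (radial tension)
around a contracting spheroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator

from .materials import MaterialParameters, tangent_stiffness
from .piv import ProjectedField

__all__ = ["StiffnessMap", "radial_strain", "local_stiffness"]


@dataclass
class StiffnessMap:
    """Radial strain and local tangent stiffness on the tile grid."""

    positions: np.ndarray     # (N, 2) µm
    strain: np.ndarray        # (N,) radial strain, NaN outside the field
    stiffness: np.ndarray     # (N,) Pa, NaN where strain undefined
    delta: float              # differentiation step, µm


def radial_strain(
    fieldp: ProjectedField,
    delta: float | None = None,
    positions: np.ndarray | None = None,
) -> StiffnessMap:
    """Radial strain map by finite differences of the projected deformation.

    The scattered per-tile projected deformations are linearly interpolated
    on the tile grid, then differenced along the outward radial unit vector
    with step ``delta`` (defaults to the PIV window size in µm).  Points
    where either end of the difference leaves the measured field are NaN.
    The ``stiffness`` entry of the returned map is filled by
    :func:`local_stiffness`.
    """
    if delta is None:
        delta = fieldp.meta.get("window", 40) * fieldp.meta.get("pixel_size", 1.0)
    if delta <= 0:
        raise ValueError("delta must be positive")
    good = fieldp.passes
    if good.sum() < 4:
        raise ValueError("not enough valid tiles to interpolate the field")
    interp = LinearNDInterpolator(fieldp.positions[good], fieldp.u_proj[good])
    pts = fieldp.positions if positions is None else np.asarray(positions, float)
    dvec = pts - fieldp.centroid[None, :]
    dist = np.linalg.norm(dvec, axis=1)
    e_r = dvec / np.maximum(dist, 1e-9)[:, None]
    u_here = interp(pts)
    u_out = interp(pts + delta * e_r)
    eps = (u_here - u_out) / delta
    return StiffnessMap(
        positions=pts,
        strain=eps,
        stiffness=np.full(len(pts), np.nan),
        delta=float(delta),
    )


def local_stiffness(
    strain_map: StiffnessMap,
    params: MaterialParameters,
) -> StiffnessMap:
    """Tangent stiffness k = d sigma/d eps at the measured radial strain.

    Under deep compression the affine uniaxial tangent is not meaningful
    (the buckled-fiber tension saturates while its axial projection keeps
    shrinking, so the raw derivative can cross zero); the map is floored at
    the buckled-plateau stiffness scale ``k0 * d0 / 5`` so reported values
    stay positive.  Around a contracting spheroid the radial strain is
    tensile and the floor is never active.
    """
    eps = strain_map.strain
    finite = np.isfinite(eps)
    if np.any(eps[finite] <= -1.0):
        raise ValueError("radial strain <= -1 (material inversion) in the map")
    k = np.full_like(eps, np.nan)
    if finite.any():
        floor = params.k0 * params.d0 / 5.0
        k[finite] = np.maximum(tangent_stiffness(eps[finite], params), floor)
    return StiffnessMap(
        positions=strain_map.positions,
        strain=eps,
        stiffness=k,
        delta=strain_map.delta,
    )
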