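"""Pressure-indexed family of normalized deformation curves and its inverse.

The scale invariance of the contracting-inclusion problem means a single
family of normalized curves y(x; P), with y = u/r0 and x the normalized
lab-frame distance, covers spheroids of every size.  The family is built by
sweeping simulations over a logarithmic pressure grid (150 pressures from
0.1 to 10,000 Pa by default), resampling each solution onto a common
logarithmic x grid.  Because y is strictly increasing in P at every fixed
x, the family inverts uniquely: a measured (u/r0, d/r0) tuple maps to a
best-fit pressure.  All interpolation is done in log-log space, where the
curves are close to power laws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .materials import MaterialParameters, get_preset
from .simulate import DeformationProfile, SphericalDomain, solve_contraction

__all__ = [
    "LookupTable",
    "build_lookup",
    "pressure_from_deformation",
    "deformation_from_pressure",
    "save_lookup",
    "load_lookup",
    "OUT_OF_RANGE",
]

FORMAT_VERSION = 1

#: sentinel for measurements outside the invertible range (never clamped)
OUT_OF_RANGE = float("nan")

#: common normalized-distance grid (log-spaced)
X_MIN, X_MAX, N_X = 1.05, 50.0, 120


@dataclass
class LookupTable:
    """Interpolable map between pressure and normalized deformation curves.

    ``y[i, j]`` is the normalized *static* deformation u/r0 of the
    equilibrium at ``pressures[i]``, observed at normalized lab-frame
    distance ``x[j]``.  ``y_acc`` is the corresponding *accumulated*
    deformation: the value a tile-based Eulerian measurement (incremental
    displacement fields summed at fixed positions) reports after a monotone
    quasi-static pressure ramp from zero.  The accumulated value exceeds
    the static one at large strain, because the tiles successively track
    material arriving from farther away; inverting accumulated
    measurements against the accumulated family removes that bias.
    """

    pressures: np.ndarray        # ascending (Pa)
    x: np.ndarray                # common normalized distance grid
    y: np.ndarray                # (n_pressures, n_x) static curves
    y_acc: np.ndarray | None = None  # (n_pressures, n_x) accumulated curves
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y_acc is not None:
            self.y_acc = np.asarray(self.y_acc, dtype=float)
            if self.y_acc.shape != self.y.shape:
                raise ValueError("y_acc shape does not match y")
        if self.y.shape != (len(self.pressures), len(self.x)):
            raise ValueError("y matrix shape does not match grids")
        if np.any(np.diff(self.pressures) <= 0):
            raise ValueError("pressure grid must be strictly ascending")

    @property
    def p_min(self) -> float:
        return float(self.pressures[0])

    @property
    def p_max(self) -> float:
        return float(self.pressures[-1])

    def curve(self, i: int):
        """Normalized curve at grid pressure index ``i`` as (x, y) arrays."""
        return self.x, self.y[i]

    def _log_y_at(self, x_norm: np.ndarray, accumulated: bool = False) -> np.ndarray:
        """log y interpolated at query x values, for every grid pressure.

        Returns an array of shape (n_pressures, n_query); queries outside
        the x grid give NaN columns.
        """
        x_norm = np.atleast_1d(np.asarray(x_norm, dtype=float))
        logx = np.log(self.x)
        if accumulated:
            if self.y_acc is None:
                raise ValueError("this table carries no accumulated curves")
            logY = np.log(self.y_acc)
        else:
            logY = np.log(self.y)
        q = np.log(x_norm)
        j = np.clip(np.searchsorted(logx, q) - 1, 0, len(logx) - 2)
        w = (q - logx[j]) / (logx[j + 1] - logx[j])
        out = logY[:, j] * (1.0 - w) + logY[:, j + 1] * w
        out[:, (x_norm < self.x[0]) | (x_norm > self.x[-1])] = np.nan
        return out


def build_lookup(
    params: MaterialParameters | str = "collagen-1.2",
    p_min: float = 0.1,
    p_max: float = 10000.0,
    n: int = 150,
    domain: SphericalDomain | None = None,
    x_grid: np.ndarray | None = None,
    progress: bool = False,
) -> LookupTable:
    """Sweep contraction simulations over a log-spaced pressure grid.

    Simulations are warm-started from the previous pressure (continuation),
    so the full 150-pressure default sweep is a desk-scale computation.
    Any non-converged pressure aborts the build with the offending value.
    """
    if isinstance(params, str):
        material_name = params
        params = get_preset(params)
    else:
        material_name = "custom"
    if not (0 < p_min < p_max):
        raise ValueError("need 0 < p_min < p_max")
    if n < 2:
        raise ValueError("need at least 2 grid pressures")
    domain = domain or SphericalDomain()
    pressures = np.geomspace(p_min, p_max, n)
    x = np.asarray(x_grid, dtype=float) if x_grid is not None else np.geomspace(
        X_MIN, X_MAX, N_X
    )
    Y = np.empty((n, len(x)))
    M = np.empty((n, len(x)))
    d_lab = x * domain.r0
    u_prev = None
    prof_prev = None
    for i, P in enumerate(pressures):
        try:
            prof = solve_contraction(P, domain, params, u_init=u_prev)
        except Exception as exc:
            raise RuntimeError(
                f"lookup build failed at grid pressure {P:.6g} Pa: {exc}"
            ) from exc
        u_prev = prof.u
        Y[i] = _resample(prof, x)
        if i == 0:
            # ramp integral from 0 to p_min: displacements are tiny there,
            # so the accumulated and static curves coincide
            M[0] = Y[0]
        else:
            M[i] = M[i - 1] + _acc_increment(prof_prev, prof, d_lab) / domain.r0
        prof_prev = prof
        if progress:
            print(f"  [{i + 1}/{n}] P = {P:.4g} Pa, u(r0) = {prof.u[0]:.3g} um")
    table = LookupTable(
        pressures=pressures,
        x=x,
        y=Y,
        y_acc=M,
        metadata={
            "material": material_name,
            "params": {"k0": params.k0, "d0": params.d0, "ds": params.ds,
                       "eps_s": params.eps_s},
            "domain": {"r0_um": domain.r0, "r_outer_um": domain.r_outer,
                       "n_nodes": domain.n_nodes, "spacing": domain.spacing},
            "format_version": FORMAT_VERSION,
        },
    )
    _check_monotone(table)
    return table


def _resample(profile: DeformationProfile, x: np.ndarray) -> np.ndarray:
    """Normalized curve of a profile on the common x grid (log-log interp)."""
    norm = profile.normalized()
    pos = norm.y > 0
    return np.exp(np.interp(np.log(x), np.log(norm.x[pos]), np.log(norm.y[pos])))


def _ref_position(profile: DeformationProfile, d_lab: np.ndarray) -> np.ndarray:
    """Reference radius X of the material at lab distance d: X - u(X) = d."""
    X = d_lab.copy()
    for _ in range(50):
        X_new = d_lab + profile.interp_u(X)
        if np.max(np.abs(X_new - X)) < 1e-9 * profile.r0:
            return X_new
        X = X_new
    return X


def _acc_increment(prof_a: DeformationProfile, prof_b: DeformationProfile,
                   d_lab: np.ndarray) -> np.ndarray:
    """Displacement increment a fixed lab-position observer sees from a to b.

    Trapezoidal rule: average of the Lagrangian increment of the particle
    at d in state a and of the particle at d in state b.
    """
    inc = 0.0
    for prof in (prof_a, prof_b):
        X = _ref_position(prof, d_lab)
        inc = inc + 0.5 * (prof_b.interp_u(X) - prof_a.interp_u(X))
    return inc


def _check_monotone(table: LookupTable) -> None:
    if np.any(np.diff(np.log(table.y), axis=0) <= 0):
        raise RuntimeError("lookup curves are not strictly increasing in pressure")
    if table.y_acc is not None and np.any(np.diff(np.log(table.y_acc), axis=0) <= 0):
        raise RuntimeError("accumulated curves are not strictly increasing in pressure")


def pressure_from_deformation(table: LookupTable, u_norm, x_norm,
                              accumulated: bool = False):
    """Invert the curve family: (u/r0, x/r0) -> pressure (Pa).

    With ``accumulated=True`` the inversion uses the accumulated curves,
    the right target for deformations obtained by summing incremental PIV
    fields at fixed tile positions.  Measurements outside the range spanned
    by the weakest/strongest curve at that distance return NaN
    (out-of-range flag), never a clamped value.  Accepts scalars or arrays
    (broadcast elementwise).
    """
    u_arr = np.atleast_1d(np.asarray(u_norm, dtype=float))
    x_arr = np.atleast_1d(np.asarray(x_norm, dtype=float))
    u_arr, x_arr = np.broadcast_arrays(u_arr, x_arr)
    if np.any(x_arr <= 1.0):
        raise ValueError("x_norm must be > 1 (outside the inclusion)")
    logY = table._log_y_at(x_arr.ravel(), accumulated=accumulated)  # (n_p, n_q)
    logP = np.log(table.pressures)
    out = np.full(x_arr.size, np.nan)
    u_flat = u_arr.ravel()
    for k in range(x_arr.size):
        col = logY[:, k]
        if not np.all(np.isfinite(col)) or u_flat[k] <= 0:
            continue
        lu = np.log(u_flat[k])
        if lu < col[0] or lu > col[-1]:
            continue  # out of range: leave NaN
        out[k] = np.exp(np.interp(lu, col, logP))
    out = out.reshape(u_arr.shape)
    if np.isscalar(u_norm) and np.isscalar(x_norm):
        return float(out.ravel()[0])
    return out


def deformation_from_pressure(table: LookupTable, pressure, x_norm):
    """Forward interpolation: pressure (Pa), x = d/r0 -> u/r0."""
    p_arr = np.atleast_1d(np.asarray(pressure, dtype=float))
    x_arr = np.atleast_1d(np.asarray(x_norm, dtype=float))
    p_arr, x_arr = np.broadcast_arrays(p_arr, x_arr)
    if np.any((p_arr < table.p_min) | (p_arr > table.p_max)):
        raise ValueError(
            f"pressure outside table grid [{table.p_min}, {table.p_max}] Pa"
        )
    if np.any(x_arr <= 1.0):
        raise ValueError("x_norm must be > 1")
    logY = table._log_y_at(x_arr.ravel())
    logP = np.log(table.pressures)
    lp = np.log(p_arr.ravel())
    i = np.clip(np.searchsorted(logP, lp) - 1, 0, len(logP) - 2)
    w = (lp - logP[i]) / (logP[i + 1] - logP[i])
    cols = np.arange(x_arr.size)
    out = np.exp(logY[i, cols] * (1.0 - w) + logY[i + 1, cols] * w)
    out = out.reshape(p_arr.shape)
    if np.isscalar(pressure) and np.isscalar(x_norm):
        return float(out.ravel()[0])
    return out


def save_lookup(table: LookupTable, path: str | Path) -> None:
    """Persist as a versioned JSON document (portable, diff-able)."""
    doc = {
        "format_version": FORMAT_VERSION,
        "metadata": table.metadata,
        "pressures_Pa": table.pressures.tolist(),
        "x_norm": table.x.tolist(),
        "y_norm": table.y.tolist(),
    }
    if table.y_acc is not None:
        doc["y_acc_norm"] = table.y_acc.tolist()
    Path(path).write_text(json.dumps(doc))


def load_lookup(path: str | Path) -> LookupTable:
    doc = json.loads(Path(path).read_text())
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"lookup file format version {version!r} not supported "
            f"(expected {FORMAT_VERSION})"
        )
    return LookupTable(
        pressures=np.array(doc["pressures_Pa"]),
        x=np.array(doc["x_norm"]),
        y=np.array(doc["y_norm"]),
        y_acc=(np.array(doc["y_acc_norm"]) if "y_acc_norm" in doc else None),
        metadata=doc.get("metadata", {}),
    )
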