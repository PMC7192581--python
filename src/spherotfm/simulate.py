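"""Equilibrium deformation of a contracting spherical inclusion.

A spheroid embedded in a large gel volume is modeled as a spherical
inclusion of radius ``r0`` that pulls on the surrounding matrix with a
uniform inbound surface pressure ``P``.  Because the solution of this
boundary-value problem is spherically symmetric, the full 3-D problem
reduces to a one-dimensional radial one: the unknown is the inward radial
displacement ``u(r)`` on ``[r0, r_outer]`` with ``u(r_outer) = 0``.

The matrix is the semi-affine fiber network of :mod:`spherotfm.materials`.
Within each radial element the deformation is the affine map with principal
stretches

    lam_r = 1 - du/dr      (radial)
    lam_t = 1 - u/r        (tangential, twice degenerate)

and the element energy density is the isotropic orientation average of the
fiber energy at fiber stretch ``sqrt(lam_r^2 c^2 + lam_t^2 (1 - c^2))``.

The contractile pressure acts on the *deformed* inclusion surface (a
follower load): the equilibrium minimizes total strain energy minus the
boundary work ``P * 4 pi / 3 * (r0^3 - (r0 - delta)^3)`` with
``delta = u(r0)``.  Under this convention equilibria exist for arbitrarily
large pressures (with a reference-surface dead load the problem loses
solutions once buckling lets the inclusion collapse), and the geometric
scale invariance ``P = P(delta / r0)`` holds identically.  The discrete
energy has a tridiagonal Hessian, so a damped Newton iteration converges in
a handful of steps; pressure-controlled solves are root-finds on the
surface displacement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import solve_banded

from .materials import (
    MaterialParameters,
    fiber_energy,
    fiber_stiffness,
    fiber_tension,
    _quad_directions,
)

__all__ = [
    "SphericalDomain",
    "DeformationProfile",
    "NormalizedProfile",
    "solve_contraction",
    "solve_displacement_controlled",
    "rescale_profile",
    "fit_powerlaw_slope",
    "strain_energy",
    "save_profile",
    "load_profile",
    "ConvergenceError",
]

#: quadrature directions used inside the solver
N_QUAD_SOLVER = 120

#: relative residual-force tolerance (fraction of the applied boundary force)
RESIDUAL_RTOL = 1e-10


class ConvergenceError(RuntimeError):
    """Raised when the Newton iteration fails; carries the residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class SphericalDomain:
    """Radial mesh: inclusion radius to outer (fixed) boundary, in µm."""

    r0: float = 100.0
    r_outer: float = 2.0e4  # 2 cm
    n_nodes: int = 200
    spacing: str = "log"

    def __post_init__(self) -> None:
        if not (0 < self.r0 < self.r_outer):
            raise ValueError("need 0 < r0 < r_outer")
        if self.n_nodes < 50:
            raise ValueError("n_nodes must be >= 50")
        if self.spacing not in ("log", "linear"):
            raise ValueError("spacing must be 'log' or 'linear'")

    def nodes(self) -> np.ndarray:
        if self.spacing == "log":
            return np.geomspace(self.r0, self.r_outer, self.n_nodes)
        return np.linspace(self.r0, self.r_outer, self.n_nodes)


@dataclass
class DeformationProfile:
    """Radial inward displacement u(r) at equilibrium for one pressure."""

    r: np.ndarray          # radial positions (µm, ascending)
    u: np.ndarray          # inward displacement magnitude (µm, >= 0)
    pressure: float        # inbound surface pressure (Pa)
    r0: float              # inclusion radius (µm)
    meta: dict = field(default_factory=dict)

    def normalized(self) -> "NormalizedProfile":
        """Size-free curve in lab (deformed) coordinates.

        ``x = (r - u(r)) / r0`` is the distance at which the displacement is
        observed after the contraction -- the quantity a tile-based
        measurement of the deformed gel reports -- and ``y = u / r0``.
        """
        return NormalizedProfile(
            x=(self.r - self.u) / self.r0, y=self.u / self.r0,
            pressure=self.pressure,
        )

    def interp_u(self, r) -> np.ndarray:
        """Displacement at arbitrary radii by log-log interpolation."""
        r = np.asarray(r, dtype=float)
        pos = self.u > 0
        if pos.sum() < 2:
            return np.zeros_like(r)
        # drop the clamped outer node(s) for log interpolation
        logu = np.interp(np.log(r), np.log(self.r[pos]), np.log(self.u[pos]))
        return np.exp(logu)


@dataclass
class NormalizedProfile:
    """Size-free profile: y = u/r0 against x = r/r0 (collapses across r0)."""

    x: np.ndarray
    y: np.ndarray
    pressure: float


# ----------------------------------------------------------------------
# element-level energetics


class _ElementModel:
    """Vectorized orientation-averaged energy density W(lam_r, lam_t)."""

    def __init__(self, params: MaterialParameters, n_quad: int = N_QUAD_SOLVER):
        self.params = params
        c, w = _quad_directions(n_quad)
        self.c2 = c * c
        self.s2 = 1.0 - self.c2
        self.w = w

    def _lam(self, lr, lt):
        # (n_el, n_quad) fiber stretch
        return np.sqrt(
            np.multiply.outer(lr * lr, self.c2) + np.multiply.outer(lt * lt, self.s2)
        )

    def energy(self, lr, lt):
        lam = self._lam(lr, lt)
        return fiber_energy(lam - 1.0, self.params) @ self.w

    def gradients(self, lr, lt):
        """Return (W, dW/dlr, dW/dlt, d2W/dlr2, d2W/dlt2, d2W/dlrdlt)."""
        lam = self._lam(lr, lt)
        eps = lam - 1.0
        wE = fiber_energy(eps, self.params)
        wT = fiber_tension(eps, self.params)
        wK = fiber_stiffness(eps, self.params)
        # d lam / d lam_r = lr c^2 / lam etc.
        gr = lr[:, None] * self.c2[None, :] / lam
        gt = lt[:, None] * self.s2[None, :] / lam
        # second derivatives of lam
        hrr = (self.c2[None, :] * (lt * lt)[:, None] * self.s2[None, :]) / lam**3
        htt = (self.s2[None, :] * (lr * lr)[:, None] * self.c2[None, :]) / lam**3
        hrt = -(lr * lt)[:, None] * self.c2[None, :] * self.s2[None, :] / lam**3
        W = wE @ self.w
        Wr = (wT * gr) @ self.w
        Wt = (wT * gt) @ self.w
        Wrr = (wK * gr * gr + wT * hrr) @ self.w
        Wtt = (wK * gt * gt + wT * htt) @ self.w
        Wrt = (wK * gr * gt + wT * hrt) @ self.w
        return W, Wr, Wt, Wrr, Wtt, Wrt


class _RadialSystem:
    """Discretized energy of the radial problem.

    Unknowns are the nodal inward displacements ``u[0..n-1]`` at radii
    ``r[0..n-1]``; the outer node ``u[n-1] = 0`` is held fixed (and, for the
    displacement-controlled variant, the inner node as well).
    """

    def __init__(self, domain: SphericalDomain, params: MaterialParameters,
                 n_quad: int = N_QUAD_SOLVER):
        self.domain = domain
        self.r = domain.nodes()
        self.h = np.diff(self.r)
        self.rm = 0.5 * (self.r[:-1] + self.r[1:])
        self.vol = (4.0 * np.pi / 3.0) * np.diff(self.r**3)
        self.model = _ElementModel(params, n_quad)
        self.area0 = 4.0 * np.pi * domain.r0**2

    def stretches(self, u):
        lr = 1.0 + (u[:-1] - u[1:]) / self.h          # = 1 - du/dr
        lt = 1.0 - 0.5 * (u[:-1] + u[1:]) / self.rm   # = 1 - u/r at midpoint
        return lr, lt

    def strain_energy(self, u) -> float:
        lr, lt = self.stretches(u)
        if np.any(lr <= 0) or np.any(lt <= 0):
            return np.inf
        return float(self.model.energy(lr, lt) @ self.vol)

    def grad_hess(self, u):
        """Gradient (n,) and tridiagonal Hessian bands of the strain energy."""
        lr, lt = self.stretches(u)
        _, Wr, Wt, Wrr, Wtt, Wrt = self.model.gradients(lr, lt)
        n = len(u)
        g = np.zeros(n)
        # d lam_r/d u_i = 1/h, d lam_r/d u_{i+1} = -1/h
        # d lam_t/d u_i = d lam_t/d u_{i+1} = -1/(2 rm)
        a = 1.0 / self.h
        q = -0.5 / self.rm
        gi = self.vol * (Wr * a + Wt * q)
        gj = self.vol * (-Wr * a + Wt * q)
        np.add.at(g, np.arange(n - 1), gi)
        np.add.at(g, np.arange(1, n), gj)
        # Hessian bands
        Hii = self.vol * (Wrr * a * a + 2 * Wrt * a * q + Wtt * q * q)
        Hjj = self.vol * (Wrr * a * a - 2 * Wrt * a * q + Wtt * q * q)
        Hij = self.vol * (-Wrr * a * a + Wtt * q * q)
        diag = np.zeros(n)
        np.add.at(diag, np.arange(n - 1), Hii)
        np.add.at(diag, np.arange(1, n), Hjj)
        off = Hij.copy()
        return g, diag, off

    def reaction_pressure(self, u) -> float:
        """Follower pressure balancing the matrix at surface displacement u[0].

        The reaction force dE_strain/du_0 divided by the *deformed* surface
        area 4 pi (r0 - u_0)^2.
        """
        g, _, _ = self.grad_hess(u)
        a_def = 4.0 * np.pi * (self.domain.r0 - u[0]) ** 2
        return float(g[0] / a_def)


def _interior_newton(system: _RadialSystem, u: np.ndarray,
                     max_iter: int = 60) -> tuple[np.ndarray, float]:
    """Damped Newton on the interior nodes with u[0] and u[-1] held fixed.

    Returns the solution and the achieved interior residual relative to the
    boundary reaction force.  Convergence targets ``RESIDUAL_RTOL`` of the
    reaction force; in double precision the volume-weighted assembly has a
    cancellation floor, so a stalled iteration is accepted once the residual
    is below 1e-6 of the reaction force (typically it reaches ~1e-9).
    """
    n = len(u)
    lo, hi = 1, n - 2  # free node range (contiguous)
    best = np.inf
    stall = 0
    for _ in range(max_iter):
        g, diag, off = system.grad_hess(u)
        f_ref = max(abs(g[0]), 1.0)
        res = np.max(np.abs(g[lo:hi + 1])) if hi >= lo else 0.0
        if res <= RESIDUAL_RTOL * f_ref:
            return u, res / f_ref
        if res < best * 0.5:
            best = res
            stall = 0
        else:
            stall += 1
            if stall >= 4 and res <= 1e-6 * f_ref:
                return u, res / f_ref
            if stall >= 8:
                break
        tau = 0.0
        ok = False
        for _damp in range(40):
            m = hi - lo + 1
            ab = np.zeros((3, m))
            ab[1] = diag[lo:hi + 1] + tau * (np.abs(diag[lo:hi + 1]) + 1e-30)
            sub = off[lo:hi]
            ab[0, 1:] = sub
            ab[2, :-1] = sub
            try:
                step = solve_banded((1, 1), ab, -g[lo:hi + 1])
            except np.linalg.LinAlgError:
                step = None
            if step is None or not np.all(np.isfinite(step)):
                tau = max(4 * tau, 1e-6)
                continue
            e0 = system.strain_energy(u)
            alpha = 1.0
            for _ls in range(30):
                trial = u.copy()
                trial[lo:hi + 1] += alpha * step
                e1 = system.strain_energy(trial)
                if e1 <= e0 + 1e-12 * abs(e0):
                    u = trial
                    ok = True
                    break
                alpha *= 0.5
            if ok:
                break
            tau = max(4 * tau, 1e-6)
        if not ok:
            raise ConvergenceError("Newton damping failed", residual=res)
    g, _, _ = system.grad_hess(u)
    f_ref = max(abs(g[0]), 1.0)
    res = np.max(np.abs(g[lo:hi + 1])) / f_ref
    if res > 1e-6:
        raise ConvergenceError(
            f"interior Newton stalled (relative residual {res:.3g})", residual=res
        )
    return u, res


def _solve_delta(system: _RadialSystem, delta: float,
                 u_init: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Solve with prescribed inward surface displacement ``delta`` (µm).

    Warm-starts from ``u_init`` when given; if the jump in surface
    displacement is too large for Newton, the path is bisected adaptively.
    """
    r = system.r
    r0 = system.domain.r0
    if delta == 0:
        return np.zeros_like(r), 0.0
    if u_init is None or u_init[0] == 0:
        u = delta * (r0 / r) ** 2
        u[-1] = 0.0
        u[0] = delta
        d_cur = None  # no known-good state yet
    else:
        u = u_init.copy()
        d_cur = u[0]
    targets = [delta]
    depth = 0
    res = 0.0
    while targets:
        d = targets[-1]
        trial = u.copy()
        if d_cur is not None:
            trial[1:-1] *= d / d_cur
        trial[0] = d
        try:
            u_new, res = _interior_newton(system, trial)
        except ConvergenceError:
            depth += 1
            if depth > 30:
                raise
            mid = 0.5 * ((d_cur or 0.0) + d)
            if u_init is None and d_cur is None:
                # start the path from a small, safely linear contraction
                mid = min(mid, 0.02 * r0)
            targets.append(mid)
            continue
        u = u_new
        d_cur = d
        targets.pop()
    return u, res


def _expand_bracket(system: _RadialSystem, pressure: float):
    """Find (d_lo, d_hi) with reaction(d_lo) < pressure <= reaction(d_hi)."""
    r0 = system.domain.r0
    d = 0.01 * r0
    u, _ = _solve_delta(system, d)
    p = system.reaction_pressure(u)
    if p >= pressure:
        return 0.0, 0.0, d, p, u
    while True:
        d_new = min(d * 1.6, 0.5 * (d + r0 * 0.999))
        if r0 - d_new < 1e-9 * r0:
            raise ConvergenceError(
                f"pressure {pressure} Pa would invert the material (delta -> r0)"
            )
        u_new, _ = _solve_delta(system, d_new, u)
        p_new = system.reaction_pressure(u_new)
        if p_new >= pressure:
            return d, p, d_new, p_new, u_new
        d, p, u = d_new, p_new, u_new


def solve_contraction(
    pressure: float,
    domain: SphericalDomain | None = None,
    params: MaterialParameters | None = None,
    u_init: np.ndarray | None = None,
    n_quad: int = N_QUAD_SOLVER,
) -> DeformationProfile:
    """Equilibrium displacement profile for an inbound surface pressure (Pa).

    The pressure acts as nominal traction on the reference inclusion surface;
    the outer boundary is held fixed.  Internally the solve is displacement-
    controlled (robust under severe strain stiffening): the surface
    displacement is found by a bracketed root-find on the reaction pressure,
    each step warm-starting a damped Newton solve of the interior nodes.
    """
    if pressure < 0:
        raise ValueError("pressure must be >= 0")
    domain = domain or SphericalDomain()
    if params is None:
        from .materials import get_preset

        params = get_preset("collagen-1.2")
    system = _RadialSystem(domain, params, n_quad)
    r = system.r
    if pressure == 0:
        return DeformationProfile(r=r, u=np.zeros_like(r), pressure=0.0,
                                  r0=domain.r0, meta={"residual": 0.0})
    if u_init is not None and u_init[0] > 0:
        u = np.asarray(u_init, dtype=float).copy()
        d = u[0]
        u, _ = _solve_delta(system, d, u)
        p = system.reaction_pressure(u)
        if p >= pressure:
            d_lo, p_lo, d_hi, p_hi, u_hi = 0.0, 0.0, d, p, u
        else:
            d_lo, p_lo = d, p
            d_hi, p_hi, u_hi = d, p, u
            while p_hi < pressure:
                d_lo, p_lo = d_hi, p_hi
                d_hi = min(d_hi * 1.6, 0.5 * (d_hi + domain.r0 * 0.999))
                u_hi, _ = _solve_delta(system, d_hi, u_hi)
                p_hi = system.reaction_pressure(u_hi)
    else:
        d_lo, p_lo, d_hi, p_hi, u_hi = _expand_bracket(system, pressure)
    # regula-falsi / secant iteration on log-pressure, warm-started
    u = u_hi
    d, p = d_hi, p_hi
    res = 0.0
    for _ in range(100):
        if abs(p - pressure) <= 1e-10 * pressure or (d_hi - d_lo) < 1e-14 * domain.r0:
            break
        if p_lo > 0:
            # log-log secant within the bracket (pressure-delta is near power law)
            t = (np.log(pressure) - np.log(p_lo)) / (np.log(p_hi) - np.log(p_lo))
            d_new = float(np.exp(np.log(d_lo) + t * (np.log(d_hi) - np.log(d_lo))))
        else:
            d_new = d_lo + (pressure - p_lo) / (p_hi - p_lo) * (d_hi - d_lo)
        # keep strictly inside the bracket
        span = d_hi - d_lo
        d_new = min(max(d_new, d_lo + 1e-3 * span), d_hi - 1e-3 * span)
        u, res = _solve_delta(system, d_new, u)
        p = system.reaction_pressure(u)
        d = d_new
        if p < pressure:
            d_lo, p_lo = d, p
        else:
            d_hi, p_hi = d, p
    if np.any(1.0 + (u[:-1] - u[1:]) / system.h <= 0):
        raise ConvergenceError("material inversion (lam_r <= 0) at this pressure")
    return DeformationProfile(
        r=r, u=u, pressure=float(pressure), r0=domain.r0,
        meta={"residual": float(res),
              "pressure_mismatch": float(abs(p - pressure) / pressure)},
    )


def solve_displacement_controlled(
    delta: float,
    domain: SphericalDomain | None = None,
    params: MaterialParameters | None = None,
    n_quad: int = N_QUAD_SOLVER,
) -> tuple[DeformationProfile, float]:
    """Equilibrium with a prescribed inward surface displacement ``delta`` (µm).

    Returns the profile and the conjugate surface pressure
    ``P = (dE/d delta) / (4 pi r0^2)``.
    """
    domain = domain or SphericalDomain()
    if params is None:
        from .materials import get_preset

        params = get_preset("collagen-1.2")
    if not (0 <= delta < domain.r0):
        raise ValueError("need 0 <= delta < r0")
    system = _RadialSystem(domain, params, n_quad)
    r = system.r
    if delta == 0:
        return (
            DeformationProfile(r=r, u=np.zeros_like(r), pressure=0.0,
                               r0=domain.r0, meta={"residual": 0.0}),
            0.0,
        )
    u, res = _solve_delta(system, delta)
    pressure = system.reaction_pressure(u)
    prof = DeformationProfile(r=r, u=u, pressure=pressure, r0=domain.r0,
                              meta={"residual": float(res),
                                    "controlled": "displacement"})
    return prof, pressure


def rescale_profile(profile: DeformationProfile, a: float) -> DeformationProfile:
    """Geometric rescaling U*(r) = a U(r/a), r0* = a r0; pressure unchanged.

    An equilibrium profile for inclusion radius ``r0`` maps onto the
    equilibrium for radius ``a r0`` at the same pressure.
    """
    if a <= 0:
        raise ValueError("scale factor must be positive")
    return DeformationProfile(
        r=a * profile.r,
        u=a * profile.u,
        pressure=profile.pressure,
        r0=a * profile.r0,
        meta=dict(profile.meta, rescaled_by=a),
    )


def strain_energy(profile: DeformationProfile, params: MaterialParameters,
                  n_quad: int = N_QUAD_SOLVER) -> float:
    """Total strain energy (Pa µm^3 = 1e-18 J) stored in a profile."""
    r, u = profile.r, profile.u
    h = np.diff(r)
    rm = 0.5 * (r[:-1] + r[1:])
    vol = (4.0 * np.pi / 3.0) * np.diff(r**3)
    lr = 1.0 + (u[:-1] - u[1:]) / h
    lt = 1.0 - 0.5 * (u[:-1] + u[1:]) / rm
    model = _ElementModel(params, n_quad)
    return float(model.energy(lr, lt) @ vol)


def fit_powerlaw_slope(profile: NormalizedProfile,
                       x_range: tuple[float, float]) -> float:
    """Least-squares slope of log y vs log x restricted to ``x_range``.

    This is the exponent of the deformation decay in a double-logarithmic
    plot (-2 for a linear material, flattening toward ~-0.2 under strong
    strain stiffening).
    """
    lo, hi = x_range
    mask = (profile.x >= lo) & (profile.x <= hi) & (profile.y > 0)
    if mask.sum() < 5:
        raise ValueError("need at least 5 samples inside x_range")
    slope = np.polyfit(np.log(profile.x[mask]), np.log(profile.y[mask]), 1)[0]
    return float(slope)


# ----------------------------------------------------------------------
# persistence: CSV (r_um, u_um) + JSON sidecar


def save_profile(profile: DeformationProfile, path: str | Path) -> None:
    """Write a profile as CSV (r_um, u_um) with a JSON metadata sidecar."""
    import pandas as pd

    path = Path(path)
    pd.DataFrame({"r_um": profile.r, "u_um": profile.u}).to_csv(
        path, index=False, float_format="%.12g"
    )
    sidecar = {
        "pressure_Pa": profile.pressure,
        "r0_um": profile.r0,
        "meta": {k: v for k, v in profile.meta.items() if _json_ok(v)},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_profile(path: str | Path) -> DeformationProfile:
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path)
    side = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return DeformationProfile(
        r=df["r_um"].to_numpy(),
        u=df["u_um"].to_numpy(),
        pressure=float(side["pressure_Pa"]),
        r0=float(side["r0_um"]),
        meta=side.get("meta", {}),
    )


def _json_ok(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
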