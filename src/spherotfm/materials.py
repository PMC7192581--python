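"""Semi-affine fiber material model for collagen networks.

Collagen and similar biopolymer gels respond to strain in three regimes:
individual fibers buckle under compression (exponentially suppressed
stiffness), respond linearly at small extension, and stiffen exponentially
beyond an onset strain.  The per-fiber stiffness is

    kappa(eps) = k0 * exp(eps / d0)            eps < 0        (buckling)
    kappa(eps) = k0                            0 <= eps <= eps_s
    kappa(eps) = k0 * exp((eps - eps_s) / ds)  eps > eps_s    (stiffening)

where ``k0`` is the linear fiber stiffness (Pa), ``d0`` the buckling decay
strain, ``ds`` the stiffening strain scale and ``eps_s`` the onset of
strain stiffening.  Bulk behavior arises by averaging an isotropic fiber
ensemble that deforms affinely with the surrounding continuum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "MaterialParameters",
    "get_preset",
    "load_material",
    "fiber_stiffness",
    "fiber_tension",
    "fiber_energy",
    "uniaxial_stress",
    "tangent_stiffness",
]

#: central finite-difference step used by :func:`tangent_stiffness`
FD_STEP = 1e-4

#: number of Gauss-Legendre directions for the orientation average
N_QUAD = 200


@dataclass(frozen=True)
class MaterialParameters:
    """Constitutive constants of the semi-affine fiber law.

    Parameters
    ----------
    k0
        Linear fiber stiffness (Pa).
    d0
        Buckling decay strain (dimensionless).
    ds
        Stiffening strain scale (dimensionless).
    eps_s
        Strain at the onset of stiffening (dimensionless).
    """

    k0: float
    d0: float
    ds: float
    eps_s: float

    def __post_init__(self) -> None:
        if not (self.k0 > 0 and self.d0 > 0 and self.ds > 0):
            raise ValueError("k0, d0 and ds must be positive")
        if self.eps_s < 0:
            raise ValueError("eps_s must be non-negative")


# Parameters for reconstituted collagen (1:1 rat tail / bovine skin mixture).
# Only the linear stiffness varies with concentration; the strain scales are
# shared across concentrations.
_PRESETS = {
    "collagen-0.6": MaterialParameters(k0=447.0, d0=0.0008, ds=0.033, eps_s=0.0075),
    "collagen-1.2": MaterialParameters(k0=1645.0, d0=0.0008, ds=0.033, eps_s=0.0075),
    "collagen-2.4": MaterialParameters(k0=5208.0, d0=0.0008, ds=0.033, eps_s=0.0075),
}


def get_preset(name: str) -> MaterialParameters:
    """Return a named collagen parameter preset.

    Available presets: ``collagen-0.6``, ``collagen-1.2``, ``collagen-2.4``
    (mg/ml collagen concentration).
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown material preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


def load_material(source: str | Path | dict) -> MaterialParameters:
    """Resolve a material from a preset name, a JSON/YAML file, or a dict.

    A file must contain the four keys ``k0``, ``d0``, ``ds``, ``eps_s``.
    """
    if isinstance(source, dict):
        return MaterialParameters(**{k: float(source[k]) for k in ("k0", "d0", "ds", "eps_s")})
    if isinstance(source, str) and source in _PRESETS:
        return _PRESETS[source]
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"material file or preset not found: {source}")
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return load_material(data)


def _check_finite(eps: np.ndarray) -> np.ndarray:
    eps = np.asarray(eps, dtype=float)
    if not np.all(np.isfinite(eps)):
        raise ValueError("strain must be finite")
    return eps


def fiber_stiffness(eps, params: MaterialParameters):
    """Per-fiber stiffness kappa(eps) in Pa (piecewise exponential law)."""
    eps = _check_finite(eps)
    k0, d0, ds, es = params.k0, params.d0, params.ds, params.eps_s
    out = np.where(
        eps < 0,
        k0 * np.exp(np.minimum(eps, 0.0) / d0),
        np.where(eps <= es, k0, k0 * np.exp((np.maximum(eps, es) - es) / ds)),
    )
    return out if out.ndim else float(out)


def fiber_tension(eps, params: MaterialParameters):
    """First antiderivative w'(eps) of the stiffness, with w'(0) = 0 (Pa).

    This is the tension-strain relation of a single fiber.
    """
    eps = _check_finite(eps)
    k0, d0, ds, es = params.k0, params.d0, params.ds, params.eps_s
    buck = k0 * d0 * (np.exp(np.minimum(eps, 0.0) / d0) - 1.0)
    lin = k0 * eps
    stif = k0 * es + k0 * ds * (np.exp((np.maximum(eps, es) - es) / ds) - 1.0)
    out = np.where(eps < 0, buck, np.where(eps <= es, lin, stif))
    return out if out.ndim else float(out)


def fiber_energy(eps, params: MaterialParameters):
    """Fiber strain-energy density w(eps) (Pa), with w(0) = w'(0) = 0.

    Closed-form double antiderivative of the piecewise stiffness; C1 across
    the branch joins and convex.
    """
    eps = _check_finite(eps)
    k0, d0, ds, es = params.k0, params.d0, params.ds, params.eps_s
    en = np.minimum(eps, 0.0)
    buck = k0 * (d0 * d0 * (np.exp(en / d0) - 1.0) - d0 * en)
    lin = 0.5 * k0 * eps * eps
    ep = np.maximum(eps, es)
    stif = (
        0.5 * k0 * es * es
        + k0 * es * (ep - es)
        + k0 * (ds * ds * (np.exp((ep - es) / ds) - 1.0) - ds * (ep - es))
    )
    out = np.where(eps < 0, buck, np.where(eps <= es, lin, stif))
    return out if out.ndim else float(out)


def _quad_directions(n: int = N_QUAD) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights for c = cos(theta) on [0, 1].

    By axial symmetry the average over the unit sphere of a function of the
    polar angle reduces to an integral over c with uniform measure.
    """
    x, w = np.polynomial.legendre.leggauss(n)
    c = 0.5 * (x + 1.0)
    w = 0.5 * w
    return c, w


def uniaxial_stress(eps, params: MaterialParameters, n_quad: int = N_QUAD):
    """Orientation-averaged uniaxial stress sigma(eps) (Pa).

    An isotropic ensemble of fibers is stretched affinely by
    ``diag(1 + eps, 1, 1)`` with no lateral strain (the configuration probed
    by a radial strain measurement in the matrix).  A fiber at polar angle
    theta from the stretch axis has stretch
    ``lam(c) = sqrt((1 + eps)^2 c^2 + 1 - c^2)`` with ``c = cos(theta)``, and
    the stress is the derivative of the ensemble-averaged fiber energy:

        sigma(eps) = < w'(lam - 1) * (1 + eps) c^2 / lam >

    averaged over the unit sphere.
    """
    eps = _check_finite(eps)
    scalar = eps.ndim == 0
    eps = np.atleast_1d(eps)
    if np.any(eps <= -1.0):
        raise ValueError("axial strain must be > -1")
    c, w = _quad_directions(n_quad)
    s = (1.0 + eps)[:, None]
    lam = np.sqrt(s * s * c[None, :] ** 2 + (1.0 - c[None, :] ** 2))
    tension = fiber_tension(lam - 1.0, params)
    integrand = tension * s * c[None, :] ** 2 / lam
    sigma = integrand @ w
    return float(sigma[0]) if scalar else sigma


def tangent_stiffness(eps, params: MaterialParameters, step: float = FD_STEP,
                      n_quad: int = N_QUAD):
    """Tangent stiffness k(eps) = d sigma / d eps by central finite difference.

    The step defaults to 1e-4, well below the strain scales of the fiber law
    branches while keeping truncation error negligible.
    """
    eps = np.atleast_1d(_check_finite(eps))
    scalar = np.isscalar(step) and eps.size == 1 and np.ndim(eps) == 1
    hi = uniaxial_stress(eps + step, params, n_quad=n_quad)
    lo = uniaxial_stress(eps - step, params, n_quad=n_quad)
    k = (np.atleast_1d(hi) - np.atleast_1d(lo)) / (2.0 * step)
    return float(k[0]) if eps.size == 1 else k
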