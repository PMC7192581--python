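"""Contractile pressure and total contractility from deformation fields.

Every tile that passes the angular filter and the distance cut contributes
one pressure estimate via lookup inversion of its normalized deformation;
the per-timestep summary is the *median* over in-range tiles, which is
robust to locally distorted near fields and PIV outliers.  Total
contractility follows from the effective spheroid radius:

    F = P * 4 pi r0^2,     r0 = sqrt(A_projected / pi)

Angular pressure profiles (72 bins of 5 degrees) quantify the directional
variability of the contraction, and per-tile deviation maps localize where
a measured field departs from the best-fit spherically symmetric one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lookup import LookupTable, pressure_from_deformation
from .piv import ProjectedField, SpheroidGeometry

__all__ = [
    "PressureField",
    "ContractilityRecord",
    "AngularPressureProfile",
    "infer_pressures",
    "contractility",
    "angular_pressures",
    "deviation_map",
    "time_series",
    "MIN_DISTANCE_FACTOR",
]

#: default far-field cut: tiles closer than this multiple of r0 are excluded
MIN_DISTANCE_FACTOR = 2.0

#: recommended cut for irregular (non-spherical) samples
MIN_DISTANCE_FACTOR_IRREGULAR = 4.0


@dataclass
class PressureField:
    """Per-tile best-fit pressures for one timestep."""

    pressures: np.ndarray     # (N,) Pa, NaN where out of range/ineligible
    in_range: np.ndarray      # (N,) bool
    eligible: np.ndarray      # (N,) bool: passed filters and distance cut
    median: float             # Pa (NaN if no usable tile)
    n_used: int

    @property
    def ok(self) -> bool:
        return np.isfinite(self.median) and self.n_used > 0


@dataclass
class ContractilityRecord:
    """Per-timestep summary of the force state of one spheroid."""

    time: float               # minutes from first frame
    pressure: float           # median contractile pressure, Pa
    r0: float                 # effective radius, µm
    force: float              # total contractility, N
    n_tiles: int              # tiles used for the median
    n_excluded: int           # eligible tiles whose lookup was out of range

    @property
    def force_uN(self) -> float:
        return self.force * 1e6


@dataclass
class AngularPressureProfile:
    """Median pressure in angular segments around the spheroid."""

    angles: np.ndarray        # bin centers, degrees in [-180, 180)
    pressures: np.ndarray     # per-bin median pressure, Pa (NaN if empty)
    counts: np.ndarray        # tiles per bin
    cov: float                # coefficient of variation over bins (std/mean)
    bin_width: float = 5.0


def infer_pressures(
    fieldp: ProjectedField,
    table: LookupTable,
    min_distance_factor: float = MIN_DISTANCE_FACTOR,
) -> PressureField:
    """Assign a best-fit pressure to every eligible tile; summarize by median.

    Tiles closer than ``min_distance_factor * r0`` to the spheroid center
    are excluded (near-field distortions from invading cells or
    non-spherical geometry).  Deformations outside the lookup range are
    flagged and excluded from the median, never clamped.
    """
    d_norm = fieldp.d_norm
    u_norm = fieldp.u_norm
    eligible = fieldp.passes & (d_norm >= min_distance_factor) & (d_norm > 1.0)
    pressures = np.full(len(d_norm), np.nan)
    if np.any(eligible):
        # accumulated PIV fields are inverted against the accumulated curves
        pressures[eligible] = pressure_from_deformation(
            table, u_norm[eligible], d_norm[eligible],
            accumulated=table.y_acc is not None,
        )
    in_range = np.isfinite(pressures)
    used = pressures[in_range]
    return PressureField(
        pressures=pressures,
        in_range=in_range,
        eligible=eligible,
        median=float(np.median(used)) if used.size else float("nan"),
        n_used=int(used.size),
    )


def contractility(pressure: float, geom: SpheroidGeometry | float) -> float:
    """Total contractile force F = P * 4 pi r0^2, in newtons.

    ``geom`` may be a segmented geometry or an effective radius in µm.
    """
    r0_um = geom.r0 if isinstance(geom, SpheroidGeometry) else float(geom)
    if r0_um <= 0:
        raise ValueError("effective radius must be positive")
    r0_m = r0_um * 1e-6
    return float(pressure * 4.0 * np.pi * r0_m**2)


def angular_pressures(
    fieldp: ProjectedField,
    table: LookupTable,
    bin_width: float = 5.0,
    min_distance_factor: float = MIN_DISTANCE_FACTOR,
) -> AngularPressureProfile:
    """Median pressure per angular segment (default 72 bins of 5 degrees).

    The coefficient of variation (std/mean over non-empty bins) quantifies
    the directional anisotropy of the contraction.
    """
    if not (0 < bin_width <= 360) or 360.0 % bin_width != 0:
        raise ValueError("bin_width must evenly divide 360 degrees")
    pf = infer_pressures(fieldp, table, min_distance_factor)
    dvec = fieldp.positions - fieldp.centroid[None, :]
    theta = np.degrees(np.arctan2(dvec[:, 1], dvec[:, 0]))  # [-180, 180)
    n_bins = int(360.0 / bin_width)
    edges = -180.0 + bin_width * np.arange(n_bins + 1)
    centers = edges[:-1] + bin_width / 2.0
    med = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    which = np.clip(((theta + 180.0) // bin_width).astype(int), 0, n_bins - 1)
    for b in range(n_bins):
        sel = (which == b) & pf.in_range
        counts[b] = sel.sum()
        if counts[b]:
            med[b] = np.median(pf.pressures[sel])
    good = np.isfinite(med)
    cov = float(np.std(med[good]) / np.mean(med[good])) if good.sum() > 1 else float("nan")
    return AngularPressureProfile(
        angles=centers, pressures=med, counts=counts, cov=cov, bin_width=bin_width
    )


def deviation_map(
    fieldp: ProjectedField,
    table: LookupTable,
    best_fit_pressure: float,
    min_distance_factor: float = 1.0,
) -> np.ndarray:
    """Per-tile relative deviation |P_tile - P_best| / P_best.

    Large values localize where the measured field departs from the
    spherically symmetric best fit (near-field distortions of irregular
    samples, or PIV noise at the rim of the field of view).
    """
    if best_fit_pressure == 0:
        raise ValueError("best-fit pressure must be nonzero")
    pf = infer_pressures(fieldp, table, min_distance_factor)
    return np.abs(pf.pressures - best_fit_pressure) / best_fit_pressure


def time_series(
    fields: list[ProjectedField],
    table: LookupTable,
    geom: SpheroidGeometry,
    times: np.ndarray | None = None,
    min_distance_factor: float = MIN_DISTANCE_FACTOR,
) -> list[ContractilityRecord]:
    """Per-timestep median pressure and contractility for a whole series."""
    records = []
    for t, fieldp in enumerate(fields):
        pf = infer_pressures(fieldp, table, min_distance_factor)
        P = pf.median
        records.append(
            ContractilityRecord(
                time=float(times[t]) if times is not None else float(t),
                pressure=P,
                r0=geom.r0,
                force=contractility(P, geom) if np.isfinite(P) else float("nan"),
                n_tiles=pf.n_used,
                n_excluded=int(pf.eligible.sum() - pf.n_used),
            )
        )
    return records
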