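"""Ground-truth synthetic data: bead scenes, spheroid disc, warped time-lapse.

Emulates the experimental imaging setting: micron-sized fiducial marker
beads dispersed in the gel (at ~2e8 beads/ml a 2-D optical section at low
numerical aperture sees a few thousand beads per mm^2), a dark roughly
circular spheroid in the image center, and low-NA brightfield contrast.
Frames are rendered bead-wise -- each bead is drawn as a Gaussian spot at
its displaced position -- so the imposed displacement field is known
exactly, without image-resampling artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lookup import LookupTable, deformation_from_pressure
from .piv import ImageSeries

__all__ = ["BeadScene", "GroundTruth", "generate_scene", "render_frame",
           "make_timelapse", "radial_displacement"]

#: default bead areal density (beads per µm^2) seen by a low-NA objective
DEFAULT_DENSITY = 3e-3


@dataclass
class BeadScene:
    """Reference (undeformed) scene: bead positions plus optics parameters."""

    bead_positions: np.ndarray   # (N, 2) µm, continuous coordinates
    shape: tuple[int, int]       # (H, W) pixels
    pixel_size: float            # µm/px
    spheroid_center: np.ndarray  # (x, y) µm
    spheroid_radius: float       # µm
    bead_sigma: float = 1.0      # Gaussian spot width, µm
    background: float = 200.0    # background gray level
    bead_amplitude: float = -120.0  # beads darker than background
    spheroid_depth: float = 160.0   # disc darkness below background
    noise_sigma: float = 2.0     # additive Gaussian noise level
    seed: int = 0


@dataclass
class GroundTruth:
    """Imposed conditions behind a synthetic time-lapse."""

    pressures: np.ndarray        # per-frame imposed pressure (Pa)
    r0: float
    centroid: np.ndarray
    drift: np.ndarray            # (T, 2) µm rigid stage drift per frame
    meta: dict = field(default_factory=dict)


def generate_scene(
    density: float = DEFAULT_DENSITY,
    shape: tuple[int, int] = (1000, 1000),
    pixel_size: float = 1.29,
    seed: int = 0,
    spheroid_radius: float = 150.0,
    spheroid_center: tuple[float, float] | None = None,
    **style,
) -> BeadScene:
    """Uniformly random bead positions outside the spheroid disc.

    The bead count is ``round(density * field_area)`` (deterministic);
    positions falling inside the disc are re-drawn so the count is kept.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if density > 0.25 / pixel_size**2:
        import warnings

        warnings.warn("bead density above 1 bead per 4 px^2: spots will saturate")
    h, w = shape
    field_um = (w * pixel_size, h * pixel_size)
    if spheroid_center is None:
        center = np.array([field_um[0] / 2.0, field_um[1] / 2.0])
    else:
        center = np.asarray(spheroid_center, dtype=float)
    n_beads = int(round(density * field_um[0] * field_um[1]))
    rng = np.random.default_rng(seed)
    pts = np.empty((0, 2))
    for _ in range(200):
        if len(pts) >= n_beads:
            break
        cand = rng.uniform([0, 0], field_um, size=(2 * n_beads, 2))
        cand = cand[np.linalg.norm(cand - center, axis=1) > spheroid_radius]
        pts = np.vstack([pts, cand])
    else:
        raise ValueError(
            "could not place beads outside the spheroid disc: the disc "
            "covers (nearly) the whole field of view"
        )
    pts = pts[:n_beads]
    return BeadScene(
        bead_positions=pts,
        shape=shape,
        pixel_size=pixel_size,
        spheroid_center=center,
        spheroid_radius=spheroid_radius,
        seed=seed,
        **style,
    )


def _draw_spots(img: np.ndarray, pts_px: np.ndarray, sigma_px: float,
                amplitude: float) -> None:
    """Accumulate Gaussian spots at continuous pixel positions (in place)."""
    h, w = img.shape
    half = max(2, int(np.ceil(3 * sigma_px)))
    for x, y in pts_px:
        j0, i0 = int(np.floor(x)) - half, int(np.floor(y)) - half
        j1, i1 = j0 + 2 * half + 1, i0 + 2 * half + 1
        ja, ia = max(j0, 0), max(i0, 0)
        jb, ib = min(j1, w), min(i1, h)
        if ja >= jb or ia >= ib:
            continue
        jj = np.arange(ja, jb)
        ii = np.arange(ia, ib)
        gx = np.exp(-0.5 * ((jj - x) / sigma_px) ** 2)
        gy = np.exp(-0.5 * ((ii - y) / sigma_px) ** 2)
        img[ia:ib, ja:jb] += amplitude * gy[:, None] * gx[None, :]


def render_frame(
    scene: BeadScene,
    displacement=None,
    drift: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one frame: dark spheroid disc plus displaced bead spots.

    ``displacement`` maps bead reference positions (N, 2) µm to displacement
    vectors (N, 2) µm; ``None`` renders the reference frame.  ``drift`` adds
    a rigid translation of the whole scene (µm).  Noise is only added when
    an ``rng`` is passed.
    """
    h, w = scene.shape
    img = np.full((h, w), scene.background, dtype=float)
    pts = scene.bead_positions
    if displacement is not None:
        pts = pts + displacement(pts)
    center = scene.spheroid_center.copy()
    if drift is not None:
        pts = pts + np.asarray(drift, dtype=float)[None, :]
        center = center + np.asarray(drift, dtype=float)
    # smooth-edged dark disc for the spheroid
    ps = scene.pixel_size
    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.hypot(xx * ps - center[0], yy * ps - center[1])
    edge = 2.0  # µm edge softness
    img -= scene.spheroid_depth / (1.0 + np.exp((rr - scene.spheroid_radius) / edge))
    _draw_spots(img, pts / ps, scene.bead_sigma / ps, scene.bead_amplitude)
    if rng is not None and scene.noise_sigma > 0:
        img = img + rng.normal(0.0, scene.noise_sigma, img.shape)
    return img


def radial_displacement(table: LookupTable, pressure: float,
                        center: np.ndarray, r0: float):
    """Displacement-field function: inward radial field drawn from the table.

    The curve family gives the deformation as observed at the deformed (lab)
    distance, so a bead starting at reference distance d must end at lab
    distance d - u with ``u = r0 * y(P, (d - u)/r0)``.  This fixed point is
    solved by iteration (the curves decay with distance, so the map is
    contractive).  Distances outside the tabulated range are clamped to the
    nearest curve end (they occur only at the image corners / spheroid rim).
    """
    lo = table.x[0] * 1.0000001
    hi = table.x[-1] * 0.9999999

    def disp(pts: np.ndarray) -> np.ndarray:
        if pressure <= 0:
            return np.zeros_like(pts)
        dvec = pts - center[None, :]
        d = np.linalg.norm(dvec, axis=1)
        u = r0 * deformation_from_pressure(table, pressure,
                                           np.clip(d / r0, lo, hi))
        for _ in range(30):
            x_lab = np.clip((d - u) / r0, lo, hi)
            u_new = r0 * deformation_from_pressure(table, pressure, x_lab)
            if np.max(np.abs(u_new - u)) < 1e-9 * r0:
                u = u_new
                break
            u = u_new
        return -dvec / np.maximum(d, 1e-9)[:, None] * u[:, None]

    return disp


def make_timelapse(
    scene: BeadScene,
    pressure_schedule: np.ndarray,
    table: LookupTable,
    dt: float = 10.0,
    drift_per_frame: float = 0.0,
    noise: bool = True,
    seed: int = 0,
) -> tuple[ImageSeries, GroundTruth]:
    """Render a time-lapse following a pressure schedule.

    Frame t shows the scene displaced by the forward-predicted field at
    ``pressure_schedule[t]`` (the first entry is usually 0), optionally with
    a rigid stage drift random walk of ``drift_per_frame`` µm per step.
    Returns the series together with the imposed ground truth.
    """
    schedule = np.asarray(pressure_schedule, dtype=float)
    if np.any((schedule > 0) & ((schedule < table.p_min) | (schedule > table.p_max))):
        raise ValueError("pressure schedule leaves the lookup-table range")
    rng = np.random.default_rng(seed)
    drifts = np.zeros((len(schedule), 2))
    if drift_per_frame > 0:
        steps = rng.normal(0.0, drift_per_frame, (len(schedule) - 1, 2))
        drifts[1:] = np.cumsum(steps, axis=0)
    frames = []
    for t, P in enumerate(schedule):
        fn = None
        if P > 0:
            fn = radial_displacement(table, P, scene.spheroid_center,
                                     scene.spheroid_radius)
        frames.append(
            render_frame(scene, fn, drift=drifts[t], rng=rng if noise else None)
        )
    series = ImageSeries(frames=np.stack(frames), pixel_size=scene.pixel_size,
                         dt=dt)
    truth = GroundTruth(
        pressures=schedule,
        r0=scene.spheroid_radius,
        centroid=scene.spheroid_center.copy(),
        drift=drifts,
        meta={"seed": seed, "drift_per_frame": drift_per_frame},
    )
    return series, truth
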