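"""Matrix deformation measurement from time-lapse images.

Tile-based particle image velocimetry between consecutive frames, stage
drift correction (subtracting the mean offset of each step), Eulerian
temporal accumulation at fixed tile positions, spheroid segmentation, and
radial projection of the accumulated field with an angular filter that
keeps only tiles whose deformation points within +-20 degrees of the
spheroid center.

Coordinates: origin at the top-left pixel center, x rightward, y downward,
0-based pixel indices; all public positions and displacements are in µm.
Inward (toward the spheroid centroid) projected deformations are positive.
"""

from __future__ import annotations

import glob as _glob
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "ImageSeries",
    "IncrementalField",
    "AccumulatedField",
    "SpheroidGeometry",
    "ProjectedField",
    "load_series",
    "piv_pair",
    "drift_correct",
    "accumulate",
    "segment_spheroid",
    "project_and_filter",
]

#: angular acceptance half-width of the radial filter
ANGLE_DEG = 20.0

#: minimum first-to-second correlation peak ratio for a valid tile
MIN_SNR = 1.3

#: minimum normalized-cross-correlation peak height for a valid tile
MIN_PEAK = 0.5


@dataclass
class ImageSeries:
    """Ordered grayscale frames with physical calibration."""

    frames: np.ndarray        # (T, H, W)
    pixel_size: float         # µm per pixel
    dt: float                 # minutes between frames

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("need >= 2 frames of identical shape")
        if self.pixel_size <= 0 or self.dt <= 0:
            raise ValueError("pixel_size and dt must be positive")

    @property
    def times(self) -> np.ndarray:
        """Minutes from the first frame."""
        return np.arange(self.frames.shape[0]) * self.dt


def load_series(source: str | Path, pixel_size: float, dt: float) -> ImageSeries:
    """Load a multi-page TIFF, or a glob of single-page TIFFs ordered by name."""
    import tifffile

    source = str(source)
    if any(ch in source for ch in "*?["):
        paths = sorted(_glob.glob(source))
        if len(paths) < 2:
            raise FileNotFoundError(f"glob {source!r} matched {len(paths)} files")
        frames = np.stack([tifffile.imread(p) for p in paths])
    else:
        frames = tifffile.imread(source)
        if frames.ndim == 2:
            raise ValueError("single-page TIFF: need a time series")
    return ImageSeries(frames=frames, pixel_size=pixel_size, dt=dt)


@dataclass
class IncrementalField:
    """Per-tile displacement between two consecutive frames."""

    positions: np.ndarray     # (N, 2) tile centers, µm (x, y)
    offsets: np.ndarray       # (N, 2) displacements, µm (dx, dy)
    valid: np.ndarray         # (N,) bool
    snr: np.ndarray           # (N,) peak-to-second-peak ratio
    window: int               # window size (px)
    pixel_size: float


@dataclass
class AccumulatedField:
    """Deformation summed over time steps at fixed tile positions (Eulerian)."""

    positions: np.ndarray     # (N, 2) µm
    u: np.ndarray             # (N, 2) accumulated displacement, µm
    n_invalid: np.ndarray     # (N,) count of invalid increments so far
    window: int
    pixel_size: float

    @property
    def valid(self) -> np.ndarray:
        return self.n_invalid == 0


@dataclass
class SpheroidGeometry:
    """Segmented spheroid: mask, centroid and effective radius."""

    mask: np.ndarray          # boolean image
    centroid: np.ndarray     # (x, y) µm
    area: float               # projected area, µm^2
    r0: float                 # effective radius sqrt(area/pi), µm
    pixel_size: float


@dataclass
class ProjectedField:
    """Radially projected, angularly filtered deformation field."""

    positions: np.ndarray     # (N, 2) µm
    d: np.ndarray             # distance to centroid, µm
    u_proj: np.ndarray        # inward-positive projected deformation, µm
    passes: np.ndarray        # (N,) bool: angular filter + geometry + validity
    r0: float
    centroid: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def d_norm(self) -> np.ndarray:
        return self.d / self.r0

    @property
    def u_norm(self) -> np.ndarray:
        return self.u_proj / self.r0


def _tile_grid(shape: tuple[int, int], window: int, overlap: float):
    """Top-left corners and centers (px) of the PIV tile grid."""
    step = max(1, int(round(window * (1.0 - overlap))))
    h, w = shape
    ys = np.arange(0, h - window + 1, step)
    xs = np.arange(0, w - window + 1, step)
    corners = np.array([(x, y) for y in ys for x in xs])
    centers = corners + (window - 1) / 2.0
    return corners, centers


def _subpixel(corr: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """3-point Gaussian peak interpolation per axis."""
    i, j = peak
    out = []
    for axis, k in ((0, i), (1, j)):
        if k <= 0 or k >= corr.shape[axis] - 1:
            out.append(0.0)
            continue
        if axis == 0:
            cm, c0, cp = corr[k - 1, j], corr[k, j], corr[k + 1, j]
        else:
            cm, c0, cp = corr[i, k - 1], corr[i, k], corr[i, k + 1]
        if cm > 0 and c0 > 0 and cp > 0:
            # Gaussian 3-point fit (exact for a Gaussian correlation peak)
            denom = 2.0 * (np.log(cm) + np.log(cp) - 2.0 * np.log(c0))
            delta = 0.0 if denom == 0 else (np.log(cm) - np.log(cp)) / denom
        else:
            # parabolic fallback when side lobes are non-positive
            denom = 2.0 * (cm + cp - 2.0 * c0)
            delta = 0.0 if denom == 0 else (cm - cp) / denom
        out.append(float(np.clip(delta, -1.0, 1.0)))
    return out[0], out[1]


def _gather_tiles(img: np.ndarray, corners: np.ndarray, size: int) -> np.ndarray:
    """Stack the (size x size) tiles at the given top-left corners: (N, s, s)."""
    view = np.lib.stride_tricks.sliding_window_view(img, (size, size))
    return view[corners[:, 1], corners[:, 0]]


def _tile_std(img: np.ndarray, corners: np.ndarray, size: int) -> np.ndarray:
    tiles = _gather_tiles(img, corners, size)
    return tiles.std(axis=(1, 2))


def _batched_ncc(img_a: np.ndarray, img_b: np.ndarray, corners: np.ndarray,
                 window: int, pad: int) -> np.ndarray:
    """Normalized cross-correlation of every template against its window.

    For each tile, the central (window - 2 pad) template from ``img_a`` is
    matched at all integer offsets inside the same window of ``img_b``
    (valid mode, (2 pad + 1)^2 offsets).  Numerator via batched FFT
    correlation, local window statistics via integral images — numerically
    identical to per-tile template matching, but one vectorized pass.
    """
    m = window - 2 * pad
    w = window
    B = _gather_tiles(img_b, corners, w)                      # (N, w, w)
    T = _gather_tiles(img_a, corners + pad, m)                # (N, m, m)
    T0 = T - T.mean(axis=(1, 2), keepdims=True)
    sT = T.std(axis=(1, 2))                                   # (N,)
    # cross term: sum over the template of B * (T - mean T)
    Fb = sp_fft.rfft2(B, axes=(1, 2))
    Ft = sp_fft.rfft2(T0[:, ::-1, ::-1], s=(w, w), axes=(1, 2))
    raw = sp_fft.irfft2(Fb * Ft, s=(w, w), axes=(1, 2))
    cross = raw[:, m - 1:w, m - 1:w]                          # (N, s, s)
    # local mean/std of B over each m x m placement via integral images
    ii1 = np.cumsum(np.cumsum(np.pad(B, ((0, 0), (1, 0), (1, 0))), axis=1), axis=2)
    ii2 = np.cumsum(np.cumsum(np.pad(B * B, ((0, 0), (1, 0), (1, 0))), axis=1),
                    axis=2)

    def boxsum(ii):
        return (ii[:, m:, m:] - ii[:, :-m, m:] - ii[:, m:, :-m]
                + ii[:, :-m, :-m])

    npix = float(m * m)
    mu = boxsum(ii1) / npix
    var = np.maximum(boxsum(ii2) / npix - mu * mu, 0.0)
    denom = npix * sT[:, None, None] * np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        ncc = np.where(denom > 1e-12, cross / denom, np.nan)
    return ncc


def piv_pair(
    img_a: np.ndarray,
    img_b: np.ndarray,
    window: int = 40,
    overlap: float = 0.5,
    pixel_size: float = 1.0,
) -> IncrementalField:
    """Cross-correlation template-matching of ``img_b`` against ``img_a``.

    The central region of each ``img_a`` window is used as a template and
    located inside the same window of ``img_b`` by normalized
    cross-correlation; the correlation peak (with 3-point Gaussian subpixel
    refinement) is the most likely offset.  Matching a smaller template
    inside the full window avoids the loss-of-pairs bias of plain
    same-window correlation and resolves displacements up to a quarter
    window.  Tiles with a first-to-second peak ratio below ``MIN_SNR``, a
    weak correlation peak, or no texture are flagged invalid, not errored.
    """
    img_a = np.asarray(img_a, dtype=float)
    img_b = np.asarray(img_b, dtype=float)
    if img_a.shape != img_b.shape:
        raise ValueError("images must have the same shape")
    if window < 16:
        raise ValueError("window must be >= 16 px")
    if window > min(img_a.shape):
        raise ValueError("window larger than image")
    corners, centers = _tile_grid(img_a.shape, window, overlap)
    pad = window // 4  # max resolvable displacement per step
    texture_floor = max(1e-9, 0.05 * img_a.std())
    n = len(corners)
    offsets = np.zeros((n, 2))
    valid = np.zeros(n, dtype=bool)
    snr = np.zeros(n)

    ncc = _batched_ncc(img_a, img_b, corners, window, pad)  # (n, s, s)
    s = ncc.shape[1]
    flat = np.nan_to_num(ncc.reshape(n, -1), nan=-2.0)
    peak_idx = flat.argmax(axis=1)
    pi, pj = np.unravel_index(peak_idx, (s, s))
    peak = flat[np.arange(n), peak_idx]

    # texture of the template region decides degeneracy
    tmpl_std = _tile_std(img_a, corners + pad, window - 2 * pad)
    ok = (tmpl_std > texture_floor) & (peak >= MIN_PEAK)
    # peak at/beyond the search range is untrustworthy
    ok &= (pi > 0) & (pj > 0) & (pi < s - 1) & (pj < s - 1)

    # second peak outside a 3x3 exclusion zone around the first
    masked = flat.copy()
    for di_ in (-1, 0, 1):
        for dj_ in (-1, 0, 1):
            ii = np.clip(pi + di_, 0, s - 1)
            jj = np.clip(pj + dj_, 0, s - 1)
            masked[np.arange(n), ii * s + jj] = -np.inf
    second = masked.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(second > 1e-12, peak / np.maximum(second, 1e-12), np.inf)
    snr[:] = np.where(ok, ratio, 0.0)
    ok &= ratio >= MIN_SNR

    for t in np.nonzero(ok)[0]:
        i, j = pi[t], pj[t]
        if peak[t] > 0.9999:
            di = dj = 0.0  # exact match: integer offset needs no refinement
        else:
            di, dj = _subpixel(ncc[t], (i, j))
        dy = (i - pad) + di
        dx = (j - pad) + dj
        offsets[t] = (dx * pixel_size, dy * pixel_size)
        valid[t] = True
    return IncrementalField(
        positions=centers * pixel_size,
        offsets=offsets,
        valid=valid,
        snr=snr,
        window=window,
        pixel_size=pixel_size,
    )


def drift_correct(field: IncrementalField) -> IncrementalField:
    """Remove rigid stage drift: subtract the mean offset of the valid tiles.

    After correction the mean offset over valid tiles is zero (to numerical
    precision).  A uniform translation added to every tile therefore leaves
    the corrected field unchanged.
    """
    if not np.any(field.valid):
        raise ValueError("no valid tiles to estimate drift from")
    mean = field.offsets[field.valid].mean(axis=0)
    offsets = field.offsets.copy()
    offsets[field.valid] -= mean
    return IncrementalField(
        positions=field.positions,
        offsets=offsets,
        valid=field.valid.copy(),
        snr=field.snr.copy(),
        window=field.window,
        pixel_size=field.pixel_size,
    )


def accumulate(increments: list[IncrementalField]) -> AccumulatedField:
    """Sum pair-wise deformations over time at fixed tile positions.

    The accumulation is Eulerian: offsets are summed at fixed tile indices,
    without advecting tile positions.  Invalid increments contribute zero
    and are counted per tile.
    """
    if not increments:
        raise ValueError("need at least one increment")
    pos = increments[0].positions
    for inc in increments[1:]:
        if inc.positions.shape != pos.shape or not np.allclose(inc.positions, pos):
            raise ValueError("tile grids of the increments do not match")
    u = np.zeros_like(pos, dtype=float)
    n_invalid = np.zeros(len(pos), dtype=int)
    for inc in increments:
        u[inc.valid] += inc.offsets[inc.valid]
        n_invalid[~inc.valid] += 1
    return AccumulatedField(
        positions=pos,
        u=u,
        n_invalid=n_invalid,
        window=increments[0].window,
        pixel_size=increments[0].pixel_size,
    )


def segment_spheroid(img: np.ndarray, pixel_size: float,
                     sigma: float = 2.0) -> SpheroidGeometry:
    """Segment a dark spheroid on a lighter background (Otsu threshold).

    The image is lightly smoothed, thresholded globally, holes are filled
    and the largest connected component kept.  The effective radius is that
    of the circle with the segmented projected area, r0 = sqrt(A/pi).
    """
    img = np.asarray(img, dtype=float)
    smooth = ndimage.gaussian_filter(img, sigma)
    thr = threshold_otsu(smooth)
    mask = smooth < thr
    mask = ndimage.binary_fill_holes(mask)
    lbl = label(mask)
    if lbl.max() == 0:
        raise ValueError("no foreground component found")
    props = regionprops(lbl)
    biggest = max(props, key=lambda p: p.area)
    mask = lbl == biggest.label
    cy, cx = biggest.centroid
    area = float(biggest.area) * pixel_size**2
    return SpheroidGeometry(
        mask=mask,
        centroid=np.array([cx * pixel_size, cy * pixel_size]),
        area=area,
        r0=float(np.sqrt(area / np.pi)),
        pixel_size=pixel_size,
    )


def project_and_filter(field: AccumulatedField, geom: SpheroidGeometry,
                       require_valid: bool = True) -> ProjectedField:
    """Project accumulated deformations toward the spheroid center.

    The projected deformation is ``u_proj = -(u . d_hat)``, positive for
    inward motion.  A tile passes the angular filter iff its deformation
    vector points within +-20 degrees of the direction to (or away from)
    the centroid; tiles inside the spheroid mask, at the centroid, or with
    invalid PIV history are excluded.
    """
    dvec = field.positions - geom.centroid[None, :]
    d = np.linalg.norm(dvec, axis=1)
    nonzero = d > 0
    u_proj = np.zeros(len(d))
    cosang = np.zeros(len(d))
    umag = np.linalg.norm(field.u, axis=1)
    ok = nonzero & (umag > 0)
    u_proj[ok] = -(field.u[ok] * dvec[ok]).sum(axis=1) / d[ok]
    cosang[ok] = np.abs(u_proj[ok]) / umag[ok]
    passes = ok & (cosang > np.cos(np.deg2rad(ANGLE_DEG)))
    # exclude tiles whose center lies inside the spheroid mask
    px = np.clip(
        np.round(field.positions / geom.pixel_size).astype(int),
        0,
        [geom.mask.shape[1] - 1, geom.mask.shape[0] - 1],
    )
    inside = geom.mask[px[:, 1], px[:, 0]]
    passes &= ~inside
    if require_valid:
        passes &= field.valid
    return ProjectedField(
        positions=field.positions,
        d=d,
        u_proj=u_proj,
        passes=passes,
        r0=geom.r0,
        centroid=geom.centroid.copy(),
        meta={"window": field.window, "pixel_size": field.pixel_size},
    )
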