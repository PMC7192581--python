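"""End-to-end analysis orchestration, configuration and persistence.

A single YAML/JSON config (mirrored by CLI flags) drives the whole
pipeline: PIV on consecutive frames, drift correction, Eulerian
accumulation, segmentation of the initial frame, radial projection, lookup
inversion and per-timestep contractility records.  Runs are deterministic
for a fixed config.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import piv as _piv
from . import reconstruct as _rec
from .lookup import LookupTable, load_lookup
from .materials import load_material
from .piv import ImageSeries, ProjectedField, SpheroidGeometry

__all__ = ["AnalysisConfig", "AnalysisResult", "run_analysis",
           "accumulated_series", "write_records", "read_records",
           "write_tile_table"]

_FLOAT_FMT = "%.10g"


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one analysis run."""

    images: str = ""                  # multipage TIFF path or glob
    pixel_size: float = 1.29          # µm/px
    dt: float = 5.0                   # minutes between frames
    window: int = 40                  # PIV window (px)
    overlap: float = 0.5
    material: str = "collagen-1.2"    # preset name or parameter file
    lookup_path: str = ""             # prebuilt lookup table (JSON)
    min_distance_factor: float = _rec.MIN_DISTANCE_FACTOR
    angular_bin: float = 5.0          # degrees; 0 disables angular profiles
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.dt <= 0 or self.window <= 0:
            raise ValueError("physical quantities must be positive")
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must be in [0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = asdict(self)
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=1))


@dataclass
class AnalysisResult:
    """Bundle returned by :func:`run_analysis`."""

    records: list
    fields: list                      # ProjectedField per timestep
    geometry: SpheroidGeometry
    angular: list | None = None       # AngularPressureProfile per timestep
    log: dict = field(default_factory=dict)


def accumulated_series(series: ImageSeries, window: int, overlap: float):
    """PIV + drift correction + accumulation for every timestep.

    Returns the list of accumulated fields after steps 1..T-1.
    """
    increments = []
    for t in range(len(series.frames) - 1):
        inc = _piv.piv_pair(
            series.frames[t], series.frames[t + 1],
            window=window, overlap=overlap, pixel_size=series.pixel_size,
        )
        increments.append(_piv.drift_correct(inc))
    fields = []
    for t in range(1, len(increments) + 1):
        fields.append(_piv.accumulate(increments[:t]))
    return fields


def run_analysis(
    config: AnalysisConfig,
    series: ImageSeries | None = None,
    table: LookupTable | None = None,
    write: bool = True,
) -> AnalysisResult:
    """Run the full contractility pipeline for one time-lapse.

    ``series`` and ``table`` may be passed directly (library use); otherwise
    they are loaded from the paths in the config.
    """
    if series is None:
        if not config.images:
            raise ValueError("no image source configured")
        series = _piv.load_series(config.images, config.pixel_size, config.dt)
    if table is None:
        if not config.lookup_path:
            raise ValueError("no lookup table configured")
        table = load_lookup(config.lookup_path)
    # material consistency is the caller's responsibility when passing a table
    load_material(config.material)

    geom = _piv.segment_spheroid(series.frames[0], series.pixel_size)
    acc = accumulated_series(series, config.window, config.overlap)
    fields: list[ProjectedField] = [
        _piv.project_and_filter(a, geom) for a in acc
    ]
    times = series.times[1:]
    records = _rec.time_series(
        fields, table, geom, times=times,
        min_distance_factor=config.min_distance_factor,
    )
    # one record per frame: the first frame is the undeformed reference
    records.insert(0, _rec.ContractilityRecord(
        time=0.0, pressure=0.0, r0=geom.r0, force=0.0,
        n_tiles=0, n_excluded=0))
    angular = None
    if config.angular_bin:
        angular = [
            _rec.angular_pressures(f, table, bin_width=config.angular_bin,
                                   min_distance_factor=config.min_distance_factor)
            for f in fields
        ]
    log = {
        "n_frames": int(len(series.frames)),
        "n_tiles": int(len(fields[0].d)) if fields else 0,
        "r0_um": geom.r0,
        "seed": config.seed,
        "config": asdict(config),
    }
    result = AnalysisResult(records=records, fields=fields, geometry=geom,
                            angular=angular, log=log)
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_records(result.records, out / "contractility.csv")
        write_tile_table(fields[-1], out / "tiles_final.csv")
        if angular:
            df = pd.DataFrame({
                "angle_deg_center": angular[-1].angles,
                "pressure_Pa": angular[-1].pressures,
            })
            df.to_csv(out / "angular_final.csv", index=False,
                      float_format=_FLOAT_FMT)
        (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return result


def write_records(records: list, path: str | Path) -> None:
    df = pd.DataFrame({
        "time_min": [r.time for r in records],
        "median_pressure_Pa": [r.pressure for r in records],
        "r0_um": [r.r0 for r in records],
        "contractility_uN": [r.force_uN for r in records],
        "n_tiles": [r.n_tiles for r in records],
        "n_excluded": [r.n_excluded for r in records],
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_records(path: str | Path) -> list:
    df = pd.read_csv(path)
    return [
        _rec.ContractilityRecord(
            time=row.time_min,
            pressure=row.median_pressure_Pa,
            r0=row.r0_um,
            force=row.contractility_uN * 1e-6,
            n_tiles=int(row.n_tiles),
            n_excluded=int(row.n_excluded),
        )
        for row in df.itertuples()
    ]


def write_tile_table(fieldp: ProjectedField, path: str | Path) -> None:
    """Per-tile table of the projected field (final or any timestep)."""
    df = pd.DataFrame({
        "tile_x_um": fieldp.positions[:, 0],
        "tile_y_um": fieldp.positions[:, 1],
        "u_proj_um": fieldp.u_proj,
        "d_um": fieldp.d,
        "passes_filter": fieldp.passes.astype(int),
    })
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
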