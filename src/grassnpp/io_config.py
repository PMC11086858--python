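"""Raster/table I/O and run configuration.

All gridded data live on a single projected, north-up, grid-registered
raster grid described by :class:`GridSpec`.  On disk a raster stack is a
multi-page float32 TIFF (one page per time step) with a JSON sidecar
(``<path>.meta.json``) holding the grid geometry; in memory missing data
are NaN and the nodata sentinel exists only on disk.

Run parameters are collected in :class:`RunConfig`, serialisable to a
flat ``key = value`` text file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

log = logging.getLogger(__name__)

SURVEY_COLUMNS = ["lon", "lat", "altitude", "grassland_type", "measured_npp"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the single projected raster grid.

    ``origin_x``/``origin_y`` are the projected coordinates (metres) of the
    top-left corner of the top-left pixel; rows increase southward.
    ``lon``/``lat`` columns of survey tables are interpreted as projected
    x/y on this grid (no reprojection is performed).
    """

    n_rows: int
    n_cols: int
    pixel_size: float = 1000.0  # m; the source products are 1 km grids
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(f"grid must be at least 1x1, got {self.n_rows}x{self.n_cols}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def pixel_area(self) -> float:
        """Pixel area in m^2."""
        return self.pixel_size * self.pixel_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def point_to_rowcol(self, x: float, y: float) -> tuple[int, int]:
        col = int(np.floor((x - self.origin_x) / self.pixel_size))
        row = int(np.floor((self.origin_y - y) / self.pixel_size))
        return row, col

    def rowcol_to_point(self, row: int, col: int) -> tuple[float, float]:
        """Projected coordinates of a pixel centre."""
        x = self.origin_x + (col + 0.5) * self.pixel_size
        y = self.origin_y - (row + 0.5) * self.pixel_size
        return x, y

    def contains(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**{f.name: d[f.name] for f in dataclasses.fields(cls)})


def write_raster_stack(path: str | Path, data: np.ndarray, spec: GridSpec) -> Path:
    """Write a (bands, rows, cols) float array as a multi-page TIFF + sidecar.

    NaN cells are replaced by ``spec.nodata`` on disk.  Values are stored
    as float32; round-trips are bit-exact at that width.
    """
    path = Path(path)
    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected 2-D or 3-D array, got ndim={arr.ndim}")
    if arr.shape[1:] != spec.shape:
        raise ValueError(
            f"array shape {arr.shape[1:]} does not match grid {spec.shape}"
        )
    out = np.where(np.isnan(arr), np.float32(spec.nodata), arr)
    tifffile.imwrite(path, out, photometric="minisblack")
    meta = {"grid": spec.to_dict(), "n_bands": int(out.shape[0])}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_raster_stack(
    path: str | Path,
    spec: GridSpec | None = None,
    expected_bands: int | None = None,
) -> tuple[np.ndarray, GridSpec]:
    """Read a raster stack written by :func:`write_raster_stack`.

    Returns a (bands, rows, cols) float32 array with nodata cells set to
    NaN, plus the grid spec (from the sidecar, or ``spec`` if given).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster stack not found: {path}")
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    sidecar = Path(str(path) + ".meta.json")
    if sidecar.exists():
        file_spec = GridSpec.from_dict(json.loads(sidecar.read_text())["grid"])
        if spec is not None and file_spec.shape != spec.shape:
            raise ValueError(
                f"grid mismatch: file has {file_spec.shape}, expected {spec.shape}"
            )
        spec = file_spec
    elif spec is None:
        raise ValueError(f"no sidecar metadata for {path} and no GridSpec given")
    if arr.shape[1:] != spec.shape:
        raise ValueError(
            f"raster shape {arr.shape[1:]} does not match grid {spec.shape}"
        )
    if expected_bands is not None and arr.shape[0] != expected_bands:
        raise ValueError(
            f"band count mismatch for {path.name}: expected {expected_bands}, "
            f"found {arr.shape[0]}"
        )
    arr = arr.astype(np.float32)
    arr[arr == np.float32(spec.nodata)] = np.nan
    return arr, spec


def read_survey_csv(path: str | Path, spec: GridSpec | None = None) -> pd.DataFrame:
    """Read survey points (projected coords, type, measured NPP) from CSV.

    Columns: lon, lat, altitude, grassland_type, measured_npp.  Rows with
    non-numeric coordinates/NPP raise with the offending row number.  When
    ``spec`` is given, points are mapped to (row, col) and off-grid points
    are dropped with a logged count (also in ``df.attrs['n_excluded']``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"survey file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survey file {path.name} missing columns: {missing}")
    for col in ("lon", "lat", "altitude", "measured_npp"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"survey file {path.name}: non-numeric {col!r} at data row {row + 1}"
            )
        df[col] = coerced
    df.attrs["n_excluded"] = 0
    if spec is not None:
        cols = np.floor((df["lon"].to_numpy() - spec.origin_x) / spec.pixel_size)
        rows = np.floor((spec.origin_y - df["lat"].to_numpy()) / spec.pixel_size)
        on_grid = (
            (rows >= 0) & (rows < spec.n_rows) & (cols >= 0) & (cols < spec.n_cols)
        )
        n_excluded = int((~on_grid).sum())
        if n_excluded:
            log.warning("excluded %d survey points outside the grid", n_excluded)
        df = df.loc[on_grid].reset_index(drop=True)
        df["row"] = rows[on_grid].astype(int)
        df["col"] = cols[on_grid].astype(int)
        df.attrs["n_excluded"] = n_excluded
    return df


def write_survey_csv(path: str | Path, df: pd.DataFrame) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, columns=[c for c in df.columns])
    return path


# default meteorological season -> month mapping; the source study never
# states its mapping (it calls June-August "autumn"), so this is config.
DEFAULT_SEASONS: dict[str, tuple[int, ...]] = {
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
    "winter": (12, 1, 2),
}


@dataclass
class RunConfig:
    """Tunable parameters of the NPP/attribution pipeline."""

    years: tuple[int, ...] = tuple(range(2000, 2016))
    seasons: dict[str, tuple[int, ...]] = field(
        default_factory=lambda: {k: v for k, v in DEFAULT_SEASONS.items()}
    )
    # light-use efficiency
    xi_max: float = 0.542        # g C MJ^-1, single-class default maximum
    ndvi_min: float = 0.05       # NDVI giving fpar_min
    ndvi_max: float = 0.95       # NDVI giving fpar_max
    fpar_min: float = 0.0
    fpar_max: float = 0.95
    par_fraction: float = 0.5    # PAR share of total solar radiation
    # water stress clip bounds
    w_clip: tuple[float, float] = (0.5, 1.0)
    # potential-NPP closed-form parse variant ("auto" = gated selection)
    variant: str = "auto"
    # attribution
    epsilon: float = 0.0         # slope zero-tolerance
    classification_mode: str = "residual_consistent"
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be strictly increasing")
        months = sorted(m for ms in self.seasons.values() for m in ms)
        if months != list(range(1, 13)):
            raise ValueError("season mapping must partition months 1-12")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        lo, hi = self.w_clip
        if not lo <= hi:
            raise ValueError("w_clip bounds must be ordered")

    # -- flat key=value serialisation ------------------------------------
    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [
            f"years = {','.join(str(y) for y in self.years)}",
            *(
                f"season_{name} = {','.join(str(m) for m in months)}"
                for name, months in self.seasons.items()
            ),
            f"xi_max = {self.xi_max!r}",
            f"ndvi_min = {self.ndvi_min!r}",
            f"ndvi_max = {self.ndvi_max!r}",
            f"fpar_min = {self.fpar_min!r}",
            f"fpar_max = {self.fpar_max!r}",
            f"par_fraction = {self.par_fraction!r}",
            f"w_clip = {self.w_clip[0]!r},{self.w_clip[1]!r}",
            f"variant = {self.variant}",
            f"epsilon = {self.epsilon!r}",
            f"classification_mode = {self.classification_mode}",
            f"seed = {self.seed}",
        ]
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Parse a flat config file; keyword arguments override file values."""
        raw: dict[str, str] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {i} is not 'key = value'")
            key, _, value = line.partition("=")
            raw[key.strip()] = value.strip()
        kwargs: dict = {}
        if "years" in raw:
            kwargs["years"] = tuple(int(y) for y in raw.pop("years").split(","))
        seasons = {
            key[len("season_"):]: tuple(int(m) for m in raw.pop(key).split(","))
            for key in [k for k in raw if k.startswith("season_")]
        }
        if seasons:
            kwargs["seasons"] = seasons
        for key in ("xi_max", "ndvi_min", "ndvi_max", "fpar_min", "fpar_max",
                    "par_fraction", "epsilon"):
            if key in raw:
                kwargs[key] = float(raw.pop(key))
        if "w_clip" in raw:
            lo, hi = raw.pop("w_clip").split(",")
            kwargs["w_clip"] = (float(lo), float(hi))
        if "seed" in raw:
            kwargs["seed"] = int(raw.pop("seed"))
        for key in ("variant", "classification_mode"):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if raw:
            raise ValueError(f"{path}: unknown config keys {sorted(raw)}")
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)


def save_monthly_cube(path: str | Path, cube: np.ndarray, spec: GridSpec) -> Path:
    """Write a (years, 12, rows, cols) cube as a (years*12)-band stack."""
    y, m = cube.shape[:2]
    if m != 12:
        raise ValueError("monthly cube must have 12 months on axis 1")
    return write_raster_stack(path, cube.reshape(y * 12, *cube.shape[2:]), spec)


def load_monthly_cube(
    path: str | Path, spec: GridSpec | None = None, n_years: int | None = None
) -> tuple[np.ndarray, GridSpec]:
    """Read a (years*12)-band stack back into (years, 12, rows, cols)."""
    arr, spec = read_raster_stack(
        path, spec, expected_bands=None if n_years is None else 12 * n_years
    )
    if arr.shape[0] % 12:
        raise ValueError(
            f"{Path(path).name}: band count {arr.shape[0]} is not a multiple of 12"
        )
    return arr.reshape(arr.shape[0] // 12, 12, *arr.shape[1:]), spec
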