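"""Synthetic gridded climate, NDVI and survey fixtures.

The generator emulates the statistical structure of the study inputs so
the whole pipeline is testable without external downloads: a rectangular
1 km grid with a northwest-to-southeast gradient (dry/cold NW, wet/warm
SE), 16 years x 12 months, prescribed linear trends plus i.i.d. noise,
an NDVI field responding to same-year precipitation and growing-season
temperature, an optional human-pressure term injected in NDVI only (so it
reaches actual NPP but never the climate-only potential NPP), and survey
points sampled from the generated NPP truth with observation error.

Defaults mirror the reported study conditions: annual precipitation
spanning ~100-500 mm with ~70 % falling June-September, trend +1.3 mm/a;
regional mean annual temperature ~ -2.1 degC, trend +0.01 degC/a.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_config import GridSpec

# fraction of annual precipitation per month; June-September carry 70 %
PRECIP_MONTH_WEIGHTS = np.array(
    [0.01, 0.01, 0.02, 0.04, 0.08, 0.15, 0.20, 0.20, 0.15, 0.08, 0.04, 0.02]
)

# monthly NDVI seasonal shape (peak July), scaled by the annual greenness
NDVI_SEASON_SHAPE = np.array(
    [0.15, 0.15, 0.20, 0.35, 0.60, 0.85, 1.00, 0.95, 0.75, 0.45, 0.25, 0.18]
)


@dataclass
class SimParams:
    """Parameters of the synthetic study area."""

    n_rows: int = 50
    n_cols: int = 50
    pixel_size: float = 1000.0
    n_years: int = 16
    year0: int = 2000
    # precipitation: NW -> SE base gradient (mm a^-1), trend, pixel noise
    p_base: tuple[float, float] = (100.0, 500.0)
    p_trend: float = 1.3            # mm a^-1 per year
    p_noise_sd: float = 10.0        # mm, i.i.d. per pixel-year
    month_weights: np.ndarray = field(
        default_factory=lambda: PRECIP_MONTH_WEIGHTS.copy()
    )
    # temperature: annual-mean gradient (degC), trend, seasonal cycle
    t_base: tuple[float, float] = (-6.0, 1.8)   # regional mean -2.1
    t_trend: float = 0.01           # degC per year
    t_noise_sd: float = 0.2         # degC, i.i.d. per pixel-month
    t_amplitude: float = 12.5       # seasonal half-amplitude, peak July
    # solar radiation seasonal cycle (MJ m^-2 month^-1), spatially uniform
    sol_mean: float = 500.0
    sol_amplitude: float = 200.0
    # NDVI response: greenness = a + b*(P/500) + c*(T_grow/10) + human + noise
    ndvi_a: float = 0.05
    ndvi_b: float = 0.50
    ndvi_c: float = 0.05
    ndvi_noise_sd: float = 0.02
    season_shape: np.ndarray = field(
        default_factory=lambda: NDVI_SEASON_SHAPE.copy()
    )
    # human pressure on NDVI inside a block of the grid (fractions 0-1)
    human_offset: float = 0.0
    human_trend: float = 0.0        # NDVI units per year
    human_block: tuple[float, float, float, float] = (0.0, 0.5, 0.0, 0.5)
    # survey
    survey_noise_sd: float = 40.0   # g C m^-2 a^-1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_noise_sd < 0 or self.t_noise_sd < 0 or self.ndvi_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not np.isclose(np.sum(self.month_weights), 1.0):
            raise ValueError("monthly precipitation weights must sum to 1")
        if self.n_years < 1:
            raise ValueError("need at least one year")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, self.pixel_size)

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.year0, self.year0 + self.n_years))


@dataclass
class ClimateCube:
    """Monthly temperature, precipitation and radiation cubes."""

    temperature: np.ndarray  # (years, 12, rows, cols) degC
    precip: np.ndarray       # mm month^-1
    solar: np.ndarray        # MJ m^-2 month^-1
    spec: GridSpec
    years: tuple[int, ...]


def _diag_gradient(n_rows: int, n_cols: int) -> np.ndarray:
    """0 at the NW corner, 1 at the SE corner, linear along the diagonal."""
    r = np.arange(n_rows)[:, None]
    c = np.arange(n_cols)[None, :]
    span = max(n_rows - 1 + n_cols - 1, 1)
    return (r + c) / span


def _season_cos(amplitude: float) -> np.ndarray:
    months = np.arange(1, 13)
    return amplitude * np.cos(2 * np.pi * (months - 7) / 12.0)


def _rng(params: SimParams, stream: int) -> np.random.Generator:
    # independent, reproducible streams for climate / NDVI / survey noise
    return np.random.default_rng([stream, params.seed])


def generate_climate(params: SimParams) -> ClimateCube:
    """Gridded monthly climate with prescribed gradients, trends and noise."""
    rng = _rng(params, 0)
    diag = _diag_gradient(params.n_rows, params.n_cols)
    t_idx = np.arange(params.n_years, dtype=float)[:, None, None]

    p_ann = (
        params.p_base[0] + (params.p_base[1] - params.p_base[0]) * diag
        + params.p_trend * t_idx
    )
    if params.p_noise_sd > 0:
        p_ann = p_ann + rng.normal(0.0, params.p_noise_sd, p_ann.shape)
    p_ann = np.maximum(p_ann, 0.0)
    precip = p_ann[:, None] * params.month_weights[None, :, None, None]

    t_cycle = _season_cos(params.t_amplitude)
    temp = (
        params.t_base[0] + (params.t_base[1] - params.t_base[0]) * diag
        + params.t_trend * t_idx
    )[:, None] + t_cycle[None, :, None, None]
    if params.t_noise_sd > 0:
        temp = temp + rng.normal(0.0, params.t_noise_sd, temp.shape)

    sol = np.broadcast_to(
        (params.sol_mean + _season_cos(params.sol_amplitude))[None, :, None, None],
        temp.shape,
    ).copy()

    return ClimateCube(
        temperature=temp, precip=precip, solar=sol,
        spec=params.grid, years=params.years,
    )


def human_block_mask(params: SimParams) -> np.ndarray:
    """Boolean grid of the pixels subject to the human-pressure term."""
    r0, r1, c0, c1 = params.human_block
    rows = np.arange(params.n_rows)[:, None] / max(params.n_rows, 1)
    cols = np.arange(params.n_cols)[None, :] / max(params.n_cols, 1)
    return (rows >= r0) & (rows < r1) & (cols >= c0) & (cols < c1)


def human_pressure(params: SimParams) -> np.ndarray:
    """Human NDVI perturbation h(x, year), shape (years, rows, cols)."""
    t_idx = np.arange(params.n_years, dtype=float)[:, None, None]
    block = human_block_mask(params)[None]
    return block * (params.human_offset + params.human_trend * t_idx)


def generate_ndvi(climate: ClimateCube, params: SimParams) -> np.ndarray:
    """Monthly NDVI responding to same-year climate plus human pressure.

    Annual greenness G = a + b*(P_ann/500) + c*(T_JJA/10) + h + noise is
    spread over months by the seasonal shape and clipped to [-1, 1].
    """
    if climate.temperature.shape[0] != params.n_years:
        raise ValueError("climate cube does not match params.n_years")
    rng = _rng(params, 1)
    p_ann = climate.precip.sum(axis=1)
    t_grow = climate.temperature[:, 5:8].mean(axis=1)  # June-August
    g = (
        params.ndvi_a
        + params.ndvi_b * p_ann / 500.0
        + params.ndvi_c * t_grow / 10.0
        + human_pressure(params)
    )
    if params.ndvi_noise_sd > 0:
        g = g + rng.normal(0.0, params.ndvi_noise_sd, g.shape)
    ndvi = g[:, None] * params.season_shape[None, :, None, None]
    return np.clip(ndvi, -1.0, 1.0)


def simulate_inputs(params: SimParams) -> tuple[ClimateCube, np.ndarray]:
    """Convenience: climate cube and NDVI cube for one seed."""
    climate = generate_climate(params)
    return climate, generate_ndvi(climate, params)


GRASSLAND_TYPES = ("desert_steppe", "alpine_steppe", "alpine_meadow")


def generate_survey_points(
    npp_truth: np.ndarray,
    n_points: int,
    noise_sd: float,
    seed: int,
    spec: GridSpec,
) -> pd.DataFrame:
    """Survey records sampled uniformly from valid pixels of an NPP grid.

    measured_npp = true NPP at the pixel + N(0, noise_sd).  Coordinates are
    pixel centres; altitude and grassland type follow the NW-SE gradient.
    """
    if npp_truth.shape != spec.shape:
        raise ValueError("NPP grid does not match the grid spec")
    valid = np.flatnonzero(~np.isnan(npp_truth).ravel())
    if n_points > valid.size:
        raise ValueError(f"requested {n_points} points but only {valid.size} valid pixels")
    rng = np.random.default_rng([2, seed])
    chosen = rng.choice(valid, size=n_points, replace=False)
    rows, cols = np.unravel_index(chosen, npp_truth.shape)
    diag = _diag_gradient(spec.n_rows, spec.n_cols)[rows, cols]
    true_npp = npp_truth[rows, cols]
    measured = true_npp + (rng.normal(0.0, noise_sd, n_points) if noise_sd > 0 else 0.0)
    xy = [spec.rowcol_to_point(r, c) for r, c in zip(rows, cols)]
    return pd.DataFrame(
        {
            "lon": [p[0] for p in xy],
            "lat": [p[1] for p in xy],
            "altitude": np.round(4800.0 - 1800.0 * diag, 1),
            "grassland_type": [
                GRASSLAND_TYPES[min(int(d * 3), 2)] for d in diag
            ],
            "measured_npp": measured,
            "row": rows,
            "col": cols,
        }
    )


def noise_sd_for_r2(signal: np.ndarray, target_r2: float) -> float:
    """Observation noise sd giving an expected validation R^2.

    For measured = signal + e with independent e ~ N(0, sd^2), the expected
    coefficient of determination is var(signal) / (var(signal) + sd^2).
    """
    if not 0 < target_r2 < 1:
        raise ValueError("target R^2 must be in (0, 1)")
    var = float(np.nanvar(signal))
    return float(np.sqrt(var * (1.0 - target_r2) / target_r2))


# -- scenario presets for the driver-recovery experiments -----------------

def scenario_climate_degradation(base: SimParams | None = None) -> SimParams:
    """Drought scenario: precipitation trend -3 mm/a grid-wide, no humans."""
    base = base or SimParams()
    return dataclasses.replace(base, p_trend=-3.0, human_trend=0.0, human_offset=0.0)


def scenario_human_degradation(base: SimParams | None = None) -> SimParams:
    """Grazing-pressure scenario: NDVI suppressed by 0.006/a in the NW
    block while climate keeps its (unmanipulated) default trends."""
    base = base or SimParams()
    return dataclasses.replace(
        base, human_trend=-0.006, human_offset=0.0, human_block=(0.0, 0.5, 0.0, 0.5)
    )
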