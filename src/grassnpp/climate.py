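"""Annual climate quantities shared by both NPP models.

The humidity (moisture) index of the grassland classification system is
K = P / (0.1 * sum_theta), where P is annual precipitation (mm) and
sum_theta the annual accumulated temperature over periods with mean
temperature above 0 degC (degC day).  Both the water-stress factor of the
light-use-efficiency model and the climate-potential NPP model consume
these quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# 365-day calendar; leap days are ignored, consistent with monthly products
DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


@dataclass
class AnnualClimate:
    """Per pixel-year annual precipitation, accumulated temperature and K."""

    precip: np.ndarray     # mm a^-1, shape (years, rows, cols)
    sum_theta: np.ndarray  # degC day
    k: np.ndarray          # dimensionless; NaN where sum_theta == 0


def accumulated_temperature(temperature: np.ndarray, basis: str = "monthly") -> np.ndarray:
    """Annual accumulated temperature above 0 degC.

    Parameters
    ----------
    temperature:
        One year of mean temperatures with time on the leading axis:
        12 monthly means (``basis="monthly"``) or 365/366 daily means
        (``basis="daily"``).  Trailing axes are broadcast (e.g. a grid).
    basis:
        ``"monthly"`` sums max(T_m, 0) * days-in-month; ``"daily"`` sums
        max(T_d, 0) * 1 day.

    Returns
    -------
    Accumulated temperature in degC day (scalar or grid).
    """
    t = np.asarray(temperature, dtype=float)
    if t.shape[0] == 0:
        raise ValueError("empty temperature series")
    pos = np.maximum(t, 0.0)
    if basis == "monthly":
        if t.shape[0] != 12:
            raise ValueError(f"monthly basis expects 12 values, got {t.shape[0]}")
        days = DAYS_IN_MONTH.reshape((12,) + (1,) * (t.ndim - 1))
        return np.sum(pos * days, axis=0)
    if basis == "daily":
        return np.sum(pos, axis=0)
    raise ValueError(f"unknown basis {basis!r}")


def humidity_index(precip, sum_theta):
    """K = P / (0.1 * sum_theta); NaN (signalled) where sum_theta <= 0."""
    p = np.asarray(precip, dtype=float)
    st = np.asarray(sum_theta, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(st > 0, p / (0.1 * st), np.nan)
    return k if k.ndim else float(k)


def monthly_composite(first_half: np.ndarray, second_half: np.ndarray) -> np.ndarray:
    """Maximum-value composite of two half-month NDVI grids.

    Where one grid is NaN the other value is returned; both NaN stays NaN.
    """
    a = np.asarray(first_half, dtype=float)
    b = np.asarray(second_half, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return np.fmax(a, b)


def annual_climate(temperature: np.ndarray, precip: np.ndarray) -> AnnualClimate:
    """Reduce monthly cubes (years, 12, rows, cols) to annual quantities."""
    if temperature.shape != precip.shape:
        raise ValueError(
            f"temperature {temperature.shape} and precipitation {precip.shape} differ"
        )
    if temperature.shape[1] != 12:
        raise ValueError("expected monthly cubes with 12 months on axis 1")
    p_ann = np.sum(precip, axis=1)
    st = np.stack(
        [accumulated_temperature(temperature[y], "monthly")
         for y in range(temperature.shape[0])]
    )
    return AnnualClimate(precip=p_ann, sum_theta=st, k=humidity_index(p_ann, st))
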