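"""Descriptive outputs: monthly/seasonal NPP profiles, regional annual
series with trends, and the modelled-vs-measured validation regression."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .attribution import slope


@dataclass
class SeasonalProfile:
    monthly_npp: np.ndarray      # (12,) multi-year mean regional NPP per month
    monthly_pct: np.ndarray      # (12,) % of annual total
    seasonal_pct: dict[str, float]

    def window_pct(self, months: tuple[int, ...]) -> float:
        """Percentage of annual NPP accumulated in the given months (1-12)."""
        idx = [m - 1 for m in months]
        return float(self.monthly_pct[idx].sum())


def seasonal_profile(
    monthly_npp: np.ndarray,
    seasons: dict[str, tuple[int, ...]],
) -> SeasonalProfile:
    """Regional monthly accumulation profile from a (years, 12, rows, cols) cube.

    Percentages are of the multi-year mean annual regional NPP; monthly and
    seasonal percentages each sum to 100 by construction.
    """
    months = sorted(m for ms in seasons.values() for m in ms)
    if months != list(range(1, 13)):
        raise ValueError("season mapping must partition months 1-12")
    if monthly_npp.ndim != 4 or monthly_npp.shape[1] != 12:
        raise ValueError("expected a (years, 12, rows, cols) cube")
    regional = np.nanmean(monthly_npp, axis=(2, 3))   # (years, 12)
    mean_monthly = regional.mean(axis=0)              # (12,)
    total = mean_monthly.sum()
    if total == 0:
        raise ValueError("zero annual NPP; profile undefined")
    pct = 100.0 * mean_monthly / total
    seasonal = {name: float(pct[[m - 1 for m in ms]].sum()) for name, ms in seasons.items()}
    return SeasonalProfile(monthly_npp=mean_monthly, monthly_pct=pct, seasonal_pct=seasonal)


@dataclass
class RegionalTrend:
    annual_means: np.ndarray  # regional mean per year
    mean: float               # multi-year mean
    min: float
    max: float
    slope: float              # per year
    per_decade: float         # slope * 10


def regional_trend(annual_field: np.ndarray) -> RegionalTrend:
    """Area-weighted regional annual means and their linear trend.

    ``annual_field`` has shape (years, rows, cols); pixels are equal-area so
    the regional mean is the plain mean over valid pixels.
    """
    if annual_field.ndim != 3 or annual_field.shape[0] < 2:
        raise ValueError("expected (years >= 2, rows, cols)")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN years
        means = np.nanmean(annual_field.reshape(annual_field.shape[0], -1), axis=1)
    if np.isnan(means).all():
        raise ValueError("all-masked field")
    s = float(slope(means))
    return RegionalTrend(
        annual_means=means,
        mean=float(means.mean()),
        min=float(means.min()),
        max=float(means.max()),
        slope=s,
        per_decade=10.0 * s,
    )


@dataclass
class ValidationResult:
    n: int
    intercept: float
    gain: float
    r2: float


def validate(modeled_npp: np.ndarray, points: pd.DataFrame) -> ValidationResult:
    """OLS of measured on modelled NPP at the survey pixels; reports R^2.

    ``points`` must carry ``row``/``col`` (as produced by the survey
    reader) and ``measured_npp``.  Zero variance in either variable is
    signalled rather than returning a silent 0/1.
    """
    if not {"row", "col", "measured_npp"}.issubset(points.columns):
        raise ValueError("survey points need row, col and measured_npp columns")
    modeled = modeled_npp[points["row"].to_numpy(), points["col"].to_numpy()]
    measured = points["measured_npp"].to_numpy(dtype=float)
    ok = ~(np.isnan(modeled) | np.isnan(measured))
    modeled, measured = modeled[ok], measured[ok]
    if modeled.size < 3:
        raise ValueError(f"need >= 3 valid points, got {modeled.size}")
    if np.ptp(modeled) == 0 or np.ptp(measured) == 0:
        raise ValueError("zero variance in modelled or measured NPP; R^2 undefined")
    fit = stats.linregress(modeled, measured)
    return ValidationResult(
        n=int(modeled.size),
        intercept=float(fit.intercept),
        gain=float(fit.slope),
        r2=float(fit.rvalue**2),
    )
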