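"""Actual NPP via the CASA light-use-efficiency model with a
classification-system water scalar.

Monthly NPP is the product of absorbed photosynthetically active
radiation and a realised light-use efficiency::

    NPP(x, t) = APAR(x, t) * xi(x, t)
    xi        = T_xi1 * T_xi2 * W_xi * xi_max

The water scalar W_xi is computed from the annual humidity index K and
accumulated temperature sum_theta (so it is constant within a pixel-year)
instead of the original soil-moisture sub-model; T_xi1/T_xi2 are the
standard CASA temperature stress terms around the optimum temperature
T_opt, taken as the mean temperature of the month with peak NDVI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .climate import annual_climate
from .io_config import RunConfig


def l_water(k):
    """Water-stress auxiliary L(K) = K + 0.906*K^(-1/2) + 0.22 for K > 0."""
    k = np.asarray(k, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(k > 0, k + 0.906 / np.sqrt(np.abs(k)) + 0.22, np.nan)
    return out if out.ndim else float(out)


def water_stress(k, sum_theta, clip: tuple[float, float] = (0.5, 1.0)):
    """Water scalar W_xi from annual K and sum_theta, clipped to ``clip``.

    W_xi = 0.5 + 0.5 * [(0.29 sqrt(K) + 0.6)(K L(K) + 0.469 K^(3/2) + 9.33/sum_theta)]
                     / [(K + 0.469 sqrt(K) + 0.966)(L(K) + 0.933/K)]

    The ratio tends to 0 as K -> 0+ (the 0.933/K term diverges), so W_xi
    tends to the lower bound; it grows without bound in K, hence the
    upper clip.  Invalid K or sum_theta yield NaN.
    """
    k = np.asarray(k, dtype=float)
    st = np.asarray(sum_theta, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sqrtk = np.sqrt(np.abs(k))
        lk = k + 0.906 / sqrtk + 0.22
        num = (0.29 * sqrtk + 0.6) * (k * lk + 0.469 * k * sqrtk + 9.33 / st)
        den = (k + 0.469 * sqrtk + 0.966) * (lk + 0.933 / k)
        w = 0.5 + 0.5 * num / den
        w = np.where((k > 0) & (st > 0), w, np.nan)
    w = np.clip(w, clip[0], clip[1])
    return w if w.ndim else float(w)


def temperature_stress(t_month, t_opt):
    """Standard CASA low/high temperature stress pair (T_xi1, T_xi2).

    T_xi1 = 0.8 + 0.02*T_opt - 0.0005*T_opt^2   (>= 0)
    T_xi2 = 1.1814 / ((1 + e^(0.2(T_opt - 10 - T))) (1 + e^(0.3(-T_opt - 10 + T))))
    """
    t = np.asarray(t_month, dtype=float)
    topt = np.asarray(t_opt, dtype=float)
    t1 = np.maximum(0.8 + 0.02 * topt - 0.0005 * topt**2, 0.0)
    t2 = 1.1814 / (
        (1.0 + np.exp(0.2 * (topt - 10.0 - t)))
        * (1.0 + np.exp(0.3 * (-topt - 10.0 + t)))
    )
    if t1.ndim == 0 and t2.ndim == 0:
        return float(t1), float(t2)
    return np.broadcast_to(t1, t2.shape).copy(), t2


def optimal_temperature(ndvi_monthly: np.ndarray, temp_monthly: np.ndarray) -> np.ndarray:
    """Per-pixel T_opt: temperature of the month with the year's peak NDVI.

    Inputs are one year of monthly grids, shape (12, rows, cols).
    """
    if ndvi_monthly.shape != temp_monthly.shape or ndvi_monthly.shape[0] != 12:
        raise ValueError("expected co-registered (12, rows, cols) cubes")
    filled = np.where(np.isnan(ndvi_monthly), -np.inf, ndvi_monthly)
    peak = np.argmax(filled, axis=0)  # all-NaN pixels fall back to month 1
    return np.take_along_axis(temp_monthly, peak[None], axis=0)[0]


def fpar(ndvi, cfg: RunConfig):
    """Fraction of absorbed PAR from NDVI by linear rescaling, clipped."""
    if cfg.ndvi_max == cfg.ndvi_min:
        raise ValueError("ndvi_max must differ from ndvi_min")
    frac = (np.asarray(ndvi, dtype=float) - cfg.ndvi_min) / (cfg.ndvi_max - cfg.ndvi_min)
    return np.clip(frac, cfg.fpar_min, cfg.fpar_max)


def apar(ndvi, solar, cfg: RunConfig):
    """Absorbed PAR (MJ m^-2 month^-1) = solar * fpar * PAR fraction."""
    return np.asarray(solar, dtype=float) * fpar(ndvi, cfg) * cfg.par_fraction


def actual_npp_monthly(apar_grid, xi):
    """Monthly NPP (g C m^-2 month^-1) = APAR * realised efficiency."""
    return np.asarray(apar_grid, dtype=float) * np.asarray(xi, dtype=float)


def actual_npp_annual(monthly: np.ndarray) -> np.ndarray:
    """Sum 12 monthly grids; a masked month masks the annual pixel."""
    monthly = np.asarray(monthly, dtype=float)
    if monthly.shape[0] != 12:
        raise ValueError(f"expected 12 monthly grids, got {monthly.shape[0]}")
    return np.sum(monthly, axis=0)


@dataclass
class ActualNpp:
    """Monthly and annual actual NPP plus the intermediate stress fields."""

    monthly: np.ndarray    # (years, 12, rows, cols), g C m^-2 month^-1
    annual: np.ndarray     # (years, rows, cols), g C m^-2 a^-1
    w_xi: np.ndarray       # (years, rows, cols)
    t_opt: np.ndarray      # (years, rows, cols)


def run_casa(
    temperature: np.ndarray,
    precip: np.ndarray,
    solar: np.ndarray,
    ndvi: np.ndarray,
    cfg: RunConfig | None = None,
) -> ActualNpp:
    """Actual NPP over monthly cubes of shape (years, 12, rows, cols)."""
    cfg = cfg or RunConfig()
    shapes = {a.shape for a in (temperature, precip, solar, ndvi)}
    if len(shapes) != 1:
        raise ValueError(f"input cubes differ in shape: {sorted(shapes)}")
    n_years = temperature.shape[0]
    ann = annual_climate(temperature, precip)
    w_xi = water_stress(ann.k, ann.sum_theta, cfg.w_clip)
    t_opt = np.stack(
        [optimal_temperature(ndvi[y], temperature[y]) for y in range(n_years)]
    )
    t1, t2 = temperature_stress(temperature, t_opt[:, None])
    xi = t1 * t2 * w_xi[:, None] * cfg.xi_max
    monthly = actual_npp_monthly(apar(ndvi, solar, cfg), xi)
    annual = np.stack([actual_npp_annual(monthly[y]) for y in range(n_years)])
    return ActualNpp(monthly=monthly, annual=annual, w_xi=w_xi, t_opt=t_opt)
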