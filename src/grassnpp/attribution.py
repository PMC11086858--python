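"""Residual-trend attribution of NPP change to climate and human drivers.

Human-induced NPP is the residual Nh = Np - Na between the climate-only
potential and the observed actual NPP.  Per-pixel least-squares slopes of
the three annual series (S_a, S_p, S_h) are combined into six driver
classes: restoration (S_a > 0) or degradation (S_a < 0) caused primarily
by human, climate, or joint climate-human factors.

Because the slope operator is linear, S_h = S_p - S_a identically.  The
published sign table for the six classes is stated in terms of S_h but its
triples are unreachable under that identity; the default
``residual_consistent`` mode therefore reads the table's human column as
the human-effect sign H = S_a - S_p (= -S_h), which makes all six classes
reachable and exhaustive.  The literal table is kept as an opt-in mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_config import GridSpec

UNCLASSIFIED = 0

CLASS_LABELS = {
    1: "restoration_human",
    2: "restoration_climate",
    3: "restoration_climate_human",
    4: "degradation_human",
    5: "degradation_climate",
    6: "degradation_climate_human",
}
RESTORED_CLASSES = (1, 2, 3)
DEGRADED_CLASSES = (4, 5, 6)

# literal sign triples (sign S_a, sign S_p, sign S_h) of the published table
TABLE_LITERAL = {
    (1, -1, 1): 1,
    (1, 1, -1): 2,
    (1, 1, 1): 3,
    (-1, 1, -1): 4,
    (-1, -1, 1): 5,
    (-1, -1, -1): 6,
}


def human_npp(np_potential, na_actual):
    """Human-induced NPP Nh = Np - Na (elementwise; NaN masks propagate)."""
    p = np.asarray(np_potential, dtype=float)
    a = np.asarray(na_actual, dtype=float)
    if p.shape != a.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {a.shape}")
    out = p - a
    return out if out.ndim else float(out)


def slope(series: np.ndarray, axis: int = 0) -> np.ndarray:
    """Least-squares trend slope of NPP against the year index i = 1..n.

    S = [n * sum(i * y_i) - sum(i) * sum(y_i)] / [n * sum(i^2) - (sum i)^2]

    Any NaN along ``axis`` makes the slope NaN there.
    """
    y = np.asarray(series, dtype=float)
    n = y.shape[axis]
    if n < 2:
        raise ValueError(f"need at least 2 years, got {n}")
    i = np.arange(1, n + 1, dtype=float)
    shape = [1] * y.ndim
    shape[axis] = n
    i = i.reshape(shape)
    num = n * np.sum(i * y, axis=axis) - np.sum(i) * np.sum(y, axis=axis)
    den = n * np.sum(i**2) - np.sum(i) ** 2
    out = num / den
    return out if np.ndim(out) else float(out)


@dataclass
class SlopeTriple:
    """Per-pixel trend slopes of actual, potential and human-induced NPP."""

    s_a: np.ndarray
    s_p: np.ndarray
    s_h: np.ndarray
    n_years: int


def slope_triple(na: np.ndarray, np_: np.ndarray, nh: np.ndarray | None = None) -> SlopeTriple:
    """Slopes of the three annual cubes (years, rows, cols)."""
    if nh is None:
        nh = human_npp(np_, na)
    return SlopeTriple(
        s_a=slope(na), s_p=slope(np_), s_h=slope(nh), n_years=na.shape[0]
    )


def classify(
    s_a,
    s_p,
    s_h=None,
    mode: str = "residual_consistent",
    epsilon: float = 0.0,
) -> np.ndarray:
    """Per-pixel driver class 1-6 (0 = unclassified) from the slope triple.

    ``residual_consistent`` (default): with H = S_a - S_p,
      restoration  (S_a > eps): 1 if S_p < -eps; 2 if S_p > eps and H < -eps;
                                3 if S_p > eps and H > eps
      degradation  (S_a < -eps): 4 if S_p > eps; 5 if S_p < -eps and H > eps;
                                 6 if S_p < -eps and H < -eps
    any deciding slope within eps of zero -> unclassified.

    ``table_literal``: exact sign lookup of the published triples in
    (S_a, S_p, S_h); triples absent from the table -> unclassified.
    """
    sa = np.asarray(s_a, dtype=float)
    sp = np.asarray(s_p, dtype=float)
    if s_h is None:
        sh = sp - sa
    else:
        sh = np.asarray(s_h, dtype=float)
    out = np.full(np.broadcast(sa, sp, sh).shape, UNCLASSIFIED, dtype=np.int8)
    if mode == "residual_consistent":
        h = sa - sp
        restored = sa > epsilon
        degraded = sa < -epsilon
        out[restored & (sp < -epsilon)] = 1
        out[restored & (sp > epsilon) & (h < -epsilon)] = 2
        out[restored & (sp > epsilon) & (h > epsilon)] = 3
        out[degraded & (sp > epsilon)] = 4
        out[degraded & (sp < -epsilon) & (h > epsilon)] = 5
        out[degraded & (sp < -epsilon) & (h < -epsilon)] = 6
    elif mode == "table_literal":
        for (za, zp, zh), cls in TABLE_LITERAL.items():
            mask = (
                (np.sign(sa) == za) & (np.abs(sa) > epsilon)
                & (np.sign(sp) == zp) & (np.abs(sp) > epsilon)
                & (np.sign(sh) == zh) & (np.abs(sh) > epsilon)
            )
            out[mask] = cls
    else:
        raise ValueError(f"unknown classification mode {mode!r}")
    out[np.isnan(sa) | np.isnan(sp) | np.isnan(sh)] = UNCLASSIFIED
    return out


def aggregate(
    condition_map: np.ndarray,
    mean_annual_na: np.ndarray,
    spec: GridSpec,
) -> pd.DataFrame:
    """Per-class pixel count, area share of its group, and NPP total.

    Area shares are percentages of the restored group (classes 1-3) or the
    degraded group (classes 4-6); NPP totals are sum(Na * pixel_area) in
    Gg C a^-1 over the class (1 Gg = 1e9 g), using the multi-year mean
    annual actual NPP per pixel.
    """
    if condition_map.shape != mean_annual_na.shape:
        raise ValueError("condition map and NPP grid differ in shape")
    rows = []
    n_restored = int(np.isin(condition_map, RESTORED_CLASSES).sum())
    n_degraded = int(np.isin(condition_map, DEGRADED_CLASSES).sum())
    for cls, label in CLASS_LABELS.items():
        mask = condition_map == cls
        count = int(mask.sum())
        group_n = n_restored if cls in RESTORED_CLASSES else n_degraded
        area_pct = 100.0 * count / group_n if group_n else np.nan
        npp_total = float(np.nansum(mean_annual_na[mask]) * spec.pixel_area / 1e9)
        rows.append(
            {
                "class": cls,
                "label": label,
                "pixel_count": count,
                "area_pct_of_group": area_pct,
                "npp_total_GgC": npp_total,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class Attribution:
    """Full attribution result for one run."""

    nh: np.ndarray            # (years, rows, cols)
    slopes: SlopeTriple
    condition_map: np.ndarray  # (rows, cols) int8
    summary: pd.DataFrame


def attribute(
    na: np.ndarray,
    np_: np.ndarray,
    spec: GridSpec,
    mode: str = "residual_consistent",
    epsilon: float = 0.0,
) -> Attribution:
    """Residual, slopes, classification and aggregation in one call."""
    nh = human_npp(np_, na)
    tri = slope_triple(na, np_, nh)
    cmap = classify(tri.s_a, tri.s_p, tri.s_h, mode=mode, epsilon=epsilon)
    summary = aggregate(cmap, np.nanmean(na, axis=0), spec)
    return Attribution(nh=nh, slopes=tri, condition_map=cmap, summary=summary)
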