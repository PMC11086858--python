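"""Climate-only (potential) NPP from annual precipitation and accumulated
temperature.

The closed form is the synthetic-vegetation NPP model

    Np = RDI^2 * P * (1 + RDI + RDI^2) / [(1 + RDI)(1 + RDI^2)] * exp(E)

expressed through the grassland-classification humidity index
k = P / (0.1 * sum_theta) with dryness index RDI = L(k) / k^3,
L(k) = 0.58802 k^3 + 0.50698 k^2 - 0.0257081 k + 0.0005163874.
Multiplying numerator and denominator by k^6 gives the equivalent form

    Np = L^2(k) * 0.1*sum_theta * [k^6 + L k^3 + L^2]
         / ([k^6 + L^2] [k^5 + L k^2]) * exp(E) * 100

(the factor 100 converts the model lineage's t DM hm^-2 a^-1 to g m^-2 a^-1).

The exponent E is available in several published/typeset readings that
cannot be told apart from degraded source material, so it lives behind a
registry of named variants.  :func:`select_variant` freezes one variant by
two gates: (a) Np non-decreasing in P over the study climate envelope,
(b) Np within the reported regional annual range [536.1, 812.1] g m^-2 a^-1
at the reported regional-mean climate.  Variants failing a gate are
rejected and the failure logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .climate import accumulated_temperature, humidity_index

log = logging.getLogger(__name__)

# regional-mean study climate used by the calibration gate: reported mean
# annual precipitation 448.2 mm; accumulated temperature derived from the
# reported mean annual temperature -2.1 degC with a 12.5 degC seasonal
# half-amplitude (see docs/methods.md)
CALIBRATION_PRECIP = 448.2
CALIBRATION_RANGE = (536.1, 812.1)
UNIT_SCALE = 100.0  # t DM hm^-2 a^-1 -> g m^-2 a^-1


def calibration_sum_theta(mean_annual_t: float = -2.1, amplitude: float = 12.5) -> float:
    """Accumulated temperature implied by a sinusoidal monthly climatology."""
    months = np.arange(1, 13)
    t_m = mean_annual_t + amplitude * np.cos(2 * np.pi * (months - 7) / 12.0)
    return float(accumulated_temperature(t_m, "monthly"))


def l_potential(k):
    """Cubic polynomial L(k) of the potential-NPP closed form."""
    k = np.asarray(k, dtype=float)
    out = 0.58802 * k**3 + 0.50698 * k**2 - 0.0257081 * k + 0.0005163874
    return out if out.ndim else float(out)


def _exp_inverse(k):
    return -13.55 + 3.17 / k - 0.16 / k**2 + 0.0032 / k**3


def _exp_literal(k):
    return -13.55 + 3.17 / k - 0.16 * k**2 + 0.0032 / k**3


def _exp_positive(k):
    return -13.55 + 3.17 * k - 0.16 * k**2 + 0.0032 * k**3


def _exp_mixed(k):
    return -13.55 + 3.17 * k - 0.16 * k**2 + 0.0032 / k**3


def _exp_dryness_sqrt(k):
    return -np.sqrt(9.87 + 6.25 * l_potential(k) / k**3)


#: exponent readings of the degraded print "e-13.55+3.17k-1-0.16k2+0.0032k-3";
#: ``dryness_sqrt`` is the unmodified exponent of the model lineage.
VARIANTS = {
    "inverse_poly": _exp_inverse,
    "literal": _exp_literal,
    "positive_poly": _exp_positive,
    "mixed_poly": _exp_mixed,
    "dryness_sqrt": _exp_dryness_sqrt,
}


def potential_npp(precip, sum_theta, variant: str = "mixed_poly"):
    """Potential NPP (g m^-2 a^-1) from annual P (mm) and sum_theta (degC d).

    P == 0 returns 0 by contract; sum_theta <= 0 is masked (NaN); negative
    or non-finite evaluations are clipped to 0.
    """
    if variant not in VARIANTS:
        raise KeyError(f"unregistered closed-form variant {variant!r}")
    p = np.asarray(precip, dtype=float)
    st = np.asarray(sum_theta, dtype=float)
    k = np.asarray(humidity_index(p, st), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        l = l_potential(k)
        num = k**6 + l * k**3 + l**2
        den = (k**6 + l**2) * (k**5 + l * k**2)
        e = np.exp(VARIANTS[variant](k))
        npp = UNIT_SCALE * l**2 * 0.1 * st * num / den * e
        npp = np.where(k > 0, npp, np.where(p == 0, 0.0, np.nan))
        npp = np.where(st > 0, npp, np.nan)
    n_neg = int(np.sum(npp < 0))
    if n_neg:
        log.warning("clipped %d negative potential-NPP evaluations to 0", n_neg)
    npp = np.where(npp < 0, 0.0, npp)
    npp = np.where(np.isinf(npp), 0.0, npp)
    return npp if npp.ndim else float(npp)


@dataclass
class VariantSelection:
    name: str
    value_at_calibration: float
    rejected: dict[str, str]


def select_variant(
    calib_precip: float = CALIBRATION_PRECIP,
    calib_sum_theta: float | None = None,
    value_range: tuple[float, float] = CALIBRATION_RANGE,
    precip_range: tuple[float, float] = (100.0, 500.0),
    sum_theta_range: tuple[float, float] = (800.0, 2000.0),
) -> VariantSelection:
    """Freeze one closed-form variant by the monotonicity and range gates.

    Raises ``RuntimeError`` if no variant survives both gates.  When more
    than one survives, the one closest to the centre of ``value_range`` is
    frozen (and the tie logged).
    """
    if calib_sum_theta is None:
        calib_sum_theta = calibration_sum_theta()
    ps = np.linspace(*precip_range, 81)
    sts = np.linspace(*sum_theta_range, 25)
    rejected: dict[str, str] = {}
    passed: dict[str, float] = {}
    for name in VARIANTS:
        vals = potential_npp(ps[None, :], sts[:, None] * np.ones_like(ps), name)
        if np.any(np.diff(vals, axis=1) < -1e-9):
            rejected[name] = "not non-decreasing in P over the study envelope"
            continue
        v = float(potential_npp(calib_precip, calib_sum_theta, name))
        if not value_range[0] <= v <= value_range[1]:
            rejected[name] = (
                f"calibration value {v:.1f} outside [{value_range[0]}, {value_range[1]}]"
            )
            continue
        passed[name] = v
    for name, why in rejected.items():
        log.info("variant %s rejected: %s", name, why)
    if not passed:
        raise RuntimeError(f"no closed-form variant passed both gates: {rejected}")
    centre = 0.5 * (value_range[0] + value_range[1])
    name = min(passed, key=lambda n: abs(passed[n] - centre))
    if len(passed) > 1:
        log.info("multiple variants passed %s; froze %s", sorted(passed), name)
    log.info("frozen potential-NPP variant: %s (%.1f g m^-2 a^-1 at calibration)",
             name, passed[name])
    return VariantSelection(name=name, value_at_calibration=passed[name],
                            rejected=rejected)


def run_potential(
    temperature: np.ndarray,
    precip: np.ndarray,
    variant: str = "auto",
) -> tuple[np.ndarray, str]:
    """Annual potential NPP over monthly cubes (years, 12, rows, cols).

    Returns the (years, rows, cols) cube and the frozen variant name.
    """
    from .climate import annual_climate

    ann = annual_climate(temperature, precip)
    if variant == "auto":
        variant = select_variant().name
    return potential_npp(ann.precip, ann.sum_theta, variant), variant
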