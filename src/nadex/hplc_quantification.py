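"""Through-origin HPLC calibration and quantification arithmetic.

Calibration curves for the licorice analytes are one-parameter lines
through the origin, C = k*S, with S the peak area (mAU*s) and C the
standard concentration (g/mL).  The module provides the least-squares
slope with its 95% half-width, LOD/LOQ by the ICH 3.3*sigma / 10*sigma
convention (the convention is a documented choice; printed assay limits
serve only as consistency checks), relative standard deviation, and
pharmacopoeia system-suitability threshold checks.

Chromatographic signal processing (peak detection, asymmetry, resolution)
is out of scope; those figures enter as user-supplied numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "SuitabilityLimits",
    "QuantResult",
    "fit_calibration",
    "quantify",
    "lod_loq",
    "rsd_percent",
    "suitability_check",
]


@dataclass(frozen=True)
class CalibrationCurve:
    slope: float  # g/(mL*mAU*s)
    slope_halfwidth: float
    analyte: str
    residual_sd: float  # g/mL
    lod: float | None  # None when residuals are exactly zero
    loq: float | None
    r2: float


@dataclass(frozen=True)
class SuitabilityLimits:
    """Pharmacopoeia system-suitability limits."""

    asymmetry_min: float = 0.8
    asymmetry_max: float = 1.5
    resolution_min: float = 1.5
    rsd_max_percent: float = 2.0
    r2_min: float = 0.98


@dataclass(frozen=True)
class QuantResult:
    concentration: float  # g/mL
    below_lod: bool
    below_loq: bool


def fit_calibration(pairs, analyte: str = "") -> CalibrationCurve:
    """Fit the through-origin slope k = sum(S*C)/sum(S**2).

    `pairs` is a sequence of (area mAU*s, concentration g/mL).  The 95%
    half-width comes from the slope standard error with n-1 residual
    degrees of freedom.  Degenerate inputs with exactly zero residuals
    yield LOD/LOQ of None.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need >= 3 (area, concentration) pairs")
    s, c = arr[:, 0], arr[:, 1]
    if np.all(s == 0):
        raise ValueError("all peak areas are zero; cannot calibrate")
    if np.any(s < 0):
        raise ValueError("peak areas must be > 0")
    n = len(s)
    k = float(np.sum(s * c) / np.sum(s * s))
    resid = c - k * s
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res < 1e-30 else 1.0 - ss_res / ss_tot
    sd = float(np.sqrt(ss_res / (n - 1)))
    se_k = sd / float(np.sqrt(np.sum(s * s)))
    halfwidth = float(stats.t.ppf(0.975, n - 1)) * se_k
    if sd > 0:
        lod, loq = lod_loq(sd)
    else:
        lod = loq = None
    return CalibrationCurve(
        slope=k,
        slope_halfwidth=halfwidth,
        analyte=analyte,
        residual_sd=sd,
        lod=lod,
        loq=loq,
        r2=r2,
    )


def quantify(area: float, curve: CalibrationCurve) -> QuantResult:
    """Concentration C = k*S, flagged when below the assay limits."""
    if area < 0:
        raise ValueError(f"area must be >= 0, got {area}")
    conc = curve.slope * area
    below_lod = curve.lod is not None and conc < curve.lod or (curve.lod is None and conc == 0)
    below_loq = curve.loq is not None and conc < curve.loq or (curve.loq is None and conc == 0)
    return QuantResult(concentration=conc, below_lod=below_lod, below_loq=below_loq)


def lod_loq(residual_sd: float) -> tuple[float, float]:
    """(LOD, LOQ) = (3.3*sigma, 10*sigma) on the concentration scale."""
    if not residual_sd > 0:
        raise ValueError(f"residual sd must be > 0, got {residual_sd}")
    return 3.3 * residual_sd, 10.0 * residual_sd


def rsd_percent(values) -> float:
    """Relative standard deviation, % = 100 * sample sd / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need >= 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("zero mean: RSD undefined")
    return float(100.0 * arr.std(ddof=1) / mean)


def suitability_check(
    asymmetry: float,
    resolution: float,
    rsd: float,
    r2: float,
    limits: SuitabilityLimits = SuitabilityLimits(),
) -> dict[str, bool]:
    """Per-criterion pass/fail against the pharmacopoeia limits.

    RSD and r² bounds are inclusive; the overall verdict requires every
    criterion to pass.
    """
    checks = {
        "asymmetry": limits.asymmetry_min <= asymmetry <= limits.asymmetry_max,
        "resolution": resolution >= limits.resolution_min,
        "rsd": rsd <= limits.rsd_max_percent,
        "r2": r2 >= limits.r2_min,
    }
    checks["overall"] = all(checks.values())
    return checks
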