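"""Equilibrium partition model of extraction driven by solvent polarity.

At equilibrium the fraction of a biologically active substance (BAS)
transferred from plant raw material into the solvent follows a Boltzmann
(two-level, Fermi–Dirac-shaped) partition law

    n/n0 = C*V/m0 = 1 / (1 + exp(y)),      y = Delta_mu/(R*T) + const,

where C is the measured concentration (g/mL), V the solvent volume (mL)
and m0 the total extractable BAS mass (g).  The reduced transfer
potential y is modeled as a quadratic in the reciprocal dielectric
constant of the solvent,

    y = b/eps**2 + d/eps + f,

so that ln(m0/(C*V) - 1) plotted against 1/eps is a second-order
polynomial.  For b > 0 and d < 0 the potential has an interior minimum at
1/eps = -d/(2b), i.e. the concentration is maximal at eps* = -2b/d: the
analytically optimal solvent polarity.

Units follow laboratory practice (g, mL, K) throughout; no SI
normalization is applied, so printed values are directly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

__all__ = [
    "GAS_CONSTANT",
    "ExtractionSystem",
    "ExtractionObservation",
    "ModelParams",
    "extracted_fraction",
    "transform_y",
    "inverse_transform",
    "reduced_potential",
    "predict_concentration",
    "optimal_epsilon",
    "chemical_potential_change",
]

#: Gas constant, J/(K*mol).
GAS_CONSTANT = 8.314

# relative slack on the domain guard C*V < m0, to avoid log-domain errors
# introduced by rounding
_DOMAIN_SLACK = 1e-12


@dataclass(frozen=True)
class ExtractionSystem:
    """One maceration setup.

    Parameters
    ----------
    m0 : float
        Total extractable BAS mass in the system, g.  Treated as a known
        (or synthetic-truth) calibration input; fits condition on it.
    V : float
        Solvent volume, mL.
    T : float
        Absolute temperature, K.
    ratio_note : str
        Raw-material:solvent w/v label, metadata only (e.g. "1:10 w/v").
    """

    m0: float
    V: float
    T: float
    ratio_note: str = ""

    def __post_init__(self) -> None:
        for field_name in ("m0", "V", "T"):
            if not getattr(self, field_name) > 0:
                raise ValueError(f"{field_name} must be > 0, got {getattr(self, field_name)}")


@dataclass(frozen=True)
class ExtractionObservation:
    """One (ε, C) measurement point for one analyte."""

    epsilon: float
    concentration: float
    analyte: str = ""
    solvent_label: str = ""

    def __post_init__(self) -> None:
        if not self.epsilon >= 1:
            raise ValueError(f"epsilon must be >= 1, got {self.epsilon}")
        if not self.concentration > 0:
            raise ValueError(f"concentration must be > 0, got {self.concentration}")


@dataclass(frozen=True)
class ModelParams:
    """Empirical constants (b, d, f) of the reduced transfer potential.

    f absorbs the additive constant of the partition law: only the sum is
    identifiable from (ε, C) data, so no separate constant is stored.
    An interior concentration maximum requires b > 0 and d < 0.
    """

    b: float
    d: float
    f: float

    def __post_init__(self) -> None:
        for field_name in ("b", "d", "f"):
            if not math.isfinite(getattr(self, field_name)):
                raise ValueError(f"{field_name} must be finite")

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParams":
        return cls(b=d["b"], d=d["d"], f=d["f"])


def _checked_fraction(obs: ExtractionObservation, sys: ExtractionSystem) -> float:
    frac = obs.concentration * sys.V / sys.m0
    if frac >= 1.0 - _DOMAIN_SLACK:
        raise ValueError(
            f"C*V = {obs.concentration * sys.V:g} g is not below m0 = {sys.m0:g} g: "
            "extracted more than present"
        )
    return frac


def extracted_fraction(obs: ExtractionObservation, sys: ExtractionSystem) -> float:
    """Fraction n/n0 = C*V/m0 of the BAS transferred into the liquid phase."""
    return _checked_fraction(obs, sys)


def transform_y(obs: ExtractionObservation, sys: ExtractionSystem) -> float:
    """Reduced transfer potential y = ln(m0/(C*V) - 1) of one observation.

    This is the linearizing transform: y equals Delta_mu/(R*T) up to the
    absorbed constant, and is the regression response in the quadratic
    fit against 1/ε.
    """
    frac = _checked_fraction(obs, sys)
    return math.log(1.0 / frac - 1.0)


def inverse_transform(y: float, sys: ExtractionSystem) -> float:
    """Concentration C = m0 / (V*(1 + e^y)); always inside (0, m0/V)."""
    if not math.isfinite(y):
        raise ValueError(f"y must be finite, got {y}")
    if y > 0:  # overflow-safe logistic branch
        e = math.exp(-y)
        return sys.m0 * e / (sys.V * (1.0 + e))
    return sys.m0 / (sys.V * (1.0 + math.exp(y)))


def reduced_potential(params: ModelParams, epsilon: float) -> float:
    """y(ε) = b/ε² + d/ε + f — quadratic in x = 1/ε."""
    if not epsilon >= 1:
        raise ValueError(f"epsilon must be >= 1, got {epsilon}")
    x = 1.0 / epsilon
    return params.b * x * x + params.d * x + params.f


def predict_concentration(params: ModelParams, epsilon: float, sys: ExtractionSystem) -> float:
    """Forward model: equilibrium concentration at a given ε."""
    return inverse_transform(reduced_potential(params, epsilon), sys)


def optimal_epsilon(params: ModelParams) -> float:
    """Dielectric constant maximizing the equilibrium concentration.

    The potential y is minimal at x* = -d/(2b), hence ε* = -2b/d.
    Requires an interior optimum at positive x: b > 0 and d < 0.
    Independent of f.
    """
    if not params.b > 0:
        raise ValueError(f"no interior optimum: requires b > 0, got b = {params.b}")
    if not params.d < 0:
        raise ValueError(f"no interior optimum: requires d < 0, got d = {params.d}")
    return -2.0 * params.b / params.d


def chemical_potential_change(y: float, sys: ExtractionSystem) -> float:
    """Transfer chemical potential Delta_mu = y*R*T, J/mol."""
    return y * GAS_CONSTANT * sys.T
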