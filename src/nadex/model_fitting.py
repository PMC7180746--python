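"""Quadratic regression in transformed coordinates and adequacy testing.

The transformed response y_i = ln(m0/(C_i*V) - 1) is regressed on
x_i = 1/eps_i with the basis (x², x, 1) by ordinary least squares (the
study design states no weighting).  Model adequacy is judged by comparing
the coefficient of determination R²_e of the fit against a critical value
R²_t derived from the F distribution at the chosen acceptance probability;
the model is adequate iff R²_e > R²_t (strict).

The uncertainty of the optimal dielectric constant ε* = -2b/d is attached
by a residual-resampling bootstrap, which is robust at the very small n
(five solvents) typical of these designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial
from scipy import stats

from .partition_model import (
    ExtractionObservation,
    ExtractionSystem,
    ModelParams,
    optimal_epsilon,
    transform_y,
)

__all__ = [
    "ModelFit",
    "BootstrapResult",
    "fit_transformed_quadratic",
    "r_squared",
    "critical_r_squared",
    "adequacy_decision",
    "epsilon_opt_uncertainty",
]


@dataclass
class ModelFit:
    """Result of fitting the quadratic-in-1/ε model to one analyte."""

    params: ModelParams
    r2_e: float
    r2_t: float
    n: int
    alpha: float
    p: int
    adequate: bool
    epsilon_opt: float | None
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    y_hat: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    analyte: str = ""
    epsilon_opt_halfwidth: float | None = None

    def to_dict(self) -> dict:
        """JSON-serializable fit report."""
        return {
            "analyte": self.analyte,
            "b": self.params.b,
            "d": self.params.d,
            "f": self.params.f,
            "r2_e": self.r2_e,
            "r2_t": self.r2_t,
            "adequate": self.adequate,
            "epsilon_opt": self.epsilon_opt,
            "epsilon_opt_halfwidth": self.epsilon_opt_halfwidth,
            "n": self.n,
            "alpha": self.alpha,
            "p": self.p,
        }


def r_squared(y_obs, y_fit) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot."""
    y_obs = np.asarray(y_obs, dtype=float)
    y_fit = np.asarray(y_fit, dtype=float)
    if y_obs.shape != y_fit.shape or y_obs.ndim != 1 or y_obs.size < 2:
        raise ValueError("y_obs and y_fit must be equal-length 1-d arrays with >= 2 points")
    ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("undefined variance: y_obs is constant")
    ss_res = float(np.sum((y_obs - y_fit) ** 2))
    return 1.0 - ss_res / ss_tot


def critical_r_squared(n: int, alpha: float = 0.01, p: int = 1) -> float:
    """Critical (table) determination coefficient R²_t.

    R²_t = p*F / (p*F + n - p - 1) with F the upper-alpha quantile of
    F(p, n-p-1).  The default p = 1 reproduces the classical critical
    simple-correlation table (for n = 5, alpha = 0.01 this gives 0.919);
    p = 2 is the statistically stricter convention for the two non-constant
    regressors of the quadratic model.
    """
    df2 = n - p - 1
    if df2 < 1:
        raise ValueError(f"invalid degrees of freedom: n - p - 1 = {df2} < 1")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    f_crit = float(stats.f.ppf(1.0 - alpha, p, df2))
    return p * f_crit / (p * f_crit + df2)


def _quadratic_ols(x: np.ndarray, y: np.ndarray) -> tuple[ModelParams, np.ndarray]:
    # Polynomial.fit maps x onto [-1, 1] internally, keeping the normal
    # equations well conditioned for the narrow 1/eps range (~0.016-0.04)
    poly = Polynomial.fit(x, y, deg=2).convert()
    f_, d_, b_ = poly.coef
    y_hat = poly(x)
    return ModelParams(b=float(b_), d=float(d_), f=float(f_)), y_hat


def fit_transformed_quadratic(
    observations: list[ExtractionObservation],
    sys: ExtractionSystem,
    alpha: float = 0.01,
    p: int = 1,
    analyte: str = "",
) -> ModelFit:
    """Fit y = b*x² + d*x + f to transformed observations (x = 1/ε).

    Requires at least 4 observations (one residual degree of freedom
    beyond the 3 parameters) and at least 3 distinct ε values so the
    design has full rank.  Returns the fitted parameters, R²_e against
    the critical R²_t, and ε* = -2b/d when the interior optimum exists.
    """
    n = len(observations)
    if n < 4:
        raise ValueError(f"need >= 4 observations for a 3-parameter fit, got {n}")
    eps = np.array([o.epsilon for o in observations], dtype=float)
    if len(np.unique(eps)) < 3:
        raise ValueError(
            "rank-deficient design: need >= 3 distinct epsilon values, "
            f"got {len(np.unique(eps))}"
        )
    x = 1.0 / eps
    y = np.array([transform_y(o, sys) for o in observations], dtype=float)
    params, y_hat = _quadratic_ols(x, y)
    r2_e = r_squared(y, y_hat)
    r2_t = critical_r_squared(n, alpha=alpha, p=p)
    try:
        eps_opt = optimal_epsilon(params)
    except ValueError:
        eps_opt = None
    return ModelFit(
        params=params,
        r2_e=r2_e,
        r2_t=r2_t,
        n=n,
        alpha=alpha,
        p=p,
        adequate=r2_e > r2_t,
        epsilon_opt=eps_opt,
        x=x,
        y=y,
        y_hat=y_hat,
        residuals=y - y_hat,
        analyte=analyte,
    )


def adequacy_decision(fit: ModelFit) -> tuple[bool, dict]:
    """Adequacy verdict R²_e > R²_t (strict), with an echo report."""
    verdict = fit.r2_e > fit.r2_t
    report = {
        "adequate": verdict,
        "r2_e": fit.r2_e,
        "r2_t": fit.r2_t,
        "n": fit.n,
        "alpha": fit.alpha,
        "p": fit.p,
    }
    return verdict, report


@dataclass
class BootstrapResult:
    """Bootstrap distribution summary for the optimal ε."""

    halfwidth: float
    n_boot: int
    n_dropped: int
    degenerate_warning: bool
    epsilon_opt_samples: np.ndarray = field(repr=False)


def epsilon_opt_uncertainty(
    fit: ModelFit,
    observations: list[ExtractionObservation],
    sys: ExtractionSystem,
    n_boot: int = 2000,
    seed: int = 0,
) -> BootstrapResult:
    """Residual-resampling bootstrap half-width for ε*.

    Each replicate refits the quadratic to y_hat plus residuals resampled
    with replacement; replicates without an interior optimum (b <= 0 or
    d >= 0) are dropped and counted, with a warning flag when more than
    half are lost.  The half-width is half the central 95% interval of
    the bootstrap ε* distribution; deterministic under a fixed seed.
    """
    if fit.epsilon_opt is None:
        raise ValueError("fit has no interior optimum; nothing to bootstrap")
    rng = np.random.default_rng(seed)
    n = fit.n
    samples = []
    dropped = 0
    for _ in range(n_boot):
        y_b = fit.y_hat + rng.choice(fit.residuals, size=n, replace=True)
        params_b, _ = _quadratic_ols(fit.x, y_b)
        if params_b.b > 0 and params_b.d < 0:
            samples.append(-2.0 * params_b.b / params_b.d)
        else:
            dropped += 1
    degenerate = dropped > n_boot // 2
    if degenerate:
        warnings.warn(
            f"{dropped}/{n_boot} bootstrap replicates lacked an interior optimum",
            stacklevel=2,
        )
    arr = np.asarray(samples, dtype=float)
    lo, hi = np.percentile(arr, [2.5, 97.5])
    result = BootstrapResult(
        halfwidth=float((hi - lo) / 2.0),
        n_boot=n_boot,
        n_dropped=dropped,
        degenerate_warning=degenerate,
        epsilon_opt_samples=arr,
    )
    fit.epsilon_opt_halfwidth = result.halfwidth
    return result
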