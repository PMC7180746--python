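# Methods

## Model and assumptions

The package treats equilibrium solid–liquid extraction as a two-state
partition problem: each analyte molecule is either bound in the plant
matrix or dissolved in the solvent, and the occupancy of the dissolved
state follows a Boltzmann law with a single transfer free energy.  The
extracted fraction is

    n/n0 = C·V/m0 = 1/(1 + exp(y)),    y = Δμ/(RT) + a,

a logistic (Fermi–Dirac-shaped) function of the reduced transfer
potential y.  The solvent enters only through its static dielectric
constant ε: the electrostatic contribution to the transfer energy is
modeled as a quadratic in 1/ε,

    y = b/ε² + d/ε + f.

Assumptions worth stating explicitly:

- **Equilibrium only.**  Kinetics (diffusion, particle size, agitation)
  are outside the model; the data are assumed to be taken after the
  system has equilibrated (24 h maceration in the motivating study).
- **Single descriptor.**  All solvent effects beyond ε (viscosity,
  hydrogen-bond donation, specific complexation) are absorbed into the
  empirical constants; systematic departures of individual solvents
  (as observed for eutectic mixtures vs. the sorbitol:ethanol:water
  series) appear as residuals, not model terms.
- **Known m0.**  The total extractable mass m0 is a calibration input:
  fits condition on it, and the transform ln(m0/(C·V) − 1) is only
  defined for 0 < C·V < m0.  The package enforces this with strict
  inequalities plus a relative slack of 1e−12 against log-domain errors
  from rounding.
- **Identifiability.**  The additive constant `a` of the partition law
  and the intercept of the quadratic cannot be separated from (ε, C)
  data; `f` absorbs both and no separate `a` is stored.

Units are laboratory units throughout (C in g/mL, V in mL, m0 in g,
T in K, R = 8.314 J/(K·mol)); no SI normalization is applied, so printed
values round-trip exactly.

## Fitting and adequacy

The transformed response y_i is regressed on x_i = 1/ε_i with the basis
(x², x, 1) by unweighted ordinary least squares — the study design
states no weighting, and the default synthetic noise model is
homoscedastic in y.  The fit is computed with a scaled-domain polynomial
least squares (`numpy.polynomial.Polynomial.fit`), which keeps the
normal equations well conditioned despite the narrow x range
(≈0.016–0.038); the test suite cross-checks the coefficients against an
independent statsmodels OLS on the raw design matrix.

A valid design needs n ≥ 4 observations (one residual degree of freedom
beyond the three parameters) and at least three distinct ε values;
replicate ε values are otherwise allowed.

**Adequacy** is decided by R²_e > R²_t (strict).  The critical value is

    R²_t = p·F_crit / (p·F_crit + n − p − 1),

with F_crit the upper-α quantile of F(p, n−p−1) and α = 0.01 by default
("99% acceptance probability").  The default convention is **p = 1**,
which reproduces the classical critical-correlation table entry 0.919
for n = 5 — the convention used when such five-point polarity designs
are judged.  The statistically stricter p = 2 (two non-constant
regressors) is available as an argument; it raises R²_t (to 0.990 at
n = 5, α = 0.01) and is the defensible modern choice when not anchoring
to table values.

**Optimal ε.**  For b > 0 and d < 0 the concentration maximum is at
ε* = −2b/d, independent of f.  Its uncertainty is attached by a residual
bootstrap: refit on ŷ + resampled residuals (2000 replicates by
default, seeded, bit-reproducible), drop replicates without an interior
optimum (counted; a flag is raised when more than half are lost), and
report half the central 95% interval of the bootstrap ε* distribution.
The bootstrap was chosen over the delta method because it remains usable
at n = 5, where the normal approximation for a ratio of coefficients is
poor.  Published ±-style intervals for ε* in this literature come with
no stated method; the bootstrap is this package's own convention, not a
reproduction.

## Solvent formulation

Mole ratios convert to mass fractions via w_i = r_i·M_i / Σ r_j·M_j
with fixed two-decimal molar masses (sorbitol 182.17, malic acid 134.09,
water 18.015, glycerin 92.09, ethanol 46.07 g/mol).  The inverse
conversion normalizes so the smallest mole count is 1; the two maps are
mutual inverses to 1e−9 relative.

The shipped registry (`data/solvent_registry.csv`) stores the seven
study solvents with their measured mass percentages, densities and
dielectric constants.  A known tension: the printed contents are
*measured* (weighed, n = 3 with stated half-widths), so they do not
coincide exactly with molar arithmetic — the 1:1:3 NADES computes to
sorbitol 49.2 / water 14.6 %wt against printed 49.0 / 15.0, and the
1:1:1:1 modified NADES computes to malic acid 31.45 vs printed 31.5.
The conversion functions always report the computed values; the registry
preserves the printed ones.

Along the sorbitol:ethanol:water series, ε is piecewise-linear and
monotone in the sorbitol mass fraction (the monotone axis of the five
tabulated rows, ε = 26…61).  `composition_for_epsilon` inverts this map
and interpolates all three mass fractions linearly between the
bracketing rows, so designed compositions sum to 1 and round-trip
through `epsilon_interpolate` exactly.  No extrapolation is permitted on
either side: the ε values come from an external measurement series and
the model is validated only inside it.  The ε uncertainties of the two
eutectic rows (±2) are stored as symmetric half-widths and never
propagated implicitly.

## HPLC calibration arithmetic

Calibration is through-origin, C = k·S, because the assay is reported
as a one-parameter equation: k = Σ S·C / Σ S², residual degrees of
freedom n − 1, 95% slope half-width from the t distribution.  LOD/LOQ
use the ICH 3.3σ/10σ convention on the concentration scale — the assay
limits in the motivating study are printed without a formula, and the
3.3σ reading reproduces the printed licuroside LOQ to two significant
figures, which the tests use as a consistency check only.  Degenerate
inputs with exactly zero residual scatter give residual_sd = 0 and
LOD/LOQ of None.  Peak asymmetry and resolution are accepted as numbers;
chromatogram processing is out of scope.

## Synthetic data

The generator emulates the five-solvent study design: ε grid
{26, 34, 41, 50, 61}, system m0 = 0.01 g, V = 10 mL, T = 298.15 K
(1:10 w/v maceration at 25 °C), one replicate per solvent.  Default
truth places the optimum at ε* = 45 — the center of the reported
optimal range 40–50 — with curvature b = 17400, d = −2b/45, and f set
so the vertex potential is 1 (extracted fraction ≈ 0.27 at the
optimum).  Under these parameters the concentration spans roughly two
orders of magnitude across the grid, matching the qualitative spread of
the experimental figures.

Noise defaults to Gaussian on the transformed coordinate
(σ_y = 0.05), which is homoscedastic in the regression's own
coordinates and guarantees domain-valid concentrations.
Concentration-space alternatives (additive Gaussian, multiplicative
lognormal) exercise robustness; out-of-domain draws are truncated into
(0, m0/V), counted, and flagged when more than 10% of draws were
clipped — truncation rather than resampling keeps the draw count fixed
and the distortion visible.  A seed is mandatory whenever σ > 0 and all
output is bit-reproducible under it.

What passing synthetic tests do **not** show about real data: the
generator has no solvent-specific chemistry (eutectic departures from
the series), no replicate structure beyond i.i.d. noise, no m0
uncertainty, and no HPLC quantification error feeding into C.  Recovery
statistics (|bias(ε*)| ≪ 1 unit, adequacy rate ≈ 100% at σ_y = 0.05,
200 studies) certify the estimator pipeline, not the physical model.

## Numerical choices

- Logistic inversion uses the overflow-safe branch
  C = m0·e^(−y)/(V·(1+e^(−y))) for y > 0; for |y| ≳ 745 the predicted
  concentration underflows to 0 or saturates at m0/V in double
  precision, which is far outside any physical ε for the default
  parameters.
- Transform/inverse-transform round-trip is exact to 1e−12 relative on
  (0, m0/V); the domain guard rejects C·V within 1e−12 relative of m0.
- Brute-force verification of ε* uses a 0.001-step ε grid; agreement
  with −2b/d is then limited by grid resolution (≤ 5e−4 observed).
- The recovery experiment spawns per-study seeds deterministically from
  the master seed via `numpy.random.SeedSequence`.
- Problem sizes in the shipped checks — 200 recovery studies, 50
  brute-force parameter draws, 2000 bootstrap replicates — were chosen
  as the smallest sizes at which the reported statistics are stable to
  well under their decision margins.

## Known limitations

- ε must be known for every solvent; the package interpolates it only
  along the tabulated sorbitol:ethanol:water series and refuses to
  predict ε of arbitrary mixtures.
- m0 is an input, not an estimate; misspecifying it biases the
  transform nonlinearly.
- The adequacy test with p = 1 is anchored to the classical table
  convention and is lenient for a three-parameter model; use p = 2 for
  a conservative verdict.
- Each analyte is fitted independently; no joint or hierarchical
  modeling across analytes or temperatures.
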