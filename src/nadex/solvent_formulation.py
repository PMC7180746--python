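"""Solvent recipes, mole/mass conversions, and the dielectric-constant registry.

A solvent is described either as a *recipe* (components with mole ratios,
the way deep-eutectic solvents are prescribed, e.g. sorbitol:malic
acid:water 1:1:3) or as a *composition* (mass fractions, the way a mixture
is actually weighed out).  The two views are related through the molar
masses of the components and are mutual inverses.

The module also ships a small registry of sorbitol-based solvents — five
sorbitol:ethanol:water mixtures spanning dielectric constants 26–61, a
sorbitol NADES (ε = 33 ± 2) and a glycerin-modified NADES (ε = 41 ± 2) —
with measured density and relative permittivity for each, and exposes a
piecewise-linear map between sorbitol mass fraction and ε along the
sorbitol:ethanol:water series, in both directions.  The inverse direction
supports target-oriented solvent design: given a desired ε (for instance
the fitted optimum of an extraction model) it returns the composition to
weigh out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "MOLAR_MASSES",
    "Component",
    "SolventRecipe",
    "Composition",
    "component",
    "mole_ratio_to_mass_fractions",
    "mass_fractions_to_mole_ratio",
    "registry_table",
    "epsilon_registry",
    "epsilon_interpolate",
    "composition_for_epsilon",
]

#: IUPAC molar masses, g/mol, two decimals.
MOLAR_MASSES: dict[str, float] = {
    "sorbitol": 182.17,
    "malic_acid": 134.09,
    "water": 18.015,
    "glycerin": 92.09,
    "ethanol": 46.07,
}

_FRACTION_SUM_TOL = 1e-9


@dataclass(frozen=True)
class Component:
    """A pure chemical component with its molar mass in g/mol."""

    name: str
    molar_mass: float

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ValueError(f"molar_mass of {self.name!r} must be > 0, got {self.molar_mass}")


def component(name: str) -> Component:
    """Look up a built-in component by name.

    Raises
    ------
    ValueError
        If the component has no registered molar mass; the message names it.
    """
    try:
        return Component(name, MOLAR_MASSES[name])
    except KeyError:
        known = ", ".join(sorted(MOLAR_MASSES))
        raise ValueError(
            f"unknown component {name!r}: no molar mass registered (known: {known})"
        ) from None


@dataclass(frozen=True)
class SolventRecipe:
    """A solvent as an ordered list of (component, mole ratio) parts."""

    parts: tuple[tuple[Component, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.parts) == 0:
            raise ValueError("recipe needs at least one part")
        for comp, ratio in self.parts:
            if not ratio > 0:
                raise ValueError(f"mole ratio of {comp.name!r} must be > 0, got {ratio}")


@dataclass(frozen=True)
class Composition:
    """A solvent as an ordered list of (component, mass fraction) parts.

    Optionally carries the measured density (g/mL) and dielectric constant
    ε (with a symmetric half-width uncertainty where one was reported).
    """

    parts: tuple[tuple[Component, float], ...]
    density: float | None = None
    epsilon: float | None = None
    epsilon_halfwidth: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.parts) == 0:
            raise ValueError("composition needs at least one part")
        total = 0.0
        any_positive = False
        for comp, w in self.parts:
            # zero fractions are tolerated as degenerate placeholders; the
            # recipe conversion drops them with a warning
            if not 0 <= w <= 1:
                raise ValueError(f"mass fraction of {comp.name!r} must be in [0, 1], got {w}")
            any_positive = any_positive or w > 0
            total += w
        if not any_positive:
            raise ValueError("composition needs at least one positive mass fraction")
        if abs(total - 1.0) > _FRACTION_SUM_TOL:
            raise ValueError(f"mass fractions must sum to 1 (got {total!r})")
        if self.density is not None and not self.density > 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if self.epsilon is not None and not self.epsilon >= 1:
            raise ValueError(f"epsilon must be >= 1, got {self.epsilon}")

    def mass_fraction(self, name: str) -> float:
        """Mass fraction of the named component (0.0 if absent)."""
        for comp, w in self.parts:
            if comp.name == name:
                return w
        return 0.0


def mole_ratio_to_mass_fractions(recipe: SolventRecipe) -> Composition:
    """Convert a mole-ratio recipe to mass fractions.

    w_i = r_i * M_i / sum_j r_j * M_j — e.g. the 1:1:1:1
    sorbitol:malic acid:water:glycerin recipe gives 42.7/31.5/4.2/21.6 %wt.
    """
    masses = [(comp, ratio * comp.molar_mass) for comp, ratio in recipe.parts]
    total = sum(m for _, m in masses)
    parts = tuple((comp, m / total) for comp, m in masses)
    return Composition(parts=parts, label=recipe.label)


def mass_fractions_to_mole_ratio(composition: Composition) -> SolventRecipe:
    """Convert mass fractions back to mole ratios, smallest ratio scaled to 1.

    Parts with zero mass fraction cannot occur inside a valid
    :class:`Composition`; if a raw (component, 0.0) pair is passed through
    the keyword-free path it is dropped with a warning upstream.  The
    round trip with :func:`mole_ratio_to_mass_fractions` is exact to
    1e-9 relative.
    """
    moles = []
    for comp, w in composition.parts:
        if w == 0:
            warnings.warn(f"dropping zero-mass-fraction part {comp.name!r}", stacklevel=2)
            continue
        moles.append((comp, w / comp.molar_mass))
    smallest = min(n for _, n in moles)
    parts = tuple((comp, n / smallest) for comp, n in moles)
    return SolventRecipe(parts=parts, label=composition.label)


# ---------------------------------------------------------------------------
# Registry of sorbitol-based solvents

_COMPONENT_COLUMNS = {
    "sorbitol": "sorbitol_pct",
    "ethanol": "ethanol_pct",
    "water": "water_pct",
    "malic_acid": "malic_acid_pct",
    "glycerin": "glycerin_pct",
}

_ALIASES = {"NADES": "6", "NADES-mod": "7"}


def registry_table() -> pd.DataFrame:
    """The shipped solvent registry as a DataFrame (one row per solvent)."""
    with resources.files("nadex.data").joinpath("solvent_registry.csv").open() as fh:
        return pd.read_csv(fh, dtype={"label": str})


def _row_to_composition(row: pd.Series) -> Composition:
    parts = []
    for name, col in _COMPONENT_COLUMNS.items():
        pct = float(row[col])
        if pct > 0:
            parts.append((component(name), pct / 100.0))
    halfwidth = float(row["epsilon_halfwidth"]) if pd.notna(row["epsilon_halfwidth"]) else None
    return Composition(
        parts=tuple(parts),
        density=float(row["density_g_per_ml"]),
        epsilon=float(row["epsilon"]),
        epsilon_halfwidth=halfwidth,
        label=str(row["label"]),
    )


def epsilon_registry(label: str | int) -> Composition:
    """Return the registered solvent composition for a label ("1".."7").

    The aliases ``"NADES"`` (the 1:1:3 sorbitol:malic acid:water eutectic)
    and ``"NADES-mod"`` (the 1:1:1:1 glycerin-modified variant) map to
    rows 6 and 7.
    """
    table = registry_table()
    key = _ALIASES.get(str(label), str(label))
    match = table[table["label"] == key]
    if match.empty:
        valid = ", ".join(list(table["label"]) + list(_ALIASES))
        raise ValueError(f"unknown solvent label {label!r}; valid labels: {valid}")
    return _row_to_composition(match.iloc[0])


def _series_nodes() -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Sorbitol-fraction and ε nodes of the sorbitol:ethanol:water series."""
    table = registry_table()
    series = table[table["malic_acid_pct"] == 0].sort_values("epsilon")
    s = series["sorbitol_pct"].to_numpy(float) / 100.0
    eps = series["epsilon"].to_numpy(float)
    return s, eps, series


def epsilon_interpolate(sorbitol_mass_fraction: float) -> float:
    """Dielectric constant along the sorbitol:ethanol:water series.

    Piecewise-linear and monotone in the sorbitol mass fraction (the
    monotone axis of the series), exact at the five measured nodes.
    No extrapolation: the ε data come from an external measurement series
    and the map is only trusted inside it.
    """
    s, eps, _ = _series_nodes()
    x = float(sorbitol_mass_fraction)
    if not s[0] <= x <= s[-1]:
        raise ValueError(
            f"sorbitol mass fraction {x} outside tabulated range [{s[0]}, {s[-1]}]"
        )
    return float(np.interp(x, s, eps))


def composition_for_epsilon(target_epsilon: float) -> Composition:
    """Design a sorbitol:ethanol:water composition with a target ε.

    Inverts :func:`epsilon_interpolate`: all three mass fractions are
    interpolated linearly between the bracketing registry rows, so
    ``epsilon_interpolate`` of the returned sorbitol fraction reproduces
    the target exactly.
    """
    s, eps, series = _series_nodes()
    t = float(target_epsilon)
    if not eps[0] <= t <= eps[-1]:
        raise ValueError(f"target epsilon {t} outside tabulated range [{eps[0]}, {eps[-1]}]")
    i = int(np.searchsorted(eps, t, side="right") - 1)
    i = min(i, len(eps) - 2)
    frac = (t - eps[i]) / (eps[i + 1] - eps[i])
    parts = []
    for name, col in _COMPONENT_COLUMNS.items():
        lo = float(series.iloc[i][col]) / 100.0
        hi = float(series.iloc[i + 1][col]) / 100.0
        w = (1 - frac) * lo + frac * hi
        if w > 0:
            parts.append((component(name), w))
    return Composition(parts=tuple(parts), epsilon=t, label=f"designed eps={t:g}")
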