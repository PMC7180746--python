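"""Reproducible analysis pipeline: transform -> fit -> adequacy -> optimum.

Reads an observation table (CSV) and a system descriptor (JSON), fits the
quadratic-in-1/ε model independently per analyte, attaches the bootstrap
uncertainty of the optimal dielectric constant, and writes per-analyte
report JSON plus a tidy plot-ready table of (x = 1/ε, y, y_hat, residual).
Every report embeds the package version, a hash of the run configuration,
and the seed, so identical configs reproduce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, field
from importlib import metadata
from pathlib import Path

import pandas as pd

from .model_fitting import epsilon_opt_uncertainty, fit_transformed_quadratic
from .partition_model import ExtractionObservation, ExtractionSystem

__all__ = [
    "OBSERVATION_COLUMNS",
    "RunConfig",
    "load_observations",
    "load_system",
    "run_pipeline",
]

logger = logging.getLogger("nadex")

OBSERVATION_COLUMNS = ("analyte", "solvent_label", "epsilon", "concentration_g_per_ml")


def _package_version() -> str:
    try:
        return metadata.version("nadex")
    except metadata.PackageNotFoundError:  # pragma: no cover - editable edge
        return "unknown"


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run."""

    observations_csv: str
    system_json: str
    output_dir: str
    analytes: tuple[str, ...] = ()  # empty = all analytes in the CSV
    alpha: float = 0.01
    p: int = 1
    n_boot: int = 2000
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_system(path: str | Path) -> ExtractionSystem:
    """Read a system descriptor JSON with keys m0_g, V_ml, T_K."""
    with open(path) as fh:
        raw = json.load(fh)
    missing = {"m0_g", "V_ml", "T_K"} - raw.keys()
    if missing:
        raise ValueError(f"system JSON {path} missing keys: {sorted(missing)}")
    return ExtractionSystem(
        m0=float(raw["m0_g"]),
        V=float(raw["V_ml"]),
        T=float(raw["T_K"]),
        ratio_note=str(raw.get("ratio_note", "")),
    )


def load_observations(path: str | Path) -> pd.DataFrame:
    """Read the observation CSV, validating the schema."""
    df = pd.read_csv(path)
    missing = set(OBSERVATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"observation CSV {path} missing columns: {sorted(missing)}")
    return df


def observations_to_frame(observations) -> pd.DataFrame:
    """Serialize observations to the pipeline's CSV schema."""
    return pd.DataFrame(
        {
            "analyte": [o.analyte for o in observations],
            "solvent_label": [o.solvent_label for o in observations],
            "epsilon": [o.epsilon for o in observations],
            "concentration_g_per_ml": [o.concentration for o in observations],
        }
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the full per-analyte analysis; returns the report bundle.

    Row-level transform-domain violations are logged as warnings with
    their row numbers and the rows excluded; a fit failure aborts only
    that analyte.  Artifacts per analyte: ``<analyte>_fit.json`` and
    ``<analyte>_curve.csv`` under the output directory, plus a top-level
    ``report.json``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    df = load_observations(config.observations_csv)
    sys = load_system(config.system_json)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    analytes = list(config.analytes) or sorted(df["analyte"].unique())
    bundle: dict = {
        "version": _package_version(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "system": {"m0_g": sys.m0, "V_ml": sys.V, "T_K": sys.T, "ratio_note": sys.ratio_note},
        "analytes": {},
    }
    for analyte in analytes:
        sub = df[df["analyte"] == analyte]
        observations = []
        for idx, row in sub.iterrows():
            try:
                conc = float(row["concentration_g_per_ml"])
                # surface transform-domain problems per row, not per fit
                if not 0 < conc * sys.V < sys.m0:
                    raise ValueError(f"C*V = {conc * sys.V:g} outside (0, m0 = {sys.m0:g})")
                observations.append(
                    ExtractionObservation(
                        epsilon=float(row["epsilon"]),
                        concentration=conc,
                        analyte=str(row["analyte"]),
                        solvent_label=str(row["solvent_label"]),
                    )
                )
            except ValueError as exc:
                logger.warning("row %d (%s): %s — excluded", idx, analyte, exc)
        try:
            fit = fit_transformed_quadratic(
                observations, sys, alpha=config.alpha, p=config.p, analyte=analyte
            )
        except ValueError as exc:
            logger.error("fit failed for %s: %s", analyte, exc)
            bundle["analytes"][analyte] = {"error": str(exc)}
            continue
        if fit.epsilon_opt is not None:
            epsilon_opt_uncertainty(
                fit, observations, sys, n_boot=config.n_boot, seed=config.seed
            )
        report = fit.to_dict()
        bundle["analytes"][analyte] = report

        curve = pd.DataFrame(
            {
                "x_inv_epsilon": fit.x,
                "y_transformed": fit.y,
                "y_fitted": fit.y_hat,
                "residual": fit.residuals,
            }
        )
        curve.to_csv(outdir / f"{analyte}_curve.csv", index=False)
        with open(outdir / f"{analyte}_fit.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)

    with open(outdir / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
    return bundle
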