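"""Bundled defaults and worked-example data.

The package ships the 40-analyte registry, default detection limits,
matrix moisture/lipid constants, the fitted panel-conversion coefficients,
and the published per-site summary tables (egg and nestling geometric means,
composited diet concentrations) from the Duluth, MN tree swallow study that
the worked examples reproduce.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import io as _io
from .model import AnalyteRegistry, DetectionLimitTable, MatrixConstants

TOTAL_LABELS = {"PFAS13": "Total_PFAS13", "PFAS40": "Total_PFAS40"}


def _data_path(name: str) -> Path:
    return Path(resources.files("swallowpfas").joinpath("data", name))


def default_registry() -> AnalyteRegistry:
    """The bundled 40-analyte registry."""
    return _io.read_registry(_data_path("analytes.csv"))


def default_detection_limits() -> DetectionLimitTable:
    """Default detection limits (wildcarded over matrix and year)."""
    return _io.read_detection_limits(_data_path("detection_limits.csv"))


def default_matrix_constants() -> dict[str, MatrixConstants]:
    """Mean moisture/lipid constants for egg, nestling, diet and liver."""
    return _io.read_matrix_constants(_data_path("matrix_constants.yaml"))


def panel_conversion_table() -> dict:
    """Bundled PFAS13<->PFAS40 regression coefficients per matrix."""
    with open(_data_path("panel_conversion.yaml"), encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _site_table(name: str) -> pd.DataFrame:
    df = pd.read_csv(_data_path(name), comment="#")
    return df


def egg_site_geomeans() -> pd.DataFrame:
    """Published egg-sample geometric means by site (tidy layout)."""
    return _site_table("egg_site_geomeans.csv")


def nestling_site_geomeans() -> pd.DataFrame:
    """Published nestling-carcass geometric means by site (tidy layout)."""
    return _site_table("nestling_site_geomeans.csv")


def diet_concentrations() -> pd.DataFrame:
    """Published composited diet concentrations by site (tidy layout)."""
    return _site_table("diet_concentrations.csv")


def site_geomean_map(
    table: pd.DataFrame, site: str, include_totals: bool = False
) -> dict[str, float]:
    """Extract one site's analyte -> value mapping from a tidy site table.

    Rows with missing values (not quantified) are dropped; the
    ``Total_PFAS13`` / ``Total_PFAS40`` rows are excluded unless requested.
    """
    value_col = "geo_mean" if "geo_mean" in table.columns else "value"
    sub = table[table["site"] == site]
    if sub.empty:
        raise KeyError(f"site {site!r} not present in table")
    out = {}
    for _, row in sub.iterrows():
        analyte = row["analyte"]
        if not include_totals and analyte in TOTAL_LABELS.values():
            continue
        value = row[value_col]
        if pd.isna(value):
            continue
        out[analyte] = float(value)
    return out
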