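"""Readers and writers for sample tables, registries and config files.

Sample tables are UTF-8 CSV.  The long layout has columns
``sample_id,site,region,matrix,year,nest_id,age_days,sample_mass_g,analyte,
value,detected``; a wide layout with one column per analyte plus an optional
parallel ``<analyte>_flag`` column is also accepted.  Lines starting with
``#`` are comments (writers emit one recording the package version).
"""

from __future__ import annotations

import hashlib
import math
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .model import (
    AnalyteDefinition,
    AnalyteRegistry,
    DetectionLimitTable,
    MatrixConstants,
    MeasuredValue,
    SampleRecord,
    ValidationError,
)

_LONG_COLUMNS = [
    "sample_id", "site", "region", "matrix", "year",
    "nest_id", "age_days", "sample_mass_g", "analyte", "value", "detected",
]

_TRUE = {"true", "1", "yes", "y", "t", "detect", "detected"}
_FALSE = {"false", "0", "no", "n", "f", "nd", "nondetect", "non-detect"}


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)


def read_registry(path: str | Path) -> AnalyteRegistry:
    """Load an analyte registry from CSV or YAML."""
    path = Path(path)
    rows: list[dict]
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path, encoding="utf-8") as fh:
            rows = yaml.safe_load(fh)
    else:
        rows = _read_csv(path).to_dict("records")
    defs = []
    for row in rows:
        panels = row["panels"]
        if isinstance(panels, str):
            panels = [p.strip() for p in panels.split(";") if p.strip()]
        carbon = row.get("carbon_count")
        if carbon in (None, "") or (
            isinstance(carbon, float) and math.isnan(carbon)
        ):
            carbon = None
        else:
            carbon = int(carbon)
        defs.append(
            AnalyteDefinition(
                name=str(row["name"]).strip(),
                chem_class=str(row["chem_class"]).strip(),
                panels=frozenset(panels),
                carbon_count=carbon,
            )
        )
    return AnalyteRegistry(defs)


def read_detection_limits(path: str | Path) -> DetectionLimitTable:
    """Load a detection-limit table from CSV or YAML.

    CSV columns: ``analyte,matrix,year,dl``; matrix/year may be ``'*'``.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path, encoding="utf-8") as fh:
            rows = yaml.safe_load(fh)
    else:
        rows = _read_csv(path).to_dict("records")
    table = {}
    for row in rows:
        key = (str(row["analyte"]), str(row["matrix"]), str(row["year"]))
        table[key] = float(row["dl"])
    return DetectionLimitTable(table)


def read_matrix_constants(path: str | Path) -> dict[str, MatrixConstants]:
    """Load per-matrix moisture/lipid constants from YAML."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return {
        matrix: MatrixConstants(
            matrix=matrix,
            pct_moisture=float(vals["pct_moisture"]),
            pct_lipid=(
                None if vals.get("pct_lipid") is None
                else float(vals["pct_lipid"])
            ),
        )
        for matrix, vals in raw.items()
    }


def _parse_flag(raw: object) -> bool | None:
    if raw is None:
        return None
    if isinstance(raw, float) and math.isnan(raw):
        return None
    text = str(raw).strip().lower()
    if text == "" or text == "nan":
        return None
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValidationError(f"unparseable detected flag {raw!r}")


def _measured_value(
    value: float | None, flag: bool | None, dl: float
) -> MeasuredValue:
    # An explicit lab qualifier flag takes precedence over the value-vs-DL
    # comparison; without a flag, detection is inferred as value > DL.
    if value is not None and value < 0:
        raise ValidationError(f"negative concentration {value}")
    if flag is None:
        detected = value is not None and value > dl
    else:
        detected = flag
    if not detected:
        return MeasuredValue(value=None, detected=False, dl_used=dl)
    if value is None:
        raise ValidationError("detected measurement without a value")
    return MeasuredValue(value=value, detected=True, dl_used=dl)


def _parse_float(raw: object) -> float | None:
    if raw is None:
        return None
    text = str(raw).strip()
    if text in ("", ".", "nan", "NA", "ND"):
        return None
    return float(text)


def read_samples(
    path: str | Path,
    registry: AnalyteRegistry,
    dl_table: DetectionLimitTable,
) -> list[SampleRecord]:
    """Read a sample table (long or wide CSV) into :class:`SampleRecord` s.

    Detection state comes from the ``detected`` / ``<analyte>_flag`` column
    when present, else is inferred as value > DL.  A missing detection limit
    for any (analyte, matrix, year) encountered raises ``KeyError``.
    """
    df = _read_csv(path)
    if "analyte" in df.columns:
        return _samples_from_long(df, registry, dl_table)
    return _samples_from_wide(df, registry, dl_table)


def _sample_header(row: pd.Series) -> dict:
    age = _parse_float(row.get("age_days"))
    mass = _parse_float(row.get("sample_mass_g"))
    nest = row.get("nest_id")
    if nest is not None and (str(nest).strip() in ("", "nan")):
        nest = None
    return dict(
        sample_id=str(row["sample_id"]),
        site=str(row["site"]),
        region=str(row["region"]),
        matrix=str(row["matrix"]),
        year=int(float(row["year"])),
        age_days=age,
        sample_mass_g=mass,
        nest_id=None if nest is None else str(nest),
    )


def _samples_from_long(
    df: pd.DataFrame,
    registry: AnalyteRegistry,
    dl_table: DetectionLimitTable,
) -> list[SampleRecord]:
    records: dict[str, SampleRecord] = {}
    for _, row in df.iterrows():
        header = _sample_header(row)
        sid = header["sample_id"]
        if sid not in records:
            records[sid] = SampleRecord(measurements={}, **header)
        rec = records[sid]
        analyte = str(row["analyte"]).strip()
        if analyte not in registry:
            raise ValidationError(
                f"analyte {analyte!r} in sample {sid!r} is not in the registry"
            )
        dl = dl_table.lookup(analyte, rec.matrix, rec.year)
        value = _parse_float(row.get("value"))
        flag = _parse_flag(row.get("detected"))
        rec.measurements[analyte] = _measured_value(value, flag, dl)
    return list(records.values())


def _samples_from_wide(
    df: pd.DataFrame,
    registry: AnalyteRegistry,
    dl_table: DetectionLimitTable,
) -> list[SampleRecord]:
    meta_cols = {c for c in _LONG_COLUMNS if c not in ("analyte", "value", "detected")}
    analyte_cols = [
        c for c in df.columns
        if c not in meta_cols and not c.endswith("_flag")
    ]
    unknown = [c for c in analyte_cols if c not in registry]
    if unknown:
        raise ValidationError(
            f"column(s) {unknown} are not registry analytes"
        )
    records = []
    for _, row in df.iterrows():
        header = _sample_header(row)
        measurements = {}
        for analyte in analyte_cols:
            value = _parse_float(row.get(analyte))
            flag = _parse_flag(row.get(f"{analyte}_flag"))
            if value is None and flag is None:
                continue
            dl = dl_table.lookup(analyte, header["matrix"], header["year"])
            measurements[analyte] = _measured_value(value, flag, dl)
        records.append(SampleRecord(measurements=measurements, **header))
    return records


def _config_hash(*parts: str) -> str:
    digest = hashlib.sha256("\n".join(parts).encode("utf-8")).hexdigest()
    return digest[:12]


def write_samples(
    samples: Iterable[SampleRecord], path: str | Path
) -> None:
    """Write samples as a long-format CSV (round-trips through read_samples)."""
    from . import __version__

    rows = []
    for rec in samples:
        for analyte, mv in rec.measurements.items():
            rows.append({
                "sample_id": rec.sample_id,
                "site": rec.site,
                "region": rec.region,
                "matrix": rec.matrix,
                "year": rec.year,
                "nest_id": rec.nest_id if rec.nest_id is not None else "",
                "age_days": rec.age_days if rec.age_days is not None else "",
                "sample_mass_g": (
                    rec.sample_mass_g if rec.sample_mass_g is not None else ""
                ),
                "analyte": analyte,
                "value": mv.value if mv.value is not None else "",
                "detected": mv.detected,
            })
    df = pd.DataFrame(rows, columns=_LONG_COLUMNS)
    header = (
        f"# swallowpfas {__version__} sample table; "
        f"config {_config_hash(__version__, ','.join(df.columns))}\n"
    )
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
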