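"""Core data model for PFAS tissue-residue analysis.

Concentrations are stored internally on a wet-weight basis (ng/g wet wt.);
conversion to dry-weight or lipid-normalized bases is presentation-only
(:func:`convert_basis`).  An :class:`AnalyteRegistry` defines the analyte
vocabulary, chemical classes and the nested reporting panels
(``PFAS13 ⊆ PFAS33 ⊆ PFAS40``) that grew with the commercial analyte list
across study years.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

MATRICES = ("egg", "nestling", "diet", "liver")
REGIONS = ("North", "StLouisRiver", "Reference")
PANELS = ("PFAS13", "PFAS33", "PFAS40")
CHEM_CLASSES = (
    "perfluorosulfonate",
    "perfluorocarboxylate",
    "fluorotelomer_sulfonate",
    "fluorotelomer_carboxylate",
    "sulfonamide",
    "sulfonamide_derivative",
    "ether_acid",
    "other",
)


class ValidationError(ValueError):
    """Raised when input data violate the model's invariants."""


@dataclass(frozen=True)
class AnalyteDefinition:
    """One registry entry: an analyte's code, class and panel memberships."""

    name: str
    chem_class: str
    panels: frozenset[str]
    carbon_count: int | None = None

    def __post_init__(self) -> None:
        if self.chem_class not in CHEM_CLASSES:
            raise ValidationError(
                f"unknown chemical class {self.chem_class!r} for analyte "
                f"{self.name!r}; expected one of {CHEM_CLASSES}"
            )
        unknown = set(self.panels) - set(PANELS)
        if unknown:
            raise ValidationError(
                f"unknown panel(s) {sorted(unknown)} for analyte {self.name!r}"
            )
        if "PFAS40" not in self.panels:
            raise ValidationError(
                f"analyte {self.name!r} must belong at least to PFAS40"
            )
        if self.carbon_count is not None and self.carbon_count < 3:
            raise ValidationError(
                f"carbon_count for {self.name!r} must be >= 3"
            )


class AnalyteRegistry:
    """Validated collection of :class:`AnalyteDefinition` rows.

    Enforces unique names and the panel-nesting invariant
    ``PFAS13 ⊆ PFAS33 ⊆ PFAS40`` over the whole registry.
    """

    def __init__(self, analytes: list[AnalyteDefinition]):
        self._by_name: dict[str, AnalyteDefinition] = {}
        for a in analytes:
            if a.name in self._by_name:
                raise ValidationError(f"duplicate analyte name {a.name!r}")
            self._by_name[a.name] = a
        p13, p33, p40 = (self.panel(p) for p in PANELS)
        if not (p13 <= p33 <= p40):
            raise ValidationError(
                "panel nesting violated: PFAS13 must be a subset of PFAS33, "
                "and PFAS33 of PFAS40"
            )

    def __len__(self) -> int:
        return len(self._by_name)

    def __iter__(self) -> Iterator[AnalyteDefinition]:
        return iter(self._by_name.values())

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> AnalyteDefinition:
        return self._by_name[name]

    def panel(self, panel: str) -> frozenset[str]:
        """Names of all analytes belonging to *panel*."""
        if panel not in PANELS:
            raise ValidationError(f"unknown panel {panel!r}")
        return frozenset(
            a.name for a in self._by_name.values() if panel in a.panels
        )

    def class_members(self, chem_class: str) -> frozenset[str]:
        """Names of all analytes of one chemical class."""
        if chem_class not in CHEM_CLASSES:
            raise ValidationError(f"unknown chemical class {chem_class!r}")
        return frozenset(
            a.name for a in self._by_name.values()
            if a.chem_class == chem_class
        )


class DetectionLimitTable:
    """Lookup of detection limits (ng/g wet wt.) by analyte, matrix and year.

    Rows may carry ``'*'`` wildcards for matrix and/or year; the most specific
    match wins (exact > matrix-wildcard > year-wildcard > both-wildcard).
    """

    def __init__(self, rows: Mapping[tuple[str, str, str], float]):
        self._rows: dict[tuple[str, str, str], float] = {}
        for (analyte, matrix, year), dl in rows.items():
            key = (analyte, str(matrix), str(year))
            if dl <= 0:
                raise ValidationError(
                    f"detection limit for {key} must be > 0, got {dl}"
                )
            if key in self._rows:
                raise ValidationError(f"duplicate detection-limit row {key}")
            self._rows[key] = float(dl)

    def lookup(self, analyte: str, matrix: str, year: int | str) -> float:
        year = str(year)
        for key in (
            (analyte, matrix, year),
            (analyte, matrix, "*"),
            (analyte, "*", year),
            (analyte, "*", "*"),
        ):
            if key in self._rows:
                return self._rows[key]
        raise KeyError(
            f"no detection limit on record for analyte={analyte!r}, "
            f"matrix={matrix!r}, year={year!r}"
        )

    def scaled(self, factor: float) -> "DetectionLimitTable":
        """A copy with every limit multiplied by *factor* (> 0)."""
        if factor <= 0:
            raise ValidationError("scale factor must be > 0")
        return DetectionLimitTable(
            {k: v * factor for k, v in self._rows.items()}
        )


@dataclass(frozen=True)
class MeasuredValue:
    """A single analyte measurement with its censoring state.

    ``value`` is ``None`` for a non-detect until a substitution rule
    (half-DL for per-analyte statistics, zero for composition profiles)
    fills it; ``dl_used`` is the detection limit that applied.
    """

    value: float | None
    detected: bool
    dl_used: float

    def __post_init__(self) -> None:
        if self.dl_used <= 0:
            raise ValidationError("dl_used must be > 0")
        if self.value is not None and self.value < 0:
            raise ValidationError("concentration must be >= 0")

    def half_dl_value(self) -> float:
        """The value with half-DL substitution applied to non-detects."""
        if self.detected:
            assert self.value is not None
            return self.value
        return self.dl_used / 2.0

    def detected_value(self) -> float:
        """The value under the detect-only rule (non-detects contribute 0)."""
        if self.detected and self.value is not None:
            return self.value
        return 0.0


@dataclass
class SampleRecord:
    """One tissue or diet sample with its per-analyte measurements."""

    sample_id: str
    site: str
    region: str
    matrix: str
    year: int
    measurements: dict[str, MeasuredValue] = field(default_factory=dict)
    age_days: float | None = None
    sample_mass_g: float | None = None
    nest_id: str | None = None

    def __post_init__(self) -> None:
        if self.matrix not in MATRICES:
            raise ValidationError(
                f"unsupported matrix {self.matrix!r} in sample "
                f"{self.sample_id!r}; expected one of {MATRICES}"
            )
        if self.age_days is not None and self.matrix != "nestling":
            raise ValidationError(
                f"age_days given for non-nestling sample {self.sample_id!r}"
            )
        if self.sample_mass_g is not None and self.sample_mass_g <= 0:
            raise ValidationError(
                f"sample_mass_g must be > 0 in sample {self.sample_id!r}"
            )

    def with_measurements(
        self, measurements: dict[str, MeasuredValue]
    ) -> "SampleRecord":
        return replace(self, measurements=measurements)


@dataclass(frozen=True)
class MatrixConstants:
    """Mean moisture/lipid fractions of one tissue matrix (percent of wet mass)."""

    matrix: str
    pct_moisture: float
    pct_lipid: float | None

    def __post_init__(self) -> None:
        if not 0 < self.pct_moisture < 100:
            raise ValidationError("pct_moisture must be in (0, 100)")
        if self.pct_lipid is not None and not 0 <= self.pct_lipid < 100:
            raise ValidationError("pct_lipid must be in [0, 100)")


def convert_basis(
    conc_wet: float, constants: MatrixConstants, target: str
) -> float:
    """Convert a wet-weight concentration to a dry or lipid-normalized basis.

    dry basis divides by the solids fraction ``1 - pct_moisture/100``;
    lipid basis divides by the lipid fraction ``pct_lipid/100``.
    """
    if conc_wet < 0:
        raise ValidationError("concentration must be >= 0")
    if target == "dry":
        return conc_wet / (1.0 - constants.pct_moisture / 100.0)
    if target == "lipid":
        if not constants.pct_lipid:
            raise ValidationError(
                f"no lipid fraction on record for matrix "
                f"{constants.matrix!r}; cannot lipid-normalize"
            )
        return conc_wet / (constants.pct_lipid / 100.0)
    raise ValidationError(f"unknown target basis {target!r}")


def invert_basis(
    conc_target: float, constants: MatrixConstants, target: str
) -> float:
    """Inverse of :func:`convert_basis` (back to wet weight)."""
    if target == "dry":
        return conc_target * (1.0 - constants.pct_moisture / 100.0)
    if target == "lipid":
        if not constants.pct_lipid:
            raise ValidationError("no lipid fraction on record")
        return conc_target * (constants.pct_lipid / 100.0)
    raise ValidationError(f"unknown target basis {target!r}")
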