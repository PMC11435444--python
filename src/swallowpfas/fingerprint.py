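"""Source attribution of PFAS profiles in avian tissues.

Legacy aqueous film-forming foam (AFFF) leaves a sulfonate-rich signature —
PFOS dominant with elevated PFHxS — while diffuse urban/atmospheric sources
carry a broader carboxylate spectrum.  Three simple indicators exploit this:

* the PFHxS:PFOS ratio (AFFF-indicative when PFOS is less than 20-fold
  dominant, i.e. ``1:x`` with x < 20);
* the total carboxylate : total sulfonate ratio (AFFF-indicative when
  sulfonates dominate more than 10-fold);
* the composition profile itself (PFOS share, PFHxS share, and how many
  *other* analytes exceed a minor-contribution threshold).

:func:`call_source` combines them into a single verdict.  Panel-conversion
equations translate historical 13-analyte totals onto the 40-analyte basis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .censored import (
    DEFAULT_CARBOXYLATES,
    DEFAULT_SULFONATES,
    class_sums,
    half_dl_values,
)
from .model import AnalyteRegistry, SampleRecord, ValidationError

#: Background (non-AFFF, non-urban) carb:sulf bounds by matrix: a profile is
#: background-like when sulfonates are *below* this multiple of carboxylates.
BACKGROUND_CARB_SULF_BOUND = {"nestling": 1.0, "egg": 1.5}

PFHXS_PFOS_AFFF_CUTOFF = 20.0   # "1:20": below -> AFFF-indicative
CARB_SULF_AFFF_CUTOFF = 10.0    # "1:10": above -> AFFF-indicative


@dataclass(frozen=True)
class RatioResult:
    """A dominance ratio in the ``1:x`` convention.

    ``n_value`` is the x: how many-fold the denominator-side analyte(s)
    dominate the numerator side (e.g. PFHxS:PFOS of 1:12.4 means PFOS is
    12.4 times PFHxS).  ``math.inf`` signals a zero numerator-side value.
    """

    numerator_label: str
    denominator_label: str
    n_value: float

    def __str__(self) -> str:  # one decimal, matching field convention
        return f"{self.numerator_label}:{self.denominator_label} = 1:{self.n_value:.1f}"


@dataclass(frozen=True)
class ConversionCoefficients:
    """Linear panel-total conversion: estimate = slope * value + intercept."""

    slope: float
    intercept: float
    direction: str   # "PFAS13->PFAS40" or "PFAS40->PFAS13"
    matrix: str

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValidationError("conversion slope must be > 0")


@dataclass(frozen=True)
class CompositionRule:
    """Thresholds of the composition indicator inside :func:`call_source`.

    Calibrated to the AFFF signature (PFOS ~81%, PFHxS ~8%, at most one
    other analyte >= 2%); adjust for other study systems.
    """

    min_pfos_pct: float = 70.0
    min_pfhxs_pct: float = 5.0
    max_breadth: int = 1
    breadth_threshold_pct: float = 2.0
    background_min_breadth: int = 4


@dataclass(frozen=True)
class SourceCall:
    pfhxs_pfos_rule: bool
    carb_sulf_rule: bool
    composition_rule: bool
    verdict: str   # AFFF-like | non-AFFF | background-like | indeterminate
    ratios: dict = field(default_factory=dict, compare=False)


def _as_values(sample: Mapping[str, float] | SampleRecord) -> dict[str, float]:
    if isinstance(sample, SampleRecord):
        return half_dl_values(sample)
    return dict(sample)


def pfhxs_pfos_ratio(
    sample: Mapping[str, float] | SampleRecord
) -> RatioResult:
    """PFHxS:PFOS ratio as ``1:x`` with x = PFOS / PFHxS.

    Values are half-DL substituted when a :class:`SampleRecord` is given, so
    a non-detected PFHxS still yields a finite ratio.
    """
    values = _as_values(sample)
    pfos, pfhxs = values.get("PFOS", 0.0), values.get("PFHxS", 0.0)
    if pfhxs <= 0:
        warnings.warn(
            "PFHxS is zero; PFHxS:PFOS ratio is infinite", stacklevel=2
        )
        return RatioResult("PFHxS", "PFOS", float("inf"))
    return RatioResult("PFHxS", "PFOS", pfos / pfhxs)


def classify_by_pfhxs_pfos(
    ratio: RatioResult, cutoff: float = PFHXS_PFOS_AFFF_CUTOFF
) -> bool:
    """True when the ratio indicates an AFFF source (strictly below 1:20).

    The boundary itself (exactly 1:20) is classed non-AFFF.
    """
    return ratio.n_value < cutoff


def carb_sulf_ratio(
    sample: Mapping[str, float] | SampleRecord,
    carboxylates: Sequence[str] = DEFAULT_CARBOXYLATES,
    sulfonates: Sequence[str] = DEFAULT_SULFONATES,
) -> RatioResult:
    """Total carboxylate : total sulfonate ratio as ``1:x``, x = sulf/carb."""
    values = _as_values(sample)
    carb, sulf = class_sums(values, carboxylates, sulfonates)
    if carb <= 0:
        warnings.warn(
            "carboxylate sum is zero; carb:sulf ratio is infinite",
            stacklevel=2,
        )
        return RatioResult("carboxylates", "sulfonates", float("inf"))
    return RatioResult("carboxylates", "sulfonates", sulf / carb)


def classify_by_carb_sulf(
    ratio: RatioResult, cutoff: float = CARB_SULF_AFFF_CUTOFF
) -> bool:
    """True when sulfonate dominance exceeds the AFFF threshold (1:10)."""
    return ratio.n_value > cutoff


def composition_profile(
    sample: SampleRecord,
    registry: AnalyteRegistry,
    panel: str = "PFAS40",
) -> dict[str, float]:
    """Percent of the panel total contributed by each detected analyte.

    Non-detects contribute 0%; percents sum to 100 over detected analytes.
    """
    members = registry.panel(panel)
    values = {
        a: mv.detected_value()
        for a, mv in sample.measurements.items() if a in members
    }
    return profile_from_values(values)


def profile_from_values(values: Mapping[str, float]) -> dict[str, float]:
    """Percent composition of a plain analyte -> concentration mapping."""
    total = sum(values.values())
    if total <= 0:
        raise ValidationError("profile total must be > 0")
    return {a: 100.0 * v / total for a, v in values.items()}


def site_mean_profile(
    profiles: Sequence[Mapping[str, float]]
) -> dict[str, float]:
    """Unweighted arithmetic mean of per-sample percent profiles.

    This is the mean of percents, *not* the percent of mean totals; the two
    differ whenever totals vary among samples.
    """
    if not profiles:
        raise ValidationError("need at least one profile")
    analytes = sorted({a for p in profiles for a in p})
    n = len(profiles)
    return {
        a: sum(p.get(a, 0.0) for p in profiles) / n for a in analytes
    }


def minor_analyte_breadth(
    profile: Mapping[str, float], threshold_pct: float = 2.0
) -> int:
    """Count of analytes other than PFOS and PFHxS at or above *threshold_pct*.

    High breadth marks diffuse (atmospheric/urban) sources; legacy AFFF
    concentrates the signal in PFOS and PFHxS.
    """
    return sum(
        1 for a, pct in profile.items()
        if a not in ("PFOS", "PFHxS") and pct >= threshold_pct
    )


def bundled_coefficients(
    matrix: str, direction: str = "PFAS13->PFAS40"
) -> ConversionCoefficients:
    """Fitted panel-conversion coefficients shipped with the package."""
    from .datasets import panel_conversion_table

    table = panel_conversion_table()
    if matrix not in table:
        raise ValidationError(
            f"no bundled conversion for matrix {matrix!r}"
        )
    key = "forward" if direction == "PFAS13->PFAS40" else "reverse"
    entry = table[matrix][key]
    return ConversionCoefficients(
        slope=entry["slope"], intercept=entry["intercept"],
        direction=direction, matrix=matrix,
    )


def convert_panel(
    value: float, coefficients: ConversionCoefficients
) -> float:
    """Apply a linear panel conversion to a panel total (ng/g wet wt.).

    The estimate may be negative for small inputs (the reverse egg equation
    crosses zero near 23 ng/g); negatives are warned about, not clamped.
    """
    if value < 0:
        raise ValidationError("panel total must be >= 0")
    estimate = coefficients.slope * value + coefficients.intercept
    if estimate < 0:
        warnings.warn(
            f"panel conversion produced a negative estimate ({estimate:.3g}) "
            f"for input {value:.3g}; reported unclamped",
            stacklevel=2,
        )
    return estimate


def fit_panel_conversion(
    x: Sequence[float],
    y: Sequence[float],
    direction: str = "PFAS13->PFAS40",
    matrix: str = "egg",
) -> tuple[ConversionCoefficients, float]:
    """Ordinary least squares fit of paired panel totals; returns (coeffs, r).

    Forward and reverse conversions are separate regressions, not algebraic
    inverses; their slopes multiply to r² (an OLS identity).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need at least three paired totals")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("paired totals must have positive variance")
    fit = stats.linregress(x, y)
    return (
        ConversionCoefficients(
            slope=float(fit.slope), intercept=float(fit.intercept),
            direction=direction, matrix=matrix,
        ),
        float(fit.rvalue),
    )


def site_mean_values(
    samples: Sequence[SampleRecord],
) -> dict[str, float]:
    """Arithmetic mean of half-DL-substituted concentrations over samples.

    A simple site-level aggregate for feeding :func:`call_source` when a
    verdict per site rather than per sample is wanted.
    """
    if not samples:
        raise ValidationError("need at least one sample")
    analytes = sorted({a for s in samples for a in s.measurements})
    n = len(samples)
    return {
        a: sum(
            half_dl_values(s).get(a, 0.0) for s in samples
        ) / n
        for a in analytes
    }


def call_source(
    sample: Mapping[str, float] | SampleRecord,
    matrix: str | None = None,
    registry: AnalyteRegistry | None = None,
    rule: CompositionRule = CompositionRule(),
) -> SourceCall:
    """Combined AFFF/background/non-AFFF verdict for one sample or site summary.

    Three AFFF indicators are voted: PFHxS:PFOS below 1:20, carb:sulf above
    1:10, and the concentrated-composition rule.  Two or more votes give
    ``AFFF-like``.  Otherwise a profile whose sulfonates fall below the
    matrix-specific background bound with broad minor-analyte spread is
    ``background-like``; a single stray vote is ``indeterminate``; no votes,
    ``non-AFFF``.
    """
    if isinstance(sample, SampleRecord):
        matrix = sample.matrix
        values = half_dl_values(sample)
        if registry is not None:
            profile = composition_profile(sample, registry)
        else:
            profile = profile_from_values(values)
    else:
        if matrix is None:
            raise ValidationError(
                "matrix must be given for plain value mappings"
            )
        values = dict(sample)
        profile = profile_from_values(values)

    pp = pfhxs_pfos_ratio(values)
    cs = carb_sulf_ratio(values)
    breadth = minor_analyte_breadth(profile, rule.breadth_threshold_pct)

    pp_vote = classify_by_pfhxs_pfos(pp)
    cs_vote = classify_by_carb_sulf(cs)
    comp_vote = (
        profile.get("PFOS", 0.0) >= rule.min_pfos_pct
        and profile.get("PFHxS", 0.0) >= rule.min_pfhxs_pct
        and breadth <= rule.max_breadth
    )
    votes = sum((pp_vote, cs_vote, comp_vote))

    bg_bound = BACKGROUND_CARB_SULF_BOUND.get(matrix or "", 1.0)
    background = (
        cs.n_value < bg_bound and breadth >= rule.background_min_breadth
    )

    if votes >= 2:
        verdict = "AFFF-like"
    elif background:
        verdict = "background-like"
    elif votes == 1:
        verdict = "indeterminate"
    else:
        verdict = "non-AFFF"
    return SourceCall(
        pfhxs_pfos_rule=pp_vote,
        carb_sulf_rule=cs_vote,
        composition_rule=comp_vote,
        verdict=verdict,
        ratios={
            "pfhxs_pfos": pp.n_value,
            "carb_sulf": cs.n_value,
            "breadth": breadth,
        },
    )
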