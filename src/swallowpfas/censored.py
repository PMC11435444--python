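"""Censoring rules, panel totals, class sums and site summary statistics.

Two distinct censoring rules coexist, both deliberate:

* **Panel totals** sum detected values only — a non-detect contributes zero
  (:func:`total_panel`).
* **Per-analyte statistics** (geometric means, CIs, ANOVA, class sums)
  substitute half the detection limit for non-detects, and only analytes
  detected in more than half the samples are analyzed at all
  (:func:`detection_gate`, :func:`substitute_half_dl`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .model import AnalyteRegistry, SampleRecord, ValidationError

#: Class-sum memberships: the seven carboxylic acids and three sulfonates
#: detected in >50% of egg or nestling samples in the source study.
DEFAULT_CARBOXYLATES = (
    "PFOA", "PFNA", "PFDA", "PFUnA", "PFDoA", "PFTrDA", "PFTeDA",
)
DEFAULT_SULFONATES = ("PFOS", "PFHxS", "PFDS")


class DetectionFrequency(NamedTuple):
    percent: int          # rounded to integer for reporting
    fraction: float       # raw fraction, used by the >50% gate
    n_detected: int
    n_total: int


def detection_frequency(
    samples: Sequence[SampleRecord],
    analyte: str,
    matrix: str | None = None,
) -> DetectionFrequency:
    """Percent of samples (optionally of one matrix) in which *analyte* was detected.

    Samples without a measurement for the analyte are not counted.
    """
    relevant = [
        s for s in samples
        if (matrix is None or s.matrix == matrix) and analyte in s.measurements
    ]
    if not relevant:
        raise ValidationError(
            f"analyte {analyte!r} absent from all"
            + ("" if matrix is None else f" {matrix!r}") + " samples"
        )
    n_det = sum(1 for s in relevant if s.measurements[analyte].detected)
    frac = n_det / len(relevant)
    return DetectionFrequency(
        percent=round(100.0 * frac),
        fraction=frac,
        n_detected=n_det,
        n_total=len(relevant),
    )


def detection_gate(
    samples: Sequence[SampleRecord],
    analytes: Iterable[str] | None = None,
    threshold: float = 0.5,
    matrix: str | None = None,
) -> set[str]:
    """Analytes detected in strictly more than *threshold* of the samples."""
    if analytes is None:
        analytes = sorted({a for s in samples for a in s.measurements})
    passed = set()
    for analyte in analytes:
        try:
            freq = detection_frequency(samples, analyte, matrix=matrix)
        except ValidationError:
            continue
        if freq.fraction > threshold:
            passed.add(analyte)
    return passed


def substitute_half_dl(
    samples: Sequence[SampleRecord],
    analyte_set: Iterable[str],
) -> list[SampleRecord]:
    """Return copies with half-DL substituted for non-detects of *analyte_set*.

    Detects are unchanged; analytes outside the set are left censored.
    The caller is expected to restrict the set to analytes passing the
    detection gate (the rule is meant for analytes analyzed statistically).
    """
    analyte_set = set(analyte_set)
    out = []
    for rec in samples:
        measurements = dict(rec.measurements)
        for analyte in analyte_set & set(measurements):
            mv = measurements[analyte]
            if not mv.detected:
                measurements[analyte] = type(mv)(
                    value=mv.dl_used / 2.0, detected=False, dl_used=mv.dl_used
                )
        out.append(rec.with_measurements(measurements))
    return out


def half_dl_values(rec: SampleRecord) -> dict[str, float]:
    """Mapping analyte -> half-DL-substituted value for one sample."""
    return {a: mv.half_dl_value() for a, mv in rec.measurements.items()}


def total_panel(
    sample: SampleRecord, panel: str, registry: AnalyteRegistry
) -> float:
    """Detect-only total over a reporting panel (ng/g wet wt.).

    Non-detects contribute zero; an all-non-detect sample totals 0.
    """
    members = registry.panel(panel)
    return sum(
        mv.detected_value()
        for analyte, mv in sample.measurements.items()
        if analyte in members
    )


def class_sums(
    values: Mapping[str, float] | SampleRecord,
    carboxylates: Sequence[str] = DEFAULT_CARBOXYLATES,
    sulfonates: Sequence[str] = DEFAULT_SULFONATES,
) -> tuple[float, float]:
    """(total carboxylic acids, total sulfonates) from half-DL-ready values.

    *values* is either a plain analyte -> concentration mapping (e.g. site
    geometric means) or a :class:`SampleRecord`, in which case half-DL
    substitution is applied on the fly.  Members absent from the input
    contribute nothing.
    """
    if not carboxylates or not sulfonates:
        raise ValidationError("class member lists must be non-empty")
    if isinstance(values, SampleRecord):
        values = half_dl_values(values)
    carb = sum(values[a] for a in carboxylates if a in values)
    sulf = sum(values[a] for a in sulfonates if a in values)
    return carb, sulf


def geometric_mean_ci(
    values: Sequence[float], level: float = 0.95
) -> tuple[float, float | None, float | None]:
    """Geometric mean with a t-based CI computed on the natural-log scale.

    Returns ``(geo_mean, lo, hi)``; with a single observation the CI bounds
    are ``None``.  Values must be strictly positive (half-DL substitution
    must precede this call).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("need at least one value")
    if np.any(arr <= 0):
        raise ValidationError(
            "all values must be > 0; substitute half the DL for non-detects "
            "before computing geometric means"
        )
    logs = np.log(arr)
    gm = float(np.exp(logs.mean()))
    if arr.size == 1:
        return gm, None, None
    se = logs.std(ddof=1) / math.sqrt(arr.size)
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=arr.size - 1)
    return (
        gm,
        float(np.exp(logs.mean() - tcrit * se)),
        float(np.exp(logs.mean() + tcrit * se)),
    )


def fold_difference(geo_mean_a: float, geo_mean_b: float) -> float:
    """Ratio of two geometric means (how many times higher a is than b)."""
    if geo_mean_a <= 0 or geo_mean_b <= 0:
        raise ValidationError("geometric means must be > 0")
    return geo_mean_a / geo_mean_b


@dataclass
class AnovaResult:
    """One-way ANOVA with Bonferroni pairwise letters.

    Groups sharing any letter are not significantly different at ``alpha``
    (pairwise two-sample t-tests, Bonferroni-adjusted).
    """

    f_statistic: float
    p_value: float
    letters: dict[str, str]
    alpha: float
    log_transformed: bool


def _letter_display(
    groups: Sequence[str], nonsig_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    # Letters are maximal cliques of the non-significance graph: each clique
    # gets one letter and a group carries the letters of its cliques.
    g = nx.Graph()
    g.add_nodes_from(groups)
    g.add_edges_from(nonsig_pairs)
    cliques = sorted(
        nx.find_cliques(g),
        key=lambda c: min(groups.index(m) for m in c),
    )
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    letters: dict[str, list[str]] = {name: [] for name in groups}
    for i, clique in enumerate(cliques):
        letter = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for member in clique:
            letters[member].append(letter)
    return {name: "".join(sorted(ls)) for name, ls in letters.items()}


def anova_log(
    values: Sequence[float],
    groups: Sequence[str],
    alpha: float = 0.05,
    log_transform: bool = True,
) -> AnovaResult:
    """One-way ANOVA on (optionally log10) values with Bonferroni letters.

    Chemistry concentrations are log-transformed by default to meet
    homogeneity-of-variance assumptions; pass ``log_transform=False`` for
    quantities analyzed untransformed (e.g. accumulation rates).
    """
    values = np.asarray(values, dtype=float)
    if log_transform:
        if np.any(values <= 0):
            raise ValidationError("log transform requires values > 0")
        values = np.log10(values)
    names = list(dict.fromkeys(groups))
    by_group = {
        name: values[np.asarray([g == name for g in groups])]
        for name in names
    }
    if len(names) < 2:
        raise ValidationError("need at least two groups")
    for name, arr in by_group.items():
        if arr.size < 2:
            raise ValidationError(
                f"group {name!r} has fewer than two observations"
            )
    f_stat, p_val = stats.f_oneway(*(by_group[n] for n in names))
    if not math.isfinite(f_stat):  # all values identical across groups
        f_stat, p_val = 0.0, 1.0
    m = len(names) * (len(names) - 1) // 2
    nonsig = set()
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            xa, xb = by_group[a], by_group[b]
            if np.ptp(np.concatenate([xa, xb])) == 0:
                p = 1.0
            else:
                p = stats.ttest_ind(xa, xb, equal_var=True).pvalue
            if not (p < alpha / m):
                nonsig.add((a, b))
    return AnovaResult(
        f_statistic=float(f_stat),
        p_value=float(p_val),
        letters=_letter_display(names, nonsig),
        alpha=alpha,
        log_transformed=log_transform,
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; requires n >= 3 and non-degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need paired vectors of length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in an input vector")
    return float(stats.pearsonr(x, y).statistic)


def teq(
    congener_concs: Mapping[str, float],
    tef_table: Mapping[str, float],
) -> float:
    """Total toxic equivalency: sum of concentration x TEF over congeners."""
    missing = [c for c in congener_concs if c not in tef_table]
    if missing:
        raise ValidationError(
            f"no toxic equivalency factor for congener(s): {missing}"
        )
    return sum(conc * tef_table[c] for c, conc in congener_concs.items())


def summarize_sites(
    samples: Sequence[SampleRecord],
    registry: AnalyteRegistry,
    detection_threshold: float = 0.5,
    ci_level: float = 0.95,
    panel: str = "PFAS40",
):
    """Per site x matrix x analyte summary table (geometric mean, CI, range).

    Analytes are summarized per matrix only when they pass the detection
    gate in that matrix; panel totals (detect-only rule) are appended as
    ``Total_<panel>`` rows.  Returns a pandas DataFrame.
    """
    import pandas as pd

    rows = []
    matrices = sorted({s.matrix for s in samples})
    for matrix in matrices:
        matrix_samples = [s for s in samples if s.matrix == matrix]
        gated = detection_gate(
            matrix_samples, threshold=detection_threshold
        )
        subst = substitute_half_dl(matrix_samples, gated)
        sites = sorted({s.site for s in subst})
        for site in sites:
            site_samples = [s for s in subst if s.site == site]
            for analyte in sorted(gated):
                vals = [
                    s.measurements[analyte].half_dl_value()
                    for s in site_samples if analyte in s.measurements
                ]
                if not vals:
                    continue
                gm, lo, hi = geometric_mean_ci(vals, level=ci_level)
                n_nd = sum(
                    1 for s in site_samples
                    if analyte in s.measurements
                    and not s.measurements[analyte].detected
                )
                rows.append({
                    "site": site, "matrix": matrix, "analyte": analyte,
                    "n": len(vals), "geo_mean": gm,
                    "ci_low": lo, "ci_high": hi,
                    "n_nondetect": n_nd,
                    "min_val": min(vals), "max_val": max(vals),
                })
            totals = [
                total_panel(s, panel, registry) for s in site_samples
            ]
            positive = [t for t in totals if t > 0]
            if positive:
                gm, lo, hi = geometric_mean_ci(positive, level=ci_level)
                rows.append({
                    "site": site, "matrix": matrix,
                    "analyte": f"Total_{panel}",
                    "n": len(positive), "geo_mean": gm,
                    "ci_low": lo, "ci_high": hi,
                    "n_nondetect": len(totals) - len(positive),
                    "min_val": min(positive), "max_val": max(positive),
                })
    return pd.DataFrame(rows)
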