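"""Egg-to-nestling contaminant accumulation rates.

The estimator is a net mass balance: the analyte mass already present in the
egg (concentration x sample wet mass, ng) is subtracted from the mass in the
nestling carcass at collection, and the difference is divided by nestling age
(days).  The result, ng/day, reflects what the nestling obtained from the
local environment — essentially diet — with the maternal contribution
factored out.  Negative rates (elimination exceeding intake) are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .censored import anova_log
from .model import SampleRecord, ValidationError


@dataclass(frozen=True)
class EggNestlingPair:
    site: str
    analyte: str
    egg_mass_ng: float
    nestling_mass_ng: float
    age_days: float
    egg_source: str           # "sibling" | "site_mean"
    nestling_id: str = ""

    def __post_init__(self) -> None:
        if self.egg_mass_ng < 0 or self.nestling_mass_ng < 0:
            raise ValidationError("analyte masses must be >= 0")
        if self.age_days <= 0:
            raise ValidationError("age_days must be > 0")


def _analyte_mass_ng(rec: SampleRecord, analyte: str) -> float | None:
    """Total analyte mass in a sample: half-DL value x wet mass."""
    if analyte not in rec.measurements or rec.sample_mass_g is None:
        return None
    return rec.measurements[analyte].half_dl_value() * rec.sample_mass_g


def build_pairs(
    samples: Sequence[SampleRecord], analyte: str
) -> list[EggNestlingPair]:
    """Pair each nestling with a sibling egg, or the site-mean egg mass.

    A sibling egg shares the nestling's ``nest_id``; when several sibling
    eggs exist their masses are averaged.  Without a sibling, the arithmetic
    mean of per-egg analyte masses at the site is used (``egg_source``
    records which).  Nestlings at sites with no eggs at all are skipped with
    a warning.
    """
    eggs = [s for s in samples if s.matrix == "egg"]
    nestlings = [s for s in samples if s.matrix == "nestling"]

    egg_masses: dict[str, list[tuple[str | None, float]]] = {}
    for egg in eggs:
        mass = _analyte_mass_ng(egg, analyte)
        if mass is None:
            continue
        egg_masses.setdefault(egg.site, []).append((egg.nest_id, mass))

    pairs = []
    for nestling in nestlings:
        if nestling.age_days is None:
            raise ValidationError(
                f"nestling {nestling.sample_id!r} has no recorded age"
            )
        n_mass = _analyte_mass_ng(nestling, analyte)
        if n_mass is None:
            continue
        site_eggs = egg_masses.get(nestling.site, [])
        sibling = [
            m for nid, m in site_eggs
            if nestling.nest_id is not None and nid == nestling.nest_id
        ]
        if sibling:
            egg_mass = float(np.mean(sibling))
            source = "sibling"
        elif site_eggs:
            egg_mass = float(np.mean([m for _, m in site_eggs]))
            source = "site_mean"
        else:
            warnings.warn(
                f"no eggs at site {nestling.site!r}; nestling "
                f"{nestling.sample_id!r} skipped",
                stacklevel=2,
            )
            continue
        pairs.append(
            EggNestlingPair(
                site=nestling.site,
                analyte=analyte,
                egg_mass_ng=egg_mass,
                nestling_mass_ng=n_mass,
                age_days=float(nestling.age_days),
                egg_source=source,
                nestling_id=nestling.sample_id,
            )
        )
    return pairs


def accumulation_rate(pair: EggNestlingPair) -> float:
    """(nestling mass - egg mass) / age, in ng/day; sign preserved."""
    return (pair.nestling_mass_ng - pair.egg_mass_ng) / pair.age_days


@dataclass
class SiteRates:
    """Per-site accumulation rates with an among-site comparison."""

    mean_rate: dict[str, float]
    n_pairs: dict[str, int]
    letters: dict[str, str] | None
    f_statistic: float | None
    p_value: float | None
    method: str


def site_rates(
    pairs: Sequence[EggNestlingPair],
    method: str = "mean",
    alpha: float = 0.05,
) -> SiteRates:
    """Aggregate per-pair rates by site.

    ``method="mean"`` (default) averages per-pair rates; ``"regression"``
    fits a zero-intercept least-squares line of mass gain on age per site —
    the slope-of-the-line reading of the estimator.  Sites are compared with
    one-way ANOVA on untransformed per-pair rates (letters shared = not
    significantly different); the comparison is skipped unless at least two
    sites have two or more pairs.
    """
    if not pairs:
        raise ValidationError("need at least one pair")
    if method not in ("mean", "regression"):
        raise ValidationError(f"unknown method {method!r}")
    sites = sorted({p.site for p in pairs})
    mean_rate: dict[str, float] = {}
    n_pairs: dict[str, int] = {}
    for site in sites:
        sp = [p for p in pairs if p.site == site]
        n_pairs[site] = len(sp)
        if method == "mean":
            mean_rate[site] = float(
                np.mean([accumulation_rate(p) for p in sp])
            )
        else:
            ages = np.array([p.age_days for p in sp])
            gains = np.array(
                [p.nestling_mass_ng - p.egg_mass_ng for p in sp]
            )
            mean_rate[site] = float(ages @ gains / (ages @ ages))

    comparable = [s for s in sites if n_pairs[s] >= 2]
    letters = f_stat = p_val = None
    if len(comparable) >= 2:
        rates, labels = [], []
        for p in pairs:
            if p.site in comparable:
                rates.append(accumulation_rate(p))
                labels.append(p.site)
        result = anova_log(rates, labels, alpha=alpha, log_transform=False)
        letters = result.letters
        f_stat, p_val = result.f_statistic, result.p_value
    return SiteRates(
        mean_rate=mean_rate,
        n_pairs=n_pairs,
        letters=letters,
        f_statistic=f_stat,
        p_value=p_val,
        method=method,
    )
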