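"""Compositional multivariate comparison of PFAS profiles.

Samples are standardized to percent-of-total composition (zeros, not half-DL,
for non-detects), rare analytes (detected in fewer than two samples across
the data set) are dropped, percents are ln(x+1)-transformed, and pairwise
Bray-Curtis dissimilarities feed a rank-based permutation test (ANOSIM) and
nonmetric multidimensional scaling for visualization.

ANOSIM's statistic ``R = (mean between-group rank - mean within-group rank)
/ (M/2)`` with ``M = n(n-1)/2`` is near 1 for complete group separation and
near 0 when grouping is arbitrary; being rank-based it is invariant to any
monotone transformation of the distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .model import AnalyteRegistry, SampleRecord, ValidationError


@dataclass
class ProfileMatrix:
    """Samples x analytes percent-composition matrix with sample metadata."""

    data: pd.DataFrame        # rows indexed by sample_id
    meta: pd.DataFrame        # site / region / matrix per sample
    log_transformed: bool

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.meta.index):
            raise ValidationError("data and meta indices must align")
        if self.data.shape[1] > 40:
            raise ValidationError("more than 40 analyte columns")


def build_profile_matrix(
    samples: Sequence[SampleRecord],
    registry: AnalyteRegistry,
    min_presence: int = 2,
    log_transform: bool = True,
    panel: str = "PFAS40",
) -> ProfileMatrix:
    """Standardize samples to percent composition and filter rare analytes.

    Non-detects enter as zero.  Analytes detected in fewer than
    *min_presence* samples across the whole input are dropped; rows whose
    panel total is zero are dropped with a warning.  The optional transform
    is ``x -> ln(x + 1)`` applied to the percent values.
    """
    members = registry.panel(panel)
    rows, meta_rows, index = [], [], []
    analytes = sorted({
        a for s in samples for a in s.measurements if a in members
    })
    presence = {
        a: sum(
            1 for s in samples
            if a in s.measurements and s.measurements[a].detected
        )
        for a in analytes
    }
    kept = [a for a in analytes if presence[a] >= min_presence]
    if not kept:
        raise ValidationError("no analyte detected in enough samples")

    for s in samples:
        values = np.array([
            s.measurements[a].detected_value() if a in s.measurements else 0.0
            for a in kept
        ])
        total = values.sum()
        if total <= 0:
            warnings.warn(
                f"sample {s.sample_id!r} has zero total; dropped",
                stacklevel=2,
            )
            continue
        rows.append(100.0 * values / total)
        index.append(s.sample_id)
        meta_rows.append({
            "site": s.site, "region": s.region, "matrix": s.matrix,
        })
    if not rows:
        raise ValidationError("all samples had zero totals")
    data = pd.DataFrame(rows, index=index, columns=kept)
    if log_transform:
        data = np.log1p(data)
    return ProfileMatrix(
        data=data,
        meta=pd.DataFrame(meta_rows, index=index),
        log_transformed=log_transform,
    )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with group labels per row."""

    values: np.ndarray
    ids: list[str]
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = v.shape[0]
        if v.shape != (n, n) or n != len(self.ids):
            raise ValidationError("distance matrix shape/id mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValidationError("dissimilarities must be >= 0")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    @classmethod
    def from_csv(cls, path, groups: list[str] | None = None):
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.values, ids=list(df.index), groups=groups)


def bray_curtis(u: Sequence[float], v: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity sum|u-v| / sum(u+v), bounded [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValidationError("vectors must have equal length")
    if np.any(u < 0) or np.any(v < 0):
        raise ValidationError("entries must be non-negative")
    denom = (u + v).sum()
    if denom == 0:
        raise ValidationError("both vectors are all-zero")
    return float(np.abs(u - v).sum() / denom)


def distance_matrix(
    profiles: ProfileMatrix, group_col: str = "region"
) -> DistanceMatrix:
    """Pairwise Bray-Curtis distances over profile rows."""
    condensed = pdist(profiles.data.values, metric="braycurtis")
    return DistanceMatrix(
        values=squareform(condensed),
        ids=list(profiles.data.index),
        groups=list(profiles.meta[group_col]),
    )


@dataclass
class AnosimResult:
    global_r: float
    p_value: float
    pairwise: list[tuple[str, str, float, float]]
    n_permutations: int
    seed: int | None


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    r_within = ranks[within].mean()
    r_between = ranks[~within].mean()
    return (r_between - r_within) / (m / 2.0)


def _within_mask(labels: np.ndarray) -> np.ndarray:
    n = labels.size
    iu, ju = np.triu_indices(n, k=1)
    return labels[iu] == labels[ju]


def anosim(
    dist: DistanceMatrix,
    groups: Sequence[str] | None = None,
    n_permutations: int = 9999,
    seed: int | None = None,
    pairwise: bool = True,
) -> AnosimResult:
    """Analysis of similarities on a distance matrix.

    Distances are ranked once (average ranks on ties); the permutation null
    relabels samples.  The p-value uses the add-one estimator
    ``(1 + #{R_perm >= R_obs}) / (1 + n_permutations)`` so it is never zero,
    and is reproducible bit-for-bit given (seed, n_permutations).  Pairwise
    statistics re-run the test on each group pair's submatrix, unadjusted.
    """
    labels = np.asarray(
        list(groups) if groups is not None else dist.groups
    )
    if labels is None or labels.size != dist.n:
        raise ValidationError("need one group label per sample")
    names, counts = np.unique(labels, return_counts=True)
    if names.size < 2:
        raise ValidationError("need at least two groups")
    if np.any(counts < 2):
        small = names[counts < 2].tolist()
        raise ValidationError(f"group(s) {small} have fewer than two members")

    rng = np.random.default_rng(seed)
    ranks = rankdata(dist.condensed())
    observed = _anosim_r(ranks, _within_mask(labels))
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, _within_mask(perm)) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)

    pair_stats = []
    if pairwise and names.size > 2:
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                keep = np.flatnonzero((labels == a) | (labels == b))
                sub = DistanceMatrix(
                    values=dist.values[np.ix_(keep, keep)],
                    ids=[dist.ids[k] for k in keep],
                )
                res = anosim(
                    sub, labels[keep], n_permutations=n_permutations,
                    seed=None if seed is None else seed + 1,
                    pairwise=False,
                )
                pair_stats.append((str(a), str(b), res.global_r, res.p_value))
    return AnosimResult(
        global_r=float(observed),
        p_value=float(p),
        pairwise=pair_stats,
        n_permutations=n_permutations,
        seed=seed,
    )


def interpret_r(r: float) -> str:
    """Interpretation band for an ANOSIM R value.

    >= 0.4: pattern differences are evident; 0.3-0.4: some support;
    < 0.3: very little evidence of differences.
    """
    if abs(r) > 1:
        raise ValidationError("|R| must be <= 1")
    if r >= 0.4:
        return "evident"
    if r >= 0.3:
        return "some_support"
    return "little_evidence"


@dataclass
class NmdsResult:
    coordinates: np.ndarray
    stress: float            # Kruskal stress-1
    n_restarts: int
    converged: bool
    seed: int | None


def kruskal_stress(dist: DistanceMatrix, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against input dissimilarity ranks.

    ``sqrt( sum (dhat - delta)^2 / sum delta^2 )`` where delta are the
    configuration distances and dhat their isotonic (pool-adjacent-violators)
    regression on the input-distance ranks.
    """
    from sklearn.isotonic import IsotonicRegression

    d_in = dist.condensed()
    delta = pdist(coords)
    dhat = IsotonicRegression().fit_transform(rankdata(d_in), delta)
    return float(np.sqrt(((delta - dhat) ** 2).sum() / (delta ** 2).sum()))


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
) -> NmdsResult:
    """Nonmetric multidimensional scaling of a distance matrix.

    Best of *n_restarts* random initializations; coordinates are centered
    and rotated to principal axes (the embedding is defined only up to
    rotation/reflection/translation).  Stress is recomputed as Kruskal
    stress-1 on the returned configuration.
    """
    from sklearn.manifold import MDS

    if dist.n <= k + 1:
        raise ValidationError("need more samples than dimensions + 1")
    mds = MDS(
        n_components=k,
        metric=False,
        dissimilarity="precomputed",
        n_init=n_restarts,
        max_iter=max_iter,
        eps=tol,
        random_state=None if seed is None else int(seed) % (2**32),
        normalized_stress=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = mds.fit_transform(dist.values)
    coords = coords - coords.mean(axis=0)
    # rotate to principal axes
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    coords = coords @ vt.T
    stress = kruskal_stress(dist, coords)
    return NmdsResult(
        coordinates=coords,
        stress=stress,
        n_restarts=n_restarts,
        converged=bool(mds.n_iter_ < max_iter),
        seed=seed,
    )
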