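"""Community-composition statistics for moisture-incubation experiments.

Relative-abundance tables (sample × taxon fractions) are combined with
per-sample qPCR totals into absolute abundances via the inverse hyperbolic
sine transform, asinh(rel × total) — a log-like transform that is defined at
zero. On top of this the module provides the study's community analyses:
prevalence filtering, richness/Shannon alpha diversity, Bray–Curtis
dissimilarity with principal-coordinate ordination, one-factor PERMANOVA,
and Welch-t + Benjamini–Hochberg differential abundance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import InsufficientDataError, ValidationError
from .stats import TestResult, bh_fdr, welch_t

__all__ = [
    "CommunityTable",
    "DiversityResult",
    "PermanovaResult",
    "DifferentialAbundanceResult",
    "PcoaResult",
    "prevalence_filter",
    "absolute_abundance",
    "alpha_diversity",
    "bray_curtis",
    "pcoa",
    "permanova",
    "differential_abundance",
]


@dataclass(frozen=True)
class CommunityTable:
    """Sample × taxon relative abundances plus per-sample qPCR totals.

    ``rel_abundance`` is a samples-by-taxa DataFrame of fractions whose rows
    sum to 1 (empty samples sum to 0 and are flagged downstream); ``totals``
    maps sample → concentration per mg; ``metadata`` carries the incubation
    design columns (bag, erh, time_elevated, day, condition_class);
    ``other_fraction`` tracks relative mass removed by filtering.
    """

    rel_abundance: pd.DataFrame
    totals: pd.Series
    metadata: pd.DataFrame
    other_fraction: pd.Series | None = None

    def __post_init__(self):
        mat = self.rel_abundance.to_numpy(dtype=float)
        if mat.size and mat.min() < 0:
            raise ValidationError("relative abundances must be >= 0")
        sums = mat.sum(axis=1) if mat.size else np.array([])
        removed = (
            self.other_fraction.reindex(self.rel_abundance.index).fillna(0.0).to_numpy()
            if self.other_fraction is not None
            else np.zeros(len(sums))
        )
        bad = np.abs(sums + removed - 1.0) > 1e-6
        nonempty = (sums + removed) > 0
        if np.any(bad & nonempty):
            raise ValidationError("relative-abundance rows must sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rel_abundance.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.rel_abundance.columns)


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    richness: int
    shannon: float


@dataclass(frozen=True)
class PermanovaResult:
    factor: str
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int | None


@dataclass(frozen=True)
class DifferentialAbundanceResult:
    taxon_id: str
    mean_group_a: float
    mean_group_b: float
    t_statistic: float
    p_value: float
    q_value: float
    direction: str  # "group_a" | "group_b" | "none"
    flags: tuple[str, ...] = field(default=())


@dataclass(frozen=True)
class PcoaResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def prevalence_filter(table: CommunityTable, min_prevalence: float = 0.10) -> CommunityTable:
    """Drop taxa present (abundance > 0) in fewer than ``min_prevalence`` of
    samples; the boundary is inclusive. Rows are not renormalized — removed
    mass accumulates in ``other_fraction`` so row sums remain auditable."""
    rel = table.rel_abundance
    if rel.empty:
        raise ValidationError("cannot filter an empty community table")
    prevalence = (rel > 0).mean(axis=0)
    keep = prevalence >= min_prevalence - 1e-12
    removed_mass = rel.loc[:, ~keep].sum(axis=1)
    base = (
        table.other_fraction.reindex(rel.index).fillna(0.0)
        if table.other_fraction is not None
        else pd.Series(0.0, index=rel.index)
    )
    return replace(
        table,
        rel_abundance=rel.loc[:, keep],
        other_fraction=base + removed_mass,
    )


def absolute_abundance(table: CommunityTable) -> pd.DataFrame:
    """asinh-transformed absolute abundances, asinh(rel_ij × total_i).

    The multiplication by the per-sample qPCR total precedes the transform.
    """
    missing = [s for s in table.sample_ids if s not in table.totals.index
               or not np.isfinite(table.totals[s])]
    if missing:
        raise ValidationError(f"missing qPCR totals for samples: {missing}")
    totals = table.totals.reindex(table.rel_abundance.index).to_numpy(dtype=float)
    mat = table.rel_abundance.to_numpy(dtype=float) * totals[:, None]
    return pd.DataFrame(
        np.arcsinh(mat), index=table.rel_abundance.index,
        columns=table.rel_abundance.columns,
    )


def alpha_diversity(table: CommunityTable, base: str = "e") -> list[DiversityResult]:
    """Richness and Shannon entropy per sample.

    Shannon is in nats by default (``base="e"``); ``base="2"`` gives bits,
    matching some amplicon pipelines' default.
    """
    log = np.log if base == "e" else np.log2
    out = []
    for sid, row in table.rel_abundance.iterrows():
        p = row.to_numpy(dtype=float)
        p = p[p > 0]
        if p.size:
            p = p / p.sum()  # renormalize in case of filtered rows
            shannon = float(-np.sum(p * log(p)))
        else:
            shannon = 0.0
        out.append(DiversityResult(sample_id=str(sid), richness=int(p.size),
                                   shannon=shannon))
    return out


def bray_curtis(matrix) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarities between sample rows.

    d(x, y) = 1 − 2·Σ min(x_i, y_i) / (Σx + Σy); entries in [0, 1].
    """
    df = pd.DataFrame(matrix)
    mat = df.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValidationError("abundances must be >= 0")
    zero_rows = df.index[mat.sum(axis=1) == 0].tolist()
    if zero_rows:
        raise ValidationError(f"all-zero samples have no composition: {zero_rows}")
    dist = squareform(pdist(mat, metric="braycurtis"))
    return pd.DataFrame(dist, index=df.index, columns=df.index)


def _validated_distance(distances) -> tuple[pd.DataFrame, np.ndarray]:
    df = pd.DataFrame(distances)
    mat = df.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(mat), 0.0, atol=1e-12):
        raise ValidationError("distance matrix must have a zero diagonal")
    return df, mat


def pcoa(distances, n_axes: int | None = None) -> PcoaResult:
    """Classical (metric) multidimensional scaling.

    Double-centers −½D∘D and eigendecomposes; axes are ordered by
    descending eigenvalue. Negative eigenvalues (non-Euclidean distances)
    are reported but their axes are dropped from the coordinates; no
    Lingoes/Cailliez correction is applied.
    """
    df, d = _validated_distance(distances)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > max(1e-12, 1e-10 * abs(eigvals[0]) if n else 0)
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    pos_sum = eigvals[positive].sum()
    prop = np.where(eigvals > 0, eigvals / pos_sum, 0.0) if pos_sum > 0 else eigvals * 0
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=df.index, columns=cols),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


def _permanova_f_r2(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Pseudo-F and R² from squared distances and integer group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = float(d2[iu].sum()) / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += float(np.triu(sub, k=1).sum()) / idx.size
    ss_between = ss_total - ss_within
    r2 = 1.0 - ss_within / ss_total if ss_total > 0 else 0.0
    if ss_within == 0.0:
        return math.inf, r2
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, r2


def permanova(
    distances,
    grouping,
    n_permutations: int = 999,
    seed: int | None = None,
    factor: str = "group",
    exact: bool = False,
) -> PermanovaResult:
    """One-factor permutational multivariate analysis of variance.

    SS_total is the mean pairwise squared distance times (n−1) equivalent
    (Σ_{i<j} d²_ij / n); SS_within sums the analogous within-group terms.
    R² = 1 − SS_within/SS_total and the p-value counts label permutations
    with pseudo-F at least as large as observed, with the identity included:
    p = (#{F_perm ≥ F_obs} + 1)/(n_permutations + 1). ``exact=True``
    enumerates all distinct label assignments instead (small n only).
    """
    df, mat = _validated_distance(distances)
    labels = np.asarray([grouping[s] for s in df.index] if isinstance(grouping, dict)
                        else list(grouping))
    if labels.size != mat.shape[0]:
        raise ValidationError("grouping length must match the distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = uniq.size
    if a < 2:
        raise ValidationError("permanova requires >= 2 groups")
    counts = np.bincount(codes)
    if np.any(counts == labels.size):
        raise ValidationError("a group containing every sample is untestable")
    d2 = mat**2
    f_obs, r2 = _permanova_f_r2(d2, codes, a)
    if exact:
        seen = set()
        ge = 0
        total = 0
        for perm in itertools.permutations(codes):
            if perm in seen:
                continue
            seen.add(perm)
            total += 1
            f_p, _ = _permanova_f_r2(d2, np.asarray(perm), a)
            if f_p >= f_obs - 1e-12:
                ge += 1
        return PermanovaResult(factor, float(r2), float(f_obs), ge / total, total - 1, seed)
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_permutations):
        f_p, _ = _permanova_f_r2(d2, rng.permutation(codes), a)
        if f_p >= f_obs - 1e-12:
            ge += 1
    p = (ge + 1) / (n_permutations + 1)
    return PermanovaResult(factor, float(r2), float(f_obs), float(p),
                           n_permutations, seed)


def differential_abundance(
    transformed: pd.DataFrame,
    group_a,
    group_b,
    alpha: float = 0.05,
) -> list[DifferentialAbundanceResult]:
    """Per-taxon Welch t tests on transformed abundances with BH-FDR.

    ``group_a``/``group_b`` are sample-id collections indexing the rows of
    ``transformed`` (asinh absolute abundances). Direction is the sign of
    the mean difference for taxa significant at q < alpha.
    """
    a_ids, b_ids = list(group_a), list(group_b)
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise InsufficientDataError("both groups need >= 2 samples")
    sub_a = transformed.loc[a_ids].to_numpy(dtype=float)
    sub_b = transformed.loc[b_ids].to_numpy(dtype=float)
    raw: list[tuple[str, float, float, float, float, tuple[str, ...]]] = []
    for j, taxon in enumerate(transformed.columns):
        xa, xb = sub_a[:, j], sub_b[:, j]
        if np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa[0] == xb[0]:
            raw.append((str(taxon), float(xa.mean()), float(xb.mean()), 0.0, 1.0,
                        ("constant-in-both-groups",)))
            continue
        res: TestResult = welch_t(xa, xb)
        raw.append((str(taxon), float(xa.mean()), float(xb.mean()),
                    res.statistic, res.p_value, res.flags))
    q = bh_fdr([r[4] for r in raw])
    out = []
    for (taxon, ma, mb, t, p, flags), qv in zip(raw, q):
        if qv < alpha and ma != mb:
            direction = "group_a" if ma > mb else "group_b"
        else:
            direction = "none"
        out.append(DifferentialAbundanceResult(taxon, ma, mb, t, p, float(qv),
                                               direction, flags))
    return out
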