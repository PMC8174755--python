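"""Group-level agglomeration and negative-binomial differential abundance.

ASVs are summed into taxonomic groups (genus / subgenus labels), a +1
pseudocount is added to every cell, and two-condition contrasts are tested
with a Wald test on a negative-binomial model: median-of-ratios size
factors, a method-of-moments dispersion pooled within condition, per-side
NB mean MLEs, and a Wald standard error from the observed information,
followed by Benjamini-Hochberg adjustment across groups.

This is a deliberate simplification of shrinkage-based NB frameworks: no
dispersion shrinkage toward a trend, no fold-change shrinkage, no outlier
filtering.  For balanced two-group contrasts of agglomerated (hence
high-count) groups the moments estimator is adequate and every step is
exactly specified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .community import t_test
from .io import AsvTable, SampleDesign, ValidationError, designs_to_frame
from .groups import GroupAssignment

__all__ = [
    "GroupTable",
    "Contrast",
    "DaResult",
    "agglomerate",
    "size_factors",
    "nb_wald_test",
    "bh_adjust",
    "wilcoxon_rank_sum",
    "mean_abs_lfc_compare",
]


@dataclass
class GroupTable:
    """Pseudocounted integer counts, samples x groups."""

    counts: np.ndarray
    sample_ids: list[str]
    group_labels: list[str]
    pseudo: int = 1

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.sample_ids), len(self.group_labels)):
            raise ValidationError("group table shape inconsistent with labels")
        if np.any(self.counts <= 0):
            raise ValidationError("group table must be strictly positive after pseudocount")


@dataclass(frozen=True)
class Contrast:
    """Two-group contrast: log2fc is numerator over denominator.

    ``subset`` restricts the samples first (e.g. compartment=rhizosphere,
    species=maize for a within-maize nitrogen contrast).
    """

    name: str
    factor: str
    numerator: str
    denominator: str
    subset: Mapping[str, str] = field(default_factory=dict)


@dataclass
class DaResult:
    group: str
    contrast: str
    log2fc: float
    se: float
    wald_p: float
    fdr_q: float = float("nan")

    @property
    def tier(self) -> str:
        if np.isnan(self.fdr_q):
            return "ns"
        if self.fdr_q < 0.01:
            return "***"
        if self.fdr_q < 0.05:
            return "**"
        return "ns"


def agglomerate(table: AsvTable, groups: GroupAssignment, pseudo: int = 1) -> GroupTable:
    """Sum ASV counts into groups per sample, then add the pseudocount to
    every cell."""
    unassigned = [a for a in table.asv_ids if a not in groups.labels]
    if unassigned:
        raise ValidationError(f"unassigned ASVs: {unassigned[:5]}")
    labels = sorted(set(groups.labels[a] for a in table.asv_ids))
    col = {g: i for i, g in enumerate(labels)}
    out = np.zeros((table.n_samples, len(labels)), dtype=np.int64)
    for j, asv in enumerate(table.asv_ids):
        out[:, col[groups.labels[asv]]] += table.counts[:, j]
    out += pseudo
    return GroupTable(out, list(table.sample_ids), labels, pseudo=pseudo)


def size_factors(gt: GroupTable) -> np.ndarray:
    """Median-of-ratios normalization: s_j = median over groups of the
    ratio of sample j's count to the group's geometric mean across
    samples.  Requires strictly positive counts (the pseudocount)."""
    counts = gt.counts.astype(float)
    log_geomean = np.log(counts).mean(axis=0)  # per group
    ratios = np.exp(np.log(counts) - log_geomean[None, :])
    return np.median(ratios, axis=1)


def _nb_mean_mle(k: np.ndarray, s: np.ndarray, alpha: float) -> float:
    """MLE of the NB mean parameter mu with offsets s and known dispersion:
    solves sum (k_j - s_j mu) / (1 + alpha s_j mu) = 0 (monotone in mu)."""
    if alpha <= 0:
        return float(k.sum() / s.sum())

    def score(log_mu: float) -> float:
        m = s * np.exp(log_mu)
        return float(((k - m) / (1.0 + alpha * m)).sum())

    guess = np.log(k.sum() / s.sum())
    lo, hi = guess - 30.0, guess + 30.0
    return float(np.exp(optimize.brentq(score, lo, hi, xtol=1e-12)))


def nb_wald_test(
    gt: GroupTable,
    designs: Sequence[SampleDesign],
    contrast: Contrast,
    group_filter: Sequence[str] | None = None,
) -> list[DaResult]:
    """Wald test of differential abundance per group for a two-group
    contrast, BH-adjusted across the tested groups.

    Normalizes by median-of-ratios size factors computed on the contrast's
    samples; dispersion is a per-group method-of-moments estimate
    alpha = max(0, (s2 - mean) / mean^2) on normalized counts pooled within
    condition; alpha = 0 falls back to the Poisson Wald SE.
    """
    meta = designs_to_frame(designs)
    mask = np.ones(len(meta), dtype=bool)
    for f, level in contrast.subset.items():
        mask &= (meta[f] == level).to_numpy()
    if contrast.factor not in meta.columns:
        raise ValidationError(f"unknown contrast factor {contrast.factor!r}")
    side_a = mask & (meta[contrast.factor] == contrast.numerator).to_numpy()
    side_b = mask & (meta[contrast.factor] == contrast.denominator).to_numpy()
    ids_a = [s for s, keep in zip(meta.index, side_a) if keep and s in set(gt.sample_ids)]
    ids_b = [s for s, keep in zip(meta.index, side_b) if keep and s in set(gt.sample_ids)]
    if not ids_a or not ids_b:
        raise ValidationError(f"contrast {contrast.name!r} has an empty side")

    row = {s: i for i, s in enumerate(gt.sample_ids)}
    rows = [row[s] for s in ids_a + ids_b]
    sub = GroupTable(gt.counts[rows], ids_a + ids_b, list(gt.group_labels), pseudo=gt.pseudo)
    s = size_factors(sub)
    n_a = len(ids_a)
    in_a = np.zeros(len(rows), dtype=bool)
    in_a[:n_a] = True

    groups = list(gt.group_labels)
    if group_filter is not None:
        wanted = set(group_filter)
        groups = [g for g in groups if g in wanted]
    col = {g: i for i, g in enumerate(gt.group_labels)}

    results = []
    for g in groups:
        k = sub.counts[:, col[g]].astype(float)
        q = k / s
        mu_bar = q.mean()
        centered = np.concatenate([q[in_a] - q[in_a].mean(), q[~in_a] - q[~in_a].mean()])
        s2 = float((centered**2).sum() / max(len(q) - 2, 1))
        alpha = max(0.0, (s2 - mu_bar) / mu_bar**2) if mu_bar > 0 else 0.0
        mu_a = _nb_mean_mle(k[in_a], s[in_a], alpha)
        mu_b = _nb_mean_mle(k[~in_a], s[~in_a], alpha)
        info_a = float((s[in_a] * mu_a / (1.0 + alpha * s[in_a] * mu_a)).sum())
        info_b = float((s[~in_a] * mu_b / (1.0 + alpha * s[~in_a] * mu_b)).sum())
        se_ln = np.sqrt(1.0 / info_a + 1.0 / info_b)
        beta = np.log(mu_a) - np.log(mu_b)
        z = beta / se_ln
        p = float(2.0 * stats.norm.sf(abs(z)))
        results.append(
            DaResult(
                group=g,
                contrast=contrast.name,
                log2fc=float(beta / np.log(2.0)),
                se=float(se_ln / np.log(2.0)),
                wald_p=p,
            )
        )
    qvals = bh_adjust([r.wald_p for r in results])
    for r, qv in zip(results, qvals):
        r.fdr_q = float(qv)
    return results


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(n)
    out[order] = q
    return out


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon/Mann-Whitney rank-sum test.

    Uses exact enumeration when min(n) <= 10, combined n <= 25, and no
    ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("empty input")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = min(len(x), len(y)) <= 10 and len(pooled) <= 25 and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


def mean_abs_lfc_compare(
    results_a: Sequence[DaResult], results_b: Sequence[DaResult]
) -> tuple[float, float, float]:
    """Compare effect-size magnitudes of two contrasts: means of |log2fc|
    plus a two-sided Welch t-test p-value."""
    if not results_a or not results_b:
        raise ValidationError("empty result list")
    a = np.abs([r.log2fc for r in results_a])
    b = np.abs([r.log2fc for r in results_b])
    _, p = t_test(a, b, tails="two")
    return float(a.mean()), float(b.mean()), float(p)
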