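"""Community-level structure: diversity, distances, ordination, tests.

Distances (Bray-Curtis, weighted UniFrac) feed classical PCoA, distance-based
RDA, and a sequential (Type I) PERMANOVA in the McArdle-Anderson formulation,
the combination used to describe the high-level structure of rhizosphere vs
bulk-soil communities across the factorial design.

Bray-Curtis is a semimetric; the triangle inequality is not assumed anywhere.
Negative PCoA eigenvalues are retained in the result but excluded from
percent-explained (no Cailliez/Lingoes correction by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .io import AsvTable, SampleDesign, ValidationError, designs_to_frame

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaTable",
    "shannon",
    "bray_curtis",
    "weighted_unifrac",
    "distance_matrix",
    "pcoa",
    "permanova",
    "constrained_pcoa",
    "t_test",
]


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    d: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape inconsistent with ids")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValidationError("distance matrix not symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-10):
            raise ValidationError("distance matrix diagonal not zero")
        if np.any(self.d < -1e-12):
            raise ValidationError("negative distances")
        self.d = (self.d + self.d.T) / 2.0
        np.fill_diagonal(self.d, 0.0)


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes (positive-eigenvalue axes)
    eigenvalues: np.ndarray  # all eigenvalues, nonincreasing
    percent_explained: np.ndarray  # per positive axis, sums to 100


@dataclass
class PermanovaTable:
    """Sequential decomposition of a distance matrix by model terms."""

    terms: list[str]
    df: dict[str, int]
    ss: dict[str, float]
    pseudo_f: dict[str, float]
    r2: dict[str, float]
    p: dict[str, float]
    residual_ss: float
    residual_df: int
    total_ss: float
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.terms:
            rows.append({"term": t, "df": self.df[t], "ss": self.ss[t],
                         "pseudo_F": self.pseudo_f[t], "R2": self.r2[t], "p": self.p[t]})
        rows.append({"term": "Residual", "df": self.residual_df, "ss": self.residual_ss,
                     "pseudo_F": np.nan, "R2": self.residual_ss / self.total_ss, "p": np.nan})
        rows.append({"term": "Total", "df": self.residual_df + sum(self.df.values()),
                     "ss": self.total_ss, "pseudo_F": np.nan, "R2": 1.0, "p": np.nan})
        return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# Alpha diversity and pairwise distances
# ---------------------------------------------------------------------------

def shannon(counts: Sequence[float]) -> float:
    """Shannon index H = -sum p_i ln p_i (natural log) over positive counts."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValidationError("negative counts")
    total = c.sum()
    if total <= 0:
        raise ValidationError("all-zero count vector")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity 1 - 2 sum(min) / (sum x + sum y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("length mismatch")
    if np.any(x < 0) or np.any(y < 0):
        raise ValidationError("negative counts")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValidationError("both vectors all-zero")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def _branch_table(tree: TreeNode, asv_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """(branch lengths, tip-membership indicator) for every non-root branch.

    Membership is a (n_branches, n_asvs) 0/1 matrix: tips of ``asv_ids``
    descending from each branch.
    """
    tips = {t.name for t in tree.tips()}
    missing = [a for a in asv_ids if a not in tips]
    if missing:
        raise ValidationError(f"ASVs missing from tree: {missing[:5]}")
    col = {a: i for i, a in enumerate(asv_ids)}
    lengths = []
    members = []
    for node in tree.postorder(include_self=False):
        row = np.zeros(len(asv_ids))
        for tip in node.tips(include_self=True):
            if tip.name in col:
                row[col[tip.name]] = 1.0
        lengths.append(node.length or 0.0)
        members.append(row)
    return np.asarray(lengths), np.asarray(members)


def weighted_unifrac(
    x: Sequence[float],
    y: Sequence[float],
    tree: TreeNode,
    asv_ids: Sequence[str],
    normalized: bool = True,
) -> float:
    """Weighted UniFrac between two count vectors over ``asv_ids``.

    raw = sum_b l_b |p_b - q_b| with p_b, q_b the fractions of each sample
    descending from branch b; the normalized variant divides by
    sum_b l_b (p_b + q_b) and is bounded in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValidationError("empty sample")
    p = x / x.sum()
    q = y / y.sum()
    lengths, members = _branch_table(tree, asv_ids)
    pb = members @ p
    qb = members @ q
    raw = float((lengths * np.abs(pb - qb)).sum())
    if not normalized:
        return raw
    denom = float((lengths * (pb + qb)).sum())
    if denom == 0:
        return 0.0
    return raw / denom


def distance_matrix(
    table: AsvTable,
    metric: str = "bray_curtis",
    tree: TreeNode | None = None,
    normalized: bool = True,
) -> DistanceMatrix:
    """All pairwise distances among the table's samples."""
    n = table.n_samples
    d = np.zeros((n, n))
    if metric == "bray_curtis":
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = bray_curtis(table.counts[i], table.counts[j])
    elif metric == "weighted_unifrac":
        if tree is None:
            raise ValidationError("weighted_unifrac requires a tree")
        lengths, members = _branch_table(tree, table.asv_ids)
        totals = table.counts.sum(axis=1, keepdims=True).astype(float)
        if np.any(totals <= 0):
            raise ValidationError("sample with zero total count")
        fracs = (table.counts / totals) @ members.T  # samples x branches
        for i in range(n):
            diff = np.abs(fracs[i] - fracs[i + 1:])
            raw = diff @ lengths
            if normalized:
                denom = (fracs[i] + fracs[i + 1:]) @ lengths
                raw = np.divide(raw, denom, out=np.zeros_like(raw), where=denom > 0)
            d[i, i + 1:] = raw
            d[i + 1:, i] = raw
    else:
        raise ValidationError(f"unknown metric: {metric!r}")
    return DistanceMatrix(list(table.sample_ids), d, metric)


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical scaling (principal coordinates) of a distance matrix."""
    n = len(dm.sample_ids)
    if n < 3:
        raise ValidationError("PCoA needs at least 3 samples")
    g = _gower_center(dm.d)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = eigvals > 1e-10
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pos_sum = eigvals[pos].sum()
    percent = 100.0 * eigvals[pos] / pos_sum if pos_sum > 0 else np.zeros(0)
    return OrdinationResult(list(dm.sample_ids), coords, eigvals, percent)


# ---------------------------------------------------------------------------
# Model matrices for design-based tests
# ---------------------------------------------------------------------------

def _term_columns(meta: pd.DataFrame, term: str) -> np.ndarray:
    """Treatment-coded columns for one model term (factor or ':' interaction)."""
    parts = term.split(":")
    for f in parts:
        if f not in meta.columns:
            raise ValidationError(f"unknown design factor {f!r} in term {term!r}")
        if meta[f].nunique() < 2:
            raise ValidationError(f"factor {f!r} has a single level")
    blocks = []
    for f in parts:
        levels = sorted(meta[f].unique())
        dummies = np.column_stack([(meta[f] == l).to_numpy(float) for l in levels[1:]])
        blocks.append(dummies)
    cols = blocks[0]
    for b in blocks[1:]:
        cols = np.concatenate([cols[:, i : i + 1] * b for i in range(cols.shape[1])], axis=1)
    return cols


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    rank = int((np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())).sum())
    q = q[:, :rank]
    return q @ q.T


def _sequential_hats(meta: pd.DataFrame, terms: Sequence[str]) -> tuple[list[np.ndarray], list[int]]:
    """Hat matrices for the cumulative models 1, 1+T1, 1+T1+T2, ... and the
    rank increment (df) contributed by each term."""
    n = len(meta)
    x = np.ones((n, 1))
    hats = []
    dfs = []
    prev_rank = 1
    for term in terms:
        x = np.hstack([x, _term_columns(meta, term)])
        h = _hat(x)
        rank = int(round(np.trace(h)))
        dfs.append(rank - prev_rank)
        prev_rank = rank
        hats.append(h)
    return hats, dfs


def permanova(
    dm: DistanceMatrix,
    designs: Sequence[SampleDesign],
    model: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaTable:
    """Sequential (Type I) PERMANOVA on a distance matrix.

    Partition of the Gower-centered inner-product matrix following
    McArdle & Anderson; terms enter in the order given (interactions as
    "a:b").  p-values use free permutation of sample rows:
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    meta = designs_to_frame(designs).loc[dm.sample_ids]
    g = _gower_center(dm.d)
    total_ss = float(np.trace(g))
    hats, dfs = _sequential_hats(meta, list(model))
    for term, df in zip(model, dfs):
        if df == 0:
            raise ValidationError(f"term {term!r} adds no rank (aliased)")
    n = len(meta)
    resid_df = n - 1 - sum(dfs)
    if resid_df <= 0:
        raise ValidationError("model saturates the design (no residual df)")

    def term_stats(gmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cum = np.array([float((h * gmat).sum()) for h in hats])  # tr(H G)
        ss = np.diff(np.concatenate([[0.0], cum]))
        resid = float(np.trace(gmat)) - cum[-1]
        f = (ss / np.array(dfs)) / (resid / resid_df)
        return ss, f

    ss_obs, f_obs = term_stats(g)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(model))
    # tolerance so permutations tied with the observed statistic count as
    # exceedances despite floating-point jitter
    f_ref = f_obs - 1e-10 * (1.0 + np.abs(f_obs))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, f_perm = term_stats(g[np.ix_(perm, perm)])
        exceed += f_perm >= f_ref
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    return PermanovaTable(
        terms=list(model),
        df={t: d for t, d in zip(model, dfs)},
        ss={t: float(s) for t, s in zip(model, ss_obs)},
        pseudo_f={t: float(f) for t, f in zip(model, f_obs)},
        r2={t: float(s / total_ss) for t, s in zip(model, ss_obs)},
        p={t: float(p) for t, p in zip(model, pvals)},
        residual_ss=float(total_ss - ss_obs.sum()),
        residual_df=resid_df,
        total_ss=total_ss,
        n_permutations=n_perm,
    )


def constrained_pcoa(
    dm: DistanceMatrix,
    designs: Sequence[SampleDesign],
    constraints: Sequence[str],
) -> OrdinationResult:
    """Distance-based RDA: ordination of the part of the Gower-centered
    matrix explained by the constraint terms.

    percent_explained is relative to total inertia tr(G), so the axes
    report how much of the *community* variation each constrained axis
    captures (constrained + unconstrained inertia = total).
    """
    meta = designs_to_frame(designs).loc[dm.sample_ids]
    g = _gower_center(dm.d)
    n = len(meta)
    x = np.ones((n, 1))
    prev_rank = 1
    for term in constraints:
        x = np.hstack([x, _term_columns(meta, term)])
        h = _hat(x)
        rank = int(round(np.trace(h)))
        if rank == prev_rank:
            raise ValidationError(f"constraint term {term!r} is aliased with earlier terms")
        prev_rank = rank
    h = _hat(x)
    fitted = h @ g @ h
    eigvals, eigvecs = np.linalg.eigh(fitted)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = eigvals > 1e-10
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    total = float(np.trace(g))
    percent = 100.0 * eigvals[pos] / total if total > 0 else np.zeros(0)
    return OrdinationResult(list(dm.sample_ids), coords, eigvals, percent)


# ---------------------------------------------------------------------------
# Welch t test
# ---------------------------------------------------------------------------

def t_test(
    x: Sequence[float],
    y: Sequence[float],
    tails: str = "two",
    side: str = "less",
    variant: str = "welch",
) -> tuple[float, float]:
    """Welch's unequal-variance t test with Satterthwaite df.

    ``tails="one"`` tests the hypothesis that x is shifted to the given
    ``side`` of y ("less" or "greater"); the one-tailed p is half the
    two-tailed p when the observed effect lies on the hypothesized side.
    """
    if variant != "welch":
        raise ValidationError(f"unknown t-test variant: {variant!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs n >= 2")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return (np.inf if np.mean(x) > np.mean(y) else -np.inf), 0.0
    if tails == "two":
        res = stats.ttest_ind(x, y, equal_var=False)
    elif tails == "one":
        alternative = {"less": "less", "greater": "greater"}.get(side)
        if alternative is None:
            raise ValidationError(f"unknown side: {side!r}")
        res = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
    else:
        raise ValidationError(f"tails must be 'one' or 'two', got {tails!r}")
    return float(res.statistic), float(res.pvalue)
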