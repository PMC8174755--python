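"""Subgenus functional-group discovery and the 97%-identity comparator.

The discovery procedure turns "look at the tree next to the variance
scores" into an explicit rule: per genus, fit diagonal-covariance Gaussian
mixtures with K in {1..3} on selected variance scores, pick K by BIC, and
accept a split only if every cluster is large enough, cluster means are
separated, and each cluster occupies at most ``max_components`` connected
components of the genus subtree under a minimal-change (Fitch) labelling of
internal nodes.  Subgroups are labelled Genus_S1, Genus_S2, ... by
decreasing total read count.

The OTU comparator reproduces classical de novo greedy centroid clustering
at a fixed identity threshold, the approach that can merge functionally
distinct subgroups whose 16S sequences are nearly identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skbio import TreeNode
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from .io import AsvTable, SequenceSet, Taxonomy, ValidationError
from .varpart import VarianceProfile

__all__ = [
    "GroupingParams",
    "GroupAssignment",
    "SplitDiagnostics",
    "detect_subgroups",
    "assign_all_groups",
    "cluster_otus_97",
    "compare_groupings",
]


@dataclass(frozen=True)
class GroupingParams:
    """Thresholds of the subgroup-discovery rule (all config-exposed)."""

    score_factors: tuple[str, ...] = ("species", "nitrogen")
    min_asvs: int = 5
    min_cluster_size: int = 3
    min_separation: float = 0.05
    max_components: int = 2
    max_k: int = 3
    gmm_n_init: int = 5
    gmm_seed: int = 0
    # variance floor for the mixture components; scores live on [0, 1], so
    # 1e-3 (sd ~0.03) prevents degenerate near-singleton clusters from
    # dominating the BIC
    gmm_reg_covar: float = 1e-3


@dataclass
class GroupAssignment:
    """ASV -> taxonomic-group label ("Genus" or "Genus_S<k>")."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        by_genus: dict[str, set[int]] = {}
        for asv, label in self.labels.items():
            genus, _, suffix = label.rpartition("_S")
            if suffix and suffix.isdigit():
                by_genus.setdefault(genus, set()).add(int(suffix))
        for genus, ks in by_genus.items():
            if ks != set(range(1, len(ks) + 1)):
                raise ValidationError(
                    f"{genus!r}: subgroup indices {sorted(ks)} not contiguous from 1"
                )

    @property
    def n_groups(self) -> int:
        return len(set(self.labels.values()))

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for asv, label in self.labels.items():
            out.setdefault(label, []).append(asv)
        return out


@dataclass
class SplitDiagnostics:
    genus: str
    n_asvs: int
    chosen_k: int
    decision: str  # split | no_split | rejected_incoherent
    bic: dict[int, float] = field(default_factory=dict)
    cluster_means: list[dict[str, float]] = field(default_factory=list)
    cluster_sizes: list[int] = field(default_factory=list)
    coherence: dict[str, int] = field(default_factory=dict)  # label -> n tree components

    def to_dict(self) -> dict:
        return {
            "genus": self.genus,
            "n_asvs": self.n_asvs,
            "chosen_k": self.chosen_k,
            "decision": self.decision,
            "bic": {str(k): v for k, v in self.bic.items()},
            "cluster_means": self.cluster_means,
            "cluster_sizes": self.cluster_sizes,
            "coherence": self.coherence,
        }


# ---------------------------------------------------------------------------
# Tree coherence: minimal-change labelling, component counting
# ---------------------------------------------------------------------------

def _fitch_components(tree: TreeNode, leaf_labels: Mapping[str, int]) -> dict[int, int]:
    """Connected components per label after Fitch minimal-change labelling.

    Up-pass assigns candidate label sets (intersection if nonempty, else
    union); down-pass fixes each internal node to its parent's label when
    possible, smallest label otherwise.  A component of label c is a maximal
    connected set of nodes labelled c; counted as the number of 'birth'
    edges (parent label != c, node label == c), plus one if the root
    carries c.
    """
    sub = tree.shear(list(leaf_labels)) if {t.name for t in tree.tips()} != set(leaf_labels) else tree
    cand: dict[int, set[int]] = {}
    for node in sub.postorder(include_self=True):
        if node.is_tip():
            cand[id(node)] = {leaf_labels[node.name]}
        else:
            sets = [cand[id(c)] for c in node.children]
            inter = set.intersection(*sets)
            cand[id(node)] = inter if inter else set.union(*sets)
    final: dict[int, int] = {}
    counts: dict[int, int] = {}
    for node in sub.preorder(include_self=True):
        options = cand[id(node)]
        if node.parent is None:
            label = min(options)
            counts[label] = counts.get(label, 0) + 1
        else:
            parent_label = final[id(node.parent)]
            label = parent_label if parent_label in options else min(options)
            if label != parent_label:
                counts[label] = counts.get(label, 0) + 1
        final[id(node)] = label
    return counts


# ---------------------------------------------------------------------------
# Subgroup detection
# ---------------------------------------------------------------------------

def _score_matrix(
    asv_ids: Sequence[str],
    profiles: Mapping[str, VarianceProfile],
    factors: Sequence[str],
) -> np.ndarray:
    missing = [a for a in asv_ids if a not in profiles]
    if missing:
        raise ValidationError(f"missing variance profiles for {missing[:5]}")
    return np.array([[profiles[a].scores[f] for f in factors] for a in asv_ids])


def detect_subgroups(
    genus: str,
    genus_asvs: Sequence[str],
    profiles: Mapping[str, VarianceProfile],
    tree: TreeNode,
    params: GroupingParams | None = None,
    abundance: Mapping[str, float] | None = None,
) -> tuple[dict[str, str], SplitDiagnostics]:
    """Decide whether one genus splits into subgenus groups.

    Returns the per-ASV labels for this genus and full diagnostics.  The
    result is invariant to the input order of ``genus_asvs``.
    """
    params = params or GroupingParams()
    asv_ids = sorted(genus_asvs)
    if len(asv_ids) < params.min_asvs:
        raise ValidationError(
            f"{genus!r}: {len(asv_ids)} ASVs < min_asvs={params.min_asvs}"
        )
    tips = {t.name for t in tree.tips()}
    missing = [a for a in asv_ids if a not in tips]
    if missing:
        raise ValidationError(f"{genus!r}: ASVs missing from tree: {missing[:5]}")

    x = _score_matrix(asv_ids, profiles, params.score_factors)
    diag = SplitDiagnostics(genus=genus, n_asvs=len(asv_ids), chosen_k=1, decision="no_split")

    import warnings as _warnings

    from sklearn.exceptions import ConvergenceWarning

    models = {}
    for k in range(1, params.max_k + 1):
        if k > len(asv_ids):
            break
        with _warnings.catch_warnings():
            # duplicate score vectors make kmeans init report fewer distinct
            # clusters; the mixture fit itself is fine
            _warnings.simplefilter("ignore", ConvergenceWarning)
            gm = GaussianMixture(
                n_components=k,
                covariance_type="diag",
                n_init=params.gmm_n_init,
                random_state=params.gmm_seed,
                reg_covar=params.gmm_reg_covar,
            ).fit(x)
        models[k] = gm
        diag.bic[k] = float(gm.bic(x))

    def no_split(decision: str) -> tuple[dict[str, str], SplitDiagnostics]:
        diag.chosen_k = 1
        diag.decision = decision
        diag.cluster_sizes = [len(asv_ids)]
        diag.cluster_means = [
            {f: float(m) for f, m in zip(params.score_factors, x.mean(axis=0))}
        ]
        return {a: genus for a in asv_ids}, diag

    def admissible(k: int) -> bool:
        """Cluster sizes and mean separation; K failing these falls back to
        the next-best K rather than forcing a split."""
        if k == 1:
            return True
        gm = models[k]
        raw = gm.predict(x)
        if np.bincount(raw, minlength=k).min() < params.min_cluster_size:
            return False
        means = gm.means_
        for i in range(k):
            for j in range(i + 1, k):
                if np.max(np.abs(means[i] - means[j])) < params.min_separation:
                    return False
        return True

    best_k = next(
        (k for k in sorted(diag.bic, key=diag.bic.get) if admissible(k)), 1
    )
    if best_k == 1:
        return no_split("no_split")

    gm = models[best_k]
    raw = gm.predict(x)
    sizes = np.bincount(raw, minlength=best_k)
    means = gm.means_
    genus_tree = tree.shear(asv_ids)
    components = _fitch_components(genus_tree, dict(zip(asv_ids, raw.tolist())))
    if any(c > params.max_components for c in components.values()):
        labels, diag2 = no_split("rejected_incoherent")
        diag2.coherence = {str(k): v for k, v in components.items()}
        return labels, diag2

    # order clusters by decreasing total read count (falling back to size)
    if abundance is not None:
        totals = [sum(abundance.get(a, 0.0) for a, r in zip(asv_ids, raw) if r == c)
                  for c in range(best_k)]
    else:
        totals = sizes.astype(float).tolist()
    order = sorted(range(best_k), key=lambda c: (-totals[c], c))
    rank = {c: i + 1 for i, c in enumerate(order)}
    labels = {a: f"{genus}_S{rank[r]}" for a, r in zip(asv_ids, raw.tolist())}
    diag.chosen_k = best_k
    diag.decision = "split"
    diag.cluster_sizes = [int(sizes[c]) for c in order]
    diag.cluster_means = [
        {f: float(m) for f, m in zip(params.score_factors, means[c])} for c in order
    ]
    diag.coherence = {f"S{rank[c]}": components.get(c, 0) for c in range(best_k)}
    return labels, diag


def assign_all_groups(
    profiles: Sequence[VarianceProfile],
    tax: Taxonomy,
    tree: TreeNode,
    table: AsvTable | None = None,
    params: GroupingParams | None = None,
) -> tuple[GroupAssignment, dict[str, SplitDiagnostics]]:
    """Run subgroup detection over every qualifying genus.

    Genera with fewer than ``min_asvs`` profiled ASVs, or with an
    unassigned genus rank, keep the genus (or family-level placeholder)
    label unchanged.
    """
    params = params or GroupingParams()
    prof_map = {p.asv_id: p for p in profiles}
    abundance = None
    if table is not None:
        totals = table.counts.sum(axis=0)
        abundance = dict(zip(table.asv_ids, totals.astype(float)))
    genus_series = tax.genus_of()
    by_genus: dict[str, list[str]] = {}
    for asv_id in prof_map:
        if asv_id not in genus_series.index:
            raise ValidationError(f"ASV {asv_id!r} missing from taxonomy")
        genus = genus_series[asv_id]
        label = genus if genus else f"unassigned_{tax.lineage(asv_id)[4] or 'unknown'}"
        by_genus.setdefault(label, []).append(asv_id)

    labels: dict[str, str] = {}
    diagnostics: dict[str, SplitDiagnostics] = {}
    for genus in sorted(by_genus):
        asvs = by_genus[genus]
        if len(asvs) < params.min_asvs or genus.startswith("unassigned_"):
            for a in asvs:
                labels[a] = genus
            continue
        g_labels, diag = detect_subgroups(
            genus, asvs, prof_map, tree, params=params, abundance=abundance
        )
        labels.update(g_labels)
        diagnostics[genus] = diag
    return GroupAssignment(labels), diagnostics


# ---------------------------------------------------------------------------
# Greedy 97%-identity OTU comparator
# ---------------------------------------------------------------------------

def _alignment_identity(a: str, b: str, aligner) -> float:
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(1 for c1, c2 in zip(s1, s2) if c1 == c2 and c1 != "-")
    return matches / len(s1)


def cluster_otus_97(
    seqs: SequenceSet,
    threshold: float = 0.97,
    abundance: Mapping[str, float] | None = None,
    genus: str = "OTU",
) -> GroupAssignment:
    """De novo greedy centroid clustering at a global-alignment identity
    threshold.

    ASVs are processed by decreasing total abundance (ties by id); each
    joins the first centroid with Needleman-Wunsch identity (match 1,
    mismatch -1, gap -2; identity = matches / alignment columns) >= the
    threshold, else founds a new centroid.  Labels follow the Genus_S<k>
    grammar, ordered by decreasing cluster abundance; a single cluster
    keeps the plain genus label.
    """
    from Bio import Align

    if not 0.5 < threshold <= 1.0:
        raise ValidationError(f"identity threshold {threshold} outside (0.5, 1]")
    if len(seqs) == 0:
        raise ValidationError("no sequences to cluster")
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-2,
    )
    ids = list(seqs.sequences)
    if abundance is not None:
        ids.sort(key=lambda a: (-abundance.get(a, 0.0), a))
    else:
        ids.sort()
    centroids: list[str] = []  # asv ids of cluster founders, in founding order
    members: dict[str, list[str]] = {}
    for asv in ids:
        for cen in centroids:
            if _alignment_identity(seqs[asv], seqs[cen], aligner) >= threshold:
                members[cen].append(asv)
                break
        else:
            centroids.append(asv)
            members[asv] = [asv]
    if len(centroids) == 1:
        return GroupAssignment({a: genus for a in ids})
    totals = {
        cen: sum((abundance or {}).get(a, 0.0) for a in mem) if abundance else len(mem)
        for cen, mem in members.items()
    }
    order = sorted(centroids, key=lambda c: (-totals[c], c))
    labels = {}
    for k, cen in enumerate(order, start=1):
        for a in members[cen]:
            labels[a] = f"{genus}_S{k}"
    return GroupAssignment(labels)


def compare_groupings(
    a: GroupAssignment,
    b: GroupAssignment,
    asv_ids: Sequence[str] | None = None,
) -> tuple[int, int, float]:
    """Compare two groupings on a shared ASV universe.

    Returns (number of groups under a, under b, adjusted Rand index of the
    induced partitions).  ``asv_ids`` restricts the scope (e.g. one genus);
    by default the intersection of the two assignments is used.
    """
    shared = set(a.labels) & set(b.labels)
    if asv_ids is not None:
        shared &= set(asv_ids)
    if not shared:
        raise ValidationError("no shared ASVs between assignments")
    ids = sorted(shared)
    pa = [a.labels[x] for x in ids]
    pb = [b.labels[x] for x in ids]
    return len(set(pa)), len(set(pb)), float(adjusted_rand_score(pa, pb))
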