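"""Filtering and transforms between the raw ASV table and every analysis.

Rules are applied in a fixed order (domain, lineage, min_total,
min_prevalence) and itemised in a FilterReport so the effect of each rule
is auditable.  The log-relative-abundance transform is the input to
variance partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import AsvTable, SampleDesign, Taxonomy, ValidationError

__all__ = ["FilterRules", "FilterReport", "filter_taxa", "subset_compartment", "log_relative_abundance"]

ALLOWED_DOMAINS = ("Bacteria", "Archaea")
DEFAULT_EXCLUDED_LINEAGES = ("Chloroplast", "Mitochondria")


@dataclass(frozen=True)
class FilterRules:
    """Thresholds of the filter cascade.

    min_prevalence counts samples with a nonzero count; defaults (total
    count >= 25, present in >= 2 samples) are deliberately mild and meant
    to be tuned per dataset.
    """

    allowed_domains: tuple[str, ...] = ALLOWED_DOMAINS
    excluded_lineages: tuple[str, ...] = DEFAULT_EXCLUDED_LINEAGES
    min_total: int = 25
    min_prevalence: int = 2


@dataclass
class FilterReport:
    asvs_in: int
    asvs_out: int
    reads_in: int
    reads_out: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.asvs_out <= self.asvs_in
        assert self.reads_out <= self.reads_in
        assert sum(self.removed_by_rule.values()) == self.asvs_in - self.asvs_out

    def to_dict(self) -> dict:
        return {
            "asvs_in": self.asvs_in,
            "asvs_out": self.asvs_out,
            "reads_in": self.reads_in,
            "reads_out": self.reads_out,
            "removed_by_rule": dict(self.removed_by_rule),
        }


def filter_taxa(
    table: AsvTable, tax: Taxonomy, rules: FilterRules | None = None
) -> tuple[AsvTable, FilterReport]:
    """Apply the quality/abundance filter cascade in order.

    Order: non-prokaryotic domains, excluded lineages (chloroplast,
    mitochondria at any rank), minimum total count, minimum prevalence.
    Every ASV must be annotated.  Removing all ASVs is an error.
    """
    rules = rules or FilterRules()
    missing = [a for a in table.asv_ids if a not in tax.ranks.index]
    if missing:
        raise ValidationError(f"unannotated ASVs: {missing[:5]}")

    keep = list(table.asv_ids)
    removed: dict[str, int] = {}

    ranks = tax.ranks
    bad_domain = {a for a in keep if ranks.at[a, "domain"] not in rules.allowed_domains}
    removed["domain"] = len(bad_domain)
    keep = [a for a in keep if a not in bad_domain]

    excluded = {x.lower() for x in rules.excluded_lineages}
    bad_lineage = {
        a for a in keep
        if any(v.lower() in excluded for v in ranks.loc[a] if v)
    }
    removed["lineage"] = len(bad_lineage)
    keep = [a for a in keep if a not in bad_lineage]

    col = {a: i for i, a in enumerate(table.asv_ids)}
    totals = table.counts.sum(axis=0)
    bad_total = {a for a in keep if totals[col[a]] < rules.min_total}
    removed["min_total"] = len(bad_total)
    keep = [a for a in keep if a not in bad_total]

    prevalence = (table.counts > 0).sum(axis=0)
    bad_prev = {a for a in keep if prevalence[col[a]] < rules.min_prevalence}
    removed["min_prevalence"] = len(bad_prev)
    keep = [a for a in keep if a not in bad_prev]

    if not keep:
        raise ValidationError("filter rules removed all ASVs")
    out = table.select_asvs(keep)
    report = FilterReport(
        asvs_in=table.n_asvs,
        asvs_out=out.n_asvs,
        reads_in=int(table.counts.sum()),
        reads_out=int(out.counts.sum()),
        removed_by_rule=removed,
    )
    return out, report


def subset_compartment(
    table: AsvTable, designs: Sequence[SampleDesign], compartment: str
) -> AsvTable:
    """Samples of one compartment, dropping ASVs absent from it.

    "Present" means total count > 0 within the compartment, mirroring how
    the bulk-soil ASV set is a subset of the full ASV set.
    """
    if compartment not in ("rhizosphere", "bulk"):
        raise ValidationError(f"unknown compartment: {compartment!r}")
    wanted = [d.sample_id for d in designs if d.compartment == compartment]
    wanted = [s for s in wanted if s in set(table.sample_ids)]
    if not wanted:
        raise ValidationError(f"no samples in compartment {compartment!r}")
    sub = table.select_samples(wanted)
    present = sub.counts.sum(axis=0) > 0
    keep = [a for a, p in zip(sub.asv_ids, present) if p]
    if not keep:
        raise ValidationError(f"no ASVs present in compartment {compartment!r}")
    return sub.select_asvs(keep)


def log_relative_abundance(table: AsvTable, pseudo: float = 1.0) -> np.ndarray:
    """Natural log of pseudocounted relative abundances, samples x ASVs.

    r_ij = (c_ij + pseudo) / sum_j (c_ij + pseudo); rows of exp(result)
    sum to 1.
    """
    counts = table.counts.astype(float)
    if pseudo <= 0 and (counts == 0).any():
        raise ValidationError("pseudo must be > 0 when zero counts are present")
    if pseudo < 0:
        raise ValidationError("pseudo must be nonnegative")
    shifted = counts + pseudo
    sums = shifted.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValidationError("sample with nonpositive total after pseudocount")
    return np.log(shifted / sums)
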