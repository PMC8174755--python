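"""Synthetic 16S community generator for the crossed field design.

Emulates the structure of a two-year maize/soybean rotation experiment:
2 years x 3 months x 2 blocks x 4 plots (M, S, MS, SM) x 2 N levels x
2 compartments x 2 subsamples = 384 samples, with ~2,000 ASVs organised in
genera on a simulated phylogeny.

The count model mirrors the analysis model downstream: each ASV has a
log-scale linear predictor composed of a baseline plus one random intercept
per design factor, with the per-factor share of the log-scale variance
("planted fraction") set by the ASV's class.  Effects are empirically
standardised so planted fractions hold exactly in the emitted ground truth.
Counts are gamma-Poisson (negative binomial) draws around the relative
abundances scaled by a log-normal per-sample library size, so both the
linear variance-partitioning stage and the NB differential-abundance stage
see realistic input.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import (
    AsvTable,
    RANKS,
    SampleDesign,
    SequenceSet,
    Taxonomy,
    ValidationError,
    rotation_for_plot,
    species_for_plot,
)

__all__ = [
    "FactorLevels",
    "AsvClass",
    "SubgroupSpec",
    "SimulationConfig",
    "GroundTruth",
    "enumerate_design",
    "simulate_phylogeny_and_sequences",
    "simulate_counts",
    "simulate_dataset",
]

MODEL_FACTORS = ("year", "month", "species", "rotation", "nitrogen", "block", "subsample")


@dataclass(frozen=True)
class FactorLevels:
    """Level sets of the full factorial design."""

    year: tuple[str, ...] = ("Y1", "Y2")
    month: tuple[str, ...] = ("June", "August", "September")
    block: tuple[str, ...] = ("B1", "B2")
    plot: tuple[str, ...] = ("M", "S", "MS", "SM")
    nitrogen: tuple[str, ...] = ("stdN", "lowN")
    compartment: tuple[str, ...] = ("rhizosphere", "bulk")
    subsample: tuple[str, ...] = ("R1", "R2")


@dataclass(frozen=True)
class AsvClass:
    """A class of ASVs sharing planted per-factor variance fractions.

    ``fractions`` maps model factors to their share of the total log-scale
    variance; the remainder is residual noise.
    """

    name: str
    proportion: float
    fractions: Mapping[str, float]

    def residual(self) -> float:
        return 1.0 - float(sum(self.fractions.values()))


@dataclass(frozen=True)
class SubgroupSpec:
    """Plant a divergent monophyletic clade inside one genus.

    A fraction of the genus' ASVs (one clade) receives ``high`` as the
    planted fraction for ``factor``; the sister clade receives ``low``.
    Defaults model a host-species-responsive clade next to an indifferent
    sister clade, the classic signature of a hidden subgenus group.
    """

    genus: str
    clade_fraction: float = 0.5
    factor: str = "species"
    high: float = 0.45
    low: float = 0.03


def _default_classes() -> tuple[AsvClass, ...]:
    # Chosen to reproduce the qualitative pattern of the field study: a
    # large share of ASVs responsive (>5%) to year and month, a moderate
    # share to host species and nitrogen, essentially none to rotation,
    # and negligible block/subsample structure.
    return (
        AsvClass("env_responsive", 0.40,
                 {"year": 0.25, "month": 0.15, "species": 0.04, "nitrogen": 0.02}),
        AsvClass("host_responsive", 0.15,
                 {"year": 0.10, "month": 0.06, "species": 0.30, "nitrogen": 0.03}),
        AsvClass("n_responsive", 0.15,
                 {"year": 0.10, "month": 0.06, "species": 0.03, "nitrogen": 0.20}),
        AsvClass("stable", 0.30,
                 {"year": 0.02, "month": 0.02}),
    )


@dataclass
class SimulationConfig:
    """All knobs of the generator, with defaults emulating the field study."""

    seed: int = 0
    n_genera: int = 60
    asvs_per_genus: tuple[int, int] = (10, 55)
    design: FactorLevels = field(default_factory=FactorLevels)
    classes: tuple[AsvClass, ...] = field(default_factory=_default_classes)
    subgroup_spec: tuple[SubgroupSpec, ...] = ()
    # total latent log-scale variance per ASV; 2.5 gives host/treatment
    # effect magnitudes comparable to the multi-unit log2 fold changes seen
    # for host-specific soil taxa, and leaves biological signal visible
    # above the count-level (sampling) noise at ~10K reads/sample depth
    total_log_variance: float = 2.5
    baseline_sd: float = 1.5
    library_size_median: Mapping[str, float] = field(
        default_factory=lambda: {"rhizosphere": 13100.0, "bulk": 5900.0}
    )
    library_size_log_sd: float = 0.6
    dispersion: float = 0.3
    mutation_rate: float = 1.0
    genus_depth: float = 0.015
    backbone_depth: float = 0.06
    sequence_length: int = 300

    def __post_init__(self) -> None:
        total_prop = sum(c.proportion for c in self.classes)
        if not np.isclose(total_prop, 1.0):
            raise ValidationError(f"class proportions sum to {total_prop}, expected 1")
        for c in self.classes:
            for f, v in c.fractions.items():
                if f not in MODEL_FACTORS:
                    raise ValidationError(f"class {c.name!r}: unknown factor {f!r}")
                if not 0.0 <= v <= 1.0:
                    raise ValidationError(f"class {c.name!r}: fraction {f}={v} outside [0,1]")
            if c.residual() < -1e-12:
                raise ValidationError(f"class {c.name!r}: planted fractions sum > 1")
        expected_identity = float(np.exp(-2.0 * self.mutation_rate * self.genus_depth))
        if expected_identity < 0.90:
            warnings.warn(
                f"mutation_rate={self.mutation_rate} with genus_depth={self.genus_depth} "
                f"gives expected within-genus identity {expected_identity:.3f} < 0.90"
            )


# ---------------------------------------------------------------------------
# Design enumeration
# ---------------------------------------------------------------------------

def enumerate_design(design: FactorLevels | None = None) -> list[SampleDesign]:
    """Full factorial enumeration of the sample design, deterministic order.

    With the default levels this yields the study layout: 384 samples, 192
    per compartment.  Species and rotation are derived from (plot, year).
    """
    design = design or FactorLevels()
    for name in ("year", "month", "block", "plot", "nitrogen", "compartment", "subsample"):
        if not getattr(design, name):
            raise ValidationError(f"factor {name!r} has no levels")
    out = []
    for year, month, block, plot, nitrogen, compartment, subsample in itertools.product(
        design.year, design.month, design.block, design.plot,
        design.nitrogen, design.compartment, design.subsample,
    ):
        sample_id = "_".join([year, month, block, plot, nitrogen, compartment, subsample])
        out.append(
            SampleDesign(
                sample_id=sample_id,
                year=year,
                month=month,
                species=species_for_plot(plot, year),
                rotation=rotation_for_plot(plot),
                nitrogen=nitrogen,
                block=block,
                plot=plot,
                subsample=subsample,
                compartment=compartment,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Phylogeny, sequences, taxonomy
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability p to a uniformly random other base."""
    if p <= 0:
        return seq.copy()
    hit = rng.random(seq.size) < min(p, 1.0)
    out = seq.copy()
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit)
        out[hit] = _BASES[(np.searchsorted(_BASES, out[hit]) + shift) % 4]
    return out


def _random_clade(names: list[str], age: float, rng: np.random.Generator) -> TreeNode:
    """Random ultrametric-ish binary subtree over ``names`` with root age ``age``."""
    if len(names) == 1:
        return TreeNode(name=names[0], length=age)
    k = int(rng.integers(1, len(names)))
    parts = [names[:k], names[k:]]
    children = []
    for part in parts:
        child_age = float(age * rng.uniform(0.3, 0.8)) if len(part) > 1 else 0.0
        sub = _random_clade(part, child_age, rng)
        sub.length = age - child_age if len(part) > 1 else age
        children.append(sub)
    return TreeNode(children=children)


def _lineage_for_genus(g: int) -> tuple[str, ...]:
    # deterministic coarse ranks: a handful of phyla/classes shared by
    # blocks of genera, SILVA-style names
    return (
        "Bacteria",
        f"Phylum{g % 5 + 1:02d}",
        f"Class{g % 10 + 1:02d}",
        f"Order{g % 20 + 1:02d}",
        f"Family{g % 30 + 1:02d}",
        f"Genus{g + 1:03d}",
        "",
    )


def simulate_phylogeny_and_sequences(
    cfg: SimulationConfig,
) -> tuple[TreeNode, SequenceSet, Taxonomy]:
    """Simulate one monophyletic clade per genus plus sequences and taxonomy.

    Within each genus, leaves descend from a genus ancestor sequence mutated
    along the branches; genera with a planted subgroup get two sister clades
    whose membership is recorded in leaf order (clade A first).
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.asvs_per_genus
    genus_sizes = rng.integers(lo, hi + 1, size=cfg.n_genera)
    sub_by_genus = {s.genus: s for s in cfg.subgroup_spec}

    root_seq = rng.choice(_BASES, size=cfg.sequence_length)
    genus_clades = []
    sequences: dict[str, str] = {}
    tax_rows = {}
    asv_counter = 0
    for g in range(cfg.n_genera):
        genus_name = f"Genus{g + 1:03d}"
        n = int(genus_sizes[g])
        names = [f"ASV{asv_counter + i + 1:05d}" for i in range(n)]
        asv_counter += n
        spec = sub_by_genus.get(genus_name)
        if spec is not None and n >= 4:
            n_a = max(2, int(round(spec.clade_fraction * n)))
            n_a = min(n_a, n - 2)
            age_a = cfg.genus_depth * 0.5
            clade_a = _random_clade(names[:n_a], age_a if n_a > 1 else 0.0, rng)
            clade_b = _random_clade(names[n_a:], age_a if n - n_a > 1 else 0.0, rng)
            clade_a.length = cfg.genus_depth - (age_a if n_a > 1 else 0.0)
            clade_b.length = cfg.genus_depth - (age_a if n - n_a > 1 else 0.0)
            clade = TreeNode(children=[clade_a, clade_b])
        else:
            clade = _random_clade(names, cfg.genus_depth if n > 1 else 0.0, rng)
        clade.length = cfg.backbone_depth
        clade.name = None
        genus_clades.append(clade)

        genus_seq = _mutate(root_seq, cfg.mutation_rate * cfg.backbone_depth, rng)
        # evolve sequences down the clade
        stack = [(clade, genus_seq)]
        while stack:
            node, seq = stack.pop()
            for child in node.children:
                child_seq = _mutate(seq, cfg.mutation_rate * (child.length or 0.0), rng)
                if child.is_tip():
                    sequences[child.name] = child_seq.tobytes().decode("ascii")
                else:
                    stack.append((child, child_seq))
        if n == 1:
            sequences[names[0]] = _mutate(
                genus_seq, cfg.mutation_rate * cfg.genus_depth, rng
            ).tobytes().decode("ascii")
        lineage = _lineage_for_genus(g)
        for name in names:
            tax_rows[name] = lineage

    tree = TreeNode(children=genus_clades)
    tree.length = 0.0
    tax = Taxonomy(pd.DataFrame.from_dict(tax_rows, orient="index", columns=list(RANKS)))
    seqs = SequenceSet(sequences, length_bounds=(cfg.sequence_length, cfg.sequence_length))
    return tree, seqs, tax


# ---------------------------------------------------------------------------
# Counts with planted variance components
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted truth emitted alongside a simulated dataset."""

    asv_ids: list[str]
    asv_class: pd.Series  # class name per ASV
    genus: pd.Series  # genus per ASV
    subgroup: pd.Series  # "" or "S1"/"S2" style clade label per ASV
    true_fractions: pd.DataFrame  # ASV x (factors + residual)
    effects: dict[str, pd.DataFrame]  # factor -> (level x ASV) effect matrix
    seed: int

    def to_json(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed,
            "asv_ids": self.asv_ids,
            "asv_class": self.asv_class.to_dict(),
            "genus": self.genus.to_dict(),
            "subgroup": self.subgroup.to_dict(),
            "true_fractions": self.true_fractions.to_dict(orient="index"),
            "effects": {f: df.to_dict(orient="index") for f, df in self.effects.items()},
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        doc = json.loads(Path(path).read_text())
        asv_ids = doc["asv_ids"]
        return cls(
            asv_ids=asv_ids,
            asv_class=pd.Series(doc["asv_class"]).reindex(asv_ids),
            genus=pd.Series(doc["genus"]).reindex(asv_ids),
            subgroup=pd.Series(doc["subgroup"]).reindex(asv_ids),
            true_fractions=pd.DataFrame.from_dict(doc["true_fractions"], orient="index").reindex(asv_ids),
            effects={f: pd.DataFrame.from_dict(d, orient="index") for f, d in doc["effects"].items()},
            seed=doc["seed"],
        )


def _standardized_effects(
    raw: np.ndarray, level_idx: np.ndarray, n_levels: int, target_var: np.ndarray
) -> np.ndarray:
    """Center raw per-level effects and rescale each column so the sample
    variance of the level effects (ddof=1) equals target_var exactly.

    The level-effect variance is what a REML random-intercept component
    estimates, so planting on this scale makes the planted fractions land
    on the same scale as fitted variance scores.  raw: (n_levels, n_asv);
    level_idx: per-sample level index; returns the rescaled effect matrix.
    """
    mean = raw.mean(axis=0)
    centered = raw - mean
    if n_levels < 2:
        return np.zeros_like(raw)
    var = (centered**2).sum(axis=0) / (n_levels - 1)
    scale = np.zeros_like(var)
    nz = var > 0
    scale[nz] = np.sqrt(np.maximum(target_var[nz], 0.0) / var[nz])
    return centered * scale


def _assign_fractions(
    cfg: SimulationConfig,
    asv_ids: list[str],
    genus: pd.Series,
    subgroup: pd.Series,
    rng: np.random.Generator,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-ASV class labels and planted fraction table (factors + residual)."""
    props = np.array([c.proportion for c in cfg.classes])
    # classes are drawn per genus: treatment response is phylogenetically
    # conserved, so a genus responds as a unit unless a subgroup is planted
    genera = sorted(genus.unique())
    genus_class = {
        g: int(i) for g, i in zip(
            genera, rng.choice(len(cfg.classes), size=len(genera), p=props / props.sum())
        )
    }
    class_idx = [genus_class[genus[a]] for a in asv_ids]
    class_names = pd.Series([cfg.classes[i].name for i in class_idx], index=asv_ids)
    frac = pd.DataFrame(0.0, index=asv_ids, columns=list(MODEL_FACTORS))
    for i, asv in enumerate(asv_ids):
        for f, v in cfg.classes[class_idx[i]].fractions.items():
            frac.loc[asv, f] = v
    # planted subgenus clades override one factor's fraction
    for spec in cfg.subgroup_spec:
        members = genus[genus == spec.genus].index
        for asv in members:
            frac.loc[asv, spec.factor] = spec.high if subgroup[asv] == "S1" else spec.low
    total = frac.sum(axis=1)
    if (total > 1.0 + 1e-12).any():
        bad = total.idxmax()
        raise ValidationError(f"planted fractions for {bad!r} sum to {total.max():.3f} > 1")
    frac["residual"] = 1.0 - total
    return class_names, frac


def _clade_labels(cfg: SimulationConfig, tree: TreeNode, genus: pd.Series) -> pd.Series:
    """S1/S2 labels for ASVs in genera with planted subgroups.

    The simulator builds subgroup genera as two sister clades with clade A
    (S1) holding the first ``clade_fraction`` of the genus' leaves in id
    order, matching the tree construction.
    """
    labels = pd.Series("", index=genus.index)
    for spec in cfg.subgroup_spec:
        members = sorted(genus[genus == spec.genus].index)
        n = len(members)
        if n < 4:
            continue
        n_a = max(2, int(round(spec.clade_fraction * n)))
        n_a = min(n_a, n - 2)
        for asv in members[:n_a]:
            labels[asv] = "S1"
        for asv in members[n_a:]:
            labels[asv] = "S2"
    return labels


def simulate_counts(
    designs: Sequence[SampleDesign],
    cfg: SimulationConfig,
    tree: TreeNode | None = None,
    taxonomy: Taxonomy | None = None,
) -> tuple[AsvTable, GroundTruth]:
    """Draw the count table for ``designs`` with planted variance components.

    If ``taxonomy``/``tree`` are omitted they are simulated first (same
    seed), so genus membership is consistent with the emitted tree.
    """
    if not designs:
        raise ValidationError("designs must be non-empty")
    if taxonomy is None:
        tree, _, taxonomy = simulate_phylogeny_and_sequences(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))

    asv_ids = list(taxonomy.asv_ids)
    n_asv = len(asv_ids)
    n = len(designs)
    genus = taxonomy.genus_of()
    subgroup = _clade_labels(cfg, tree, genus)
    class_names, frac = _assign_fractions(cfg, asv_ids, genus, subgroup, rng)

    meta = pd.DataFrame(
        {f: [getattr(d, f) for d in designs] for f in MODEL_FACTORS + ("compartment",)},
        index=[d.sample_id for d in designs],
    )
    tau2 = cfg.total_log_variance
    eta = rng.normal(0.0, cfg.baseline_sd, size=n_asv)[None, :].repeat(n, axis=0)
    # response patterns are shared within a response unit (a genus, or a
    # planted subgenus clade), so groups respond to treatments as coherent
    # units; each ASV rescales the shared pattern to its own planted
    # fraction
    unit_of = {
        a: f"{genus[a]}|{subgroup[a]}" for a in asv_ids
    }
    units = sorted(set(unit_of.values()))
    unit_idx = np.array([units.index(unit_of[a]) for a in asv_ids])
    effects: dict[str, pd.DataFrame] = {}
    for f in MODEL_FACTORS:
        levels = sorted(meta[f].unique())
        level_idx = meta[f].map({l: i for i, l in enumerate(levels)}).to_numpy()
        raw_units = rng.normal(size=(len(levels), len(units)))
        raw = raw_units[:, unit_idx]
        target = frac[f].to_numpy() * tau2
        u = _standardized_effects(raw, level_idx, len(levels), target)
        effects[f] = pd.DataFrame(u, index=levels, columns=asv_ids)
        eta += u[level_idx, :]
    # residual, empirically standardised per ASV so fractions are exact
    e = rng.normal(size=(n, n_asv))
    e -= e.mean(axis=0)
    sd = e.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    e = e / sd * np.sqrt(frac["residual"].to_numpy() * tau2)
    eta += e

    rel = np.exp(eta)
    rel /= rel.sum(axis=1, keepdims=True)
    medians = np.array(
        [cfg.library_size_median.get(c, 10000.0) for c in meta["compartment"]]
    )
    lib = np.exp(rng.normal(np.log(medians), cfg.library_size_log_sd))
    mu = rel * lib[:, None]
    if cfg.dispersion > 0:
        lam = rng.gamma(shape=1.0 / cfg.dispersion, scale=mu * cfg.dispersion)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    table = AsvTable(counts, [d.sample_id for d in designs], asv_ids)
    truth = GroundTruth(
        asv_ids=asv_ids,
        asv_class=class_names,
        genus=genus,
        subgroup=subgroup,
        true_fractions=frac,
        effects=effects,
        seed=cfg.seed,
    )
    return table, truth


def simulate_responses(
    designs: Sequence[SampleDesign],
    fractions: Mapping[str, float],
    n_responses: int,
    seed: int,
    total_variance: float = 1.0,
) -> np.ndarray:
    """Gaussian responses from the random-intercepts model with exact
    planted variance fractions (no count layer).

    Returns an (n_samples, n_responses) matrix; the remainder
    1 - sum(fractions) is iid residual noise, empirically standardised per
    response so the planted decomposition holds exactly.
    """
    rng = np.random.default_rng(seed)
    meta = pd.DataFrame(
        {f: [getattr(d, f) for d in designs] for f in MODEL_FACTORS},
        index=[d.sample_id for d in designs],
    )
    resid_frac = 1.0 - float(sum(fractions.values()))
    if resid_frac < -1e-12:
        raise ValidationError("planted fractions sum > 1")
    n = len(designs)
    y = np.zeros((n, n_responses))
    for f in MODEL_FACTORS:
        target = np.full(n_responses, fractions.get(f, 0.0) * total_variance)
        levels = sorted(meta[f].unique())
        idx = meta[f].map({l: i for i, l in enumerate(levels)}).to_numpy()
        raw = rng.normal(size=(len(levels), n_responses))
        u = _standardized_effects(raw, idx, len(levels), target)
        y += u[idx, :]
    e = rng.normal(size=(n, n_responses))
    e -= e.mean(axis=0)
    sd = e.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    y += e / sd * np.sqrt(resid_frac * total_variance)
    return y


def plant_subgroups_in_abundant_genera(
    cfg: SimulationConfig,
    n: int = 12,
    min_genus_size: int = 20,
    **spec_kwargs,
) -> SimulationConfig:
    """Return a config planting divergent subgenus clades in the ``n`` most
    abundant sufficiently large genera realised at this config's seed.

    Subgenus structure is detectable only in well-sampled, abundant genera
    (low-count ASVs fall to abundance curation and their variance scores
    are attenuated by sampling noise), which mirrors where such groups are
    found in real surveys.  Baselines are drawn before treatment effects in
    the generator's random stream, so the abundance ranking is stable when
    the returned config is simulated.
    """
    import dataclasses

    designs = enumerate_design(cfg.design)
    tree, _, tax = simulate_phylogeny_and_sequences(cfg)
    table, _ = simulate_counts(designs, cfg, tree=tree, taxonomy=tax)
    genus = tax.genus_of()
    sizes = genus.value_counts()
    totals = pd.Series(table.counts.sum(axis=0), index=table.asv_ids).groupby(genus).sum()
    eligible = totals[sizes[totals.index] >= min_genus_size]
    chosen = sorted(eligible.nlargest(n).index)
    return dataclasses.replace(
        cfg, subgroup_spec=tuple(SubgroupSpec(g, **spec_kwargs) for g in chosen)
    )


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[list[SampleDesign], AsvTable, Taxonomy, TreeNode, SequenceSet, GroundTruth]:
    """One-call convenience: design + tree + sequences + taxonomy + counts."""
    designs = enumerate_design(cfg.design)
    tree, seqs, tax = simulate_phylogeny_and_sequences(cfg)
    table, truth = simulate_counts(designs, cfg, tree=tree, taxonomy=tax)
    return designs, table, tax, tree, seqs, truth
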