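"""End-to-end orchestration: simulate -> preprocess -> community structure ->
variance partitioning -> functional groups -> differential abundance ->
report.

A single global seed fans out to per-stage seeds through
numpy.random.SeedSequence, so each stage is independently reproducible and
identical config+seed gives byte-identical report bodies.  Each stage
serializes its products under the output directory together with a marker
holding the config hash; a resumed run reuses any stage whose marker
matches and recomputes the rest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from . import io as rio
from .community import distance_matrix, pcoa, permanova, shannon
from .dastats import Contrast, agglomerate, mean_abs_lfc_compare, nb_wald_test
from .groups import GroupAssignment, GroupingParams, assign_all_groups
from .preprocess import FilterRules, filter_taxa, log_relative_abundance, subset_compartment
from .simulate import SimulationConfig, simulate_dataset
from .varpart import compare_compartments, partition_all, tally_responsive

__all__ = ["PipelineConfig", "run_pipeline", "DEFAULT_THRESHOLDS", "DEFAULT_CONTRASTS"]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.025, 0.05, 0.10, 0.20)

DEFAULT_CONTRASTS = (
    Contrast("soybean_vs_maize_rhizosphere", "species", "soybean", "maize",
             {"compartment": "rhizosphere"}),
    Contrast("stdN_vs_lowN_maize_rhizosphere", "nitrogen", "stdN", "lowN",
             {"compartment": "rhizosphere", "species": "maize"}),
    Contrast("stdN_vs_lowN_soybean_rhizosphere", "nitrogen", "stdN", "lowN",
             {"compartment": "rhizosphere", "species": "soybean"}),
    Contrast("stdN_vs_lowN_bulk", "nitrogen", "stdN", "lowN",
             {"compartment": "bulk"}),
)


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from a single YAML file."""

    out_dir: str = "rhizovar_out"
    seed: int = 0
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # input paths, used when simulate is False
    counts_path: str | None = None
    counts_format: str = "tsv"
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    tree_path: str | None = None
    fasta_path: str | None = None
    filter_rules: FilterRules = field(default_factory=FilterRules)
    pseudo: float = 1.0
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    permanova_model: tuple[str, ...] = (
        "year", "month", "species", "rotation", "nitrogen", "block", "species:nitrogen"
    )
    n_permutations: int = 999
    beta_metric: str = "bray_curtis"
    grouping: GroupingParams = field(default_factory=GroupingParams)
    contrasts: tuple[Contrast, ...] = DEFAULT_CONTRASTS
    max_em_iter: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise rio.ValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = dict(doc)
        if "sim" in kwargs and isinstance(kwargs["sim"], Mapping):
            kwargs["sim"] = SimulationConfig(**kwargs["sim"])
        if "filter_rules" in kwargs and isinstance(kwargs["filter_rules"], Mapping):
            kwargs["filter_rules"] = FilterRules(**kwargs["filter_rules"])
        if "grouping" in kwargs and isinstance(kwargs["grouping"], Mapping):
            kwargs["grouping"] = GroupingParams(**kwargs["grouping"])
        if "contrasts" in kwargs:
            kwargs["contrasts"] = tuple(
                Contrast(**c) if isinstance(c, Mapping) else c for c in kwargs["contrasts"]
            )
        for key in ("thresholds", "permanova_model"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(o: Any) -> Any:
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ["simulate", "community", "varpart", "groups", "dastats"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _marker(out: Path, stage: str) -> Path:
    return out / f".{stage}.done.json"


def _stage_fresh(out: Path, stage: str, cfg_hash: str) -> bool:
    m = _marker(out, stage)
    if not m.exists():
        return False
    try:
        return json.loads(m.read_text()).get("config_hash") == cfg_hash
    except json.JSONDecodeError:
        return False


def _mark(out: Path, stage: str, cfg_hash: str) -> None:
    _marker(out, stage).write_text(json.dumps({"config_hash": cfg_hash}))


def run_pipeline(cfg: PipelineConfig, resume: bool = False) -> dict:
    """Execute every stage and write the JSON + markdown report.

    Returns the report dict.  Any stage failure raises PipelineError naming
    the stage; with ``resume=True`` stages whose serialized outputs match
    the current config hash are reused.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    seeds = _stage_seeds(cfg.seed)
    provenance = {"tool": "rhizovar", "config_hash": cfg_hash, "seed": cfg.seed}

    # ---- inputs ---------------------------------------------------------
    stage = "simulate"
    try:
        if cfg.simulate:
            sim_cfg = dataclasses.replace(cfg.sim, seed=seeds["simulate"])
            if not (resume and _stage_fresh(out, stage, cfg_hash)):
                designs, table, tax, tree, seqs, truth = simulate_dataset(sim_cfg)
                rio.write_asv_table(table, out / "counts.tsv", provenance=provenance)
                rio.write_metadata(designs, out / "metadata.tsv", provenance=provenance)
                rio.write_taxonomy(tax, out / "taxonomy.tsv")
                rio.write_tree(tree, out / "tree.nwk")
                rio.write_fasta(seqs, out / "sequences.fasta")
                truth.to_json(out / "ground_truth.json")
                _mark(out, stage, cfg_hash)
            table = rio.read_asv_table(out / "counts.tsv")
            designs = rio.read_metadata(out / "metadata.tsv")
            tax = rio.read_taxonomy(out / "taxonomy.tsv")
            tree = rio.read_tree(out / "tree.nwk")
        else:
            if not (cfg.counts_path and cfg.metadata_path and cfg.taxonomy_path and cfg.tree_path):
                raise rio.ValidationError("non-simulated runs need counts/metadata/taxonomy/tree paths")
            table = rio.read_asv_table(cfg.counts_path, format=cfg.counts_format)
            designs = rio.read_metadata(cfg.metadata_path)
            tax = rio.read_taxonomy(cfg.taxonomy_path)
            tree = rio.read_tree(cfg.tree_path)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    report: dict[str, Any] = {
        "provenance": provenance,
        "design": {
            "n_samples": len(designs),
            "n_per_compartment": {
                c: sum(1 for d in designs if d.compartment == c)
                for c in ("rhizosphere", "bulk")
            },
        },
    }

    # ---- preprocess -----------------------------------------------------
    stage = "preprocess"
    try:
        filtered, filt_report = filter_taxa(table, tax, cfg.filter_rules)
        (out / "filter_report.json").write_text(json.dumps(filt_report.to_dict(), indent=1))
        compartments = {
            c: subset_compartment(filtered, designs, c) for c in ("rhizosphere", "bulk")
        }
        report["filter"] = filt_report.to_dict()
        report["compartment_asvs"] = {c: t.n_asvs for c, t in compartments.items()}
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    by_id = {d.sample_id: d for d in designs}

    # ---- community structure -------------------------------------------
    stage = "community"
    try:
        rh = compartments["rhizosphere"]
        div = {s: shannon(rh.counts[i]) for i, s in enumerate(rh.sample_ids)}
        dm = distance_matrix(rh, metric=cfg.beta_metric, tree=tree)
        ord_res = pcoa(dm)
        rh_designs = [by_id[s] for s in rh.sample_ids]
        perm = permanova(dm, rh_designs, cfg.permanova_model,
                         n_perm=cfg.n_permutations, seed=seeds["community"])
        perm.to_frame().to_csv(out / "permanova.tsv", sep="\t")
        report["community"] = {
            "shannon_mean": float(np.mean(list(div.values()))),
            "pcoa_percent_explained": [round(float(v), 2) for v in ord_res.percent_explained[:4]],
            "permanova": {
                t: {"R2": round(perm.r2[t], 4), "p": perm.p[t]} for t in perm.terms
            },
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- variance partitioning ------------------------------------------
    stage = "varpart"
    try:
        profiles = {}
        tallies: dict[str, Any] = {}
        for comp, tab in compartments.items():
            comp_designs = [by_id[s] for s in tab.sample_ids]
            profs = partition_all(tab, comp_designs, pseudo=cfg.pseudo,
                                  max_iter=cfg.max_em_iter)
            profiles[comp] = profs
            rows = []
            for p in profs:
                row = {"asv_id": p.asv_id, **{f: p.scores[f] for f in p.components},
                       "residual": p.residual_score, "converged": p.converged}
                rows.append(row)
            import pandas as pd

            pd.DataFrame(rows).to_csv(out / f"variance_scores_{comp}.tsv", sep="\t", index=False)
            tallies[comp] = {
                f"{thr:g}": {
                    f: dataclasses.asdict(tally_responsive(profs, f, thr))
                    for f in profs[0].components
                }
                for thr in cfg.thresholds
            }
        chi = {}
        for thr in cfg.thresholds:
            key = f"{thr:g}"
            chi[key] = {}
            for f in profiles["rhizosphere"][0].components:
                ta = tallies["rhizosphere"][key][f]
                tb = tallies["bulk"][key][f]
                chi2, p = compare_compartments(ta["count"], ta["total"], tb["count"], tb["total"])
                chi[key][f] = {"chi2": round(chi2, 4), "p": p}
        report["variance_partition"] = {"tallies": tallies, "compartment_chi2": chi}
        (out / "tallies.json").write_text(json.dumps(tallies, indent=1))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- functional groups ----------------------------------------------
    stage = "groups"
    try:
        rh = compartments["rhizosphere"]
        assignment, diagnostics = assign_all_groups(
            profiles["rhizosphere"], tax, tree, table=rh, params=cfg.grouping
        )
        n_split = sum(1 for d in diagnostics.values() if d.decision == "split")
        (out / "group_assignment.tsv").write_text(
            "asv_id\tgroup\n" + "\n".join(
                f"{a}\t{l}" for a, l in sorted(assignment.labels.items())
            ) + "\n"
        )
        (out / "split_diagnostics.json").write_text(
            json.dumps({g: d.to_dict() for g, d in diagnostics.items()}, indent=1)
        )
        report["groups"] = {
            "n_groups": assignment.n_groups,
            "n_genera_evaluated": len(diagnostics),
            "n_genera_split": n_split,
        }
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- differential abundance ------------------------------------------
    stage = "dastats"
    try:
        full_assignment = dict(assignment.labels)
        genus_series = tax.genus_of()
        for a in filtered.asv_ids:
            if a not in full_assignment:
                full_assignment[a] = genus_series.get(a, "") or "unassigned"
        grp_table = agglomerate(filtered, GroupAssignment(full_assignment), pseudo=1)
        da_report = {}
        da_results = {}
        for contrast in cfg.contrasts:
            res = nb_wald_test(grp_table, designs, contrast)
            da_results[contrast.name] = res
            da_report[contrast.name] = {
                "n_groups": len(res),
                "n_sig_q05": sum(1 for r in res if r.fdr_q < 0.05),
                "top": [
                    {"group": r.group, "log2fc": round(r.log2fc, 3),
                     "q": r.fdr_q, "tier": r.tier}
                    for r in sorted(res, key=lambda r: r.fdr_q)[:5]
                ],
            }
            import pandas as pd

            pd.DataFrame(
                [{"group": r.group, "contrast": r.contrast, "log2fc": r.log2fc,
                  "se": r.se, "p": r.wald_p, "q": r.fdr_q, "tier": r.tier} for r in res]
            ).to_csv(out / f"da_{contrast.name}.tsv", sep="\t", index=False)
        maize = da_results.get("stdN_vs_lowN_maize_rhizosphere")
        soy = da_results.get("stdN_vs_lowN_soybean_rhizosphere")
        if maize and soy:
            ma, mb, wp = mean_abs_lfc_compare(maize, soy)
            da_report["mean_abs_log2fc_maize_vs_soybean_N_response"] = {
                "maize": round(ma, 4), "soybean": round(mb, 4), "welch_p": wp,
            }
        report["differential_abundance"] = da_report
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ---- report ----------------------------------------------------------
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (out / "report.md").write_text(_render_markdown(report))
    return report


def _render_markdown(report: Mapping[str, Any]) -> str:
    lines = ["# rhizovar pipeline report", ""]
    d = report["design"]
    lines.append(
        f"Design: {d['n_samples']} samples "
        f"({d['n_per_compartment']['rhizosphere']} rhizosphere, "
        f"{d['n_per_compartment']['bulk']} bulk soil)."
    )
    f = report["filter"]
    lines.append(
        f"Filtering: {f['asvs_in']} -> {f['asvs_out']} ASVs "
        f"({f['reads_in']} -> {f['reads_out']} reads)."
    )
    lines.append("")
    lines.append("## Responsive-ASV tallies (score > threshold)")
    for comp, per_thr in report["variance_partition"]["tallies"].items():
        lines.append(f"### {comp}")
        for thr, factors in per_thr.items():
            parts = [
                f"{fac}: {t['count']}/{t['total']}"
                for fac, t in factors.items()
            ]
            lines.append(f"- threshold {thr}: " + ", ".join(parts))
    g = report["groups"]
    lines.append("")
    lines.append(
        f"## Functional groups: {g['n_groups']} groups "
        f"({g['n_genera_split']} of {g['n_genera_evaluated']} evaluated genera split)."
    )
    lines.append("")
    lines.append("## Differential abundance")
    for name, res in report["differential_abundance"].items():
        if "n_groups" in (res if isinstance(res, dict) else {}):
            lines.append(f"- {name}: {res['n_sig_q05']}/{res['n_groups']} groups at q < 0.05")
    return "\n".join(lines) + "\n"
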