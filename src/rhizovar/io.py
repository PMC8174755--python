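"""Domain types and on-disk formats.

The pipeline's canonical objects are small and explicit: a factorial sample
design, an integer ASV count table (samples x ASVs), a seven-rank taxonomy,
a rooted phylogeny over ASV ids, and a set of ~300 bp V4 sequences.  Readers
validate on construction and fail loudly, naming the offending row/column;
writers round-trip bit-exactly through the matching reader.

Counts are stored as integers on disk; relative abundances are always derived
in memory and never serialized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "FormatError",
    "ValidationError",
    "YEARS",
    "MONTHS",
    "SPECIES",
    "ROTATIONS",
    "NITROGENS",
    "BLOCKS",
    "PLOTS",
    "SUBSAMPLES",
    "COMPARTMENTS",
    "RANKS",
    "SampleDesign",
    "species_for_plot",
    "AsvTable",
    "Taxonomy",
    "SequenceSet",
    "read_asv_table",
    "write_asv_table",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "read_tree",
    "write_tree",
    "read_fasta",
    "write_fasta",
]


class FormatError(ValueError):
    """A file failed to parse as the expected format."""


class ValidationError(ValueError):
    """Parsed content violated a domain invariant."""


# Declared factor level sets of the field design.
YEARS = ("Y1", "Y2")
MONTHS = ("June", "August", "September")
SPECIES = ("maize", "soybean")
ROTATIONS = ("continuous", "rotated")
NITROGENS = ("stdN", "lowN")
BLOCKS = ("B1", "B2")
PLOTS = ("M", "S", "MS", "SM")
SUBSAMPLES = ("R1", "R2")
COMPARTMENTS = ("rhizosphere", "bulk")

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

#: Which crop each plot carries in each year.  Plots M and S are continuous
#: crops; MS starts as maize in year 1 and alternates, SM the reverse.  The
#: phase of the rotated plots is a configurable convention, recorded in
#: output provenance by the pipeline.
DEFAULT_ROTATION_PHASE: Mapping[str, Mapping[str, str]] = {
    "M": {"Y1": "maize", "Y2": "maize"},
    "S": {"Y1": "soybean", "Y2": "soybean"},
    "MS": {"Y1": "maize", "Y2": "soybean"},
    "SM": {"Y1": "soybean", "Y2": "maize"},
}


def species_for_plot(plot: str, year: str, phase: Mapping[str, Mapping[str, str]] | None = None) -> str:
    """Crop species grown on ``plot`` in ``year`` under the rotation rule."""
    phase = DEFAULT_ROTATION_PHASE if phase is None else phase
    try:
        return phase[plot][year]
    except KeyError as exc:
        raise ValidationError(f"unknown plot/year combination: {plot!r}/{year!r}") from exc


def rotation_for_plot(plot: str) -> str:
    if plot in ("M", "S"):
        return "continuous"
    if plot in ("MS", "SM"):
        return "rotated"
    raise ValidationError(f"unknown plot: {plot!r}")


@dataclass(frozen=True)
class SampleDesign:
    """Factor levels of one sample in the crossed field design."""

    sample_id: str
    year: str
    month: str
    species: str
    rotation: str
    nitrogen: str
    block: str
    plot: str
    subsample: str
    compartment: str

    _LEVELS = {
        "year": YEARS,
        "month": MONTHS,
        "species": SPECIES,
        "rotation": ROTATIONS,
        "nitrogen": NITROGENS,
        "block": BLOCKS,
        "plot": PLOTS,
        "subsample": SUBSAMPLES,
        "compartment": COMPARTMENTS,
    }

    def __post_init__(self) -> None:
        for name, levels in self._LEVELS.items():
            value = getattr(self, name)
            if value not in levels:
                raise ValidationError(
                    f"sample {self.sample_id!r}: {name}={value!r} not in {levels}"
                )
        expected = species_for_plot(self.plot, self.year)
        if self.species != expected:
            raise ValidationError(
                f"sample {self.sample_id!r}: species={self.species!r} contradicts "
                f"plot={self.plot!r} in year {self.year!r} (expected {expected!r})"
            )
        if self.rotation != rotation_for_plot(self.plot):
            raise ValidationError(
                f"sample {self.sample_id!r}: rotation={self.rotation!r} contradicts plot={self.plot!r}"
            )


def designs_to_frame(designs: Sequence[SampleDesign]) -> pd.DataFrame:
    """Sample metadata as a DataFrame indexed by sample_id."""
    rows = [
        {
            "sample_id": d.sample_id,
            "year": d.year,
            "month": d.month,
            "species": d.species,
            "rotation": d.rotation,
            "nitrogen": d.nitrogen,
            "block": d.block,
            "plot": d.plot,
            "subsample": d.subsample,
            "compartment": d.compartment,
        }
        for d in designs
    ]
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class AsvTable:
    """Integer count matrix, samples x ASVs.

    ``counts`` is always dense int64; sample and ASV ids are ordered and
    unique.  The canonical in-memory orientation is samples on rows.
    """

    counts: np.ndarray
    sample_ids: list[str]
    asv_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, ASV {self.asv_ids[j]!r}"
            )
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.asv_ids = [str(a) for a in self.asv_ids]
        if self.counts.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.asv_ids)} ASVs"
            )
        for kind, ids in (("sample", self.sample_ids), ("ASV", self.asv_ids)):
            seen: set[str] = set()
            for x in ids:
                if x in seen:
                    raise ValidationError(f"duplicate {kind} id: {x!r}")
                seen.add(x)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.asv_ids)

    def select_samples(self, keep: Sequence[str]) -> "AsvTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in keep if s not in idx]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        rows = [idx[s] for s in keep]
        return AsvTable(self.counts[rows], list(keep), list(self.asv_ids))

    def select_asvs(self, keep: Sequence[str]) -> "AsvTable":
        idx = {a: i for i, a in enumerate(self.asv_ids)}
        missing = [a for a in keep if a not in idx]
        if missing:
            raise ValidationError(f"unknown ASV ids: {missing[:5]}")
        cols = [idx[a] for a in keep]
        return AsvTable(self.counts[:, cols], list(self.sample_ids), list(keep))


@dataclass
class Taxonomy:
    """Seven-rank (SILVA-style) assignments per ASV.

    Unassigned ranks are empty strings and may appear only as a contiguous
    suffix (an ASV cannot have a genus without a family).
    """

    ranks: pd.DataFrame  # index asv_id, columns RANKS

    def __post_init__(self) -> None:
        if list(self.ranks.columns) != list(RANKS):
            raise ValidationError(f"taxonomy columns must be {RANKS}")
        if self.ranks.index.has_duplicates:
            dup = self.ranks.index[self.ranks.index.duplicated()][0]
            raise ValidationError(f"duplicate ASV id in taxonomy: {dup!r}")
        filled = self.ranks.fillna("").astype(str)
        assigned = (filled != "").to_numpy()
        # once a rank is unassigned, all deeper ranks must be too
        bad = (~assigned[:, :-1] & assigned[:, 1:]).any(axis=1)
        if bad.any():
            raise ValidationError(
                f"non-contiguous unassigned ranks for ASV {self.ranks.index[np.argmax(bad)]!r}"
            )
        self.ranks = filled

    @property
    def asv_ids(self) -> list[str]:
        return list(self.ranks.index)

    def genus_of(self) -> pd.Series:
        return self.ranks["genus"]

    def lineage(self, asv_id: str) -> tuple[str, ...]:
        return tuple(self.ranks.loc[asv_id])


@dataclass
class SequenceSet:
    """DNA sequences keyed by ASV id, restricted to A/C/G/T."""

    sequences: dict[str, str]
    length_bounds: tuple[int, int] = (200, 400)

    def __post_init__(self) -> None:
        norm = {}
        for asv_id, seq in self.sequences.items():
            s = seq.upper()
            bad = set(s) - set("ACGT")
            if bad:
                raise ValidationError(f"sequence {asv_id!r} has invalid characters {sorted(bad)}")
            lo, hi = self.length_bounds
            if not lo <= len(s) <= hi:
                raise ValidationError(
                    f"sequence {asv_id!r} length {len(s)} outside [{lo}, {hi}]"
                )
            norm[asv_id] = s
        self.sequences = norm

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, asv_id: str) -> str:
        return self.sequences[asv_id]


# ---------------------------------------------------------------------------
# Count table I/O (TSV and BIOM-JSON dialects)
# ---------------------------------------------------------------------------

def _write_provenance(path: Path, provenance: Mapping | None) -> None:
    if provenance:
        side = path.with_suffix(path.suffix + ".provenance.json")
        side.write_text(json.dumps(dict(provenance), indent=1, sort_keys=True))


def read_asv_table(
    path: str | Path,
    format: str = "tsv",
    orientation: str = "asvs_by_samples",
) -> AsvTable:
    """Read a count table.

    TSV layout follows the common amplicon convention: first column holds ASV
    ids and the header holds sample ids (``orientation="asvs_by_samples"``);
    pass ``orientation="samples_by_asvs"`` for the transposed layout.  BIOM
    input is the JSON (BIOM 1.0) dialect.
    """
    path = Path(path)
    if format == "biom":
        return _read_biom_json(path)
    if format != "tsv":
        raise FormatError(f"unknown count table format: {format!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # malformed TSV
        raise FormatError(f"{path}: failed to parse TSV: {exc}") from exc
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate column id {dup!r}")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate row id {dup!r}")
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric count: {exc}") from exc
    if np.any(values != np.round(values)):
        i, j = np.argwhere(values != np.round(values))[0]
        raise FormatError(
            f"{path}: non-integer count at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise FormatError(
            f"{path}: negative count at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if orientation == "asvs_by_samples":
        return AsvTable(values.T.astype(np.int64), list(df.columns), list(df.index))
    if orientation == "samples_by_asvs":
        return AsvTable(values.astype(np.int64), list(df.index), list(df.columns))
    raise FormatError(f"unknown orientation: {orientation!r}")


def write_asv_table(
    table: AsvTable,
    path: str | Path,
    format: str = "tsv",
    orientation: str = "asvs_by_samples",
    provenance: Mapping | None = None,
) -> None:
    path = Path(path)
    if format == "biom":
        _write_biom_json(table, path)
    elif format == "tsv":
        df = table.to_frame()
        if orientation == "asvs_by_samples":
            df = df.T
            df.index.name = "asv_id"
        else:
            df.index.name = "sample_id"
        df.to_csv(path, sep="\t")
    else:
        raise FormatError(f"unknown count table format: {format!r}")
    _write_provenance(path, provenance)


def _read_biom_json(path: Path) -> AsvTable:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid BIOM-JSON: {exc}") from exc
    try:
        asv_ids = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        shape = tuple(doc["shape"])
        mtype = doc.get("matrix_type", "sparse")
        data = doc["data"]
    except KeyError as exc:
        raise FormatError(f"{path}: missing BIOM field {exc}") from exc
    counts = np.zeros((shape[0], shape[1]), dtype=np.int64)
    if mtype == "sparse":
        for i, j, v in data:
            counts[int(i), int(j)] = int(v)
    else:
        counts[:] = np.asarray(data, dtype=np.int64)
    # BIOM rows are observations (ASVs); transpose to samples x ASVs
    return AsvTable(counts.T, sample_ids, asv_ids)


def _write_biom_json(table: AsvTable, path: Path) -> None:
    obs = table.counts.T  # ASVs x samples
    rows, cols = np.nonzero(obs)
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "rhizovar",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [table.n_asvs, table.n_samples],
        "rows": [{"id": a, "metadata": None} for a in table.asv_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": [[int(i), int(j), int(obs[i, j])] for i, j in zip(rows, cols)],
    }
    Path(path).write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# Metadata I/O
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "sample_id", "year", "month", "species", "rotation",
    "nitrogen", "block", "plot", "subsample", "compartment",
]


def read_metadata(path: str | Path) -> list[SampleDesign]:
    """Read sample metadata TSV ('#' comment lines allowed).

    The species column may be omitted, in which case it is derived from
    (plot, year) by the rotation rule; if present it is checked against it.
    Likewise rotation is derivable from plot.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:
        raise FormatError(f"{path}: failed to parse metadata TSV: {exc}") from exc
    required = [c for c in _META_COLUMNS if c not in ("species", "rotation")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    designs = []
    for _, row in df.iterrows():
        plot, year = row["plot"], row["year"]
        species = row["species"] if "species" in df.columns else species_for_plot(plot, year)
        rotation = row["rotation"] if "rotation" in df.columns else rotation_for_plot(plot)
        designs.append(
            SampleDesign(
                sample_id=row["sample_id"],
                year=year,
                month=row["month"],
                species=species,
                rotation=rotation,
                nitrogen=row["nitrogen"],
                block=row["block"],
                plot=plot,
                subsample=row["subsample"],
                compartment=row["compartment"],
            )
        )
    seen: set[str] = set()
    for d in designs:
        if d.sample_id in seen:
            raise ValidationError(f"duplicate sample id: {d.sample_id!r}")
        seen.add(d.sample_id)
    return designs


def write_metadata(
    designs: Sequence[SampleDesign],
    path: str | Path,
    provenance: Mapping | None = None,
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if provenance:
            for key in sorted(provenance):
                fh.write(f"# {key}: {provenance[key]}\n")
        fh.write("\t".join(_META_COLUMNS) + "\n")
        for d in designs:
            fh.write(
                "\t".join(
                    [d.sample_id, d.year, d.month, d.species, d.rotation,
                     d.nitrogen, d.block, d.plot, d.subsample, d.compartment]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Taxonomy I/O
# ---------------------------------------------------------------------------

def read_taxonomy(path: str | Path) -> Taxonomy:
    """Read taxonomy TSV: either 7 rank columns or a single SILVA-style
    semicolon string column named 'taxonomy'."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    except Exception as exc:
        raise FormatError(f"{path}: failed to parse taxonomy TSV: {exc}") from exc
    if "asv_id" not in df.columns:
        raise FormatError(f"{path}: taxonomy must have an 'asv_id' column")
    df = df.set_index("asv_id")
    if "taxonomy" in df.columns:
        parts = df["taxonomy"].str.split(";", expand=True).reindex(columns=range(7)).fillna("")
        parts.columns = list(RANKS)
        ranks = parts.apply(lambda s: s.str.strip())
    else:
        missing = [c for c in RANKS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing rank columns {missing}")
        ranks = df[list(RANKS)]
    return Taxonomy(ranks)


def write_taxonomy(
    tax: Taxonomy,
    path: str | Path,
    style: str = "columns",
    provenance: Mapping | None = None,
) -> None:
    path = Path(path)
    if style == "columns":
        out = tax.ranks.reset_index().rename(columns={"index": "asv_id"})
        if out.columns[0] != "asv_id":
            out = out.rename(columns={out.columns[0]: "asv_id"})
        out.to_csv(path, sep="\t", index=False)
    elif style == "silva":
        with open(path, "w") as fh:
            fh.write("asv_id\ttaxonomy\n")
            for asv_id, row in tax.ranks.iterrows():
                lineage = ";".join(v for v in row if v != "")
                fh.write(f"{asv_id}\t{lineage}\n")
    else:
        raise FormatError(f"unknown taxonomy style: {style!r}")
    _write_provenance(path, provenance)


# ---------------------------------------------------------------------------
# Tree and sequence I/O
# ---------------------------------------------------------------------------

def read_tree(path: str | Path) -> TreeNode:
    """Read a rooted newick tree; missing branch lengths become 0 with a
    warning, duplicate leaf labels are an error."""
    import warnings

    path = Path(path)
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise FormatError(f"{path}: failed to parse newick: {exc}") from exc
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        dup = next(n for n in names if names.count(n) > 1)
        raise ValidationError(f"{path}: duplicate leaf label {dup!r}")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise ValidationError(f"{path}: negative branch length on {node.name!r}")
    if n_missing:
        warnings.warn(f"{path}: {n_missing} missing branch lengths treated as 0")
    if tree.length is None:
        tree.length = 0.0
    return tree


def write_tree(tree: TreeNode, path: str | Path, provenance: Mapping | None = None) -> None:
    path = Path(path)
    tree.write(str(path), format="newick")
    _write_provenance(path, provenance)


def read_fasta(path: str | Path, length_bounds: tuple[int, int] = (200, 400)) -> SequenceSet:
    """Read FASTA; lowercase bases are normalized to uppercase."""
    from Bio import SeqIO

    path = Path(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise FormatError(f"{path}: no FASTA records found")
    return SequenceSet(seqs, length_bounds=length_bounds)


def write_fasta(seqs: SequenceSet, path: str | Path, provenance: Mapping | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for asv_id, seq in seqs.sequences.items():
            fh.write(f">{asv_id}\n{seq}\n")
    _write_provenance(path, provenance)
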