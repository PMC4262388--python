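"""Readers, writers and core container types for expression data.

All downstream analysis consumes only the types defined here:
:class:`ExpressionMatrix` (probes x samples, log2 scale),
:class:`BatchDesign` (sample -> batch under one named factor),
:class:`OrthologMap` (cross-species probe pairs joined by gene id) and
:class:`PathwaySet` (gene-set collections in KEGG link or GMT dialect).

Expression values are exchanged on log2 scale; linear (raw) intensities
exist only inside the preprocessing step.  Sample and batch labels are
opaque strings -- no date parsing is attempted even when labels look like
dates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "BatchDesign",
    "OrthologMap",
    "PathwaySet",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_batch_design",
    "write_batch_design",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_pathway_sets",
    "write_run_manifest",
]


class FormatError(ValueError):
    """Raised on malformed or inconsistent input files."""


def _check_unique(ids, kind: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    if dups:
        raise FormatError(f"duplicate {kind} id(s): {', '.join(map(str, dups))}")


@dataclass
class ExpressionMatrix:
    """Probes x samples grid of log2-scale intensities."""

    probe_ids: list
    sample_ids: list
    values: np.ndarray
    species: str = ""

    def __post_init__(self) -> None:
        self.probe_ids = list(map(str, self.probe_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise FormatError(
                f"value grid shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, species: str = "") -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float), species)

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        idx = {p: i for i, p in enumerate(self.probe_ids)}
        rows = [idx[p] for p in probe_ids]
        return ExpressionMatrix(list(probe_ids), list(self.sample_ids), self.values[rows], self.species)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(list(self.probe_ids), list(sample_ids), self.values[:, cols], self.species)

    def drop_probes(self, blacklist) -> "ExpressionMatrix":
        """Remove blacklisted probes (e.g. array-QC flagged spots)."""
        bad = set(blacklist)
        keep = [p for p in self.probe_ids if p not in bad]
        return self.subset_probes(keep)


@dataclass
class BatchDesign:
    """Assignment of samples to batches under one named factor."""

    factor_name: str
    assignment: dict  # sample_id -> batch label

    def __post_init__(self) -> None:
        self.assignment = {str(k): str(v) for k, v in self.assignment.items()}
        for s, b in self.assignment.items():
            if b == "" or b.lower() == "nan":
                raise FormatError(f"empty batch label for sample {s!r} under factor {self.factor_name!r}")

    @property
    def batch_sizes(self) -> dict:
        sizes: dict[str, int] = {}
        for b in self.assignment.values():
            sizes[b] = sizes.get(b, 0) + 1
        return sizes

    @property
    def batches(self) -> list:
        return sorted(set(self.assignment.values()))

    @property
    def sample_ids(self) -> list:
        return list(self.assignment)

    @property
    def n_samples(self) -> int:
        return len(self.assignment)

    def samples_in(self, batch: str) -> list:
        return [s for s, b in self.assignment.items() if b == batch]

    def restrict(self, sample_ids) -> "BatchDesign":
        missing = [s for s in sample_ids if s not in self.assignment]
        if missing:
            raise FormatError(
                f"sample(s) absent from design under factor {self.factor_name!r}: "
                + ", ".join(missing)
            )
        return BatchDesign(self.factor_name, {s: self.assignment[s] for s in sample_ids})


@dataclass
class OrthologMap:
    """Cross-species probe pairs joined through a shared gene identifier."""

    records: list  # (species_a_probe, species_b_probe, gene_id)
    probe_to_gene_a: dict = field(init=False)
    probe_to_gene_b: dict = field(init=False)

    def __post_init__(self) -> None:
        self.records = [(str(a), str(b), str(g)) for a, b, g in self.records]
        self.probe_to_gene_a = {}
        self.probe_to_gene_b = {}
        for a, b, g in self.records:
            for probe, index, side in ((a, self.probe_to_gene_a, "a"), (b, self.probe_to_gene_b, "b")):
                if probe in index and index[probe] != g:
                    raise FormatError(
                        f"species-{side} probe {probe!r} maps to two genes: {index[probe]!r} and {g!r}"
                    )
                index[probe] = g

    @property
    def gene_ids(self) -> set:
        return {g for _, _, g in self.records}

    def genes_for_probes(self, probes, side: str) -> dict:
        index = self.probe_to_gene_a if side == "a" else self.probe_to_gene_b
        return {p: index[p] for p in probes if p in index}


@dataclass
class PathwaySet:
    """pathway_id -> set of member gene ids."""

    sets: dict
    names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {str(k): set(map(str, v)) for k, v in self.sets.items()}
        empties = [k for k, v in self.sets.items() if not v]
        if empties:
            raise FormatError(f"pathway(s) with empty member set: {', '.join(empties)}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, key: str) -> set:
        return self.sets[key]

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path, dialect: str = "plain-matrix", species: str = "",
                           sep: str = "\t", na_token: str = "NA"):
    """Read an expression matrix from delimited text.

    ``plain-matrix``: first column probe ids, header row sample ids, one
    numeric cell per probe/sample; returns :class:`ExpressionMatrix`.

    ``agilent-fe-subset``: long-format spot table with columns
    ``probe_id, sample_id, signal, background`` (a minimal subset of an
    Agilent Feature Extraction export); returns a pair of linear-scale
    matrices ``(signal, background)`` for background correction.
    """
    if dialect == "plain-matrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)
        _check_unique(header[1:], "sample")  # pandas would silently mangle duplicates
        frame = pd.read_csv(path, sep=sep, index_col=0, na_values=[na_token], keep_default_na=False)
        frame.index = frame.index.map(str)
        frame.columns = frame.columns.map(str)
        _check_unique(list(frame.index), "probe")
        _check_unique(list(frame.columns), "sample")
        values = np.empty(frame.shape, dtype=float)
        for j, col in enumerate(frame.columns):
            converted = pd.to_numeric(frame[col], errors="coerce")
            bad = converted.isna() & frame[col].notna()
            if bad.any():
                row = frame.index[int(np.flatnonzero(bad.to_numpy())[0])]
                raise FormatError(f"non-numeric cell at probe {row!r}, sample {col!r}")
            values[:, j] = converted.to_numpy(dtype=float)
        return ExpressionMatrix(list(frame.index), list(frame.columns), values, species)
    if dialect == "agilent-fe-subset":
        table = pd.read_csv(path, sep=sep)
        required = {"probe_id", "sample_id", "signal", "background"}
        if not required.issubset(table.columns):
            raise FormatError(f"agilent-fe-subset requires columns {sorted(required)}")
        pairs = []
        for col in ("signal", "background"):
            wide = table.pivot_table(index="probe_id", columns="sample_id", values=col, aggfunc="first")
            if wide.isna().any().any():
                raise FormatError("incomplete spot table: some probe/sample pairs are missing")
            pairs.append(ExpressionMatrix.from_frame(wide, species))
        return tuple(pairs)
    raise FormatError(f"unknown dialect {dialect!r}")


def write_expression_matrix(matrix: ExpressionMatrix, path, sep: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=sep, index_label="probe_id")


def read_batch_design(path, sample_ids=None, sep: str = "\t") -> list:
    """Read a sample annotation table: one row per sample, one column per factor.

    Returns one :class:`BatchDesign` per factor column.  When ``sample_ids``
    is given (the matrix columns), every one of them must be present.
    """
    table = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if table.shape[1] < 2:
        raise FormatError("design table needs a sample column plus at least one factor column")
    sample_col = table.columns[0]
    samples = list(table[sample_col])
    _check_unique(samples, "sample")
    if sample_ids is not None:
        missing = [s for s in sample_ids if s not in set(samples)]
        if missing:
            raise FormatError("sample(s) in matrix but absent from design: " + ", ".join(missing))
    designs = []
    for factor in table.columns[1:]:
        assignment = dict(zip(samples, table[factor]))
        for s, b in assignment.items():
            if b == "":
                raise FormatError(f"empty batch label for sample {s!r} under factor {factor!r}")
        designs.append(BatchDesign(str(factor), assignment))
    return designs


def write_batch_design(designs, path, sep: str = "\t") -> None:
    samples = designs[0].sample_ids
    frame = pd.DataFrame({"sample_id": samples})
    for d in designs:
        frame[d.factor_name] = [d.assignment[s] for s in samples]
    frame.to_csv(path, sep=sep, index=False)


def read_ortholog_map(path, sep: str = "\t") -> OrthologMap:
    """Read a three-column ortholog table: probe_a, probe_b, gene_id."""
    records = []
    with open(path) as fh:
        header = fh.readline()
        if header.count(sep) != 2:
            raise FormatError("ortholog map must have exactly three columns")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(sep)
            if len(parts) != 3 or not all(parts):
                raise FormatError(f"malformed ortholog record at line {lineno}")
            records.append(tuple(parts))
    return OrthologMap(records)


def write_ortholog_map(ortholog_map: OrthologMap, path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(sep.join(["probe_a", "probe_b", "gene_id"]) + "\n")
        for a, b, g in ortholog_map.records:
            fh.write(sep.join([a, b, g]) + "\n")


def read_pathway_sets(path, format: str = "kegg-link") -> PathwaySet:
    """Read gene sets in KEGG link format or GMT.

    KEGG link lines look like ``path:dre03010\tdre:12345``; the species
    prefix before the colon is stripped from gene ids.  GMT lines are
    ``pathway_id<TAB>description<TAB>gene1<TAB>gene2...``.
    """
    sets: dict[str, set] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if format == "kegg-link":
                if len(parts) != 2:
                    raise FormatError(f"malformed KEGG link line {lineno}: expected 2 columns")
                pw, gene = parts
                pw = pw.split(":", 1)[-1]
                gene = gene.split(":", 1)[-1]
                if not pw or not gene:
                    raise FormatError(f"malformed KEGG link line {lineno}")
                sets.setdefault(pw, set()).add(gene)
            elif format == "gmt":
                if len(parts) < 3:
                    raise FormatError(f"malformed GMT line {lineno}: expected >= 3 columns")
                pw, desc, genes = parts[0], parts[1], parts[2:]
                sets[pw] = set(g for g in genes if g)
                names[pw] = desc
            else:
                raise FormatError(f"unknown pathway format {format!r}")
    return PathwaySet(sets, names)


def write_pathway_sets(pathways: PathwaySet, path, format: str = "gmt") -> None:
    with open(path, "w") as fh:
        for pw, genes in sorted(pathways.items()):
            if format == "gmt":
                fh.write("\t".join([pw, pathways.names.get(pw, pw)] + sorted(genes)) + "\n")
            else:
                for g in sorted(genes):
                    fh.write(f"path:{pw}\t{g}\n")


def write_run_manifest(path, **entries) -> None:
    """Write a JSON manifest of seeds, parameters and artifact paths."""
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
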