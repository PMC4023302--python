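"""Readers and writers for the tool's text formats.

Canonical expression input is a TSV with a header row of sample ids and a
first column of gene (or probe) ids; the GCT dialect (``#1.2`` version line,
dimensions line, Name/Description columns) and its CLS phenotype companion
are supported because the gene-set ecosystem these collections come from
uses them.  Gene sets are read from GMT (name, description, members).  All
readers fail with line-numbered messages on malformed input, and every
writer/reader pair is inverse on valid data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .dataset import GeneSetCollection

__all__ = [
    "read_expression",
    "write_expression",
    "read_gene_sets",
    "write_gene_sets",
    "read_classes",
    "write_classes",
    "RunConfig",
]


class ParseError(ValueError):
    """Malformed input file; the message carries the offending line number."""


def _parse_matrix_rows(lines, n_cols: int, path, start_line: int, desc_col: bool):
    gene_ids, descriptions, rows = [], [], []
    for lineno, line in enumerate(lines, start=start_line):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        expected = n_cols + (2 if desc_col else 1)
        if len(parts) != expected:
            raise ParseError(f"{path}:{lineno}: expected {expected} fields, got {len(parts)}")
        gene_ids.append(parts[0])
        offset = 2 if desc_col else 1
        if desc_col:
            descriptions.append(parts[1])
        try:
            rows.append([float(x) for x in parts[offset:]])
        except ValueError:
            bad = next(x for x in parts[offset:] if not _is_float(x))
            raise ParseError(f"{path}:{lineno}: non-numeric value {bad!r}") from None
    return gene_ids, descriptions, np.asarray(rows, dtype=float)


def _is_float(x: str) -> bool:
    try:
        float(x)
        return True
    except ValueError:
        return False


def read_expression(path, format: str = "tsv"):
    """Read an expression matrix.

    Returns ``(values, gene_ids, sample_ids)``; gene ids may repeat at the
    probe level (they are resolved by probe collapsing before any analysis
    that needs unique identifiers).
    """
    if format not in ("tsv", "gct"):
        raise ValueError(f"unknown expression format {format!r}")
    with open(path) as fh:
        lines = fh.readlines()
    if format == "tsv":
        if not lines:
            raise ParseError(f"{path}:1: empty expression file")
        header = lines[0].rstrip("\n").split("\t")
        sample_ids = header[1:]
        if not sample_ids:
            raise ParseError(f"{path}:1: header row has no sample ids")
        gene_ids, _, values = _parse_matrix_rows(
            lines[1:], len(sample_ids), path, start_line=2, desc_col=False
        )
        return values, gene_ids, sample_ids
    # GCT
    if len(lines) < 3:
        raise ParseError(f"{path}:1: GCT file needs a version line, dimensions and a header")
    if lines[0].strip() != "#1.2":
        raise ParseError(f"{path}:1: expected GCT version line '#1.2', got {lines[0].strip()!r}")
    dims = lines[1].split()
    if len(dims) != 2 or not all(d.isdigit() for d in dims):
        raise ParseError(f"{path}:2: expected 'n_genes\\tn_samples', got {lines[1].strip()!r}")
    n_genes, n_samples = int(dims[0]), int(dims[1])
    header = lines[2].rstrip("\n").split("\t")
    if len(header) != n_samples + 2:
        raise ParseError(
            f"{path}:3: header has {len(header) - 2} sample columns, dimensions say {n_samples}"
        )
    sample_ids = header[2:]
    gene_ids, _, values = _parse_matrix_rows(
        lines[3:], n_samples, path, start_line=4, desc_col=True
    )
    if len(gene_ids) != n_genes:
        raise ParseError(
            f"{path}:{3 + len(gene_ids)}: {len(gene_ids)} data rows, dimensions say {n_genes}"
        )
    return values, gene_ids, sample_ids


def write_expression(path, values, gene_ids, sample_ids, format: str = "tsv") -> None:
    values = np.asarray(values, dtype=float)
    if format not in ("tsv", "gct"):
        raise ValueError(f"unknown expression format {format!r}")
    with open(path, "w") as fh:
        if format == "gct":
            fh.write("#1.2\n")
            fh.write(f"{values.shape[0]}\t{values.shape[1]}\n")
            fh.write("Name\tDescription\t" + "\t".join(sample_ids) + "\n")
            for g, row in zip(gene_ids, values):
                fh.write(g + "\tna\t" + "\t".join(f"{x:.17g}" for x in row) + "\n")
        else:
            fh.write("gene_id\t" + "\t".join(sample_ids) + "\n")
            for g, row in zip(gene_ids, values):
                fh.write(g + "\t" + "\t".join(f"{x:.17g}" for x in row) + "\n")


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: name, description, then tab-separated member ids."""
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 member, "
                    f"got {len(parts)} fields"
                )
            name, description = parts[0], parts[1]
            if name in collection.sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene set {name!r}")
            members = [m for m in parts[2:] if m]
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                warnings.warn(f"{path}:{lineno}: duplicate members in {name!r} removed")
            if not deduped:
                warnings.warn(f"{path}:{lineno}: gene set {name!r} empty after cleaning; dropped")
                continue
            collection.add(name, deduped, description)
    return collection


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "") or "na"
            fh.write("\t".join([name, desc, *collection[name]]) + "\n")


def read_classes(path, format: str = "cls"):
    """Read per-sample phenotype labels.

    CLS: a counts line (``n_samples n_classes 1``), a ``#``-prefixed line of
    class names, then one line of per-sample labels (numeric indices or
    names).  Two-column TSV: ``sample_id<TAB>label`` with a header line.
    Returns ``(labels, sample_ids)``; sample ids are None for CLS, whose
    labels follow the expression column order.
    """
    if format not in ("cls", "two_column_tsv"):
        raise ValueError(f"unknown class format {format!r}")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if format == "cls":
        body = [ln for ln in lines if ln.strip()]
        if len(body) < 3:
            raise ParseError(f"{path}:1: CLS needs counts, class-name and label lines")
        counts = body[0].split()
        if len(counts) < 2:
            raise ParseError(f"{path}:1: malformed CLS counts line {body[0]!r}")
        n_samples, n_classes = int(counts[0]), int(counts[1])
        if n_classes != 2:
            raise ParseError(f"{path}:1: expected 2 classes, CLS declares {n_classes}")
        names_line = body[1].split()
        if names_line and names_line[0].startswith("#"):
            names_line = [names_line[0][1:], *names_line[1:]]
            names_line = [x for x in names_line if x]
        if len(names_line) != 2:
            raise ParseError(f"{path}:2: expected 2 class names, got {names_line}")
        raw = body[2].split()
        if len(raw) != n_samples:
            raise ParseError(
                f"{path}:3: {len(raw)} labels for {n_samples} declared samples"
            )
        if all(x.isdigit() for x in raw):
            order = list(dict.fromkeys(raw))
            if len(order) != 2:
                raise ParseError(f"{path}:3: labels use {len(order)} distinct codes, expected 2")
            mapping = {code: names_line[i] for i, code in enumerate(order)}
            labels = [mapping[x] for x in raw]
        else:
            if set(raw) != set(names_line):
                raise ParseError(f"{path}:3: labels {sorted(set(raw))} do not match class names")
            labels = raw
        return labels, None
    # two-column TSV
    if not lines:
        raise ParseError(f"{path}:1: empty class file")
    sample_ids, labels = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        sample_ids.append(parts[0])
        labels.append(parts[1])
    levels = list(dict.fromkeys(labels))
    if len(levels) != 2:
        raise ParseError(f"{path}: expected exactly 2 label levels, got {levels}")
    return labels, sample_ids


def write_classes(path, labels, sample_ids=None, format: str = "cls") -> None:
    levels = list(dict.fromkeys(labels))
    if format == "cls":
        with open(path, "w") as fh:
            fh.write(f"{len(labels)} {len(levels)} 1\n")
            fh.write("# " + " ".join(levels) + "\n")
            fh.write(" ".join(str(levels.index(x)) for x in labels) + "\n")
    elif format == "two_column_tsv":
        if sample_ids is None:
            raise ValueError("two-column TSV classes need sample ids")
        with open(path, "w") as fh:
            fh.write("sample_id\tlabel\n")
            for s, lab in zip(sample_ids, labels):
                fh.write(f"{s}\t{lab}\n")
    else:
        raise ValueError(f"unknown class format {format!r}")


@dataclass
class RunConfig:
    """Validated run parameters; round-trips through a flat key-value file."""

    expression: str = ""
    classes: str = ""
    gene_sets: str = ""
    method: str = "pearson"
    n_permutations: int = 1000
    alpha: float = 0.05
    min_size: int = 15
    max_size: int = 500
    seed: int = 0
    output_dir: str = "."
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.method not in ("pearson", "spearman"):
            raise ValueError(f"method must be pearson or spearman, got {self.method!r}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_size < 2 or self.max_size < self.min_size:
            raise ValueError(f"bad set-size bounds [{self.min_size}, {self.max_size}]")
        if self.verbosity < 0:
            raise ValueError("verbosity must be >= 0")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for key, val in asdict(self).items():
                fh.write(f"{key} = {val}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        fields: dict = {}
        types = {f: t for f, t in cls.__annotations__.items()}
        casts = {"str": str, "int": int, "float": float}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ParseError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if key not in types:
                    raise ParseError(f"{path}:{lineno}: unknown config key {key!r}")
                fields[key] = casts[types[key]](val)
        return cls(**fields)
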