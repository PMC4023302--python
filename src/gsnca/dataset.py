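"""In-memory containers for expression data and gene-set collections.

An :class:`ExpressionDataset` holds a genes x samples matrix of (already
normalized, typically log-scale) expression values together with gene and
sample identifiers and a two-level condition label per sample.  All
downstream tests compare the coexpression structure of a gene set between
the two condition levels, so the container enforces exactly two levels with
at least three samples each (the minimum for a non-degenerate correlation).

A :class:`GeneSetCollection` is an ordered mapping of named gene sets in the
GMT spirit: each set has a description and an ordered, duplicate-free member
list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ExpressionDataset", "GeneSetCollection"]


@dataclass
class ExpressionDataset:
    """Expression matrix with identifiers and a two-group phenotype.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_samples)
        Expression measurements; must be finite.
    gene_ids : sequence of str
        Unique row identifiers (genes, or probes before collapsing).
    sample_ids : sequence of str
        Unique column identifiers.
    condition : sequence of str
        Per-sample phenotype label; exactly two distinct levels, each
        represented by at least three samples.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    condition: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.condition = [str(c) for c in self.condition]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D genes x samples array")
        p, n = self.values.shape
        if len(self.gene_ids) != p:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {p} matrix rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} matrix columns")
        if len(self.condition) != n:
            raise ValueError(f"{len(self.condition)} condition labels for {n} samples")
        if not np.isfinite(self.values).all():
            bad = int(np.flatnonzero(~np.isfinite(self.values).all(axis=1))[0])
            raise ValueError(f"non-finite expression values (first bad gene: {self.gene_ids[bad]!r})")
        if len(set(self.gene_ids)) != p:
            raise ValueError("gene ids are not unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")
        levels = self.condition_levels
        if len(levels) != 2:
            raise ValueError(f"expected exactly two condition levels, got {levels}")
        for lev in levels:
            k = self.condition.count(lev)
            if k < 3:
                raise ValueError(f"condition level {lev!r} has {k} samples; at least 3 required")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- basic views ------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def condition_levels(self) -> tuple[str, ...]:
        """The two phenotype levels, in order of first appearance."""
        return tuple(dict.fromkeys(self.condition))

    def group_columns(self, level: str) -> np.ndarray:
        """Column indices of the samples carrying ``level``."""
        if level not in self.condition_levels:
            raise KeyError(f"unknown condition level {level!r}")
        return np.flatnonzero(np.asarray(self.condition) == level)

    def group_matrix(self, level: str) -> np.ndarray:
        """The genes x n_level sub-matrix for one condition."""
        return self.values[:, self.group_columns(level)]

    def subset(self, gene_ids: list[str]) -> "ExpressionDataset":
        """Restrict to ``gene_ids`` (kept in the requested order)."""
        missing = [g for g in gene_ids if g not in self._gene_index]
        if missing:
            raise KeyError(f"gene ids not in dataset: {missing}")
        rows = [self._gene_index[g] for g in gene_ids]
        return ExpressionDataset(
            values=self.values[rows, :],
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            condition=list(self.condition),
        )


@dataclass
class GeneSetCollection:
    """Ordered named gene sets with descriptions (GMT-style)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            deduped = list(dict.fromkeys(m for m in members if m))
            if len(deduped) != len(members):
                warnings.warn(f"gene set {name!r}: duplicate or empty members removed")
            self.sets[name] = deduped
        self.descriptions = {name: self.descriptions.get(name, "") for name in self.sets}

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def add(self, name: str, members: list[str], description: str = "") -> None:
        if name in self.sets:
            raise ValueError(f"gene set {name!r} already present")
        self.sets[name] = list(dict.fromkeys(m for m in members if m))
        self.descriptions[name] = description
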