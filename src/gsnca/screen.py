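"""Collection-wide differential-coexpression screening.

Runs the weight-vector test and the pairwise-correlation comparator over
every set in a gene-set collection, after the standard preprocessing of
probe-level microarray data: probes without a gene mapping are dropped, and
among probes sharing a gene the one with the largest absolute Welch
t-statistic between the two phenotypes is kept.  Sets are intersected with
the measured gene universe and filtered to 15..500 members before testing.

Each set is categorized by which test detects it at the configured alpha on
the raw p-values; Benjamini-Hochberg q-values are reported alongside.  Two
per-set effect summaries separate the regimes the two tests respond to: the
difference in average signed correlation between phenotypes, and the average
per-gene difference in weight factors.  Hub-gene membership questions are
answered with a hypergeometric upper-tail enrichment test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from statsmodels.stats.multitest import multipletests

from .core import (
    CorrelationStructure,
    WeightSolution,
    correlation_structure,
    gene_weights,
    gsnca_statistic,
    permutation_test,
)
from .dataset import ExpressionDataset, GeneSetCollection

__all__ = [
    "collapse_probes",
    "filter_gene_sets",
    "screen",
    "average_correlation_difference",
    "average_weight_difference",
    "hypergeometric_enrichment",
    "write_screen_results",
    "read_screen_results",
]

SCREEN_COLUMNS = [
    "set_name",
    "set_size",
    "gsnca_p",
    "gsca_p",
    "gsnca_q",
    "gsca_q",
    "hub_cond1",
    "hub_cond2",
    "avg_corr_difference",
    "avg_weight_difference",
    "category",
]


def collapse_probes(
    probes: ExpressionDataset, probe_to_gene: dict[str, str]
) -> ExpressionDataset:
    """Reduce a probe-level matrix to one row per gene.

    Unmapped probes are discarded.  When several probes map to the same
    gene, the probe with the largest |Welch t| between the two conditions is
    kept; probes constant in both groups (undefined t) are skipped with a
    warning.
    """
    lev1, lev2 = probes.condition_levels
    X1 = probes.group_matrix(lev1)
    X2 = probes.group_matrix(lev2)
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    v1 = X1.var(axis=1, ddof=1)
    v2 = X2.var(axis=1, ddof=1)
    denom = np.sqrt(v1 / X1.shape[1] + v2 / X2.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    # |t| is inf when only the means differ between constant groups, and NaN
    # (skipped) when the probe is constant in both groups with equal means.
    best: dict[str, tuple[float, int]] = {}
    order: list[str] = []
    for i, probe in enumerate(probes.gene_ids):
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        score = abs(t[i])
        if np.isnan(score):
            warnings.warn(f"probe {probe!r} is constant in both groups; skipped")
            continue
        if gene not in best:
            best[gene] = (score, i)
            order.append(gene)
        elif score > best[gene][0]:
            best[gene] = (score, i)
    if not best:
        raise ValueError("no probes survived gene mapping and variance screening")
    rows = [best[g][1] for g in order]
    return ExpressionDataset(
        values=probes.values[rows, :],
        gene_ids=order,
        sample_ids=list(probes.sample_ids),
        condition=list(probes.condition),
    )


def filter_gene_sets(
    collection: GeneSetCollection,
    universe_gene_ids,
    min_size: int = 15,
    max_size: int = 500,
) -> GeneSetCollection:
    """Intersect each set with the measured universe, then bound its size.

    Intersection precedes the size test, so a large nominal set whose
    measured overlap falls inside the bounds is retained at its overlap.
    """
    universe = set(universe_gene_ids)
    kept = GeneSetCollection()
    for name in collection.names():
        members = [g for g in collection[name] if g in universe]
        if min_size <= len(members) <= max_size:
            kept.add(name, members, collection.descriptions.get(name, ""))
    return kept


def average_correlation_difference(C1: CorrelationStructure, C2: CorrelationStructure) -> float:
    """|mean off-diagonal signed correlation, condition 1 minus condition 2|."""
    if C1.p != C2.p:
        raise ValueError(f"correlation matrices differ in size: {C1.p} vs {C2.p}")
    iu = np.triu_indices(C1.p, k=1)
    return float(abs(C1.signed_corr[iu].mean() - C2.signed_corr[iu].mean()))


def average_weight_difference(w1, w2) -> float:
    """Mean per-gene |weight difference|; equals the L1 statistic / p."""
    a = w1.weights if isinstance(w1, WeightSolution) else np.asarray(w1, dtype=float)
    b = w2.weights if isinstance(w2, WeightSolution) else np.asarray(w2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"weight vectors differ in length: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).mean())


def hypergeometric_enrichment(
    overlap: int, annotated_total: int, set_size: int, universe_size: int
) -> float:
    """Upper-tail P(X >= overlap) for annotated-gene membership in a set.

    X counts annotated genes in a draw of ``set_size`` from a universe of
    ``universe_size`` containing ``annotated_total`` annotated genes.
    """
    if not (0 <= overlap <= min(annotated_total, set_size)):
        raise ValueError(
            f"overlap {overlap} inconsistent with annotated {annotated_total} and set {set_size}"
        )
    if max(annotated_total, set_size) > universe_size:
        raise ValueError("annotated/set counts exceed the universe size")
    return float(_sstats.hypergeom.sf(overlap - 1, universe_size, annotated_total, set_size))


def _categorize(p_gsnca: float, p_gsca: float, alpha: float) -> str:
    a, b = p_gsnca <= alpha, p_gsca <= alpha
    if a and b:
        return "both"
    if a:
        return "gsnca_only"
    if b:
        return "gsca_only"
    return "neither"


def screen(
    ds: ExpressionDataset,
    collection: GeneSetCollection,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed=None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Run both tests over every set and tabulate the results.

    Per-set permutation streams are spawned from the master seed, so the
    whole screen is bit-reproducible and insensitive to set order changes
    only through the spawn index.  Categories use the raw p-values at
    ``alpha``; BH-adjusted q-values (across sets, per test) are reported
    alongside.
    """
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    genes = set(ds.gene_ids)
    rows = []
    for name, child in zip(collection.names(), master.spawn(max(len(collection), 1))):
        members = [g for g in collection[name] if g in genes]
        if len(members) < 3:
            raise ValueError(f"gene set {name!r} has {len(members)} measured genes; need >= 3")
        s_gsnca, s_gsca = child.spawn(2)
        res_w = permutation_test(
            ds, members, statistic="gsnca", n_permutations=n_permutations,
            seed=s_gsnca, method=method,
        )
        res_c = permutation_test(
            ds, members, statistic="gsca", n_permutations=n_permutations,
            seed=s_gsca, method=method,
        )
        sub = ds.subset(members)
        lev1, lev2 = sub.condition_levels
        C1 = correlation_structure(sub.group_matrix(lev1), method=method, gene_ids=members)
        C2 = correlation_structure(sub.group_matrix(lev2), method=method, gene_ids=members)
        rows.append(
            {
                "set_name": name,
                "set_size": len(members),
                "gsnca_p": res_w.p_value,
                "gsca_p": res_c.p_value,
                "hub_cond1": res_w.hub_cond1,
                "hub_cond2": res_w.hub_cond2,
                "avg_corr_difference": average_correlation_difference(C1, C2),
                "avg_weight_difference": average_weight_difference(
                    res_w.weights_cond1, res_w.weights_cond2
                ),
            }
        )
    table = pd.DataFrame(rows)
    table["gsnca_q"] = multipletests(table["gsnca_p"], method="fdr_bh")[1]
    table["gsca_q"] = multipletests(table["gsca_p"], method="fdr_bh")[1]
    table["category"] = [
        _categorize(pn, pc, alpha) for pn, pc in zip(table["gsnca_p"], table["gsca_p"])
    ]
    return table[SCREEN_COLUMNS]


def write_screen_results(table: pd.DataFrame, path) -> None:
    table[SCREEN_COLUMNS].to_csv(path, sep="\t", index=False)


def read_screen_results(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in SCREEN_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"screen-result table is missing columns: {missing}")
    return table[SCREEN_COLUMNS]
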