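"""Substitution-saturation diagnostics and posterior-sample convergence.

Saturation (multiple substitutions overwriting each other at the same site)
makes uncorrected distances plateau while model-based estimates keep
growing.  Plotting the uncorrected pairwise distance of every taxon pair
against its patristic distance on a model-based tree therefore gives a
simple diagnostic: the weaker the linear relationship (the lower the R^2 of
the ordinary least-squares fit), the more saturated the matrix.

Also provided is the standard convergence statistic for independent Bayesian
tree samples: the maximum over all non-trivial bipartitions of the absolute
difference in bipartition frequency between two samples ("maxdiff").
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, LabelingError, StatisticalError
from .supermatrix import Supermatrix

__all__ = [
    "DistanceMatrix", "SaturationResult", "p_distance_matrix",
    "patristic_matrix", "saturation_fit", "paired_distance_table",
    "bipartition_maxdiff", "saturation_plot",
]

#: symbols excluded from pairwise-deletion distance computation
P_DISTANCE_MISSING = ("?", "-", "X", "*", ".")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances; undefined pairs are NaN."""

    taxa: list[str]
    values: np.ndarray
    kind: str = "uncorrected_p"

    def validate(self) -> None:
        v = self.values
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise DataError("distance matrix shape does not match taxa")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(v - v.T), initial=0.0) > 1e-9:
                raise DataError("distance matrix is not symmetric")
            if np.nanmax(np.abs(np.diag(v)), initial=0.0) > 1e-12:
                raise DataError("distance matrix diagonal is not zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)


@dataclass
class SaturationResult:
    pairs_used: int
    slope: float
    intercept: float
    r_squared: float


def p_distance_matrix(matrix: Supermatrix) -> DistanceMatrix:
    """Uncorrected pairwise distances with pairwise deletion.

    For each taxon pair: proportion of differing sites among columns where
    both taxa carry a non-missing residue.  Pairs with no comparable column
    are NaN (excluded from downstream fits).
    """
    if matrix.n_taxa < 2:
        raise DataError("need at least 2 taxa for distances")
    data = matrix.data
    present = ~np.isin(data, list(P_DISTANCE_MISSING))
    n = matrix.n_taxa
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = present[i] & present[j]
            m = int(comparable.sum())
            if m == 0:
                d = np.nan
            else:
                d = float((data[i, comparable] != data[j, comparable]).mean())
            values[i, j] = values[j, i] = d
    return DistanceMatrix(list(matrix.taxa), values, kind="uncorrected_p")


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Tip-to-tip path-length distances (independent of root placement)."""
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None:
            head = edge.head_node
            label = head.taxon.label if head.taxon else "<internal>"
            raise DataError(f"missing branch length on edge above {label!r}")
    taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    pdm = tree.phylogenetic_distance_matrix()
    by_label = {t.label: t for t in tree.taxon_namespace if t.label in set(taxa)}
    n = len(taxa)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(pdm.patristic_distance(by_label[taxa[i]], by_label[taxa[j]]))
            values[i, j] = values[j, i] = d
    return DistanceMatrix(taxa, values, kind="patristic")


def _paired_vectors(observed: DistanceMatrix, patristic: DistanceMatrix):
    shared = sorted(set(observed.taxa) & set(patristic.taxa))
    if len(shared) < len(observed.taxa) or len(shared) < len(patristic.taxa):
        import warnings
        warnings.warn("taxon sets differ; using their intersection",
                      stacklevel=3)
    oi = {t: observed.taxa.index(t) for t in shared}
    pi = {t: patristic.taxa.index(t) for t in shared}
    xs, ys, pairs = [], [], []
    for a in range(len(shared)):
        for b in range(a + 1, len(shared)):
            ta, tb = shared[a], shared[b]
            x = patristic.values[pi[ta], pi[tb]]
            y = observed.values[oi[ta], oi[tb]]
            if np.isnan(x) or np.isnan(y):
                continue
            xs.append(float(x))
            ys.append(float(y))
            pairs.append((ta, tb))
    return np.array(xs), np.array(ys), pairs


def saturation_fit(observed: DistanceMatrix,
                   patristic: DistanceMatrix) -> SaturationResult:
    """OLS of uncorrected on patristic distances over defined pairs.

    ``r_squared`` is the squared Pearson correlation of the paired vectors
    (identical between the two regression orientations).
    """
    xs, ys, _ = _paired_vectors(observed, patristic)
    if xs.size < 3:
        raise StatisticalError(
            f"only {xs.size} defined taxon pairs; need >= 3 for the fit")
    fit = stats.linregress(xs, ys)
    return SaturationResult(
        pairs_used=int(xs.size),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
    )


def paired_distance_table(observed: DistanceMatrix,
                          patristic: DistanceMatrix) -> pd.DataFrame:
    """Plot-ready long table: one row per taxon pair with both distances."""
    xs, ys, pairs = _paired_vectors(observed, patristic)
    return pd.DataFrame({
        "taxon_a": [p[0] for p in pairs],
        "taxon_b": [p[1] for p in pairs],
        "patristic": xs,
        "uncorrected_p": ys,
    })


def saturation_plot(observed: DistanceMatrix, patristic: DistanceMatrix,
                    path=None, ax=None):
    """Scatter of uncorrected vs patristic distance with the OLS line."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    table = paired_distance_table(observed, patristic)
    result = saturation_fit(observed, patristic)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(table["patristic"], table["uncorrected_p"], s=8, alpha=0.5)
    xs = np.linspace(0, table["patristic"].max(), 50)
    ax.plot(xs, result.intercept + result.slope * xs, color="firebrick",
            label=f"$R^2$ = {result.r_squared:.2f}")
    ax.set_xlabel("patristic distance")
    ax.set_ylabel("uncorrected p-distance")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


# ---------------------------------------------------------------------------
# Posterior-sample convergence

def _split_frequencies(sample: list[dendropy.Tree],
                       tns: dendropy.TaxonNamespace) -> dict[int, float]:
    counts: dict[int, int] = {}
    all_mask = tns.all_taxa_bitmask()
    for tree in sample:
        clone = dendropy.Tree.get(
            data=tree.as_string(schema="newick"), schema="newick",
            taxon_namespace=tns)
        clone.encode_bipartitions()
        seen: set[int] = set()
        for bp in clone.bipartition_encoding:
            if bp.is_trivial():
                continue
            mask = bp.split_bitmask
            if mask in (0, all_mask):
                continue
            seen.add(mask)
        for mask in seen:
            counts[mask] = counts.get(mask, 0) + 1
    return {m: c / len(sample) for m, c in counts.items()}


def bipartition_maxdiff(sample_a: list[dendropy.Tree],
                        sample_b: list[dendropy.Tree]) -> float:
    """Maximum bipartition-frequency difference between two tree samples.

    For every non-trivial unrooted split observed in either sample, the
    frequency (fraction of trees containing it) is computed per sample; the
    statistic is the maximum absolute difference.  0 means the samples agree
    on every split frequency; values near 1 mean the samples support
    incompatible topologies.  Burn-in removal is the caller's concern.
    """
    if not sample_a or not sample_b:
        raise DataError("tree samples must be non-empty")

    def tipset(trees):
        out = set()
        for t in trees:
            out.add(frozenset(leaf.taxon.label for leaf in t.leaf_node_iter()))
        return out

    sets_a, sets_b = tipset(sample_a), tipset(sample_b)
    if len(sets_a | sets_b) != 1:
        raise LabelingError("tree samples do not share a common tip set")

    labels = sorted(next(iter(sets_a)))
    tns = dendropy.TaxonNamespace(labels)
    freq_a = _split_frequencies(sample_a, tns)
    freq_b = _split_frequencies(sample_b, tns)
    maxdiff = 0.0
    for mask in set(freq_a) | set(freq_b):
        maxdiff = max(maxdiff, abs(freq_a.get(mask, 0.0) - freq_b.get(mask, 0.0)))
    return maxdiff
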