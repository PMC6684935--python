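"""Gene-tree quality control: long-branch detection and tip pruning.

Fast-evolving sequences produce disproportionately long branches in gene
trees and are a classic source of long-branch-attraction artifacts in the
concatenated analysis.  The rule here is a robust-center outlier test: a tip
is flagged when its chosen statistic (terminal branch length, or root-to-tip
path length) exceeds ``multiplier`` times the median (or mean) of that
statistic over all tips.  The rule is deliberately explicit and configurable
rather than tied to any particular published cleaning script.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError, LabelingError

__all__ = ["LongBranchPolicy", "flag_long_branches", "prune_tips",
           "flag_report", "nj_gene_tree"]


@dataclass(frozen=True)
class LongBranchPolicy:
    """Outlier rule for long-branch tips.

    statistic : "terminal_branch" (default) or "root_to_tip"
    multiplier : flag tips whose statistic exceeds multiplier x center
    center : "median" (default, robust) or "mean"
    min_tips : below this many tips the test is skipped with a warning
    """

    statistic: str = "terminal_branch"
    multiplier: float = 4.0
    center: str = "median"
    min_tips: int = 4

    def validate(self) -> None:
        if self.statistic not in ("terminal_branch", "root_to_tip"):
            raise ConfigurationError(
                "statistic must be 'terminal_branch' or 'root_to_tip'")
        if self.multiplier <= 1:
            raise ConfigurationError("multiplier must be > 1")
        if self.center not in ("median", "mean"):
            raise ConfigurationError("center must be 'median' or 'mean'")
        if self.min_tips < 3:
            raise ConfigurationError("min_tips must be >= 3")


def _tip_statistics(tree: dendropy.Tree, statistic: str) -> dict[str, float]:
    stats: dict[str, float] = {}
    if statistic == "terminal_branch":
        for leaf in tree.leaf_node_iter():
            bl = leaf.edge.length
            if bl is None or not math.isfinite(bl) or bl < 0:
                raise DataError(f"bad branch length on tip {leaf.taxon.label!r}")
            stats[leaf.taxon.label] = float(bl)
    else:
        for leaf in tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                bl = node.edge.length or 0.0
                if not math.isfinite(bl) or bl < 0:
                    raise DataError(
                        f"bad branch length above tip {leaf.taxon.label!r}")
                d += bl
                node = node.parent_node
            stats[leaf.taxon.label] = d
    return stats


def flag_long_branches(tree: dendropy.Tree,
                       policy: LongBranchPolicy = LongBranchPolicy()
                       ) -> list[str]:
    """Tip labels whose statistic exceeds ``multiplier x center``; sorted.

    Trees with fewer than ``policy.min_tips`` tips are skipped (a warning is
    emitted and no tips are flagged).
    """
    policy.validate()
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    if n_tips < policy.min_tips:
        warnings.warn(
            f"tree has {n_tips} tips (< {policy.min_tips}); "
            "long-branch test skipped", stacklevel=2)
        return []
    stats = _tip_statistics(tree, policy.statistic)
    values = np.array(list(stats.values()))
    center = float(np.median(values) if policy.center == "median"
                   else np.mean(values))
    threshold = policy.multiplier * center
    return sorted(label for label, v in stats.items() if v > threshold)


def flag_report(gene_id: str, tree: dendropy.Tree,
                policy: LongBranchPolicy = LongBranchPolicy()) -> pd.DataFrame:
    """Per-tip audit table: gene, tip, statistic, center, threshold, flagged."""
    policy.validate()
    stats = _tip_statistics(tree, policy.statistic)
    values = np.array(list(stats.values()))
    center = float(np.median(values) if policy.center == "median"
                   else np.mean(values))
    threshold = policy.multiplier * center
    flagged = set(flag_long_branches(tree, policy))
    rows = [(gene_id, label, stats[label], center, threshold, label in flagged)
            for label in sorted(stats)]
    return pd.DataFrame(rows, columns=[
        "gene_id", "tip", "statistic", "center", "threshold", "flagged"])


def prune_tips(tree: dendropy.Tree, tips: list[str]) -> dendropy.Tree:
    """Return a copy of *tree* without the listed tips.

    Degree-2 nodes arising from the removal are suppressed with their branch
    lengths summed, so patristic distances among remaining tips are
    preserved.  Unknown tips raise :class:`LabelingError`.
    """
    present = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    unknown = sorted(set(tips) - present)
    if unknown:
        raise LabelingError(f"tips not in tree: {', '.join(unknown)}")
    pruned = tree.clone(depth=1)
    if tips:
        pruned.prune_taxa_with_labels(list(tips))
        pruned.purge_taxon_namespace()
    return pruned


def nj_gene_tree(sequences: dict[str, str], correct: bool = True,
                 max_distance: float = 5.0) -> dendropy.Tree | None:
    """Neighbor-joining tree from aligned sequences (quick gene-tree estimate).

    Distances are uncorrected p-distances, optionally transformed by the
    20-state Poisson correction ``d = -(19/20) ln(1 - (20/19) p)``; distances
    at or beyond the correction's domain are capped at *max_distance*.
    Returns ``None`` for fewer than 4 sequences (no meaningful topology).
    Negative NJ branch estimates are clamped to zero.
    """
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    ids = sorted(sequences)
    if len(ids) < 4:
        return None
    arrs = {i: np.frombuffer(sequences[i].encode(), dtype="S1") for i in ids}
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[ids[i]], arrs[ids[j]]
            comparable = (a != b"?") & (b != b"?") & (a != b"-") & (b != b"-")
            m = int(comparable.sum())
            p = float((a[comparable] != b[comparable]).mean()) if m else 0.0
            if correct:
                if p >= 0.94:
                    d = max_distance
                else:
                    d = min(-(19.0 / 20.0) * math.log(1.0 - (20.0 / 19.0) * p),
                            max_distance)
            else:
                d = p
            mat[i, j] = mat[j, i] = d
    tree = nj(SkbioDM(mat, ids=ids), neg_as_zero=True)
    return dendropy.Tree.get(data=str(tree), schema="newick")
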