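"""Ortholog selection from homology-search hit tables.

Implements the hit-selection rules used when expanding a curated phylogenomic
gene set by BLAST-searching new proteomes:

1.  a length-dependent e-value ceiling — hits against short reference
    proteins (< 150 aa) must reach 1e-20, hits against longer proteins must
    reach the stricter 1e-80 (short proteins cannot attain extreme e-values,
    long ones that fail 1e-80 are likely false positives);
2.  per taxon, the best (minimum e-value) hit is kept **together with** every
    hit within a configurable number of orders of magnitude of it (default
    three), so that plausible alternative orthologs stay available;
3.  final resolution to one sequence per taxon, preferring the best-ranked
    candidate not flagged as a long branch in the gene tree.

Hit tables are pandas DataFrames with columns ``gene_id, seq_id, taxon_id,
evalue, query_length, subject_length``; :func:`read_blast_tabular` builds one
from standard 12-column BLAST tabular output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError, LabelingError
from .treeqc import LongBranchPolicy, flag_long_branches

__all__ = [
    "SelectionConfig", "read_blast_tabular", "apply_evalue_ceiling",
    "select_candidates", "resolve_orthologs", "selection_report",
]

HIT_COLUMNS = ["gene_id", "seq_id", "taxon_id", "evalue",
               "query_length", "subject_length"]

_BLAST_NAMES = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for hit filtering and candidate windowing.

    ``window_orders`` — orders of magnitude around the best hit to keep
    alternatives (inclusive boundary: ``evalue <= best * 10**window_orders``).
    ``short_len_cutoff`` — proteins strictly shorter use the lenient ceiling;
    the boundary length itself uses the stricter one.
    ``length_field`` — which length the ceiling tests ("subject" by default:
    the candidate sequence; switchable to "query").
    ``per_taxon`` — window applied within each taxon (default) or across the
    whole gene.
    """

    window_orders: float = 3.0
    short_len_cutoff: int = 150
    evalue_max_short: float = 1e-20
    evalue_max_long: float = 1e-80
    length_field: str = "subject"
    per_taxon: bool = True

    def validate(self) -> None:
        if self.window_orders < 0:
            raise ConfigurationError("window_orders must be >= 0")
        if not (0.0 < self.evalue_max_long <= self.evalue_max_short <= 1.0):
            raise ConfigurationError(
                "require 0 < evalue_max_long <= evalue_max_short <= 1")
        if self.short_len_cutoff <= 0:
            raise ConfigurationError("short_len_cutoff must be > 0")
        if self.length_field not in ("subject", "query"):
            raise ConfigurationError("length_field must be 'subject' or 'query'")


def _check_hits(hits: pd.DataFrame) -> None:
    missing = [c for c in HIT_COLUMNS if c not in hits.columns]
    if missing:
        raise DataError(f"hit table lacks columns {missing}")
    if len(hits) and (hits["evalue"] < 0).any():
        bad = hits.loc[hits["evalue"] < 0, "seq_id"].iloc[0]
        raise DataError(f"negative e-value for hit {bad!r}")
    if len(hits):
        for col in ("query_length", "subject_length"):
            if (hits[col] <= 0).any():
                raise DataError(f"non-positive {col} in hit table")


def read_blast_tabular(path: str | Path, gene_id: str | None = None,
                       taxon_delimiter: str = "|") -> pd.DataFrame:
    """Parse 12-column BLAST tabular output into the internal hit schema.

    The subject taxon is taken as the ``sseqid`` prefix before
    *taxon_delimiter*.  Alignment length stands in for both query and subject
    length (the tabular dialect carries no full-sequence lengths).
    """
    path = Path(path)
    gid = gene_id if gene_id is not None else path.stem.split(".")[0]
    raw = pd.read_csv(path, sep="\t", names=_BLAST_NAMES, comment="#")
    out = pd.DataFrame({
        "gene_id": gid,
        "seq_id": raw["sseqid"].astype(str),
        "taxon_id": raw["sseqid"].astype(str).str.split(taxon_delimiter).str[0],
        "evalue": raw["evalue"].astype(float),
        "query_length": raw["length"].astype(int),
        "subject_length": raw["length"].astype(int),
    })
    _check_hits(out)
    return out


def apply_evalue_ceiling(hits: pd.DataFrame,
                         config: SelectionConfig = SelectionConfig()) -> pd.DataFrame:
    """Drop hits exceeding the length-dependent e-value ceiling.

    Idempotent: the retained set already satisfies the ceiling.
    """
    config.validate()
    _check_hits(hits)
    if not len(hits):
        return hits.copy()
    length = hits[f"{config.length_field}_length"]
    ceiling = np.where(length < config.short_len_cutoff,
                       config.evalue_max_short, config.evalue_max_long)
    return hits[hits["evalue"].to_numpy() <= ceiling].copy()


def _window_groups(hits: pd.DataFrame, config: SelectionConfig):
    keys = ["gene_id", "taxon_id"] if config.per_taxon else ["gene_id"]
    return hits.groupby(keys, sort=True)


def select_candidates(hits: pd.DataFrame,
                      config: SelectionConfig = SelectionConfig(),
                      apply_ceiling: bool = True,
                      ) -> dict[tuple[str, str], list[str]]:
    """Best hit per (gene, taxon) plus all hits within the e-value window.

    Returns ``(gene_id, taxon_id) -> [seq_id, ...]`` ordered best-first with
    deterministic ``(evalue, seq_id)`` tie-breaking.  An exact-zero best
    e-value keeps only other exact zeros (order of magnitude is undefined
    at zero).
    """
    config.validate()
    _check_hits(hits)
    if apply_ceiling:
        hits = apply_evalue_ceiling(hits, config)
    out: dict[tuple[str, str], list[str]] = {}
    if not len(hits):
        return out
    for key, grp in _window_groups(hits, config):
        if not isinstance(key, tuple):
            key = (key,)
        grp = grp.sort_values(["evalue", "seq_id"], kind="mergesort")
        best = float(grp["evalue"].iloc[0])
        if best == 0.0:
            kept = grp[grp["evalue"] == 0.0]
        else:
            kept = grp[grp["evalue"] <= best * 10.0 ** config.window_orders]
        if config.per_taxon:
            out[(key[0], key[1])] = list(kept["seq_id"])
        else:
            for taxon, sub in kept.groupby("taxon_id", sort=True):
                sub = sub.sort_values(["evalue", "seq_id"], kind="mergesort")
                out[(key[0], str(taxon))] = list(sub["seq_id"])
    return out


def resolve_orthologs(candidates: dict[tuple[str, str], list[str]],
                      gene_trees: dict[str, "dendropy.Tree"] | None = None,
                      policy: LongBranchPolicy = LongBranchPolicy(),
                      ) -> dict[str, dict[str, str]]:
    """One sequence per taxon per gene.

    For each (gene, taxon) the best-ranked candidate not flagged as a long
    branch in the gene's tree is selected; taxa whose candidates are all
    flagged are dropped.  Without gene trees the best candidate wins
    everywhere.  Candidates absent from a supplied tree raise
    :class:`LabelingError` listing the offenders.
    """
    flags: dict[str, set[str]] = {}
    tips: dict[str, set[str]] = {}
    if gene_trees:
        for gene_id, tree in gene_trees.items():
            tips[gene_id] = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
            flags[gene_id] = set(flag_long_branches(tree, policy))

    missing: list[str] = []
    for (gene_id, _taxon), seq_ids in sorted(candidates.items()):
        if gene_id in tips:
            missing.extend(s for s in seq_ids if s not in tips[gene_id])
    if missing:
        raise LabelingError(
            "candidates absent from gene tree: " + ", ".join(sorted(missing)))

    resolved: dict[str, dict[str, str]] = {}
    for (gene_id, taxon), seq_ids in sorted(candidates.items()):
        flagged = flags.get(gene_id, set())
        chosen = next((s for s in seq_ids if s not in flagged), None)
        if chosen is not None:
            resolved.setdefault(gene_id, {})[taxon] = chosen
    return resolved


def selection_report(candidates: dict[tuple[str, str], list[str]],
                     resolved: dict[str, dict[str, str]],
                     hits: pd.DataFrame) -> pd.DataFrame:
    """Tabular audit trail: gene, taxon, seq_id, evalue, rank, status."""
    evalue = dict(zip(hits["seq_id"], hits["evalue"]))
    rows = []
    for (gene_id, taxon), seq_ids in sorted(candidates.items()):
        selected = resolved.get(gene_id, {}).get(taxon)
        for rank, sid in enumerate(seq_ids, start=1):
            if sid == selected:
                status = "selected"
            elif selected is None:
                status = "dropped_all_flagged"
            else:
                status = "alternative"
            rows.append((gene_id, taxon, sid, evalue.get(sid, float("nan")),
                         rank, status))
    return pd.DataFrame(rows, columns=[
        "gene_id", "taxon_id", "seq_id", "evalue", "rank", "status"])
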