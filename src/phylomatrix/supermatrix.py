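"""Supermatrix concatenation, occupancy accounting, and alignment I/O.

A :class:`Supermatrix` is the concatenation of per-gene alignments over the
union of their taxa.  Blocks for taxa absent from a gene are filled with the
missing symbol ``?``.  A partition table records each gene's column span in
1-based inclusive coordinates (RAxML-style).  Completeness is the percentage
of non-missing cells; by default ``?``, ``-`` and ``X`` all count as missing
(``X`` optionally not, since conventions differ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, DataError
from .families import GeneFamily

__all__ = [
    "Supermatrix", "concatenate", "occupancy_filter", "completeness",
    "occupancy_report", "simple_column_filter",
    "write_fasta", "read_fasta", "write_phylip", "read_phylip",
    "write_nexus", "write_partitions", "read_partitions",
]

MISSING_SYMBOLS = ("?", "-", "X")


@dataclass
class Supermatrix:
    """Concatenated alignment with partition map.

    ``data`` is an (n_taxa, n_columns) array of single characters, rows in
    ``taxa`` order; ``partitions`` is a list of ``(gene_id, start, end)``
    with 1-based inclusive coordinates tiling ``[1, n_columns]``.
    """

    taxa: list[str]
    data: np.ndarray
    partitions: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return int(self.data.shape[1])

    def row(self, taxon: str) -> str:
        return "".join(self.data[self.taxa.index(taxon)])

    def validate(self) -> None:
        if self.data.shape[0] != len(self.taxa):
            raise DataError("row count does not match taxa list")
        pos = 1
        for gene_id, start, end in self.partitions:
            if start != pos or end < start:
                raise DataError(
                    f"partition {gene_id} ({start}-{end}) breaks the tiling")
            pos = end + 1
        if self.partitions and pos != self.n_columns + 1:
            raise DataError("partitions do not tile the full matrix")


def concatenate(genes: list[GeneFamily]) -> Supermatrix:
    """Concatenate aligned single-copy gene families into a supermatrix.

    Taxa are the sorted union over genes; missing gene x taxon blocks are
    filled with ``?``.  Genes must be aligned with one sequence per taxon;
    ragged genes raise :class:`AlignmentError` naming the gene.
    """
    for fam in genes:
        if not fam.aligned:
            raise AlignmentError(f"gene {fam.gene_id} is not aligned")
        fam.validate_aligned()
        for taxon, entries in fam.members.items():
            if len(entries) != 1:
                raise AlignmentError(
                    f"gene {fam.gene_id}: taxon {taxon} has "
                    f"{len(entries)} sequences (need exactly 1)")

    taxa = sorted(set().union(*(set(f.members) for f in genes))) if genes else []
    total = sum(f.alignment_length for f in genes)
    data = np.full((len(taxa), total), "?", dtype="<U1")
    partitions: list[tuple[str, int, int]] = []
    index = {t: i for i, t in enumerate(taxa)}
    pos = 0
    for fam in genes:
        width = fam.alignment_length
        for taxon, entries in fam.members.items():
            seq = entries[0][1]
            data[index[taxon], pos:pos + width] = list(seq)
        partitions.append((fam.gene_id, pos + 1, pos + width))
        pos += width
    return Supermatrix(taxa, data, partitions)


def _missing_mask(matrix: Supermatrix, count_x_as_missing: bool = True) -> np.ndarray:
    symbols = MISSING_SYMBOLS if count_x_as_missing else ("?", "-")
    mask = np.zeros(matrix.data.shape, dtype=bool)
    for s in symbols:
        mask |= matrix.data == s
    return mask


def completeness(matrix: Supermatrix, count_x_as_missing: bool = True) -> float:
    """Percentage of non-missing cells: 100 x filled / (taxa x columns)."""
    if matrix.data.size == 0:
        return 0.0
    missing = _missing_mask(matrix, count_x_as_missing)
    return 100.0 * (1.0 - missing.sum() / matrix.data.size)


def occupancy_filter(genes: list[GeneFamily], min_taxon_fraction: float = 0.5,
                     taxon_universe: list[str] | None = None) -> list[GeneFamily]:
    """Keep genes present in at least ``min_taxon_fraction`` of the taxa.

    The boundary is inclusive ("at least 50%" keeps a gene in exactly half
    the taxa).  The universe defaults to the union of taxa across *genes*.
    """
    if taxon_universe is None:
        taxon_universe = sorted(set().union(*(set(f.members) for f in genes))) \
            if genes else []
    universe = set(taxon_universe)
    if not universe:
        raise DataError("taxon universe is empty")
    kept = []
    for fam in genes:
        frac = len(set(fam.members) & universe) / len(universe)
        if frac >= min_taxon_fraction:
            kept.append(fam)
    return kept


def occupancy_report(matrix: Supermatrix,
                     count_x_as_missing: bool = True) -> dict:
    """Per-gene and per-taxon occupancy plus overall completeness.

    A gene counts as present for a taxon when its block contains at least one
    non-missing cell.
    """
    missing = _missing_mask(matrix, count_x_as_missing)
    per_gene = {}
    gene_present = np.zeros((matrix.n_taxa, len(matrix.partitions)), dtype=bool)
    for k, (gene_id, start, end) in enumerate(matrix.partitions):
        block_filled = ~missing[:, start - 1:end]
        present = block_filled.any(axis=1)
        gene_present[:, k] = present
        per_gene[gene_id] = float(present.mean())
    per_taxon = {t: float(gene_present[i].mean())
                 for i, t in enumerate(matrix.taxa)} if matrix.partitions else {}
    return {
        "per_gene": per_gene,
        "per_taxon": per_taxon,
        "completeness": completeness(matrix, count_x_as_missing),
    }


def simple_column_filter(matrix: Supermatrix, max_gap_fraction: float,
                         count_x_as_missing: bool = True) -> Supermatrix:
    """Drop columns whose missing fraction exceeds *max_gap_fraction*.

    Partitions are re-spanned to the surviving columns; partitions losing all
    columns are dropped.  This is a plain per-column occupancy trim and makes
    no attempt to emulate block-based trimmers such as Gblocks.
    """
    if not (0.0 <= max_gap_fraction <= 1.0):
        raise DataError("max_gap_fraction must be in [0, 1]")
    if matrix.data.size == 0:
        return Supermatrix(list(matrix.taxa), matrix.data.copy(),
                           list(matrix.partitions))
    missing = _missing_mask(matrix, count_x_as_missing)
    keep = missing.mean(axis=0) <= max_gap_fraction
    new_partitions: list[tuple[str, int, int]] = []
    pos = 1
    for gene_id, start, end in matrix.partitions:
        width = int(keep[start - 1:end].sum())
        if width > 0:
            new_partitions.append((gene_id, pos, pos + width - 1))
            pos += width
    return Supermatrix(list(matrix.taxa), matrix.data[:, keep], new_partitions)


# ---------------------------------------------------------------------------
# I/O

def write_fasta(matrix: Supermatrix, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for i, taxon in enumerate(matrix.taxa):
            fh.write(f">{taxon}\n{''.join(matrix.data[i])}\n")
    return path


def read_fasta(path: str | Path,
               partitions: list[tuple[str, int, int]] | None = None) -> Supermatrix:
    taxa: list[str] = []
    seqs: list[str] = []
    with open(path) as fh:
        name, chunks = None, []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    taxa.append(name)
                    seqs.append("".join(chunks))
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
        if name is not None:
            taxa.append(name)
            seqs.append("".join(chunks))
    if len({len(s) for s in seqs}) > 1:
        raise AlignmentError(f"ragged alignment in {path}")
    data = np.array([list(s) for s in seqs], dtype="<U1") if seqs else \
        np.empty((0, 0), dtype="<U1")
    return Supermatrix(taxa, data, partitions or [])


def write_phylip(matrix: Supermatrix, path: str | Path) -> Path:
    """Relaxed (whitespace-delimited names) sequential PHYLIP."""
    path = Path(path)
    width = max((len(t) for t in matrix.taxa), default=0) + 2
    with open(path, "w") as fh:
        fh.write(f"{matrix.n_taxa} {matrix.n_columns}\n")
        for i, taxon in enumerate(matrix.taxa):
            fh.write(f"{taxon:<{width}}{''.join(matrix.data[i])}\n")
    return path


def read_phylip(path: str | Path,
                partitions: list[tuple[str, int, int]] | None = None) -> Supermatrix:
    with open(path) as fh:
        header = fh.readline().split()
        n_taxa, n_cols = int(header[0]), int(header[1])
        taxa, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            taxa.append(name)
            rows.append(seq.replace(" ", "").strip())
    if len(taxa) != n_taxa or any(len(r) != n_cols for r in rows):
        raise AlignmentError(f"PHYLIP dimensions disagree with header in {path}")
    data = np.array([list(r) for r in rows], dtype="<U1") if rows else \
        np.empty((0, n_cols), dtype="<U1")
    return Supermatrix(taxa, data, partitions or [])


def write_nexus(matrix: Supermatrix, path: str | Path,
                datatype: str = "protein") -> Path:
    """NEXUS with a charset per partition."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#NEXUS\nbegin data;\n")
        fh.write(f"  dimensions ntax={matrix.n_taxa} nchar={matrix.n_columns};\n")
        fh.write(f"  format datatype={datatype} missing=? gap=-;\n  matrix\n")
        width = max((len(t) for t in matrix.taxa), default=0) + 2
        for i, taxon in enumerate(matrix.taxa):
            fh.write(f"    {taxon:<{width}}{''.join(matrix.data[i])}\n")
        fh.write("  ;\nend;\n")
        if matrix.partitions:
            fh.write("begin sets;\n")
            for gene_id, start, end in matrix.partitions:
                fh.write(f"  charset {gene_id} = {start}-{end};\n")
            fh.write("end;\n")
    return path


def write_partitions(matrix: Supermatrix, path: str | Path) -> Path:
    """RAxML-style partition file: one ``GENE = start-end`` line per gene."""
    path = Path(path)
    with open(path, "w") as fh:
        for gene_id, start, end in matrix.partitions:
            fh.write(f"{gene_id} = {start}-{end}\n")
    return path


def read_partitions(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            name, span = line.split("=")
            start, end = span.strip().split("-")
            out.append((name.strip().split(",")[-1].strip(),
                        int(start), int(end)))
    return out
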