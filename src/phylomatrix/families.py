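"""Gene-family containers and FASTA I/O.

A :class:`GeneFamily` holds the protein sequences recovered for one locus,
keyed by taxon.  Before ortholog resolution a taxon may carry several
candidate sequences (the best homology hit plus near-tied alternatives and
putative paralogs); after resolution each taxon carries exactly one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import AlignmentError

__all__ = ["GeneFamily", "read_gene_fasta", "write_gene_fasta"]


@dataclass
class GeneFamily:
    """Protein sequences for one locus.

    Parameters
    ----------
    gene_id : str
        Locus identifier.
    members : dict
        Mapping ``taxon_id -> list of (seq_id, sequence)``.  Multiple entries
        per taxon are candidate sequences awaiting resolution.
    aligned : bool
        Whether all sequences share coordinates (equal length, gaps allowed).
    meta : dict
        Free-form provenance (e.g. the simulated rate class).
    """

    gene_id: str
    members: dict[str, list[tuple[str, str]]]
    aligned: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return sorted(self.members)

    @property
    def alignment_length(self) -> int:
        if not self.aligned:
            raise AlignmentError(f"gene {self.gene_id} is not aligned")
        for entries in self.members.values():
            for _, seq in entries:
                return len(seq)
        return 0

    def validate_aligned(self) -> None:
        """Raise :class:`AlignmentError` naming the gene on ragged lengths."""
        lengths = {len(s) for entries in self.members.values() for _, s in entries}
        if len(lengths) > 1:
            raise AlignmentError(
                f"gene {self.gene_id}: ragged sequence lengths {sorted(lengths)}"
            )

    def single_copy(self) -> "GeneFamily":
        """Return a copy keeping only the first (best-ranked) sequence per taxon."""
        return GeneFamily(
            gene_id=self.gene_id,
            members={t: [entries[0]] for t, entries in self.members.items() if entries},
            aligned=self.aligned,
            meta=dict(self.meta),
        )

    def subset(self, selection: dict[str, str]) -> "GeneFamily":
        """Keep one named sequence per taxon (``taxon_id -> seq_id``)."""
        members: dict[str, list[tuple[str, str]]] = {}
        for taxon, seq_id in selection.items():
            for sid, seq in self.members.get(taxon, []):
                if sid == seq_id:
                    members[taxon] = [(sid, seq)]
                    break
        return GeneFamily(self.gene_id, members, aligned=self.aligned, meta=dict(self.meta))

    def sequence_for(self, taxon: str) -> str:
        return self.members[taxon][0][1]


def read_gene_fasta(path: str | Path, gene_id: str | None = None,
                    taxon_delimiter: str = "|") -> GeneFamily:
    """Read one per-gene FASTA into a :class:`GeneFamily`.

    The taxon is the part of the record id before *taxon_delimiter*; records
    without the delimiter are their own taxon.  Sequences of equal length are
    marked aligned.
    """
    path = Path(path)
    gid = gene_id if gene_id is not None else path.stem.split(".")[0]
    members: dict[str, list[tuple[str, str]]] = {}
    lengths = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        taxon = rec.id.split(taxon_delimiter)[0]
        seq = str(rec.seq)
        members.setdefault(taxon, []).append((rec.id, seq))
        lengths.add(len(seq))
    return GeneFamily(gid, members, aligned=(len(lengths) <= 1))


def write_gene_fasta(family: GeneFamily, path: str | Path) -> Path:
    path = Path(path)
    records = []
    for taxon in family.taxa:
        for seq_id, seq in family.members[taxon]:
            records.append(SeqRecord(Seq(seq), id=seq_id, description=""))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")
    return path
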