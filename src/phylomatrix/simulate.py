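"""Synthetic gene-family datasets with known ground truth.

The generator emulates the raw material of a transcriptome-based phylogenomic
study: a collection of protein-coding gene families sampled from a set of
taxa, each family evolved along one species tree, with

* per-gene rate multipliers (a saturation gradient across loci),
* taxa missing at random from individual genes (incomplete transcriptomes),
* occasional fast-evolving ("long-branch") tip sequences, and
* decoy paralogs that enter the homology-search hit tables with
  stochastically worse e-values than the true ortholog.

Sequences evolve under a 20-state Poisson process (uniform exchangeabilities
and stationary frequencies).  For an edge of expected length ``t``
substitutions/site the probability that a site keeps its parent state is
``exp(-20 t / 19)``; otherwise the state is redrawn uniformly from all 20
amino acids.  This closed form makes simulation exact and fast; downstream
stages only require realistic divergence, not model fidelity.

Homology-search e-values are synthesised from each sequence's identity to the
ancestral (root) query sequence: ``log10 E = -identity^2 * L / 2`` plus
Gaussian noise on the log scale (equivalently, lognormal noise on E).  Only
the ordering and the order-of-magnitude structure of e-values matter to the
selection stage, both of which this map preserves.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .families import GeneFamily, write_gene_fasta

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate_dataset", "write_dataset"]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: BLAST tabular ("outfmt 6") column order used for hit-table files.
BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror a mid-sized phylogenomic compilation: 20 taxa, 200 loci,
    ~25% of taxon/gene slots missing (≈75% supermatrix completeness), a
    four-class rate spread creating a saturation gradient, sparse paralog
    contamination, and rare 8x-accelerated tip sequences.
    """

    n_taxa: int = 20
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (120, 600)
    rate_classes: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    missing_fraction: float = 0.25
    paralog_fraction: float = 0.10
    long_branch_fraction: float = 0.05
    long_branch_multiplier: float = 8.0
    #: i.i.d. gamma branch lengths (substitutions/site at rate class 1.0).
    #: The high shape (low CV) emulates a roughly clock-like species history;
    #: rate variation is injected explicitly via rate_classes and the
    #: long-branch multiplier so that injected outliers are conspicuous
    #: against the background spread.
    mean_branch_length: float = 0.08
    branch_length_shape: float = 12.0
    #: rate acceleration applied to a duplicate's independent history
    paralog_rate_multiplier: float = 2.0
    #: std-dev of Gaussian noise added to log10(e-value)
    evalue_log_noise: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 4:
            raise ConfigurationError("n_taxa must be >= 4")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ConfigurationError("gene_length_range must satisfy 0 < min <= max")
        for name in ("missing_fraction", "paralog_fraction", "long_branch_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1)")
        if not self.rate_classes or any(r <= 0 for r in self.rate_classes):
            raise ConfigurationError("rate_classes must be non-empty and positive")
        if self.long_branch_multiplier <= 1:
            raise ConfigurationError("long_branch_multiplier must be > 1")
        if self.mean_branch_length <= 0:
            raise ConfigurationError("mean_branch_length must be > 0")
        if self.branch_length_shape <= 0:
            raise ConfigurationError("branch_length_shape must be > 0")
        if self.paralog_rate_multiplier <= 0:
            raise ConfigurationError("paralog_rate_multiplier must be > 0")
        if self.evalue_log_noise < 0:
            raise ConfigurationError("evalue_log_noise must be >= 0")


@dataclass
class GeneTruth:
    """Ground truth for one simulated gene."""

    ortholog_ids: dict[str, str]          # taxon -> true ortholog seq_id
    paralog_ids: dict[str, list[str]]     # taxon -> decoy seq_ids
    long_branch_ids: list[str]            # seq_ids evolved at elevated rate
    rate_class: float


@dataclass
class SyntheticDataset:
    species_tree: dendropy.Tree
    gene_families: list[GeneFamily]
    hit_tables: dict[str, pd.DataFrame]   # gene_id -> BLAST-dialect table
    truth: dict[str, GeneTruth] = field(default_factory=dict)
    #: true per-gene trees (tips are seq_ids; branch lengths in subs/site for
    #: that gene, i.e. species-tree lengths x rate class, with long-branch
    #: terminal edges inflated and paralog tips attached at their source node)
    gene_trees: dict[str, dendropy.Tree] = field(default_factory=dict)

    def ortholog_families(self) -> list[GeneFamily]:
        """True single-copy families (orthologs only), for concatenation."""
        out = []
        for fam in self.gene_families:
            tr = self.truth[fam.gene_id]
            out.append(fam.subset({t: s for t, s in tr.ortholog_ids.items()}))
        return out


def _random_topology(taxa: list[str], rng: np.random.Generator) -> str:
    """Random bifurcating topology via iterative pair joining (newick, no lengths)."""
    nodes = list(taxa)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


def _simulate_species_tree(config: SimulationConfig,
                           rng: np.random.Generator) -> dendropy.Tree:
    taxa = [f"T{i:03d}" for i in range(1, config.n_taxa + 1)]
    newick = _random_topology(taxa, rng)
    tree = dendropy.Tree.get(data=newick, schema="newick")
    scale = config.mean_branch_length / config.branch_length_shape
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            edge.length = 0.0
        else:
            edge.length = float(rng.gamma(config.branch_length_shape, scale))
    return tree


def _evolve(parent_states: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """One edge of the 20-state Poisson process; ``t`` in substitutions/site."""
    if t <= 0:
        return parent_states.copy()
    keep = rng.random(parent_states.size) < np.exp(-20.0 * t / 19.0)
    redraw = rng.integers(0, 20, size=parent_states.size)
    return np.where(keep, parent_states, redraw)


def _log10_evalue(identity: float, length: int, noise_sd: float,
                  rng: np.random.Generator) -> float:
    raw = -(identity ** 2) * length / 2.0 + rng.normal(0.0, noise_sd)
    return float(np.clip(raw, -300.0, 0.0))


def _gene_tree(tree: dendropy.Tree, gene_id: str, rate: float,
               present: list[str], lb_tips: set[str], multiplier: float,
               paralogs: dict[int, list[tuple[str, float]]]) -> dendropy.Tree:
    """True gene tree: species tree scaled by *rate*, long-branch terminal
    edges inflated, paralog tips hung off their source internal node, absent
    taxa pruned.  Tip labels are sequence ids."""

    def render(node) -> str:
        if node.is_leaf():
            taxon = node.taxon.label
            edge = (node.edge.length or 0.0) * rate
            if taxon in lb_tips:
                edge *= multiplier
            return f"{taxon}|{gene_id}|o:{edge:.10f}"
        parts = [render(c) for c in node.child_nodes()]
        for p_id, t_extra in paralogs.get(id(node), []):
            parts.append(f"{p_id}:{t_extra:.10f}")
        edge = (node.edge.length or 0.0) * rate
        return "(" + ",".join(parts) + f"):{edge:.10f}"

    newick = render(tree.seed_node) + ";"
    gt = dendropy.Tree.get(data=newick, schema="newick",
                           suppress_internal_node_taxa=True,
                           preserve_underscores=True)
    absent = [f"{t}|{gene_id}|o" for t in
              sorted({x.label for x in tree.taxon_namespace} - set(present))]
    if absent:
        gt.prune_taxa_with_labels(absent)
        gt.purge_taxon_namespace()
    return gt


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a :class:`SyntheticDataset` under *config* (fully seeded)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = _simulate_species_tree(config, rng)

    # Per-node mean distance to descendant tips (used to give duplicates an
    # independent post-duplication history of comparable depth).
    tip_depth: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tip_depth[id(node)] = 0.0
        else:
            tip_depth[id(node)] = float(np.mean([
                tip_depth[id(c)] + (c.edge.length or 0.0) for c in node.child_nodes()
            ]))

    internal_nodes = [n for n in tree.preorder_node_iter()
                      if not n.is_leaf() and n is not tree.seed_node]
    taxa = sorted(t.label for t in tree.taxon_namespace)

    families: list[GeneFamily] = []
    hit_tables: dict[str, pd.DataFrame] = {}
    truth: dict[str, GeneTruth] = {}
    gene_trees: dict[str, dendropy.Tree] = {}

    for g in range(1, config.n_genes + 1):
        gene_id = f"G{g:04d}"
        length = int(rng.integers(config.gene_length_range[0],
                                  config.gene_length_range[1] + 1))
        rate = float(rng.choice(config.rate_classes))
        present = [t for t in taxa if rng.random() >= config.missing_fraction]
        lb_tips = {t for t in present if rng.random() < config.long_branch_fraction}

        root_states = rng.integers(0, 20, size=length)
        node_states: dict[int, np.ndarray] = {id(tree.seed_node): root_states}
        tip_states: dict[str, np.ndarray] = {}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            t_edge = (node.edge.length or 0.0) * rate
            if node.is_leaf() and node.taxon.label in lb_tips:
                t_edge *= config.long_branch_multiplier
            states = _evolve(node_states[id(node.parent_node)], t_edge, rng)
            node_states[id(node)] = states
            if node.is_leaf():
                tip_states[node.taxon.label] = states

        members: dict[str, list[tuple[str, str]]] = {}
        ortholog_ids: dict[str, str] = {}
        paralog_ids: dict[str, list[str]] = {}
        long_branch_ids: list[str] = []
        paralogs_by_node: dict[int, list[tuple[str, float]]] = {}
        rows: list[tuple] = []
        qseqid = f"{gene_id}_query"

        def add_hit(seq_id: str, states: np.ndarray) -> None:
            identity = float(np.mean(states == root_states))
            log10e = _log10_evalue(identity, length, config.evalue_log_noise, rng)
            pident = round(100.0 * identity, 2)
            mismatch = int(round(length * (1.0 - identity)))
            bitscore = round(-2.0 * log10e + 30.0, 1)
            rows.append((qseqid, seq_id, pident, length, mismatch, 0,
                         1, length, 1, length, 10.0 ** log10e, bitscore))

        for taxon in present:
            states = tip_states[taxon]
            seq_id = f"{taxon}|{gene_id}|o"
            members[taxon] = [(seq_id, "".join(AMINO_ACIDS[states]))]
            ortholog_ids[taxon] = seq_id
            if taxon in lb_tips:
                long_branch_ids.append(seq_id)
            add_hit(seq_id, states)

            if rng.random() < config.paralog_fraction and internal_nodes:
                src = internal_nodes[int(rng.integers(0, len(internal_nodes)))]
                t_extra = (tip_depth[id(src)] + config.mean_branch_length) \
                    * config.paralog_rate_multiplier * rate
                p_states = _evolve(node_states[id(src)], t_extra, rng)
                p_id = f"{taxon}|{gene_id}|p1"
                members[taxon].append((p_id, "".join(AMINO_ACIDS[p_states])))
                paralog_ids.setdefault(taxon, []).append(p_id)
                paralogs_by_node.setdefault(id(src), []).append((p_id, t_extra))
                add_hit(p_id, p_states)

        families.append(GeneFamily(gene_id, members, aligned=True,
                                   meta={"rate_class": rate, "length": length}))
        hit_tables[gene_id] = pd.DataFrame(rows, columns=BLAST_COLUMNS)
        truth[gene_id] = GeneTruth(ortholog_ids, paralog_ids,
                                   sorted(long_branch_ids), rate)
        gene_trees[gene_id] = _gene_tree(
            tree, gene_id, rate, present, lb_tips,
            config.long_branch_multiplier, paralogs_by_node)

    return SyntheticDataset(tree, families, hit_tables, truth, gene_trees)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> Path:
    """Write FASTA/hit/tree/truth files plus a JSON manifest; returns its path.

    Layout: ``genes/<gene>.fasta``, ``hits/<gene>.hits.tsv`` (12-column BLAST
    tabular), ``species_tree.nwk``, ``truth.tsv``.
    """
    directory = Path(directory)
    try:
        (directory / "genes").mkdir(parents=True, exist_ok=True)
        (directory / "hits").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {directory}: {exc}") from exc

    files: list[Path] = []
    tree_path = directory / "species_tree.nwk"
    dataset.species_tree.write(path=str(tree_path), schema="newick",
                               suppress_rooting=True)
    files.append(tree_path)

    if dataset.gene_trees:
        (directory / "gene_trees").mkdir(parents=True, exist_ok=True)
    for fam in dataset.gene_families:
        p = write_gene_fasta(fam, directory / "genes" / f"{fam.gene_id}.fasta")
        files.append(p)
        hp = directory / "hits" / f"{fam.gene_id}.hits.tsv"
        dataset.hit_tables[fam.gene_id].to_csv(hp, sep="\t", header=False,
                                               index=False, float_format="%.6g")
        files.append(hp)
        gt = dataset.gene_trees.get(fam.gene_id)
        if gt is not None:
            tp = directory / "gene_trees" / f"{fam.gene_id}.nwk"
            gt.write(path=str(tp), schema="newick", suppress_rooting=True,
                     unquoted_underscores=True)
            files.append(tp)

    truth_rows = []
    for gene_id in sorted(dataset.truth):
        tr = dataset.truth[gene_id]
        for taxon in sorted(tr.ortholog_ids):
            sid = tr.ortholog_ids[taxon]
            truth_rows.append((gene_id, taxon, sid, "ortholog",
                               int(sid in tr.long_branch_ids), tr.rate_class))
        for taxon in sorted(tr.paralog_ids):
            for sid in tr.paralog_ids[taxon]:
                truth_rows.append((gene_id, taxon, sid, "paralog", 0, tr.rate_class))
    truth_path = directory / "truth.tsv"
    pd.DataFrame(truth_rows, columns=[
        "gene_id", "taxon_id", "seq_id", "role", "long_branch", "rate_class",
    ]).to_csv(truth_path, sep="\t", index=False)
    files.append(truth_path)

    manifest_path = directory / "manifest.json"
    manifest = {
        "files": {str(p.relative_to(directory)): _sha256(p) for p in sorted(files)},
        "n_genes": len(dataset.gene_families),
        "n_taxa": len(dataset.species_tree.taxon_namespace),
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest_path
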