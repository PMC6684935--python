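import numpy as np
import pandas as pd
import pytest

import phylomatrix as pm


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 20 taxa, 200 genes, seed 1."""
    return pm.simulate_dataset(pm.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    return pm.simulate_dataset(pm.SimulationConfig(n_taxa=8, n_genes=12, seed=7))


def hits_from_blast(dataset, gene_id):
    """Convert a dataset's raw BLAST-dialect table to the internal schema."""
    raw = dataset.hit_tables[gene_id]
    return pd.DataFrame({
        "gene_id": gene_id,
        "seq_id": raw["sseqid"].astype(str),
        "taxon_id": raw["sseqid"].astype(str).str.split("|").str[0],
        "evalue": raw["evalue"].astype(float),
        "query_length": raw["length"].astype(int),
        "subject_length": raw["length"].astype(int),
    })


@pytest.fixture(scope="session")
def default_resolution(default_dataset):
    """Select + resolve every gene of the default dataset using its true
    gene trees; returns {gene_id: {taxon: seq_id}}."""
    resolved = {}
    for fam in default_dataset.gene_families:
        g = fam.gene_id
        cand = pm.select_candidates(hits_from_blast(default_dataset, g))
        res = pm.resolve_orthologs(cand, {g: default_dataset.gene_trees[g]})
        resolved.update(res)
    return resolved


def make_matrix(rows: dict[str, str], partitions=None) -> pm.Supermatrix:
    taxa = list(rows)
    data = np.array([list(s) for s in rows.values()], dtype="<U1")
    return pm.Supermatrix(taxa, data, partitions or [])
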