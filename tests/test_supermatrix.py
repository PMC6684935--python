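"""Concatenation, occupancy, completeness and column filtering."""

import numpy as np
import pytest

import phylomatrix as pm
from phylomatrix.exceptions import AlignmentError
from phylomatrix.families import GeneFamily
from conftest import make_matrix


def fam(gene_id, seqs, aligned=True):
    return GeneFamily(gene_id,
                      {t: [(f"{t}|{gene_id}", s)] for t, s in seqs.items()},
                      aligned=aligned)


def test_concatenate_worked_example():
    """Genes of 10 and 20 columns over {A,B,C} and {A,B}: 30 columns,
    C's last 20 cells missing, completeness 70/90 = 77.8%."""
    g1 = fam("g1", {"A": "M" * 10, "B": "K" * 10, "C": "L" * 10})
    g2 = fam("g2", {"A": "M" * 20, "B": "K" * 20})
    m = pm.concatenate([g1, g2])
    assert m.taxa == ["A", "B", "C"]
    assert m.n_columns == 30
    assert m.partitions == [("g1", 1, 10), ("g2", 11, 30)]
    assert m.row("C") == "L" * 10 + "?" * 20
    assert pm.completeness(m) == pytest.approx(77.8, abs=0.1)


def test_single_gene_identity():
    g = fam("g1", {"A": "MKLV", "B": "MKIV"})
    m = pm.concatenate([g])
    assert m.n_columns == 4
    assert m.partitions == [("g1", 1, 4)]
    assert m.row("A") == "MKLV"


def test_concatenation_associativity(small_dataset):
    """concat(concat(g1,g2),g3) == concat(g1,g2,g3) cell-wise."""
    genes = [f.single_copy() for f in small_dataset.ortholog_families()[:3]]
    direct = pm.concatenate(genes)
    left = pm.concatenate(genes[:2])
    # rebuild families from the intermediate matrix, then add g3
    inter = []
    for gid, start, end in left.partitions:
        members = {}
        for i, t in enumerate(left.taxa):
            seg = "".join(left.data[i, start - 1:end])
            if set(seg) != {"?"}:
                members[t] = [(f"{t}|{gid}", seg)]
        inter.append(GeneFamily(gid, members, aligned=True))
    nested = pm.concatenate(inter + [genes[2]])
    assert nested.taxa == direct.taxa
    assert nested.partitions == direct.partitions
    assert (nested.data == direct.data).all()


def test_ragged_gene_rejected():
    bad = GeneFamily("g1", {"A": [("a", "MKL")], "B": [("b", "MK")]},
                     aligned=True)
    with pytest.raises(AlignmentError, match="g1"):
        pm.concatenate([bad])


def test_unaligned_gene_rejected():
    with pytest.raises(AlignmentError, match="g1"):
        pm.concatenate([fam("g1", {"A": "MK"}, aligned=False)])


@pytest.mark.parametrize("n_present,threshold,kept", [
    (2, 0.5, True),    # exactly 50%: inclusive boundary
    (1, 0.5, False),
    (1, 0.0, True),    # vacuous filter
    (4, 1.0, True),
])
def test_occupancy_filter_boundaries(n_present, threshold, kept):
    universe = ["A", "B", "C", "D"]
    g = fam("g1", {t: "MK" for t in universe[:n_present]})
    out = pm.occupancy_filter([g], threshold, universe)
    assert (len(out) == 1) == kept


def test_occupancy_filter_monotone(small_dataset):
    genes = [f.single_copy() for f in small_dataset.ortholog_families()]
    universe = sorted({t for g in genes for t in g.members})
    prev = None
    for thr in (0.0, 0.25, 0.5, 0.75, 1.0):
        ids = {g.gene_id for g in pm.occupancy_filter(genes, thr, universe)}
        if prev is not None:
            assert ids <= prev
        prev = ids


def test_completeness_fully_populated():
    m = make_matrix({"A": "MKLV", "B": "MKIV"})
    assert pm.completeness(m) == 100.0


def test_completeness_x_mode():
    m = make_matrix({"A": "MX-?", "B": "MKLV"})
    assert pm.completeness(m, count_x_as_missing=True) == pytest.approx(62.5)
    assert pm.completeness(m, count_x_as_missing=False) == pytest.approx(75.0)


def test_completeness_is_occupancy_weighted_average(small_dataset):
    """Matrix completeness equals the column-weighted mean of per-gene
    completeness."""
    genes = [f.single_copy() for f in small_dataset.ortholog_families()]
    matrix = pm.concatenate(genes)
    taxa = set(matrix.taxa)
    weighted = 0.0
    for g in genes:
        width = g.alignment_length
        per_gene = 100.0 * len(set(g.members) & taxa) / len(taxa)
        weighted += per_gene * width
    expected = weighted / matrix.n_columns
    assert pm.completeness(matrix) == pytest.approx(expected, abs=1e-6)


def test_column_filter_identity_and_all_missing():
    m = make_matrix({"A": "M?LV", "B": "M?IV", "C": "M?I?"},
                    [("g1", 1, 4)])
    assert pm.simple_column_filter(m, 1.0).n_columns == 4
    out = pm.simple_column_filter(m, 0.99)
    assert out.n_columns == 3
    assert out.partitions == [("g1", 1, 3)]


def test_column_filter_matches_naive_recount(default_dataset):
    matrix = pm.concatenate(default_dataset.ortholog_families()[:20])
    for thr in (0.2, 0.5, 0.8):
        out = pm.simple_column_filter(matrix, thr)
        naive = 0
        for j in range(matrix.n_columns):
            col = matrix.data[:, j]
            frac = np.isin(col, ["?", "-", "X"]).mean()
            naive += frac <= thr
        assert out.n_columns == naive
        assert sum(e - s + 1 for _, s, e in out.partitions) == out.n_columns


def test_occupancy_report(small_dataset):
    genes = [f.single_copy() for f in small_dataset.ortholog_families()]
    matrix = pm.concatenate(genes)
    rep = pm.occupancy_report(matrix)
    assert set(rep["per_gene"]) == {g.gene_id for g in genes}
    for g in genes:
        expected = len(g.members) / matrix.n_taxa
        assert rep["per_gene"][g.gene_id] == pytest.approx(expected)
    assert all(0.0 <= v <= 1.0 for v in rep["per_taxon"].values())
    assert rep["completeness"] == pytest.approx(pm.completeness(matrix))


@pytest.mark.parametrize("writer,reader", [
    (pm.write_fasta, pm.read_fasta),
    (pm.write_phylip, pm.read_phylip),
])
def test_alignment_round_trip(tmp_path, small_dataset, writer, reader):
    matrix = pm.concatenate(
        [f.single_copy() for f in small_dataset.ortholog_families()[:4]])
    path = tmp_path / "aln.txt"
    writer(matrix, path)
    back = reader(path, partitions=list(matrix.partitions))
    assert back.taxa == matrix.taxa
    assert (back.data == matrix.data).all()
    assert back.partitions == matrix.partitions


def test_partition_file_round_trip(tmp_path, small_dataset):
    matrix = pm.concatenate(
        [f.single_copy() for f in small_dataset.ortholog_families()[:4]])
    path = tmp_path / "parts.txt"
    pm.write_partitions(matrix, path)
    assert pm.read_partitions(path) == matrix.partitions


def test_nexus_has_charsets(tmp_path, small_dataset):
    matrix = pm.concatenate(
        [f.single_copy() for f in small_dataset.ortholog_families()[:2]])
    path = tmp_path / "m.nex"
    pm.write_nexus(matrix, path)
    text = path.read_text()
    assert text.startswith("#NEXUS")
    for gid, start, end in matrix.partitions:
        assert f"charset {gid} = {start}-{end};" in text
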