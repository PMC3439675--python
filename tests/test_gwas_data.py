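"""Data model and text I/O: recoding conventions and round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bonb.gwas_data import (
    CASE,
    CONTROL,
    MISSING,
    GenotypeDataset,
    ParseError,
    SnpInfo,
    ValidationError,
    read_genotype_tsv,
    read_tped_tfam,
    write_genotype_tsv,
    write_tped_tfam,
)


def write(path, text):
    path.write_text(text)
    return path


class TestTpedReading:
    def test_minor_allele_recoding(self, tmp_path):
        """A (freq 0.3) minor vs G major: AA->0, AG->1, GG->2, 00->MISSING."""
        # 5 subjects: allele counts A=3, G=7 -> A is minor
        tped = write(
            tmp_path / "x.tped",
            "1 rs1 0 100 A A A G G G G G 0 0\n",
        )
        tfam = write(
            tmp_path / "x.tfam",
            "".join(f"f{i} i{i} 0 0 0 2\n" for i in range(5)),
        )
        ds = read_tped_tfam(tped, tfam)
        assert ds.genotypes[:, 0].tolist() == [0, 1, 2, 2, MISSING]

    def test_tfam_phenotype_convention(self, tmp_path):
        """Phenotypes 2/1 map to case/control."""
        tped = write(tmp_path / "x.tped", "1 rs1 0 5 A A A C C C\n")
        tfam = write(
            tmp_path / "x.tfam", "f0 a 0 0 0 2\nf1 b 0 0 0 1\nf2 c 0 0 0 2\n"
        )
        ds = read_tped_tfam(tped, tfam)
        assert ds.labels.tolist() == [CASE, CONTROL, CASE]
        assert ds.subject_ids == ["a", "b", "c"]

    def test_unknown_phenotype_dropped(self, tmp_path):
        tped = write(tmp_path / "x.tped", "1 rs1 0 5 A A A C C C\n")
        tfam = write(
            tmp_path / "x.tfam", "f0 a 0 0 0 2\nf1 b 0 0 0 0\nf2 c 0 0 0 -9\n"
        )
        ds = read_tped_tfam(tped, tfam)
        assert ds.n_subjects == 1
        assert ds.subject_ids == ["a"]

    def test_duplicate_snp_id_rejected(self, tmp_path):
        tped = write(tmp_path / "x.tped", "1 rs1 0 5 A A\n1 rs1 0 6 C C\n")
        tfam = write(tmp_path / "x.tfam", "f0 a 0 0 0 2\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_tped_tfam(tped, tfam)

    def test_malformed_line_names_file_and_line(self, tmp_path):
        tped = write(tmp_path / "x.tped", "1 rs1 0 5 A A\n1 rs2 0 6 A\n")
        tfam = write(tmp_path / "x.tfam", "f0 a 0 0 0 2\n")
        with pytest.raises(ParseError, match=r"x\.tped:2"):
            read_tped_tfam(tped, tfam)


class TestTsvReading:
    def _write_trio(self, tmp_path, matrix, snp_map, pheno):
        return (
            write(tmp_path / "m.tsv", matrix),
            write(tmp_path / "map.tsv", snp_map),
            write(tmp_path / "p.tsv", pheno),
        )

    def test_na_becomes_missing(self, tmp_path):
        paths = self._write_trio(
            tmp_path,
            "subject_id\tsnpA\tsnpB\na\t0\tNA\nb\t2\t1\n",
            "snp_id\tchromosome\tposition_bp\nsnpA\t1\t100\nsnpB\t2\t200\n",
            "subject_id\tphenotype\na\tcase\nb\tcontrol\n",
        )
        ds = read_genotype_tsv(*paths)
        assert ds.genotypes[0, 1] == MISSING
        assert ds.genotypes.tolist() == [[0, MISSING], [2, 1]]

    def test_map_row_parsing(self, tmp_path):
        paths = self._write_trio(
            tmp_path,
            "subject_id\trs9273363\na\t1\nb\t2\n",
            "snp_id\tchromosome\tposition_bp\nrs9273363\t6\t32626272\n",
            "subject_id\tphenotype\na\tcase\nb\tcontrol\n",
        )
        ds = read_genotype_tsv(*paths)
        assert ds.snps[0] == SnpInfo("rs9273363", "6", 32626272)

    def test_snp_absent_from_map_rejected(self, tmp_path):
        paths = self._write_trio(
            tmp_path,
            "subject_id\tsnpA\na\t1\nb\t2\n",
            "snp_id\tchromosome\tposition_bp\nsnpB\t1\t100\n",
            "subject_id\tphenotype\na\tcase\nb\tcontrol\n",
        )
        with pytest.raises(ValidationError, match="snpA"):
            read_genotype_tsv(*paths)

    def test_bad_cell_rejected(self, tmp_path):
        paths = self._write_trio(
            tmp_path,
            "subject_id\tsnpA\na\t3\nb\t2\n",
            "snp_id\tchromosome\tposition_bp\nsnpA\t1\t100\n",
            "subject_id\tphenotype\na\tcase\nb\tcontrol\n",
        )
        with pytest.raises(ParseError, match="'3'"):
            read_genotype_tsv(*paths)


# -- round trips -----------------------------------------------------------


def _random_dataset(draw, frequency_consistent: bool):
    n = draw(st.integers(2, 8))
    p = draw(st.integers(0, 6))
    rng = np.random.default_rng(draw(st.integers(0, 2**31 - 1)))
    g = rng.choice([0, 1, 2, MISSING], size=(n, p), p=[0.25, 0.25, 0.4, 0.1]).astype(
        np.int8
    )
    if frequency_consistent:
        # flip columns whose minor-role allele would be the majority one
        for j in range(p):
            col = g[:, j]
            obs = col[col != MISSING]
            if obs.size and (2 - obs).sum() > obs.size:  # minor freq > 0.5
                g[col != MISSING, j] = 2 - obs
    labels = rng.integers(0, 2, size=n).astype(np.int8)
    labels[0] = CASE
    chrom = ["1", "2", "X"]
    return GenotypeDataset(
        genotypes=g,
        snps=[SnpInfo(f"rs{j}", chrom[j % 3], 100 + 50 * j) for j in range(p)],
        labels=labels,
        subject_ids=[f"id{i}" for i in range(n)],
    )


@settings(max_examples=30, deadline=None, derandomize=True)
@given(data=st.data())
def test_tsv_round_trip_any_dataset(data, tmp_path_factory):
    """TSV stores codes literally, so any dataset survives the round trip."""
    ds = _random_dataset(data.draw, frequency_consistent=False)
    d = tmp_path_factory.mktemp("tsv")
    write_genotype_tsv(ds, d / "m.tsv", d / "map.tsv", d / "p.tsv")
    ds2 = read_genotype_tsv(d / "m.tsv", d / "map.tsv", d / "p.tsv")
    assert ds.equals(ds2)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(data=st.data())
def test_tped_round_trip_frequency_consistent(data, tmp_path_factory):
    """tped recodes from allele frequencies; orientation-consistent datasets
    survive the round trip including MISSING placement."""
    ds = _random_dataset(data.draw, frequency_consistent=True)
    d = tmp_path_factory.mktemp("tped")
    write_tped_tfam(ds, d / "x.tped", d / "x.tfam")
    ds2 = read_tped_tfam(d / "x.tped", d / "x.tfam")
    assert ds.equals(ds2)


def test_tped_reader_orientation_invariant(tmp_path):
    """After reading, code 2 is always the majority-dosage genotype class."""
    # written with code 0 dominant: reader must re-canonicalise to code 2
    ds = GenotypeDataset(
        genotypes=np.array([[0], [0], [0], [2]], dtype=np.int8),
        snps=[SnpInfo("rs1", "1", 10)],
        labels=np.array([CASE, CASE, CONTROL, CONTROL], dtype=np.int8),
        subject_ids=list("abcd"),
    )
    write_tped_tfam(ds, tmp_path / "x.tped", tmp_path / "x.tfam")
    ds2 = read_tped_tfam(tmp_path / "x.tped", tmp_path / "x.tfam")
    assert ds2.genotypes[:, 0].tolist() == [2, 2, 2, 0]


@pytest.mark.parametrize("dialect", ["tped", "tsv"])
def test_degenerate_datasets_round_trip(dialect, tmp_path):
    """Empty SNP panels and all-MISSING columns survive both dialects."""
    for g, p in [(np.empty((3, 0), dtype=np.int8), 0),
                 (np.full((3, 1), MISSING, dtype=np.int8), 1)]:
        ds = GenotypeDataset(
            genotypes=g,
            snps=[SnpInfo("rs0", "1", 5)][:p],
            labels=np.array([CASE, CONTROL, CONTROL], dtype=np.int8),
            subject_ids=["a", "b", "c"],
        )
        if dialect == "tped":
            write_tped_tfam(ds, tmp_path / "x.tped", tmp_path / "x.tfam")
            ds2 = read_tped_tfam(tmp_path / "x.tped", tmp_path / "x.tfam")
        else:
            write_genotype_tsv(ds, tmp_path / "m.tsv", tmp_path / "map.tsv", tmp_path / "p.tsv")
            ds2 = read_genotype_tsv(tmp_path / "m.tsv", tmp_path / "map.tsv", tmp_path / "p.tsv")
        assert ds.equals(ds2)


def test_dataset_validation():
    with pytest.raises(ValidationError, match="position_bp"):
        SnpInfo("rs1", "1", 0)
    with pytest.raises(ValidationError, match="code"):
        GenotypeDataset(
            genotypes=np.array([[5]], dtype=np.int8),
            snps=[SnpInfo("rs1", "1", 1)],
            labels=np.array([CASE], dtype=np.int8),
            subject_ids=["a"],
        )
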