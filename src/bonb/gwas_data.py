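"""Genotype data model and plain-text I/O for case/control SNP datasets.

The in-memory container is :class:`GenotypeDataset`: an ``n x p`` matrix of
genotype codes over ``{0, 1, 2, MISSING}`` together with per-SNP genomic
metadata and a binary case/control label per subject.

Genotype coding convention (used throughout the package):

* ``0`` — homozygous for the **minor** allele
* ``1`` — heterozygous
* ``2`` — homozygous for the **major** allele
* :data:`MISSING` (``-1``) — genotype not observed

Note this is the *opposite* orientation of PLINK's additive minor-allele
dosage; the ``.tped`` reader performs the flip so that code 2 is always the
genotype class with the higher major-allele dosage.

Two text dialects are supported: PLINK-style transposed files
(``.tped``/``.tfam``) and a simple TSV trio (matrix + SNP map + phenotype).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel genotype code for a missing call.
MISSING: int = -1

#: Integer label for an affected subject (the positive class).
CASE: int = 1

#: Integer label for an unaffected subject.
CONTROL: int = 0

_VALID_CODES = frozenset({0, 1, 2, MISSING})


class ParseError(ValueError):
    """A file could not be parsed; message names the file and line."""


class ValidationError(ValueError):
    """Parsed content violates a dataset invariant."""


def chromosome_sort_key(chromosome: str) -> tuple:
    """Sort key placing numeric chromosome tokens first, in numeric order."""
    if chromosome.isdigit():
        return (0, int(chromosome), "")
    return (1, 0, chromosome)


@dataclass(frozen=True)
class SnpInfo:
    """Genomic metadata for one SNP.

    Parameters
    ----------
    snp_id : str
        Unique identifier (e.g. an rs number).
    chromosome : str
        Chromosome token, kept as a string so "X"/"Y"/"MT" need no special
        casing.
    position_bp : int
        1-based base-pair position; drives the < 1 Mb linkage window.
    """

    snp_id: str
    chromosome: str
    position_bp: int

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValidationError("snp_id must be a non-empty string")
        if self.position_bp < 1:
            raise ValidationError(
                f"position_bp must be >= 1, got {self.position_bp} for {self.snp_id}"
            )


@dataclass(eq=False)
class GenotypeDataset:
    """An ``n x p`` case/control genotype matrix with SNP map and labels.

    Attributes
    ----------
    genotypes : ndarray of int8, shape (n, p)
        Genotype codes over ``{0, 1, 2, MISSING}``.
    snps : list of SnpInfo
        Per-column metadata, length ``p``; snp_ids unique.
    labels : ndarray of int8, shape (n,)
        ``CASE`` (1) or ``CONTROL`` (0) per subject.
    subject_ids : list of str
        Unique subject identifiers, length ``n``.
    """

    genotypes: np.ndarray
    snps: list[SnpInfo]
    labels: np.ndarray
    subject_ids: list[str]
    _snp_index: dict = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValidationError("genotypes must be a 2-D matrix")
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.snps = list(self.snps)
        self.subject_ids = [str(s) for s in self.subject_ids]
        n, p = self.genotypes.shape
        if len(self.snps) != p:
            raise ValidationError(
                f"snps list length {len(self.snps)} != matrix column count {p}"
            )
        if self.labels.shape != (n,):
            raise ValidationError(
                f"labels length {self.labels.shape} != subject count {n}"
            )
        if len(self.subject_ids) != n:
            raise ValidationError("subject_ids length != subject count")
        if len(set(self.subject_ids)) != n:
            raise ValidationError("subject_ids must be unique")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != p:
            raise ValidationError("duplicate snp_id in dataset")
        bad = ~np.isin(self.genotypes, list(_VALID_CODES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"genotype code {self.genotypes[i, j]} at ({i}, {j}) outside "
                "{0, 1, 2, MISSING}"
            )
        if not np.isin(self.labels, [CASE, CONTROL]).all():
            raise ValidationError("labels must be CASE (1) or CONTROL (0)")
        self._snp_index = {sid: j for j, sid in enumerate(ids)}

    # -- basic accessors ---------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([s.chromosome for s in self.snps], dtype=object)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position_bp for s in self.snps], dtype=np.int64)

    @property
    def n_cases(self) -> int:
        return int((self.labels == CASE).sum())

    @property
    def n_controls(self) -> int:
        return int((self.labels == CONTROL).sum())

    def snp_index(self, snp_id: str) -> int:
        """Column index of ``snp_id``; KeyError if absent."""
        return self._snp_index[snp_id]

    def require_two_classes(self) -> None:
        """Raise unless the dataset holds at least one case and one control."""
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValidationError(
                "dataset must contain at least one case and one control "
                f"(got {self.n_cases} cases, {self.n_controls} controls)"
            )

    # -- derived datasets --------------------------------------------------

    def subset_subjects(self, indices: Sequence[int]) -> "GenotypeDataset":
        """New dataset restricted to the given subject rows (in order)."""
        idx = np.asarray(indices, dtype=np.intp)
        return GenotypeDataset(
            genotypes=self.genotypes[idx].copy(),
            snps=list(self.snps),
            labels=self.labels[idx].copy(),
            subject_ids=[self.subject_ids[i] for i in idx],
        )

    def subset_snps(self, indices: Sequence[int]) -> "GenotypeDataset":
        idx = np.asarray(indices, dtype=np.intp)
        return GenotypeDataset(
            genotypes=self.genotypes[:, idx].copy(),
            snps=[self.snps[j] for j in idx],
            labels=self.labels.copy(),
            subject_ids=list(self.subject_ids),
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        """Field-by-field equality, including MISSING placement."""
        return (
            isinstance(other, GenotypeDataset)
            and self.genotypes.shape == other.genotypes.shape
            and np.array_equal(self.genotypes, other.genotypes)
            and self.snps == other.snps
            and np.array_equal(self.labels, other.labels)
            and self.subject_ids == other.subject_ids
        )


# ---------------------------------------------------------------------------
# PLINK transposed text dialect (.tped / .tfam)
# ---------------------------------------------------------------------------


def _parse_tfam(tfam_path: Path) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Return (subject_ids, labels, keep_mask) from a .tfam file.

    Phenotype column: 1 = control, 2 = case; 0 or -9 = unknown (dropped).
    """
    subject_ids: list[str] = []
    labels: list[int] = []
    keep: list[bool] = []
    with open(tfam_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(
                    f"{tfam_path}:{lineno}: expected 6 columns, got {len(fields)}"
                )
            pheno = fields[5]
            if pheno == "2":
                subject_ids.append(fields[1]); labels.append(CASE); keep.append(True)
            elif pheno == "1":
                subject_ids.append(fields[1]); labels.append(CONTROL); keep.append(True)
            elif pheno in ("0", "-9"):
                subject_ids.append(fields[1]); labels.append(CONTROL); keep.append(False)
            else:
                raise ParseError(
                    f"{tfam_path}:{lineno}: unrecognised phenotype {pheno!r}"
                )
    return subject_ids, np.array(labels, dtype=np.int8), np.array(keep, dtype=bool)


def _recode_allele_pairs(
    pairs: list[tuple[str, str]], path: Path, lineno: int, snp_id: str
) -> np.ndarray:
    """Convert allele pairs to genotype codes (0 homo-minor .. 2 homo-major).

    The minor allele is the less frequent of the two observed alleles; ties
    break toward the lexicographically smaller allele. Pairs containing "0"
    are MISSING.
    """
    counts: dict[str, int] = {}
    for a1, a2 in pairs:
        for al in (a1, a2):
            if al != "0":
                counts[al] = counts.get(al, 0) + 1
    alleles = sorted(counts)
    if len(alleles) > 2:
        raise ParseError(
            f"{path}:{lineno}: SNP {snp_id} has {len(alleles)} alleles "
            f"({', '.join(alleles)}); expected at most 2"
        )
    if not alleles:  # all-missing column
        return np.full(len(pairs), MISSING, dtype=np.int8)
    if len(alleles) == 1:
        minor = None  # no minor allele observed; every call is homo-major
    else:
        # less frequent allele is minor; lexicographic tie-break
        a, b = alleles
        minor = a if counts[a] <= counts[b] else b
    out = np.empty(len(pairs), dtype=np.int8)
    for i, (a1, a2) in enumerate(pairs):
        if a1 == "0" or a2 == "0":
            out[i] = MISSING
        elif minor is None:
            out[i] = 2
        else:
            out[i] = 2 - ((a1 == minor) + (a2 == minor))
    return out


def read_tped_tfam(tped_path, tfam_path) -> GenotypeDataset:
    """Read a PLINK transposed-text dataset.

    Subjects with unknown phenotype (0 / -9) are dropped, with the dropped
    count logged. Allele pairs are recoded to minor-allele orientation:
    homozygous-minor -> 0, heterozygous -> 1, homozygous-major -> 2,
    "0 0" -> MISSING.
    """
    tped_path, tfam_path = Path(tped_path), Path(tfam_path)
    subject_ids, labels, keep = _parse_tfam(tfam_path)
    n_total = len(subject_ids)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "%s: dropped %d subject(s) with unknown phenotype", tfam_path, n_dropped
        )
    kept_ids = [sid for sid, k in zip(subject_ids, keep) if k]
    if len(set(kept_ids)) != len(kept_ids):
        raise ValidationError(f"{tfam_path}: duplicate subject ids")

    snps: list[SnpInfo] = []
    columns: list[np.ndarray] = []
    seen: set[str] = set()
    with open(tped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4 + 2 * n_total:
                raise ParseError(
                    f"{tped_path}:{lineno}: expected {4 + 2 * n_total} fields "
                    f"for {n_total} subjects, got {len(fields)}"
                )
            chrom, snp_id, _cm, pos = fields[:4]
            if snp_id in seen:
                raise ValidationError(f"{tped_path}:{lineno}: duplicate snp_id {snp_id}")
            seen.add(snp_id)
            try:
                position = int(pos)
            except ValueError as exc:
                raise ParseError(f"{tped_path}:{lineno}: bad position {pos!r}") from exc
            pairs = [
                (fields[4 + 2 * i], fields[5 + 2 * i])
                for i in range(n_total)
                if keep[i]
            ]
            columns.append(_recode_allele_pairs(pairs, tped_path, lineno, snp_id))
            snps.append(SnpInfo(snp_id=snp_id, chromosome=chrom, position_bp=position))

    n_kept = len(kept_ids)
    if columns:
        genotypes = np.column_stack(columns)
    else:
        genotypes = np.empty((n_kept, 0), dtype=np.int8)
    return GenotypeDataset(
        genotypes=genotypes,
        snps=snps,
        labels=labels[keep],
        subject_ids=kept_ids,
    )


def write_tped_tfam(ds: GenotypeDataset, tped_path, tfam_path) -> None:
    """Write a dataset in PLINK transposed text form.

    The minor-role allele is written as "A" and the major-role allele as
    "B"; MISSING becomes "0 0". Re-reading recodes from observed allele
    frequencies, so codes survive the round trip whenever the dataset's
    orientation is frequency-consistent (code 0 no more frequent than code 2).
    """
    tped_path, tfam_path = Path(tped_path), Path(tfam_path)
    with open(tfam_path, "w") as fh:
        for sid, lab in zip(ds.subject_ids, ds.labels):
            pheno = 2 if lab == CASE else 1
            fh.write(f"{sid} {sid} 0 0 0 {pheno}\n")
    code_to_pair = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}
    with open(tped_path, "w") as fh:
        for j, snp in enumerate(ds.snps):
            col = ds.genotypes[:, j]
            cells = " ".join(code_to_pair[int(g)] for g in col)
            fh.write(f"{snp.chromosome} {snp.snp_id} 0 {snp.position_bp} {cells}\n")


# ---------------------------------------------------------------------------
# TSV dialect: matrix + map + phenotype
# ---------------------------------------------------------------------------

_TSV_CELLS = {"0": 0, "1": 1, "2": 2, "NA": MISSING}


def read_genotype_tsv(matrix_path, map_path, pheno_path) -> GenotypeDataset:
    """Read the TSV dialect.

    ``matrix_path``: header ``subject_id<TAB>snp1<TAB>...``, one subject per
    row, cells in {0, 1, 2, NA} (codes stored literally, no recoding).
    ``map_path``: header ``snp_id  chromosome  position_bp``.
    ``pheno_path``: header ``subject_id  phenotype`` with phenotype in
    {case, control}.
    """
    matrix_path, map_path, pheno_path = Path(matrix_path), Path(map_path), Path(pheno_path)

    snp_meta: dict[str, SnpInfo] = {}
    with open(map_path) as fh:
        header = fh.readline()
        if header.split("\t")[0].strip() != "snp_id":
            raise ParseError(f"{map_path}:1: expected header starting with 'snp_id'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise ParseError(f"{map_path}:{lineno}: expected 3 columns")
            sid, chrom, pos = fields
            try:
                snp_meta[sid] = SnpInfo(sid, chrom, int(pos))
            except ValueError as exc:
                raise ParseError(f"{map_path}:{lineno}: bad position {pos!r}") from exc

    pheno: dict[str, int] = {}
    with open(pheno_path) as fh:
        header = fh.readline()
        if header.split("\t")[0].strip() != "subject_id":
            raise ParseError(f"{pheno_path}:1: expected header starting with 'subject_id'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ParseError(f"{pheno_path}:{lineno}: expected 2 columns")
            sid, lab = fields
            if lab == "case":
                pheno[sid] = CASE
            elif lab == "control":
                pheno[sid] = CONTROL
            else:
                raise ParseError(f"{pheno_path}:{lineno}: phenotype must be case/control")

    subject_ids: list[str] = []
    rows: list[list[int]] = []
    with open(matrix_path) as fh:
        header_fields = fh.readline().rstrip("\n").split("\t")
        if not header_fields or header_fields[0] != "subject_id":
            raise ParseError(f"{matrix_path}:1: header must start with 'subject_id'")
        snp_ids = header_fields[1:]
        for sid in snp_ids:
            if sid not in snp_meta:
                raise ValidationError(
                    f"{matrix_path}: snp_id {sid!r} absent from map file {map_path}"
                )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 1 + len(snp_ids):
                raise ParseError(
                    f"{matrix_path}:{lineno}: expected {1 + len(snp_ids)} columns, "
                    f"got {len(fields)}"
                )
            subject_ids.append(fields[0])
            row = []
            for sid, cell in zip(snp_ids, fields[1:]):
                if cell not in _TSV_CELLS:
                    raise ParseError(
                        f"{matrix_path}:{lineno}: cell {cell!r} for {sid} outside "
                        "{0, 1, 2, NA}"
                    )
                row.append(_TSV_CELLS[cell])
            rows.append(row)

    labels = []
    for sid in subject_ids:
        if sid not in pheno:
            raise ValidationError(f"{pheno_path}: no phenotype for subject {sid!r}")
        labels.append(pheno[sid])

    genotypes = (
        np.array(rows, dtype=np.int8)
        if rows and snp_ids
        else np.empty((len(subject_ids), len(snp_ids)), dtype=np.int8)
    )
    if rows and not snp_ids:
        genotypes = np.empty((len(subject_ids), 0), dtype=np.int8)
    return GenotypeDataset(
        genotypes=genotypes,
        snps=[snp_meta[sid] for sid in snp_ids],
        labels=np.array(labels, dtype=np.int8),
        subject_ids=subject_ids,
    )


def write_genotype_tsv(ds: GenotypeDataset, matrix_path, map_path, pheno_path) -> None:
    """Write the TSV dialect; MISSING becomes "NA"."""
    rev = {0: "0", 1: "1", 2: "2", MISSING: "NA"}
    with open(map_path, "w") as fh:
        fh.write("snp_id\tchromosome\tposition_bp\n")
        for snp in ds.snps:
            fh.write(f"{snp.snp_id}\t{snp.chromosome}\t{snp.position_bp}\n")
    with open(pheno_path, "w") as fh:
        fh.write("subject_id\tphenotype\n")
        for sid, lab in zip(ds.subject_ids, ds.labels):
            fh.write(f"{sid}\t{'case' if lab == CASE else 'control'}\n")
    with open(matrix_path, "w") as fh:
        fh.write("\t".join(["subject_id"] + ds.snp_ids) + "\n")
        for i, sid in enumerate(ds.subject_ids):
            cells = "\t".join(rev[int(g)] for g in ds.genotypes[i])
            fh.write(sid + ("\t" + cells if ds.n_snps else "") + "\n")
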