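"""Categorical Naive Bayes over SNP genotypes.

The classifier factorises the class posterior as

    Pr(Y = y_k | X_1..X_m)  ∝  pi_k * prod_i theta_ijk,

where each attribute X_i is a SNP genotype in {0, 1, 2} and the two classes
are case/control. Conditional probability tables theta_ijk and the prior
pi_k are estimated by counting with a Dirichlet pseudo-count l (l = 1 is
Laplace smoothing, the package default):

    theta_ijk = (#{X_i = j, Y = k} + l) / (#{Y = k} + 3 l)
    pi_k      = (#{Y = k} + l) / (n + 2 l)

Missing genotypes are first-class: they are excluded from contingency
counts, and at prediction time a missing attribute is skipped (its factor
marginalises out under the factorisation). Posteriors are accumulated in
log space so that models with hundreds of attributes do not underflow.

Class order convention: wherever a pair or an axis runs over classes, case
comes first, control second.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .gwas_data import CASE, CONTROL, MISSING, GenotypeDataset

N_GENOTYPES = 3  # J: genotype codes 0, 1, 2


@dataclass(frozen=True)
class ContingencyTable:
    """2 x 3 genotype-by-class counts for one SNP.

    Cases at genotype 0/1/2 are ``a``/``b``/``c``; controls are
    ``d``/``e``/``f``. Missing genotypes contribute to no cell, so ``n``
    is the per-SNP observed count, not the dataset size.
    """

    a: int
    b: int
    c: int
    d: int
    e: int
    f: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d, self.e, self.f) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_ca(self) -> int:
        return self.a + self.b + self.c

    @property
    def n_co(self) -> int:
        return self.d + self.e + self.f

    @property
    def n0(self) -> int:
        return self.a + self.d

    @property
    def n1(self) -> int:
        return self.b + self.e

    @property
    def n2(self) -> int:
        return self.c + self.f

    @property
    def n(self) -> int:
        return self.n_ca + self.n_co

    @property
    def case_counts(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=np.int64)

    @property
    def control_counts(self) -> np.ndarray:
        return np.array([self.d, self.e, self.f], dtype=np.int64)


def build_contingency_table(
    ds: GenotypeDataset, snp_index: int, subject_indices: Sequence[int]
) -> ContingencyTable:
    """Count genotype-by-class occurrences over a multiset of subject rows.

    ``subject_indices`` may contain repeats (a bootstrap multiset); each
    occurrence contributes one count. Subjects whose genotype at
    ``snp_index`` is MISSING contribute nothing.
    """
    if not 0 <= snp_index < ds.n_snps:
        raise IndexError(f"snp_index {snp_index} out of range [0, {ds.n_snps})")
    idx = np.asarray(subject_indices, dtype=np.intp)
    g = ds.genotypes[idx, snp_index]
    y = ds.labels[idx]
    counts = np.zeros((2, N_GENOTYPES), dtype=np.int64)  # rows: case, control
    for j in range(N_GENOTYPES):
        gj = g == j
        counts[0, j] = int((gj & (y == CASE)).sum())
        counts[1, j] = int((gj & (y == CONTROL)).sum())
    return ContingencyTable(*counts[0], *counts[1])


def estimate_theta(table: ContingencyTable, l: float = 1.0) -> np.ndarray:
    """Smoothed conditional probability table, shape (2, 3).

    Row 0 is the case class, row 1 the control class; columns are genotype
    codes 0, 1, 2. Each row sums to 1; with l > 0 every entry is strictly
    positive even for empty classes.
    """
    if l <= 0:
        raise ValueError("Dirichlet weight l must be positive")
    counts = np.stack([table.case_counts, table.control_counts]).astype(float)
    class_totals = np.array([table.n_ca, table.n_co], dtype=float)
    return (counts + l) / (class_totals[:, None] + l * N_GENOTYPES)


def estimate_prior(n_ca: int, n_co: int, l: float = 1.0) -> tuple[float, float]:
    """Smoothed class prior ``(pi_case, pi_control)``."""
    if l <= 0:
        raise ValueError("Dirichlet weight l must be positive")
    n = n_ca + n_co
    return (n_ca + l) / (n + 2 * l), (n_co + l) / (n + 2 * l)


@dataclass
class NBClassifier:
    """A fitted Naive Bayes model over a selected SNP subset.

    Attributes
    ----------
    snp_ids : list of str
        Identifiers of the selected SNPs, in attribute order.
    attributes : ndarray of int
        Column indices of the SNPs in the training dataset (used when the
        model is applied to the same column layout; prediction on other
        datasets realigns by snp_id).
    theta : ndarray, shape (2, m, 3)
        Conditional probability tables; axis 0 is class (case, control),
        axis 1 the attribute, axis 2 the genotype code.
    prior : ndarray, shape (2,)
        ``(pi_case, pi_control)``.
    l : float
        Dirichlet weight used at estimation time.
    """

    snp_ids: list[str]
    attributes: np.ndarray
    theta: np.ndarray
    prior: np.ndarray
    l: float = 1.0
    _log_lookup: np.ndarray = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.attributes = np.asarray(self.attributes, dtype=np.intp)
        self.theta = np.asarray(self.theta, dtype=float)
        self.prior = np.asarray(self.prior, dtype=float)
        m = len(self.snp_ids)
        if self.theta.shape != (2, m, N_GENOTYPES):
            raise ValueError(f"theta must have shape (2, {m}, 3)")
        if not np.allclose(self.theta.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("each theta row must sum to 1")
        if not np.isclose(self.prior.sum(), 1.0, atol=1e-12):
            raise ValueError("prior must sum to 1")

    @property
    def n_attributes(self) -> int:
        return len(self.snp_ids)

    def _lookup(self) -> np.ndarray:
        # (2, m, 4): log theta per genotype, with slot 3 = 0.0 for MISSING
        if self._log_lookup is None or self._log_lookup.shape[1] != len(self.snp_ids):
            m = len(self.snp_ids)
            lut = np.zeros((2, m, N_GENOTYPES + 1))
            lut[:, :, :N_GENOTYPES] = np.log(self.theta)
            self._log_lookup = lut
        return self._log_lookup

    def posterior_matrix(
        self, genotypes: np.ndarray, columns: np.ndarray | None = None
    ) -> np.ndarray:
        """Posterior ``(p_case, p_control)`` for each row of ``genotypes``.

        ``columns`` maps each attribute to a column of ``genotypes``;
        defaults to the training column indices.
        """
        cols = self.attributes if columns is None else np.asarray(columns, dtype=np.intp)
        m = len(self.snp_ids)
        if m == 0:
            out = np.empty((genotypes.shape[0], 2))
            out[:] = self.prior
            return out
        g = genotypes[:, cols]
        g = np.where(g == MISSING, N_GENOTYPES, g)  # missing -> zero log-factor
        lut = self._lookup()
        attr_idx = np.arange(m)
        log_scores = np.log(self.prior)[None, :] + np.stack(
            [lut[k, attr_idx, g].sum(axis=1) for k in range(2)], axis=1
        )
        log_scores -= log_scores.max(axis=1, keepdims=True)
        probs = np.exp(log_scores)
        probs /= probs.sum(axis=1, keepdims=True)
        return probs

    def posterior(self, genotype_row: Sequence[int]) -> tuple[float, float]:
        """Posterior ``(Pr(case), Pr(control))`` for one genotype row."""
        row = np.asarray(genotype_row, dtype=np.int8)[None, :]
        p = self.posterior_matrix(row)
        return float(p[0, 0]), float(p[0, 1])

    def classify(self, genotype_row: Sequence[int]) -> int:
        """CASE iff Pr(case) strictly exceeds Pr(control); ties -> CONTROL."""
        p_case, p_control = self.posterior(genotype_row)
        return CASE if p_case > p_control else CONTROL

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "snp_ids": list(self.snp_ids),
            "attributes": self.attributes.tolist(),
            "theta_case": self.theta[0].tolist(),
            "theta_control": self.theta[1].tolist(),
            "prior": {"case": float(self.prior[0]), "control": float(self.prior[1])},
            "dirichlet_weight": self.l,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NBClassifier":
        theta = np.stack(
            [np.asarray(d["theta_case"], dtype=float).reshape(-1, N_GENOTYPES),
             np.asarray(d["theta_control"], dtype=float).reshape(-1, N_GENOTYPES)]
        )
        return cls(
            snp_ids=list(d["snp_ids"]),
            attributes=np.asarray(d["attributes"], dtype=np.intp),
            theta=theta,
            prior=np.array([d["prior"]["case"], d["prior"]["control"]]),
            l=float(d["dirichlet_weight"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "NBClassifier":
        return cls.from_dict(json.loads(s))


def fit_nbc(
    ds: GenotypeDataset,
    subject_indices: Sequence[int],
    attribute_indices: Sequence[int],
    l: float = 1.0,
) -> NBClassifier:
    """Fit an NBClassifier on a subject multiset with the given attributes."""
    idx = np.asarray(subject_indices, dtype=np.intp)
    attrs = np.asarray(attribute_indices, dtype=np.intp)
    y = ds.labels[idx]
    n_ca = int((y == CASE).sum())
    n_co = int((y == CONTROL).sum())
    theta = np.empty((2, len(attrs), N_GENOTYPES))
    for i, j in enumerate(attrs):
        theta[:, i, :] = estimate_theta(build_contingency_table(ds, int(j), idx), l)
    return NBClassifier(
        snp_ids=[ds.snps[int(j)].snp_id for j in attrs],
        attributes=attrs,
        theta=theta,
        prior=np.array(estimate_prior(n_ca, n_co, l)),
        l=l,
    )


# Thin functional wrappers over the model methods.


def posterior(model: NBClassifier, genotype_row: Sequence[int]) -> tuple[float, float]:
    return model.posterior(genotype_row)


def classify(model: NBClassifier, genotype_row: Sequence[int]) -> int:
    return model.classify(genotype_row)
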