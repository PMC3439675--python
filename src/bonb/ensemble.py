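"""Bagged Naive Bayes training engine.

Training draws B bootstrap replicates of the subjects. On each replicate
the SNPs are ranked by the closed-form attribute score computed on the
in-bag multiset, then attributes are added to the replicate's classifier in
batches of exponentially doubling size (1, 2, 4, 8, ...). Every time a SNP
is included, all still-eligible SNPs on the same chromosome within 1 Mb and
with in-bag squared correlation r^2 above the threshold theta are removed
from future consideration, enforcing approximate conditional independence
between attributes in the face of genetic linkage. A grown candidate is
accepted only while its MCC on the out-of-bag (OOB) subjects strictly
improves on the incumbent's; the first non-improvement stops growth and
the incumbent (without the last batch) is kept.

Ensemble prediction averages the per-classifier class posteriors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed

from .gwas_data import CASE, CONTROL, MISSING, GenotypeDataset, ValidationError, chromosome_sort_key
from .nb_core import NBClassifier, fit_nbc
from .scoring import _scores_from_counts, mcc_from_predictions

logger = logging.getLogger(__name__)


@dataclass
class BonbParams:
    """Tunable parameters of the training procedure.

    B : number of bootstrap replicates / classifiers (default 200).
    theta : r^2 threshold above which two nearby SNPs count as linked
        (default 0.1).
    l : Dirichlet weight for probability estimation (default 1, Laplace).
    ld_window_bp : genomic distance below which the linkage rule applies
        (default 1 Mb); pairs on different chromosomes are never pruned.
    inclusion_fraction : fraction of classifiers that must include a SNP
        for it to become a biomarker candidate (default 0.05).
    alpha : significance level of the one-tailed Wilcoxon signed-rank test
        on marginal utilities (default 0.05).
    r2_on_full_train : compute pruning r^2 on the full training set rather
        than the in-bag multiset (default False).
    """

    B: int = 200
    theta: float = 0.1
    l: float = 1.0
    ld_window_bp: int = 1_000_000
    inclusion_fraction: float = 0.05
    alpha: float = 0.05
    r2_on_full_train: bool = False

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be a positive integer")
        if not 0 < self.theta <= 1:
            raise ValueError("theta must lie in (0, 1]")
        if self.l <= 0:
            raise ValueError("l must be positive")
        if self.ld_window_bp < 1:
            raise ValueError("ld_window_bp must be positive")


@dataclass
class BootstrapReplicate:
    """In-bag multiset (n draws with replacement) and its out-of-bag set."""

    in_bag: np.ndarray
    oob: np.ndarray

    def __post_init__(self) -> None:
        self.in_bag = np.asarray(self.in_bag, dtype=np.intp)
        self.oob = np.asarray(self.oob, dtype=np.intp)


def draw_replicate(n: int, rng: np.random.Generator) -> BootstrapReplicate:
    """Draw one bootstrap replicate of ``n`` subjects.

    The OOB set (subjects never drawn) has expected size tending to
    (1 - 1/e) * n for large n.
    """
    in_bag = rng.integers(0, n, size=n)
    mask = np.ones(n, dtype=bool)
    mask[in_bag] = False
    return BootstrapReplicate(in_bag=in_bag, oob=np.flatnonzero(mask))


def _class_genotype_counts(
    ds: GenotypeDataset, subject_indices: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP genotype counts by class over a subject multiset.

    Returns (case_counts, control_counts), each shaped (3, p). MISSING
    genotypes fall outside all three genotype slots.
    """
    g = ds.genotypes[subject_indices]
    y = ds.labels[subject_indices]
    case_rows = g[y == CASE]
    ctrl_rows = g[y == CONTROL]
    case_counts = np.stack([(case_rows == j).sum(axis=0) for j in range(3)])
    ctrl_counts = np.stack([(ctrl_rows == j).sum(axis=0) for j in range(3)])
    return case_counts.astype(np.int64), ctrl_counts.astype(np.int64)


def _genomic_rank(ds: GenotypeDataset) -> np.ndarray:
    """Rank of each SNP column in (chromosome, position, snp_id) order."""
    keys = sorted(
        range(ds.n_snps),
        key=lambda j: (
            chromosome_sort_key(ds.snps[j].chromosome),
            ds.snps[j].position_bp,
            ds.snps[j].snp_id,
        ),
    )
    rank = np.empty(ds.n_snps, dtype=np.int64)
    rank[np.array(keys, dtype=np.intp)] = np.arange(ds.n_snps)
    return rank


def rank_snps(
    ds: GenotypeDataset, rep: BootstrapReplicate, l: float = 1.0
) -> list[tuple[int, float]]:
    """Score every SNP on the in-bag multiset and sort by descending score.

    Ties break by ascending genomic order (chromosome, position, snp_id)
    so the ranking is deterministic.
    """
    del l  # the closed form is the l = 1 score; kept for signature symmetry
    case_counts, ctrl_counts = _class_genotype_counts(ds, rep.in_bag)
    scores = _scores_from_counts(case_counts, ctrl_counts)
    order = np.lexsort((_genomic_rank(ds), -scores))
    return [(int(j), float(scores[j])) for j in order]


def squared_correlation(
    ds: GenotypeDataset,
    snp_i: int,
    snp_j: int,
    subject_indices: Sequence[int],
) -> float:
    """Squared Pearson correlation of two SNPs' genotype codes.

    Computed over the subject multiset (with multiplicity) restricted to
    rows where both genotypes are observed; returns 0.0 when fewer than two
    usable rows remain or either SNP is constant on them.
    """
    idx = np.asarray(subject_indices, dtype=np.intp)
    x = ds.genotypes[idx, snp_i].astype(float)
    y = ds.genotypes[idx, snp_j].astype(float)
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if x.size < 2:
        return 0.0
    x = x - x.mean()
    y = y - y.mean()
    sx = float(x @ x)
    sy = float(y @ y)
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = float(x @ y) / np.sqrt(sx * sy)
    return r * r


def _r2_against(
    G_rows: np.ndarray, col: int, others: np.ndarray
) -> np.ndarray:
    """r^2 of one column against several, pairwise-complete, on given rows."""
    out = np.zeros(len(others))
    x_all = G_rows[:, col].astype(float)
    for k, j in enumerate(others):
        y_all = G_rows[:, j].astype(float)
        ok = (x_all != MISSING) & (y_all != MISSING)
        x, y = x_all[ok], y_all[ok]
        if x.size < 2:
            continue
        x = x - x.mean()
        y = y - y.mean()
        sx, sy = float(x @ x), float(y @ y)
        if sx == 0.0 or sy == 0.0:
            continue
        r = float(x @ y) / np.sqrt(sx * sy)
        out[k] = r * r
    return out


@dataclass
class SelectionResult:
    """Outcome of attribute selection on one replicate."""

    classifier: NBClassifier
    batch_sizes: list[int]
    oob_mcc_trace: list[float]


def _oob_mcc(clf: NBClassifier, ds: GenotypeDataset, oob: np.ndarray) -> float:
    probs = clf.posterior_matrix(ds.genotypes[oob])
    pred = np.where(probs[:, 0] > probs[:, 1], CASE, CONTROL)
    return mcc_from_predictions(ds.labels[oob], pred)


def select_attributes_detailed(
    ds: GenotypeDataset,
    rep: BootstrapReplicate,
    params: BonbParams,
    ranked: list[tuple[int, float]] | None = None,
) -> SelectionResult:
    """Grow one classifier by doubling batches under the OOB stopping rule.

    Batches of size 1, 2, 4, ... are pulled from the top of the ranked
    list; each included SNP prunes its linked neighbours (same chromosome,
    distance < ld_window_bp, r^2 > theta on the in-bag multiset) from
    eligibility. A candidate is accepted only if its OOB MCC strictly
    exceeds the incumbent's (the empty model counts as OOB MCC 0); the
    first rejection returns the incumbent.
    """
    if rep.oob.size == 0:
        raise ValidationError(
            "empty out-of-bag set; use a larger number of subjects"
        )
    if ranked is None:
        ranked = rank_snps(ds, rep, params.l)
    order = [j for j, _ in ranked]
    eligible = np.ones(ds.n_snps, dtype=bool)
    chroms = ds.chromosomes
    positions = ds.positions
    r2_rows = (
        np.arange(ds.n_subjects) if params.r2_on_full_train else rep.in_bag
    )
    G_rows = ds.genotypes[r2_rows]

    incumbent_attrs: list[int] = []
    incumbent_clf = fit_nbc(ds, rep.in_bag, [], params.l)
    incumbent_mcc = 0.0  # the empty model is a majority classifier
    batch_sizes: list[int] = []
    mcc_trace: list[float] = []
    cursor = 0
    M = 1

    while True:
        batch: list[int] = []
        while len(batch) < M and cursor < len(order):
            j = order[cursor]
            cursor += 1
            if not eligible[j]:
                continue
            eligible[j] = False
            batch.append(j)
            # prune linked neighbours of the newly included SNP
            near = (
                eligible
                & (chroms == chroms[j])
                & (np.abs(positions - positions[j]) < params.ld_window_bp)
            )
            near_idx = np.flatnonzero(near)
            if near_idx.size:
                r2 = _r2_against(G_rows, j, near_idx)
                eligible[near_idx[r2 > params.theta]] = False
        if not batch:
            break  # ranked list exhausted before the batch started
        batch_sizes.append(M)
        candidate_attrs = incumbent_attrs + batch
        candidate_clf = fit_nbc(ds, rep.in_bag, candidate_attrs, params.l)
        candidate_mcc = _oob_mcc(candidate_clf, ds, rep.oob)
        if candidate_mcc > incumbent_mcc:
            incumbent_attrs = candidate_attrs
            incumbent_clf = candidate_clf
            incumbent_mcc = candidate_mcc
            mcc_trace.append(candidate_mcc)
            M *= 2
            if cursor >= len(order) and not eligible.any():
                break
        else:
            break

    return SelectionResult(
        classifier=incumbent_clf,
        batch_sizes=batch_sizes,
        oob_mcc_trace=mcc_trace,
    )


def select_attributes(
    ds: GenotypeDataset,
    rep: BootstrapReplicate,
    params: BonbParams,
    ranked: list[tuple[int, float]] | None = None,
) -> NBClassifier:
    """Classifier for one replicate (see :func:`select_attributes_detailed`)."""
    return select_attributes_detailed(ds, rep, params, ranked).classifier


@dataclass
class BonbEnsemble:
    """A trained bag of Naive Bayes classifiers with full bookkeeping."""

    classifiers: list[NBClassifier]
    replicates: list[BootstrapReplicate]
    params: BonbParams
    rng_seed: int
    snp_ids: list[str]
    batch_traces: list[list[int]] = field(default_factory=list)
    oob_mcc_traces: list[list[float]] = field(default_factory=list)

    @property
    def B(self) -> int:
        return len(self.classifiers)

    def mean_attributes_per_classifier(self) -> float:
        return float(np.mean([c.n_attributes for c in self.classifiers]))

    def inclusion_counts(self) -> dict[str, int]:
        """Number of classifiers whose attribute set contains each SNP."""
        counts: dict[str, int] = {}
        for clf in self.classifiers:
            for sid in clf.snp_ids:
                counts[sid] = counts.get(sid, 0) + 1
        return counts

    def _column_map(self, ds: GenotypeDataset) -> dict[str, int]:
        needed = {sid for clf in self.classifiers for sid in clf.snp_ids}
        missing = sorted(sid for sid in needed if sid not in ds._snp_index)
        if missing:
            raise ValidationError(
                "dataset lacks SNPs required by the ensemble: "
                + ", ".join(missing)
            )
        return {sid: ds.snp_index(sid) for sid in needed}

    def predict_proba(self, ds: GenotypeDataset) -> np.ndarray:
        """Mean posterior ``(p_case, p_control)`` per subject.

        SNPs are matched by snp_id, not column position, so the test
        dataset may order its columns differently.
        """
        cmap = self._column_map(ds)
        total = np.zeros((ds.n_subjects, 2))
        for clf in self.classifiers:
            cols = np.array([cmap[sid] for sid in clf.snp_ids], dtype=np.intp)
            total += clf.posterior_matrix(ds.genotypes, cols)
        return total / self.B

    def predict(self, ds: GenotypeDataset) -> np.ndarray:
        """CASE/CONTROL labels; posterior ties resolve to CONTROL."""
        probs = self.predict_proba(ds)
        return np.where(probs[:, 0] > probs[:, 1], CASE, CONTROL).astype(np.int8)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "params": asdict(self.params),
            "rng_seed": self.rng_seed,
            "snp_ids": list(self.snp_ids),
            "classifiers": [c.to_dict() for c in self.classifiers],
            "replicates": [
                {"in_bag": r.in_bag.tolist(), "oob": r.oob.tolist()}
                for r in self.replicates
            ],
            "batch_traces": self.batch_traces,
            "oob_mcc_traces": self.oob_mcc_traces,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BonbEnsemble":
        return cls(
            classifiers=[NBClassifier.from_dict(c) for c in d["classifiers"]],
            replicates=[
                BootstrapReplicate(
                    in_bag=np.asarray(r["in_bag"], dtype=np.intp),
                    oob=np.asarray(r["oob"], dtype=np.intp),
                )
                for r in d["replicates"]
            ],
            params=BonbParams(**d["params"]),
            rng_seed=int(d["rng_seed"]),
            snp_ids=list(d["snp_ids"]),
            batch_traces=[list(t) for t in d.get("batch_traces", [])],
            oob_mcc_traces=[list(t) for t in d.get("oob_mcc_traces", [])],
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "BonbEnsemble":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _train_one(
    ds: GenotypeDataset, params: BonbParams, child_seed: np.random.SeedSequence
) -> tuple[BootstrapReplicate, SelectionResult]:
    rng = np.random.default_rng(child_seed)
    rep = draw_replicate(ds.n_subjects, rng)
    return rep, select_attributes_detailed(ds, rep, params)


def train(
    ds: GenotypeDataset,
    params: BonbParams | None = None,
    seed: int = 0,
    n_jobs: int = 1,
) -> BonbEnsemble:
    """Train the full ensemble.

    Each replicate uses an independent RNG stream spawned from the master
    seed, so results are bit-identical regardless of ``n_jobs``.
    """
    params = params or BonbParams()
    ds.require_two_classes()
    children = np.random.SeedSequence(seed).spawn(params.B)
    if n_jobs == 1:
        results = [_train_one(ds, params, c) for c in children]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_train_one)(ds, params, c) for c in children
        )
    reps = [r for r, _ in results]
    sels = [s for _, s in results]
    return BonbEnsemble(
        classifiers=[s.classifier for s in sels],
        replicates=reps,
        params=params,
        rng_seed=seed,
        snp_ids=ds.snp_ids,
        batch_traces=[s.batch_sizes for s in sels],
        oob_mcc_traces=[s.oob_mcc_trace for s in sels],
    )


def ld_violations(ens: BonbEnsemble, ds: GenotypeDataset) -> list[tuple[int, str, str]]:
    """Post-hoc check of the linkage invariant on every trained classifier.

    Returns (classifier index, snp_id, snp_id) triples for every attribute
    pair at same-chromosome distance < ld_window_bp with in-bag r^2 above
    theta. An empty list means the invariant holds.
    """
    bad: list[tuple[int, str, str]] = []
    for b, (clf, rep) in enumerate(zip(ens.classifiers, ens.replicates)):
        attrs = [ds.snp_index(sid) for sid in clf.snp_ids]
        rows = (
            np.arange(ds.n_subjects)
            if ens.params.r2_on_full_train
            else rep.in_bag
        )
        for i in range(len(attrs)):
            for j in range(i + 1, len(attrs)):
                si, sj = ds.snps[attrs[i]], ds.snps[attrs[j]]
                if si.chromosome != sj.chromosome:
                    continue
                if abs(si.position_bp - sj.position_bp) >= ens.params.ld_window_bp:
                    continue
                r2 = squared_correlation(ds, attrs[i], attrs[j], rows)
                if r2 > ens.params.theta:
                    bad.append((b, si.snp_id, sj.snp_id))
    return bad
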