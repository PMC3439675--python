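"""Experimental harness: repeated sub-sampling CV, curves, baselines, sweeps.

Classification performance is assessed with repeated random sub-sampling:
90% of subjects train, 10% test, repeated (default 10 times), summarised by
the MCC (insensitive to class unbalance; exactly 0 for a majority
classifier) and accuracy. Splits are stratified by class so small datasets
never produce single-class training sets. The standard univariate
comparator trains one Naive Bayes classifier on every SNP passing the
genome-wide 2-df chi-square threshold (5e-7) on the training split.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_data import CASE, CONTROL, GenotypeDataset, ValidationError
from .nb_core import build_contingency_table, fit_nbc
from .scoring import chi2_general_2df, mcc, mcc_from_predictions, ConfusionCounts
from .ensemble import BonbParams, train

logger = logging.getLogger(__name__)

#: Genome-wide significance threshold of the univariate-test era.
GENOME_WIDE_ALPHA = 5e-7


@dataclass
class CvSplit:
    """One train/test partition of the subjects."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    fraction_test: float
    repetition: int


@dataclass
class EvalReport:
    """Summary of one repeated sub-sampling experiment."""

    mcc_values: np.ndarray
    accuracy_values: np.ndarray
    pr_points: pd.DataFrame
    roc_points: pd.DataFrame
    majority_mcc_values: np.ndarray
    majority_accuracy_values: np.ndarray

    @property
    def mcc_mean(self) -> float:
        return float(self.mcc_values.mean())

    @property
    def mcc_sd(self) -> float:
        return float(self.mcc_values.std(ddof=1)) if len(self.mcc_values) > 1 else 0.0

    @property
    def accuracy_mean(self) -> float:
        return float(self.accuracy_values.mean())

    @property
    def accuracy_sd(self) -> float:
        return (
            float(self.accuracy_values.std(ddof=1))
            if len(self.accuracy_values) > 1
            else 0.0
        )


def stratified_splits(
    labels: np.ndarray,
    repetitions: int,
    test_fraction: float,
    rng: np.random.Generator,
) -> list[CvSplit]:
    """Random class-stratified train/test splits.

    The test set has round(test_fraction * n) subjects overall, allocated
    to classes by largest remainder so the split preserves the case/control
    balance as closely as the rounding allows.
    """
    labels = np.asarray(labels)
    n = len(labels)
    n_test = int(round(test_fraction * n))
    if n_test < 1 or n_test >= n:
        raise ValidationError(
            f"test fraction {test_fraction} gives an unusable test size {n_test}"
        )
    class_idx = {k: np.flatnonzero(labels == k) for k in (CASE, CONTROL)}
    raw = {k: test_fraction * len(v) for k, v in class_idx.items()}
    base = {k: int(np.floor(r)) for k, r in raw.items()}
    short = n_test - sum(base.values())
    for k in sorted(raw, key=lambda k: raw[k] - base[k], reverse=True)[:short]:
        base[k] += 1
    splits = []
    for rep in range(repetitions):
        test_parts, train_parts = [], []
        for k, idx in class_idx.items():
            perm = rng.permutation(idx)
            test_parts.append(perm[: base[k]])
            train_parts.append(perm[base[k]:])
        splits.append(
            CvSplit(
                train_indices=np.sort(np.concatenate(train_parts)),
                test_indices=np.sort(np.concatenate(test_parts)),
                fraction_test=test_fraction,
                repetition=rep,
            )
        )
    return splits


def curves(y_true: np.ndarray, p_case: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Precision/recall and TPR/TNR points from a threshold sweep.

    The sweep runs over the distinct posterior values in descending order;
    a subject is called a case when its score is >= the threshold. Returns
    (pr_points, roc_points) with the threshold carried in both tables so
    the ROC can be re-rendered as TPR vs FPR if preferred.
    """
    y_true = np.asarray(y_true)
    p_case = np.asarray(p_case, dtype=float)
    n_pos = int((y_true == CASE).sum())
    n_neg = int((y_true != CASE).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("curves need at least one case and one control")
    thresholds = np.unique(p_case)[::-1]
    pr_rows, roc_rows = [], []
    for t in thresholds:
        pred = p_case >= t
        tp = int((pred & (y_true == CASE)).sum())
        fp = int((pred & (y_true != CASE)).sum())
        recall = tp / n_pos
        precision = tp / (tp + fp) if tp + fp else 1.0
        tnr = 1.0 - fp / n_neg
        pr_rows.append({"threshold": t, "recall": recall, "precision": precision})
        roc_rows.append({"threshold": t, "tpr": recall, "tnr": tnr})
    return pd.DataFrame(pr_rows), pd.DataFrame(roc_rows)


class MajorityModel:
    """Predicts the training majority class for every subject."""

    def __init__(self, train_ds: GenotypeDataset):
        n_ca, n_co = train_ds.n_cases, train_ds.n_controls
        self.p_case = n_ca / (n_ca + n_co)

    def predict_proba(self, ds: GenotypeDataset) -> np.ndarray:
        out = np.empty((ds.n_subjects, 2))
        out[:, 0] = self.p_case
        out[:, 1] = 1.0 - self.p_case
        return out


def subsample_cv(
    ds: GenotypeDataset,
    model_factory: Callable[[GenotypeDataset, int], object],
    repetitions: int = 10,
    test_fraction: float = 0.10,
    seed: int = 0,
) -> EvalReport:
    """Repeated stratified 90/10 sub-sampling of one model family.

    ``model_factory(train_ds, seed)`` must return a fitted object exposing
    ``predict_proba(ds) -> (n, 2)`` with columns (p_case, p_control). The
    report carries per-repetition MCC and accuracy, curves from the first
    repetition, and the majority-classifier baseline computed on the same
    splits. Deterministic given the seed.
    """
    ds.require_two_classes()
    ss = np.random.SeedSequence(seed)
    split_rng = np.random.default_rng(ss.spawn(1)[0])
    model_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(repetitions + 1)[1:]]
    splits = stratified_splits(ds.labels, repetitions, test_fraction, split_rng)
    mccs, accs, maj_mccs, maj_accs = [], [], [], []
    pr_points = roc_points = None
    for rep, split in enumerate(splits):
        train_ds = ds.subset_subjects(split.train_indices)
        test_ds = ds.subset_subjects(split.test_indices)
        model = model_factory(train_ds, model_seeds[rep])
        probs = np.asarray(model.predict_proba(test_ds))
        pred = np.where(probs[:, 0] > probs[:, 1], CASE, CONTROL)
        mccs.append(mcc_from_predictions(test_ds.labels, pred))
        accs.append(float((pred == test_ds.labels).mean()))
        maj_label = CASE if train_ds.n_cases > train_ds.n_controls else CONTROL
        maj_pred = np.full(test_ds.n_subjects, maj_label)
        maj_mccs.append(mcc_from_predictions(test_ds.labels, maj_pred))
        maj_accs.append(float((maj_pred == test_ds.labels).mean()))
        if rep == 0:
            pr_points, roc_points = curves(test_ds.labels, probs[:, 0])
    return EvalReport(
        mcc_values=np.array(mccs),
        accuracy_values=np.array(accs),
        pr_points=pr_points,
        roc_points=roc_points,
        majority_mcc_values=np.array(maj_mccs),
        majority_accuracy_values=np.array(maj_accs),
    )


def chi2_significant_snps(
    ds: GenotypeDataset, alpha_gw: float = GENOME_WIDE_ALPHA
) -> list[int]:
    """Columns whose applicable 2-df chi-square p-value beats ``alpha_gw``."""
    rows = np.arange(ds.n_subjects)
    out = []
    for j in range(ds.n_snps):
        stat, ok = chi2_general_2df(build_contingency_table(ds, j, rows))
        if ok and stats.chi2.sf(stat, df=2) < alpha_gw:
            out.append(j)
    return out


class StandardNBModel:
    """Single NB classifier on the genome-wide-significant SNPs."""

    def __init__(self, train_ds: GenotypeDataset, alpha_gw: float = GENOME_WIDE_ALPHA, l: float = 1.0):
        sig = chi2_significant_snps(train_ds, alpha_gw)
        if not sig:
            logger.warning(
                "no SNP reaches p < %g; falling back to majority classification",
                alpha_gw,
            )
            self._model = MajorityModel(train_ds)
            self.attributes = []
        else:
            self._model = None
            self.attributes = sig
            self._nbc = fit_nbc(train_ds, np.arange(train_ds.n_subjects), sig, l)
            self._snp_ids = [train_ds.snps[j].snp_id for j in sig]

    def predict_proba(self, ds: GenotypeDataset) -> np.ndarray:
        if self._model is not None:
            return self._model.predict_proba(ds)
        cols = np.array([ds.snp_index(sid) for sid in self._snp_ids], dtype=np.intp)
        return self._nbc.posterior_matrix(ds.genotypes, cols)


def standard_nb_baseline(
    ds_train: GenotypeDataset,
    ds_test: GenotypeDataset,
    alpha_gw: float = GENOME_WIDE_ALPHA,
    l: float = 1.0,
) -> np.ndarray:
    """Posterior (p_case, p_control) of the univariate-screen NB comparator."""
    return StandardNBModel(ds_train, alpha_gw, l).predict_proba(ds_test)


def bonb_model_factory(
    params: BonbParams | None = None, n_jobs: int = 1
) -> Callable[[GenotypeDataset, int], object]:
    """Factory adapter: trains a full ensemble on each training split."""

    def factory(train_ds: GenotypeDataset, seed: int):
        return train(train_ds, params, seed=seed, n_jobs=n_jobs)

    return factory


def standard_nb_factory(
    alpha_gw: float = GENOME_WIDE_ALPHA, l: float = 1.0
) -> Callable[[GenotypeDataset, int], object]:
    def factory(train_ds: GenotypeDataset, seed: int):
        del seed  # deterministic model
        return StandardNBModel(train_ds, alpha_gw, l)

    return factory


def parameter_sweep(
    ds: GenotypeDataset,
    B_grid: Sequence[int],
    theta_grid: Sequence[float],
    repetitions: int = 10,
    seed: int = 0,
    test_fraction: float = 0.10,
    base_params: BonbParams | None = None,
    n_jobs: int = 1,
) -> tuple[pd.DataFrame, float]:
    """MCC of the ensemble over a (B, theta) grid of parameter settings.

    Every grid cell reuses the same sub-sampling splits (same seed), so
    cells differ only in parameters. Returns a tidy table with one row per
    (B, theta, repetition) and the Kruskal-Wallis p-value comparing the
    per-repetition MCC across grid cells (NaN for a single-cell grid).
    """
    if not B_grid or not theta_grid:
        raise ValueError("parameter grids must be non-empty")
    base = base_params or BonbParams()
    rows = []
    groups = []
    for B, theta in itertools.product(B_grid, theta_grid):
        params = BonbParams(
            B=B,
            theta=theta,
            l=base.l,
            ld_window_bp=base.ld_window_bp,
            inclusion_fraction=base.inclusion_fraction,
            alpha=base.alpha,
            r2_on_full_train=base.r2_on_full_train,
        )
        report = subsample_cv(
            ds,
            bonb_model_factory(params, n_jobs=n_jobs),
            repetitions=repetitions,
            test_fraction=test_fraction,
            seed=seed,
        )
        groups.append(report.mcc_values)
        for rep, (m, a) in enumerate(zip(report.mcc_values, report.accuracy_values)):
            rows.append(
                {"B": B, "theta": theta, "repetition": rep, "mcc": m, "accuracy": a}
            )
    if len(groups) > 1:
        kw_p = float(stats.kruskal(*groups).pvalue)
    else:
        kw_p = float("nan")
    return pd.DataFrame(rows), kw_p
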