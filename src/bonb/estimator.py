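"""scikit-learn-compatible estimator facade over the bagged NB engine."""

from __future__ import annotations

import numbers

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .gwas_data import CASE, CONTROL, MISSING, GenotypeDataset, SnpInfo
from .ensemble import BonbParams, train
from .biomarker import biomarker_table, select_biomarkers


class BonbClassifier(BaseEstimator, ClassifierMixin):
    """Bagged Naive Bayes classifier for case/control SNP matrices.

    Fits an ensemble of ``B`` Laplace-smoothed categorical Naive Bayes
    classifiers on bootstrap replicates of the subjects. Each classifier
    selects its own small attribute set by ranking SNPs with a closed-form
    single-SNP MCC score and growing the set in doubling batches under an
    out-of-bag stopping rule, pruning linked SNPs (same chromosome,
    distance < ``ld_window_bp``, r^2 > ``theta``) as it goes. Prediction
    averages the per-classifier posteriors.

    Parameters
    ----------
    B : int, default 200
        Number of bootstrap replicates / classifiers.
    theta : float, default 0.1
        r^2 threshold above which two nearby SNPs count as linked.
    l : float, default 1.0
        Dirichlet weight (1 = Laplace smoothing).
    ld_window_bp : int, default 1_000_000
        Genomic window of the linkage rule.
    inclusion_fraction : float, default 0.05
        Candidate threshold for biomarker selection.
    alpha : float, default 0.05
        Significance level of the marginal-utility test.
    random_state : int or None
        Master seed; training is bit-reproducible given it.
    n_jobs : int, default 1
        Replicates to train in parallel (results independent of n_jobs).

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted class labels; ``classes_[1]`` is treated as the case
        (positive) class.
    ensemble_ : BonbEnsemble
        The trained ensemble with full bookkeeping.
    n_features_in_ : int

    Notes
    -----
    ``X`` holds genotype codes 0 (homozygous minor), 1 (heterozygous),
    2 (homozygous major); missing genotypes may be NaN or -1. Without SNP
    metadata (``positions``/``chromosomes`` fit parameters) every SNP is
    treated as genomically distant from every other, so no linkage pruning
    occurs; pass the metadata to enable it.
    """

    def __init__(
        self,
        B: int = 200,
        theta: float = 0.1,
        l: float = 1.0,
        ld_window_bp: int = 1_000_000,
        inclusion_fraction: float = 0.05,
        alpha: float = 0.05,
        random_state=None,
        n_jobs: int = 1,
    ):
        self.B = B
        self.theta = theta
        self.l = l
        self.ld_window_bp = ld_window_bp
        self.inclusion_fraction = inclusion_fraction
        self.alpha = alpha
        self.random_state = random_state
        self.n_jobs = n_jobs

    def _params(self) -> BonbParams:
        return BonbParams(
            B=self.B,
            theta=self.theta,
            l=self.l,
            ld_window_bp=self.ld_window_bp,
            inclusion_fraction=self.inclusion_fraction,
            alpha=self.alpha,
        )

    @staticmethod
    def _coerce_X(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix of genotype codes")
        out = np.full(X.shape, MISSING, dtype=np.int8)
        finite = np.isfinite(X)
        out[finite] = X[finite].astype(np.int8)
        return out

    def _make_dataset(self, X, y=None) -> GenotypeDataset:
        G = self._coerce_X(X)
        n, p = G.shape
        if y is None:
            labels = np.zeros(n, dtype=np.int8)
            if n:
                labels[0] = CASE  # placeholder; prediction ignores labels
        else:
            labels = np.where(np.asarray(y) == self._case_label, CASE, CONTROL).astype(
                np.int8
            )
        snps = [
            SnpInfo(self._snp_ids[j], self._chromosomes[j], int(self._positions[j]))
            for j in range(p)
        ]
        return GenotypeDataset(
            genotypes=G,
            snps=snps,
            labels=labels,
            subject_ids=[f"s{i}" for i in range(n)],
        )

    def fit(self, X, y, snp_ids=None, chromosomes=None, positions=None):
        """Fit the ensemble.

        ``snp_ids``, ``chromosomes`` and ``positions`` are optional
        per-column metadata; without positions no distance-based pruning
        can apply (columns are laid out farther apart than the window).
        """
        G = self._coerce_X(X)
        n, p = G.shape
        y = np.asarray(y)
        if y.shape != (n,):
            raise ValueError("y must have one label per row of X")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(classes)}")
        self.classes_ = classes
        self._case_label = classes[1]
        self._snp_ids = (
            [str(s) for s in snp_ids] if snp_ids is not None else [f"snp{j}" for j in range(p)]
        )
        self._chromosomes = (
            [str(c) for c in chromosomes]
            if chromosomes is not None
            else ["1"] * p
        )
        if positions is not None:
            self._positions = np.asarray(positions, dtype=np.int64)
        else:
            # farther apart than the window: distance rule never fires
            self._positions = 1 + np.arange(p, dtype=np.int64) * (self.ld_window_bp + 1)
        seed = self.random_state if self.random_state is not None else 0
        if not isinstance(seed, numbers.Integral):
            raise ValueError("random_state must be an int or None")
        self._train_ds = self._make_dataset(X, y)
        self.ensemble_ = train(
            self._train_ds, self._params(), seed=int(seed), n_jobs=self.n_jobs
        )
        self.n_features_in_ = p
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Class membership probabilities, columns ordered as ``classes_``."""
        check_is_fitted(self, "ensemble_")
        ds = self._make_dataset(X)
        probs = self.ensemble_.predict_proba(ds)  # (p_case, p_control)
        return probs[:, ::-1]  # classes_ order: (control-like, case-like)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "ensemble_")
        probs = self.predict_proba(X)
        case_wins = probs[:, 1] > probs[:, 0]  # tie resolves to the control class
        return np.where(case_wins, self.classes_[1], self.classes_[0])

    def select_biomarkers(self, random_state=None) -> pd.DataFrame:
        """Marginal-utility biomarker report on the training data."""
        check_is_fitted(self, "ensemble_")
        records = select_biomarkers(
            self.ensemble_,
            self._train_ds,
            rng=np.random.default_rng(random_state),
        )
        return biomarker_table(records)
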