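"""Classification metrics and the closed-form Naive Bayes attribute score.

The attribute score of a SNP is the MCC that a single-attribute Naive Bayes
classifier (Laplace-smoothed, l = 1) would achieve when trained and tested
on the same sample — but computed in closed form directly from the SNP's
2 x 3 contingency table, which is what makes per-SNP ranking tractable at
genome scale. Three indicator inequalities I0/I1/I2 capture which class the
induced classifier predicts for each genotype:

    I_g :  (case_g + 1)/(n_ca + 3) * (n_ca + 1)  >  (ctrl_g + 1)/(n_co + 3) * (n_co + 1)

(the common 1/(n + 2) prior denominator cancels). The score is then

    S = [ (ae - bd)(I0 - I1) + (af - cd)(I0 - I2) + (bf - ce)(I1 - I2) ]
        / sqrt( n_ca n_co [ n0 n1 XOR(I0,I1) + n0 n2 XOR(I0,I2) + n1 n2 XOR(I1,I2) ] ).

When I0 = I1 = I2 the induced classifier is a majority classifier and the
score is 0, matching the MCC convention for degenerate denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .nb_core import ContingencyTable


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with case as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class AttributeScore:
    """Closed-form single-SNP score with its indicator triple."""

    snp_index: int
    score: float
    indicators: tuple[int, int, int]


def mcc(counts: ConfusionCounts) -> float:
    """Matthews Correlation Coefficient in [-1, 1].

    Returns 0.0 whenever any factor of the denominator vanishes — the
    convention under which a majority (or otherwise degenerate) classifier
    scores 0.
    """
    if counts.n == 0:
        raise ValueError("MCC undefined for zero subjects")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom2 = (
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if denom2 == 0.0:
        return 0.0
    return (float(tp) * tn - float(fp) * fn) / np.sqrt(denom2)


def mcc_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """MCC of integer CASE/CONTROL predictions against truth."""
    from .gwas_data import CASE

    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(((y_pred == CASE) & (y_true == CASE)).sum())
    tn = int(((y_pred != CASE) & (y_true != CASE)).sum())
    fp = int(((y_pred == CASE) & (y_true != CASE)).sum())
    fn = int(((y_pred != CASE) & (y_true == CASE)).sum())
    return mcc(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))


def _indicators_from_counts(
    case_counts: np.ndarray, control_counts: np.ndarray
) -> np.ndarray:
    """Vectorised indicator triple; counts have genotype on the first axis.

    Strict inequality; ties give 0 (the induced classifier predicts control
    on a tie, consistent with the prediction tie rule).
    """
    n_ca = case_counts.sum(axis=0).astype(np.int64)
    n_co = control_counts.sum(axis=0).astype(np.int64)
    # cross-multiplied to stay in exact integer arithmetic:
    # (case_g+1)(n_ca+1)(n_co+3) > (ctrl_g+1)(n_co+1)(n_ca+3)
    lhs = (case_counts + 1) * (n_ca + 1) * (n_co + 3)
    rhs = (control_counts + 1) * (n_co + 1) * (n_ca + 3)
    return (lhs > rhs).astype(np.int64)


def nb_indicators(table: ContingencyTable) -> tuple[int, int, int]:
    """Indicator triple (I0, I1, I2) for one contingency table."""
    ind = _indicators_from_counts(
        table.case_counts.astype(np.int64), table.control_counts.astype(np.int64)
    )
    return int(ind[0]), int(ind[1]), int(ind[2])


def _scores_from_counts(
    case_counts: np.ndarray, control_counts: np.ndarray
) -> np.ndarray:
    """Vectorised closed-form score; counts shaped (3,) or (3, p)."""
    a, b, c = (case_counts[g].astype(np.int64) for g in range(3))
    d, e, f = (control_counts[g].astype(np.int64) for g in range(3))
    ind = _indicators_from_counts(
        np.stack([a, b, c]), np.stack([d, e, f])
    )
    i0, i1, i2 = ind[0], ind[1], ind[2]
    n_ca, n_co = a + b + c, d + e + f
    n0, n1, n2 = a + d, b + e, c + f
    num = (
        (a * e - b * d) * (i0 - i1)
        + (a * f - c * d) * (i0 - i2)
        + (b * f - c * e) * (i1 - i2)
    ).astype(float)
    radicand = (
        n_ca.astype(float)
        * n_co
        * (n0 * n1 * (i0 ^ i1) + n0 * n2 * (i0 ^ i2) + n1 * n2 * (i1 ^ i2))
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(radicand > 0, num / np.sqrt(radicand), 0.0)
    return score


def nb_attribute_score(table: ContingencyTable, snp_index: int = -1) -> AttributeScore:
    """Closed-form score of one SNP's contingency table.

    Equals the MCC of a single-attribute Laplace-smoothed NB classifier
    trained and tested on the counts themselves; 0 whenever that classifier
    is a majority classifier (I0 = I1 = I2) or the margin is degenerate.
    """
    score = _scores_from_counts(table.case_counts, table.control_counts)
    return AttributeScore(
        snp_index=snp_index,
        score=float(score),
        indicators=nb_indicators(table),
    )


def chi2_general_2df(table: ContingencyTable) -> tuple[float, bool]:
    """Pearson chi-square on the 2 x 3 table under a general genetic model.

    Returns ``(statistic, applicable)``. The statistic is computed on the
    table with empty genotype columns dropped; ``applicable`` is True only
    when all six cells hold at least 5 observations (the classical validity
    rule), so an applicable table is always full 2 x 3 with 2 df. Tables
    with a zero class margin or fewer than two non-empty genotype columns
    return (0.0, False).
    """
    obs = np.stack([table.case_counts, table.control_counts]).astype(float)
    applicable = bool((obs >= 5).all())
    col_keep = obs.sum(axis=0) > 0
    if table.n_ca == 0 or table.n_co == 0 or col_keep.sum() < 2:
        return 0.0, False
    stat = stats.chi2_contingency(obs[:, col_keep], correction=False).statistic
    return float(stat), applicable


def score_table(ds) -> pd.DataFrame:
    """Per-SNP table of attribute score vs chi-square, for scatter plots.

    Columns: snp_id, chromosome, position_bp, score, chi2, applicable.
    """
    from .nb_core import build_contingency_table

    rows = []
    all_idx = np.arange(ds.n_subjects)
    for j, snp in enumerate(ds.snps):
        t = build_contingency_table(ds, j, all_idx)
        stat, ok = chi2_general_2df(t)
        rows.append(
            {
                "snp_id": snp.snp_id,
                "chromosome": snp.chromosome,
                "position_bp": snp.position_bp,
                "score": nb_attribute_score(t, j).score,
                "chi2": stat,
                "applicable": ok,
            }
        )
    return pd.DataFrame(rows)
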