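"""Permutation-based biomarker selection on out-of-bag samples.

Every SNP included as an attribute by at least 5% of the classifiers is a
candidate biomarker. For each classifier that includes the candidate, its
genotype column is permuted uniformly at random among that classifier's
out-of-bag subjects and the resulting relative decrease in OOB MCC is the
SNP's *marginal utility* (MU) for that classifier — the importance of the
SNP given all the other attributes. The MU samples of a candidate are
tested against zero with a one-tailed Wilcoxon signed-rank test; candidates
with p < alpha are flagged as biomarkers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_data import CASE, CONTROL, GenotypeDataset, chromosome_sort_key
from .ensemble import BonbEnsemble, BonbParams
from .scoring import mcc_from_predictions

logger = logging.getLogger(__name__)


@dataclass
class BiomarkerRecord:
    """Per-candidate summary: one row of the biomarker report."""

    snp_id: str
    chromosome: str
    position_bp: int
    inclusion_fraction: float
    mu_samples: np.ndarray
    mu_median: float
    p_value: float
    selected: bool


def wilcoxon_signed_rank_onetailed(samples) -> float:
    """One-tailed (location > 0) Wilcoxon signed-rank p-value.

    Zeros are dropped (Wilcoxon's convention); with every sample zero the
    test carries no evidence and p = 1. The exact null distribution is used
    for small tie-free samples, the tie-corrected normal approximation
    otherwise.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one sample")
    nz = x[x != 0]
    if nz.size == 0:
        return 1.0
    exact_ok = nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size
    res = stats.wilcoxon(
        nz,
        alternative="greater",
        zero_method="wilcox",
        method="exact" if exact_ok else "approx",
    )
    return float(res.pvalue)


def _oob_mcc_with_column(
    clf, G_sub: np.ndarray, y_oob: np.ndarray
) -> float:
    probs = clf.posterior_matrix(G_sub, np.arange(G_sub.shape[1]))
    pred = np.where(probs[:, 0] > probs[:, 1], CASE, CONTROL)
    return mcc_from_predictions(y_oob, pred)


def marginal_utility(
    ens: BonbEnsemble,
    ds: GenotypeDataset,
    snp_index: int,
    b: int,
    rng: np.random.Generator,
    n_permutations: int = 1,
) -> float:
    """Marginal utility of one SNP within one classifier.

    MU = (MCC_orig - MCC_perm) / |MCC_orig|, both measured on the
    classifier's OOB subjects, the second after permuting the SNP's
    genotype column (MISSING values permuted along with the rest). When
    MCC_orig is 0 the absolute decrease is returned instead. With
    ``n_permutations`` > 1 the permuted MCC is averaged over independent
    permutations.
    """
    clf = ens.classifiers[b]
    snp_id = ds.snps[snp_index].snp_id
    if snp_id not in clf.snp_ids:
        raise ValueError(f"classifier {b} does not include SNP {snp_id}")
    rep = ens.replicates[b]
    if rep.oob.size == 0:
        raise ValueError(f"classifier {b} has an empty OOB set")
    cols = np.array([ds.snp_index(sid) for sid in clf.snp_ids], dtype=np.intp)
    G_sub = ds.genotypes[rep.oob][:, cols]
    y_oob = ds.labels[rep.oob]
    pos = clf.snp_ids.index(snp_id)
    mcc_orig = _oob_mcc_with_column(clf, G_sub, y_oob)
    perm_vals = []
    for _ in range(n_permutations):
        G_perm = G_sub.copy()
        G_perm[:, pos] = G_perm[rng.permutation(G_sub.shape[0]), pos]
        perm_vals.append(_oob_mcc_with_column(clf, G_perm, y_oob))
    mcc_perm = float(np.mean(perm_vals))
    drop = mcc_orig - mcc_perm
    return drop / abs(mcc_orig) if mcc_orig != 0.0 else drop


def select_biomarkers(
    ens: BonbEnsemble,
    ds: GenotypeDataset,
    params: BonbParams | None = None,
    rng: np.random.Generator | int | None = None,
    n_permutations: int = 1,
) -> list[BiomarkerRecord]:
    """Score and test every candidate SNP; flag the significant ones.

    Candidates are SNPs included by at least ``inclusion_fraction`` of the
    classifiers; each gets one MU per including classifier (one fresh
    permutation each, by default). All candidates are reported in genomic
    order with the Wilcoxon p-value; ``selected`` is True iff p < alpha.
    Candidates with fewer than two non-zero MU samples get p = 1 (the
    signed-rank test is degenerate there).
    """
    params = params or ens.params
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    counts = ens.inclusion_counts()
    candidates = [
        sid
        for sid, cnt in counts.items()
        if cnt / ens.B >= params.inclusion_fraction
    ]
    candidates.sort(
        key=lambda sid: (
            chromosome_sort_key(ds.snps[ds.snp_index(sid)].chromosome),
            ds.snps[ds.snp_index(sid)].position_bp,
            sid,
        )
    )
    records: list[BiomarkerRecord] = []
    for sid in candidates:
        j = ds.snp_index(sid)
        mus = np.array(
            [
                marginal_utility(ens, ds, j, b, rng, n_permutations)
                for b, clf in enumerate(ens.classifiers)
                if sid in clf.snp_ids
            ]
        )
        if np.count_nonzero(mus) < 2:
            logger.warning(
                "biomarker candidate %s has <2 non-zero MU samples; p set to 1",
                sid,
            )
            p = 1.0
        else:
            p = wilcoxon_signed_rank_onetailed(mus)
        snp = ds.snps[j]
        records.append(
            BiomarkerRecord(
                snp_id=sid,
                chromosome=snp.chromosome,
                position_bp=snp.position_bp,
                inclusion_fraction=counts[sid] / ens.B,
                mu_samples=mus,
                mu_median=float(np.median(mus)),
                p_value=p,
                selected=bool(p < params.alpha),
            )
        )
    return records


def forced_inclusion_pvalue(
    ens: BonbEnsemble,
    ds: GenotypeDataset,
    snp_index: int,
    rng: np.random.Generator,
) -> float:
    """Marginal-utility p-value of a SNP forced into every classifier.

    Appends the SNP as an extra attribute of each classifier (re-estimating
    only that attribute's probability table on the classifier's in-bag
    multiset), computes one MU per classifier and returns the one-tailed
    Wilcoxon p-value. Bypassing the OOB-driven attribute selection gives an
    unconditioned read of the MU test, e.g. for type-I-error checks on
    known-null SNPs.
    """
    from .nb_core import fit_nbc

    mus = []
    for b, (clf, rep) in enumerate(zip(ens.classifiers, ens.replicates)):
        attrs = [ds.snp_index(sid) for sid in clf.snp_ids] + [snp_index]
        clf2 = fit_nbc(ds, rep.in_bag, attrs, ens.params.l)
        tmp = BonbEnsemble(
            classifiers=[clf2],
            replicates=[rep],
            params=ens.params,
            rng_seed=ens.rng_seed,
            snp_ids=ens.snp_ids,
        )
        mus.append(marginal_utility(tmp, ds, snp_index, 0, rng))
    mus = np.array(mus)
    if np.count_nonzero(mus) < 2:
        return 1.0
    return wilcoxon_signed_rank_onetailed(mus)


def biomarker_table(records: list[BiomarkerRecord]) -> pd.DataFrame:
    """Tabular report: snp_id, chromosome, position_bp, pct_nbcs,
    mu_median, p_value, selected."""
    return pd.DataFrame(
        [
            {
                "snp_id": r.snp_id,
                "chromosome": r.chromosome,
                "position_bp": r.position_bp,
                "pct_nbcs": 100.0 * r.inclusion_fraction,
                "mu_median": r.mu_median,
                "p_value": r.p_value,
                "selected": r.selected,
            }
            for r in records
        ]
    )
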