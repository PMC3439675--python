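"""Bagging engine: replicates, ranking, linkage-aware selection, prediction."""

import numpy as np
import pytest

from bonb.gwas_data import CASE, CONTROL, MISSING, ValidationError
from bonb.nb_core import NBClassifier, build_contingency_table
from bonb.scoring import nb_attribute_score
from bonb.ensemble import (
    BonbEnsemble,
    BonbParams,
    BootstrapReplicate,
    draw_replicate,
    ld_violations,
    rank_snps,
    select_attributes,
    select_attributes_detailed,
    squared_correlation,
    train,
)
from conftest import make_dataset


class TestBootstrap:
    def test_single_subject(self):
        rep = draw_replicate(1, np.random.default_rng(0))
        assert rep.in_bag.tolist() == [0]
        assert rep.oob.size == 0

    def test_oob_is_complement_of_support(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            rep = draw_replicate(50, rng)
            assert rep.in_bag.size == 50
            assert set(rep.oob) == set(range(50)) - set(rep.in_bag)

    def test_deterministic_given_seed(self):
        a = draw_replicate(100, np.random.default_rng(7))
        b = draw_replicate(100, np.random.default_rng(7))
        assert np.array_equal(a.in_bag, b.in_bag)
        assert np.array_equal(a.oob, b.oob)


class TestRanking:
    def test_perfect_snp_ranks_first_with_score_one(self):
        # SNP 1 separates classes exactly; SNPs 0 and 2 are constant
        ds = make_dataset(
            [[1, 0, 2], [1, 0, 2], [1, 2, 2], [1, 2, 2]],
            [CASE, CASE, CONTROL, CONTROL],
        )
        rep = BootstrapReplicate(in_bag=np.arange(4), oob=np.array([], dtype=int))
        ranked = rank_snps(ds, rep)
        assert ranked[0] == (1, 1.0)

    def test_ties_fall_back_to_genomic_order(self):
        ds = make_dataset(
            [[1, 1, 1]] * 2 + [[1, 1, 1]] * 2,
            [CASE, CASE, CONTROL, CONTROL],
            chromosomes=["2", "1", "1"],
            positions=[500, 900, 100],
        )
        rep = BootstrapReplicate(in_bag=np.arange(4), oob=np.array([], dtype=int))
        ranked = rank_snps(ds, rep)
        # all scores equal -> chr1:100, chr1:900, chr2:500
        assert [j for j, _ in ranked] == [2, 1, 0]

    def test_agrees_with_scoring_module(self, small_sim):
        """Ranking scores equal per-SNP closed-form scores on the in-bag
        multiset computed independently through the contingency path."""
        ds, _ = small_sim
        rep = draw_replicate(ds.n_subjects, np.random.default_rng(3))
        ranked = dict(rank_snps(ds, rep))
        for j in range(0, ds.n_snps, 7):
            t = build_contingency_table(ds, j, rep.in_bag)
            assert ranked[j] == pytest.approx(nb_attribute_score(t).score, abs=1e-12)


class TestSquaredCorrelation:
    def test_identical_and_mirrored_columns(self):
        ds = make_dataset(
            [[0, 0, 2], [1, 1, 1], [2, 2, 0], [0, 0, 2], [1, 1, 1], [2, 2, 0]],
            [CASE, CASE, CASE, CONTROL, CONTROL, CONTROL],
        )
        rows = np.arange(6)
        assert squared_correlation(ds, 0, 1, rows) == pytest.approx(1.0)
        assert squared_correlation(ds, 0, 2, rows) == pytest.approx(1.0)  # 2 - x

    def test_hand_computed_toy_pair(self):
        x = [0, 1, 2, 0, 1, 2]
        y = [0, 1, 1, 0, 2, 2]
        ds = make_dataset(list(zip(x, y)), [CASE] * 3 + [CONTROL] * 3)
        want = float(np.corrcoef(x, y)[0, 1] ** 2)
        assert squared_correlation(ds, 0, 1, np.arange(6)) == pytest.approx(want)

    def test_missing_pairs_excluded_and_constant_is_zero(self):
        ds = make_dataset(
            [[0, MISSING], [1, 1], [2, 1], [0, 1]],
            [CASE, CASE, CONTROL, CONTROL],
        )
        # usable rows have constant second column -> treated as uncorrelated
        assert squared_correlation(ds, 0, 1, np.arange(4)) == 0.0


def _selection_fixture(rng, n=240):
    """One strongly causal SNP, one exact duplicate 1 bp away, 20 noise SNPs."""
    causal = rng.integers(0, 3, n)
    labels = np.where(causal == 0, CASE, np.where(causal == 2, CONTROL,
                      rng.integers(0, 2, n))).astype(np.int8)
    noise = rng.integers(0, 3, size=(n, 20))
    genotypes = np.column_stack([causal, causal.copy(), noise])
    positions = [1_000_000, 1_000_001] + [10_000_000 + 3_000_000 * j for j in range(20)]
    return make_dataset(genotypes, labels, positions=positions)


class TestSelection:
    def test_causal_in_duplicate_never(self):
        """The causal SNP is selected; its exact duplicate 1 bp away is
        pruned by the linkage rule (r^2 = 1 > theta, distance < 1 Mb)."""
        rng = np.random.default_rng(0)
        ds = _selection_fixture(rng)
        rep = draw_replicate(ds.n_subjects, rng)
        clf = select_attributes(ds, rep, BonbParams(B=1))
        assert "snp0" in clf.snp_ids
        assert "snp1" not in clf.snp_ids

    def test_batch_sizes_double(self, small_sim):
        ds, _ = small_sim
        for seed in range(5):
            rep = draw_replicate(ds.n_subjects, np.random.default_rng(seed))
            res = select_attributes_detailed(ds, rep, BonbParams(B=1))
            assert res.batch_sizes == [2**k for k in range(len(res.batch_sizes))]

    def test_oob_trace_strictly_increases(self, small_trained):
        for trace in small_trained.oob_mcc_traces:
            assert all(b > a for a, b in zip(trace, trace[1:]))
            assert all(v > 0 for v in trace)  # first acceptance beats the
            # empty (majority) classifier at 0

    def test_empty_oob_rejected(self):
        ds = make_dataset([[0], [1]], [CASE, CONTROL])
        rep = BootstrapReplicate(in_bag=np.array([0, 1]), oob=np.array([], dtype=int))
        with pytest.raises(ValidationError, match="larger"):
            select_attributes(ds, rep, BonbParams(B=1))


class TestTrain:
    def test_single_replicate_composition(self, small_sim):
        """train with B=1 equals draw_replicate + select_attributes on the
        same spawned stream."""
        ds, _ = small_sim
        ens = train(ds, BonbParams(B=1), seed=5)
        rng = np.random.default_rng(np.random.SeedSequence(5).spawn(1)[0])
        rep = draw_replicate(ds.n_subjects, rng)
        clf = select_attributes(ds, rep, BonbParams(B=1))
        assert np.array_equal(ens.replicates[0].in_bag, rep.in_bag)
        assert ens.classifiers[0].snp_ids == clf.snp_ids
        assert np.allclose(ens.classifiers[0].theta, clf.theta)

    def test_bit_reproducible_and_parallel_invariant(self, small_sim):
        ds, _ = small_sim
        a = train(ds, BonbParams(B=6), seed=3)
        b = train(ds, BonbParams(B=6), seed=3)
        c = train(ds, BonbParams(B=6), seed=3, n_jobs=2)
        assert a.to_dict() == b.to_dict() == c.to_dict()

    def test_single_class_rejected(self):
        ds = make_dataset([[0], [1], [2]], [CASE, CASE, CASE])
        with pytest.raises(ValidationError):
            train(ds, BonbParams(B=1), seed=0)

    def test_models_stay_sparse(self, small_trained):
        """Attribute sets stay in the single digits on the small panel."""
        assert 0 < small_trained.mean_attributes_per_classifier() < 10

    def test_ld_invariant_holds(self, small_sim, small_trained):
        ds, _ = small_sim
        assert ld_violations(small_trained, ds) == []


def _prior_only(prior):
    return NBClassifier(
        snp_ids=[], attributes=np.array([], dtype=int),
        theta=np.empty((2, 0, 3)), prior=np.asarray(prior, dtype=float),
    )


class TestPrediction:
    def test_single_classifier_equals_its_posterior(self, small_sim, small_trained):
        ds, _ = small_sim
        sub = BonbEnsemble(
            classifiers=small_trained.classifiers[:1],
            replicates=small_trained.replicates[:1],
            params=small_trained.params,
            rng_seed=0,
            snp_ids=small_trained.snp_ids,
        )
        got = sub.predict_proba(ds)
        clf = small_trained.classifiers[0]
        cols = np.array([ds.snp_index(s) for s in clf.snp_ids], dtype=np.intp)
        want = clf.posterior_matrix(ds.genotypes, cols)
        assert np.allclose(got, want)

    def test_posterior_averaging(self, tiny_ds):
        ens = BonbEnsemble(
            classifiers=[_prior_only([0.9, 0.1]), _prior_only([0.5, 0.5])],
            replicates=[], params=BonbParams(B=2), rng_seed=0,
            snp_ids=tiny_ds.snp_ids,
        )
        probs = ens.predict_proba(tiny_ds)
        assert np.allclose(probs, [0.7, 0.3])
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_alignment_by_snp_id(self, small_sim, small_trained):
        """Shuffling the test dataset's columns leaves predictions intact."""
        ds, _ = small_sim
        perm = np.random.default_rng(0).permutation(ds.n_snps)
        shuffled = ds.subset_snps(perm)
        assert np.allclose(
            small_trained.predict_proba(ds), small_trained.predict_proba(shuffled)
        )

    def test_missing_snp_reported_by_id(self, small_sim, small_trained):
        ds, _ = small_sim
        needed = small_trained.classifiers[0].snp_ids[0]
        keep = [j for j in range(ds.n_snps) if ds.snps[j].snp_id != needed]
        with pytest.raises(ValidationError, match=needed):
            small_trained.predict_proba(ds.subset_snps(keep))


def test_ensemble_serialization_round_trip(small_sim, small_trained, tmp_path):
    ds, _ = small_sim
    path = tmp_path / "model.json"
    small_trained.save(path)
    clone = BonbEnsemble.load(path)
    assert clone.to_dict() == small_trained.to_dict()
    assert np.allclose(clone.predict_proba(ds), small_trained.predict_proba(ds))
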