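"""Occurrence SDM stage: metric oracles, replicate machinery, robust filtering,
ensembles, consensus weighting and cut-off search."""

import numpy as np
import pytest

from bioturb import synth
from bioturb.sdm import (
    AlgorithmConfig,
    ReplicateRun,
    auc_score,
    best_cutoff,
    binarize,
    consensus,
    ensemble_mean,
    fit_replicates,
    select_mtry,
    tss_score,
    tune_rf,
)


def auc_pairwise_oracle(scores, labels):
    """Exhaustive Mann-Whitney enumeration: fraction of positive-negative pairs
    correctly ordered, ties credited 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert auc_score([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc_score([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_hand_enumerated_example(self):
        # pairs: (.9,.8)+, (.9,.1)+, (.7,.8)-, (.7,.1)+ -> 3/4
        assert auc_score([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score([0.1, 0.2], [1, 1])

    def test_matches_pairwise_oracle_on_random_instances(self):
        """Rank-based AUC equals exhaustive pair enumeration on 500 instances."""
        rng = np.random.default_rng(0)
        for _ in range(500):
            n = int(rng.integers(4, 51))
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # many ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auc_score(scores, labels) == pytest.approx(
                auc_pairwise_oracle(scores, labels), abs=1e-12
            )


class TestTSS:
    def test_perfect_prediction(self):
        assert tss_score([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0

    def test_constant_prediction_has_no_skill(self):
        assert tss_score([1, 1, 1, 1], [1, 1, 0, 0]) == 0.0

    def test_hand_computed_confusion_matrix(self):
        # TP=8, FN=2, TN=6, FP=4 -> sens 0.8 + spec 0.6 - 1 = 0.4
        labels = [1] * 10 + [0] * 10
        preds = [1] * 8 + [0] * 2 + [0] * 6 + [1] * 4
        assert tss_score(preds, labels) == pytest.approx(0.4)


class TestBestCutoff:
    def test_separable_case_returns_midpoint(self):
        cut, tss = best_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert cut == pytest.approx(0.5)
        assert tss == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            best_cutoff([0.1, 0.9], [1, 1])

    def test_matches_exhaustive_scan(self):
        """Achieved TSS equals a brute-force scan over all candidate cut-offs
        on 200 random score/label sets."""
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(6, 40))
            scores = rng.choice(np.linspace(0, 1, 9), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            if len(np.unique(scores)) < 2:
                continue
            cut, tss = best_cutoff(scores, labels)
            distinct = np.unique(scores)
            grid = np.concatenate([(distinct[:-1] + distinct[1:]) / 2])
            brute = max(tss_score((scores >= c).astype(int), labels) for c in grid)
            assert tss == pytest.approx(brute, abs=1e-12)


class TestReplicates:
    @pytest.fixture(scope="class")
    def separable(self):
        rng = np.random.default_rng(5)
        n = 120
        x = rng.normal(size=(n, 7))
        y = (x[:, 0] > 0).astype(int)
        x[:, 0] += y * 4  # wide margin
        return x, y

    def test_exactly_n_reps_runs(self, separable):
        runs = fit_replicates(*separable, "glm", n_reps=20, seed=3)
        assert len(runs) == 20
        assert [r.replicate for r in runs] == list(range(1, 21))

    def test_separable_data_all_robust(self, separable):
        runs = fit_replicates(*separable, "glm", n_reps=10, seed=3)
        assert all(r.robust for r in runs)
        assert all(r.auc == 1.0 and r.tss == 1.0 for r in runs)

    def test_permuted_labels_have_no_skill(self, separable):
        x, y = separable
        rng = np.random.default_rng(8)
        y_perm = rng.permutation(y)
        runs = fit_replicates(x, y_perm, "glm", n_reps=20, seed=3)
        assert abs(np.mean([r.auc for r in runs]) - 0.5) < 0.1

    def test_robust_filter_thresholds_exact(self):
        """A run at AUC 0.72 / TSS 0.43 passes; AUC 0.69 / TSS 0.5 fails."""
        def flag(auc, tss):
            return bool(auc >= 0.7 and tss >= 0.4)

        weakest_reported = ReplicateRun("sp", "glm", 1, None, auc=0.72, tss=0.43, robust=flag(0.72, 0.43))
        below_auc = ReplicateRun("sp", "glm", 2, None, auc=0.69, tss=0.5, robust=flag(0.69, 0.5))
        below_tss = ReplicateRun("sp", "glm", 3, None, auc=0.75, tss=0.39, robust=flag(0.75, 0.39))
        assert weakest_reported.robust
        assert not below_auc.robust
        assert not below_tss.robust

    def test_lowering_thresholds_never_removes_runs(self, separable):
        x, y = separable
        rng = np.random.default_rng(9)
        y_noisy = np.where(rng.random(len(y)) < 0.25, 1 - y, y)
        strict = fit_replicates(x, y_noisy, "glm", n_reps=10, seed=4, auc_min=0.7, tss_min=0.4)
        loose = fit_replicates(x, y_noisy, "glm", n_reps=10, seed=4, auc_min=0.6, tss_min=0.3)
        strict_ids = {r.replicate for r in strict if r.robust}
        loose_ids = {r.replicate for r in loose if r.robust}
        assert strict_ids <= loose_ids

    def test_too_few_presences_rejected(self):
        x = np.random.default_rng(0).normal(size=(10, 3))
        y = np.array([1] + [0] * 9)
        with pytest.raises(ValueError, match="presences"):
            fit_replicates(x, y, "glm", n_reps=2, seed=0)

    def test_deterministic_given_seed(self, separable):
        a = fit_replicates(*separable, "rf", n_reps=3, seed=7)
        b = fit_replicates(*separable, "rf", n_reps=3, seed=7)
        assert [(r.auc, r.tss) for r in a] == [(r.auc, r.tss) for r in b]


class TestTuneRF:
    def test_injected_score_table(self):
        assert select_mtry({2: 0.6, 3: 0.7, 4: 0.7, 5: 0.65}) == 3

    def test_tie_resolves_to_smallest(self):
        assert select_mtry({2: 0.5, 3: 0.5, 4: 0.5, 5: 0.5}) == 2

    def test_single_candidate(self):
        assert select_mtry({4: 0.9}) == 4

    def test_candidate_exceeding_predictors_rejected(self):
        x = np.random.default_rng(0).normal(size=(40, 3))
        y = (x[:, 0] > 0).astype(int)
        with pytest.raises(ValueError, match="exceeds"):
            tune_rf(x, y, mtry_candidates=(2, 3, 4, 5), n_reps=2, seed=0)


class TestEnsembleAndConsensus:
    class _ConstModel:
        def __init__(self, value):
            self.value = value

        def predict_prob(self, X):
            return np.full(len(X), self.value)

    def _run(self, value, algorithm="glm", tss=0.5, replicate=1, robust=True):
        return ReplicateRun("sp", algorithm, replicate, self._ConstModel(value), auc=0.8, tss=tss, robust=robust)

    def test_single_run_identity(self, small_env):
        surf = ensemble_mean([self._run(0.3)], small_env, 2001)
        sea = small_env.sea_mask
        assert np.allclose(surf.values[sea], 0.3)

    def test_mean_of_constant_runs(self, small_env):
        surf = ensemble_mean([self._run(0.2, replicate=1), self._run(0.8, replicate=2)], small_env, 2001)
        sea = small_env.sea_mask
        assert np.allclose(surf.values[sea], 0.5)

    def test_no_robust_runs_rejected(self, small_env):
        with pytest.raises(ValueError, match="robust"):
            ensemble_mean([self._run(0.5, robust=False)], small_env, 2001)

    def test_equal_weights_match_unweighted_mean(self, small_env):
        runs = [self._run(0.2, tss=0.5, replicate=1), self._run(0.8, tss=0.5, replicate=2)]
        cons = consensus(runs, small_env, 2001)
        sea = small_env.sea_mask
        assert np.allclose(cons.probability.values[sea], 0.5)

    def test_zero_weight_run_ignored(self, small_env):
        runs = [self._run(0.9, tss=0.8, replicate=1), self._run(0.1, tss=0.0, replicate=2)]
        cons = consensus(runs, small_env, 2001)
        sea = small_env.sea_mask
        assert np.allclose(cons.probability.values[sea], 0.9)

    def test_weights_sum_to_one(self, small_env):
        rng = np.random.default_rng(3)
        runs = [
            self._run(float(rng.random()), tss=float(rng.uniform(0.4, 1)), replicate=i)
            for i in range(1, 8)
        ]
        cons = consensus(runs, small_env, 2001)
        assert sum(cons.weights.values()) == pytest.approx(1.0, abs=1e-12)

    def test_consensus_within_member_envelope(self, small_env):
        runs = [self._run(0.2, tss=0.9, replicate=1), self._run(0.7, tss=0.5, replicate=2)]
        cons = consensus(runs, small_env, 2001)
        sea = small_env.sea_mask
        assert (cons.probability.values[sea] >= 0.2 - 1e-12).all()
        assert (cons.probability.values[sea] <= 0.7 + 1e-12).all()


class TestBinarize:
    def _prob(self, env, value):
        values = np.where(env.sea_mask, value, np.nan)
        from bioturb.grids import Surface

        return Surface(grid=env.grid, kind="probability", year=2001, species="sp", values=values)

    def test_boundary_value_counts_as_presence(self, small_env):
        binary = binarize(self._prob(small_env, 0.5), 0.5)
        assert np.all(binary.values[small_env.sea_mask] == 1)

    def test_cutoff_above_all_probabilities_gives_absence(self, small_env):
        binary = binarize(self._prob(small_env, 0.4), 1 - 1e-9)
        assert np.all(binary.values[small_env.sea_mask] == 0)

    def test_presence_count_non_increasing_in_cutoff(self, small_env):
        rng = np.random.default_rng(2)
        values = np.where(small_env.sea_mask, rng.random(small_env.grid.shape), np.nan)
        from bioturb.grids import Surface

        prob = Surface(grid=small_env.grid, kind="probability", year=2001, species="sp", values=values)
        counts = [np.nansum(binarize(prob, c).values) for c in (0.2, 0.4, 0.6, 0.8)]
        assert counts == sorted(counts, reverse=True)

    def test_land_stays_missing(self, small_env):
        binary = binarize(self._prob(small_env, 0.9), 0.5)
        assert np.isnan(binary.values[small_env.land_mask]).all()
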