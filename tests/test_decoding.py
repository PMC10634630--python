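import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, special, stats

from race_rsa import (
    DataError,
    PermutationConfig,
    SimilarityMatrix,
    auc_from_scores,
    auc_to_dprime,
    cohens_d,
    contrast_t_holm,
    holm_adjust,
    identity_decoding,
    max_stat_permutation,
    race_decoding,
    within_between_difference,
    within_class_score,
)
from tests.conftest import block_similarity, random_similarity


def auc_enumeration_oracle(scores, positive):
    """AUC by exhaustive positive x negative comparison (ties count 1/2)."""
    pos = [s for s, p in zip(scores, positive) if p]
    neg = [s for s, p in zip(scores, positive) if not p]
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in pos for b in neg)
    return wins / (len(pos) * len(neg))


def normal_quantile_oracle(q):
    """Invert the normal CDF numerically, independent of scipy.stats.norm.ppf."""
    return optimize.brentq(lambda x: special.ndtr(x) - q, -10, 10, xtol=1e-12)


class TestWithinClassScore:
    def test_block_matrix_scores(self, block_sm):
        scores = within_class_score(block_sm, "Asian")
        target = block_sm.race_labels == "Asian"
        # self excluded: target images average only the 0.8 off-diagonal entries
        np.testing.assert_allclose(scores[target], 0.8)
        np.testing.assert_allclose(scores[~target], 0.2)

    def test_matches_bruteforce_loop(self, random_sm):
        for race in ("Asian", "Black", "White"):
            scores = within_class_score(random_sm, race)
            for i in range(random_sm.n_images):
                vals = [random_sm.values[i, j] for j in range(random_sm.n_images)
                        if j != i and random_sm.race_labels[j] == race]
                assert scores[i] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_singleton_target_errors(self):
        sm = block_similarity(n_per_race=1, races=("A", "B", "B", "B"))
        with pytest.raises(DataError, match="single image"):
            within_class_score(sm, "A")


class TestAuc:
    def test_examples(self):
        assert auc_from_scores([3, 1, 2, 0], [True, True, False, False]) == 0.75
        assert auc_from_scores([5, 5, 5, 5], [True, False, True, False]) == 0.5
        assert auc_from_scores([2, 3, 0, 1], [True, True, False, False]) == 1.0

    def test_single_class_errors(self):
        with pytest.raises(DataError):
            auc_from_scores([1.0, 2.0], [True, True])

    @settings(derandomize=True, max_examples=200)
    @given(
        scores=st.lists(st.integers(-3, 3), min_size=2, max_size=12),
        data=st.data(),
    )
    def test_equals_enumeration_oracle(self, scores, data):
        n = len(scores)
        positive = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda m: any(m) and not all(m)
            )
        )
        auc = auc_from_scores(np.asarray(scores, float), np.asarray(positive))
        assert auc == pytest.approx(auc_enumeration_oracle(scores, positive), abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        for _ in range(20):
            scores = rng.integers(0, 5, size=10).astype(float)
            mask = rng.random(10) < 0.5
            if mask.all() or not mask.any():
                continue
            assert auc_from_scores(scores, mask) == pytest.approx(
                roc_auc_score(mask, scores), abs=1e-12
            )


class TestDprime:
    def test_chance_is_exactly_zero(self):
        assert auc_to_dprime(0.5) == 0.0

    @pytest.mark.parametrize("auc,expected", [(0.75, 0.9539), (0.9, 1.8124)])
    def test_against_numeric_inversion(self, auc, expected):
        d = auc_to_dprime(auc)
        assert d == pytest.approx(np.sqrt(2) * normal_quantile_oracle(auc), abs=1e-8)
        assert d == pytest.approx(expected, abs=1e-4)

    def test_antisymmetric_and_increasing(self):
        grid = np.linspace(0.01, 0.99, 99)
        d = auc_to_dprime(grid)
        np.testing.assert_allclose(d, -auc_to_dprime(1.0 - grid), atol=1e-12)
        assert np.all(np.diff(d) > 0)

    def test_extremes_clip_by_class_size(self):
        d = auc_to_dprime(1.0, n_pos=4, n_neg=8)
        assert np.isfinite(d)
        assert d == pytest.approx(np.sqrt(2) * stats.norm.ppf(1 - 1 / 64))


class TestRaceIdentityDecoding:
    def test_planted_block_is_perfect(self, block_sm):
        res = race_decoding(block_sm, "Black")
        assert res.auc == 1.0
        assert res.dprime == pytest.approx(auc_to_dprime(1.0, n_pos=4, n_neg=8))

    def test_shuffled_labels_are_at_chance(self):
        # On exchangeable (unstructured) similarity, shuffling the race labels
        # collapses decoding to chance.  (On strongly block-structured
        # matrices the statistic has a finite-sample bias below 0.5: target
        # and non-target class means average different numbers of entries with
        # different conditional distributions, so only the exchangeable case
        # has E[AUC] = 1/2.)
        sm = random_similarity(n_images=30, n_features=25, seed=8)
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(1000):
            shuffled = SimilarityMatrix(
                values=sm.values,
                image_ids=sm.image_ids,
                race_labels=rng.permutation(sm.race_labels),
                identity_labels=sm.identity_labels,
            )
            aucs.append(race_decoding(shuffled, "Asian").auc)
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_race_decoding_matches_manual_recomputation(self, random_sm):
        res = race_decoding(random_sm, "White")
        scores = within_class_score(random_sm, "White")
        pos = random_sm.race_labels == "White"
        assert res.auc == pytest.approx(auc_enumeration_oracle(scores, pos), abs=1e-12)

    def test_identity_decoding(self):
        r = np.array([0.9, 0.9, 0.1, 0.1])
        res = identity_decoding(r, [True, True, False, False])
        assert res.auc == 1.0
        rng = np.random.default_rng(1)
        r = rng.standard_normal(9)
        flags = np.array([True] * 4 + [False] * 5)
        res = identity_decoding(r, flags)
        assert res.auc == pytest.approx(auc_enumeration_oracle(r, flags), abs=1e-12)


class TestMaxStatPermutation:
    def test_constant_matrix_gives_p_one(self):
        sm = block_similarity(4, within=0.5, between=0.5)
        p = max_stat_permutation(
            ([sm], "Asian"), PermutationConfig(n_perm=200, seed=0)
        )
        assert p[0] == 1.0

    def test_overwhelming_effect_hits_addone_floor(self):
        # 20 same pairs at high r, 20 different at low r; a permutation can
        # only reproduce the observed separation by recreating the exact split
        pair_r = np.concatenate([np.linspace(0.8, 0.9, 20), np.linspace(0.0, 0.1, 20)])
        flags = np.array([True] * 20 + [False] * 20)
        p = max_stat_permutation(
            (pair_r[None, :], flags),
            PermutationConfig(n_perm=999, seed=1, statistic="identity_dprime"),
        )
        assert p[0] == pytest.approx(1 / 1000)

    def test_reproducible_given_seed(self, random_sm):
        cfg = PermutationConfig(n_perm=99, seed=42)
        p1 = max_stat_permutation(([random_sm], "Asian"), cfg)
        p2 = max_stat_permutation(([random_sm], "Asian"), cfg)
        np.testing.assert_array_equal(p1, p2)

    def test_degenerate_labels_error(self):
        sm = block_similarity(4, races=("A",))
        with pytest.raises(DataError):
            max_stat_permutation(([sm], "A"), PermutationConfig(n_perm=10, seed=0))


class TestWithinBetween:
    def test_block_difference(self, block_sm):
        tab = within_between_difference(block_sm)
        np.testing.assert_allclose(tab["difference"], 0.6)

    def test_flat_matrix_difference_zero(self):
        tab = within_between_difference(block_similarity(3, within=0.4, between=0.4))
        np.testing.assert_allclose(tab["difference"], 0.0, atol=1e-12)

    def test_matches_loop_oracle(self, random_sm):
        tab = within_between_difference(random_sm)
        labels = random_sm.race_labels
        for row in tab.itertuples():
            i = list(random_sm.image_ids).index(row.image_id)
            own = [random_sm.values[i, j] for j in range(random_sm.n_images)
                   if j != i and labels[j] == labels[i]]
            other = [random_sm.values[i, j] for j in range(random_sm.n_images)
                     if labels[j] != labels[i]]
            assert row.within_mean == pytest.approx(np.mean(own), abs=1e-12)
            assert row.between_mean == pytest.approx(np.mean(other), abs=1e-12)


def holm_oracle(p):
    """Step-down Holm adjustment by direct enumeration of the definition."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


class TestHolmAndEffectSizes:
    def test_holm_worked_example(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.03, 0.04]), [0.03, 0.06, 0.06], atol=1e-12
        )

    def test_holm_single_test_unchanged(self):
        assert holm_adjust([0.2])[0] == pytest.approx(0.2)

    def test_holm_matches_oracle_and_is_monotone(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            p = rng.random(rng.integers(1, 20))
            adj = holm_adjust(p)
            np.testing.assert_allclose(adj, holm_oracle(p), atol=1e-12)
            assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_contrast_t_holm_within_greater_between(self):
        rng = np.random.default_rng(2)
        cells = {
            ("layer1", "Asian"): (rng.normal(1.0, 0.2, 10), rng.normal(0.0, 0.2, 10)),
            ("layer1", "White"): (rng.normal(0.0, 0.2, 10), rng.normal(0.0, 0.2, 10)),
        }
        tab = contrast_t_holm(cells, paired=True)
        assert set(tab["cell"]) == set(cells)
        assert (tab["p_holm"] >= tab["p_raw"]).all()
        assert tab.loc[tab["cell"] == ("layer1", "Asian"), "p_raw"].iloc[0] < 0.001

    def test_contrast_zero_variance_errors(self):
        with pytest.raises(DataError, match="zero-variance"):
            contrast_t_holm({"c": ([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])}, paired=True)

    def test_contrast_small_n_errors(self):
        with pytest.raises(DataError, match="n >= 3"):
            contrast_t_holm({"c": ([1.0, 2.0], [0.0, 1.0])}, paired=True)

    def test_cohens_d(self):
        assert cohens_d([2, 3, 4], [1, 1, 1], paired=True) == pytest.approx(2.0)
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True) == 0.0
        with pytest.raises(DataError):
            cohens_d([2, 3, 4], [1, 2, 3], paired=True)  # constant non-zero diff
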