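import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from freegait import (
    AnalysisWindow,
    SelectionError,
    TrainingError,
    WalkClassifier,
    build_walking_bouts,
    davies_bouldin_index,
    loso_cross_validate,
    select_features,
    select_probability_threshold,
    train_classifier,
)


def dbi_brute_force(values, labels):
    """Independent recomputation from the index definition."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    walk, rest = values[labels], values[~labels]
    m1 = sum(walk) / len(walk)
    m2 = sum(rest) / len(rest)
    if m1 == m2:
        return float("inf")
    s1 = sum(abs(v - m1) for v in walk) / len(walk)
    s2 = sum(abs(v - m2) for v in rest) / len(rest)
    return (s1 + s2) / abs(m1 - m2)


class TestDaviesBouldin:
    def test_zero_scatter(self):
        assert davies_bouldin_index([0, 0, 0, 1, 1, 1], [1, 1, 1, 0, 0, 0]) == 0.0

    def test_hand_computed(self):
        assert davies_bouldin_index([0, 2, 10, 12], [1, 1, 0, 0]) == pytest.approx(0.2)

    def test_coincident_centroids(self):
        assert davies_bouldin_index([0, 1, 0, 1], [1, 1, 0, 0]) == float("inf")

    def test_single_class_rejected(self):
        with pytest.raises(TrainingError):
            davies_bouldin_index([1, 2, 3], [1, 1, 1])

    def test_oracle_equivalence_random(self):
        gen = np.random.default_rng(42)
        for _ in range(100):
            n = int(gen.integers(4, 20))
            values = gen.normal(size=n)
            labels = np.zeros(n, dtype=bool)
            labels[: int(gen.integers(1, n))] = True
            gen.shuffle(labels)
            if labels.all() or not labels.any():
                continue
            got = davies_bouldin_index(values, labels)
            want = dbi_brute_force(values, labels)
            assert got == pytest.approx(want) or (np.isinf(got) and np.isinf(want))


class TestSelectFeatures:
    def make_matrix(self, seed=0, n=100):
        gen = np.random.default_rng(seed)
        y = np.arange(n) % 2 == 0
        return (
            pd.DataFrame(
                {
                    "separating": np.where(y, 0.0, 5.0) + gen.normal(0, 0.3, n),
                    "noise": gen.normal(size=n),
                }
            ),
            y,
        )

    def test_keeps_separating_drops_noise(self):
        matrix, y = self.make_matrix()
        assert select_features(matrix, y) == ["separating"]

    def test_infinite_threshold_keeps_all(self):
        matrix, y = self.make_matrix()
        kept = select_features(matrix, y, threshold=float("inf"))
        assert set(kept) == {"separating", "noise"}
        assert kept[0] == "separating"  # sorted ascending by DBI

    def test_zero_threshold_errors(self):
        matrix, y = self.make_matrix()
        with pytest.raises(SelectionError):
            select_features(matrix, y, threshold=0.0)


class TestTrainClassifier:
    def make_clouds(self, seed=0, n=200, gap=6.0):
        gen = np.random.default_rng(seed)
        y = np.repeat([True, False], n)
        x = pd.DataFrame(
            {
                "f1": np.where(y, 0.0, gap) + gen.normal(size=2 * n),
                "f2": gen.normal(size=2 * n),
            }
        )
        return x, y

    def test_separated_clouds_high_accuracy(self):
        x, y = self.make_clouds()
        model = train_classifier(x, y, seed=0)
        assert (model.predict(x) == y).mean() >= 0.99

    def test_single_class_errors(self):
        x, y = self.make_clouds()
        with pytest.raises(TrainingError):
            train_classifier(x, np.ones(len(x), dtype=bool))

    def test_duplicate_point_consistent(self):
        x, y = self.make_clouds(n=50)
        dup = pd.concat([x.iloc[[0]], x.iloc[[0]]], ignore_index=True)
        model = train_classifier(x, y, seed=0)
        preds = model.predict(dup)
        assert preds[0] == preds[1]

    def test_deterministic_given_seed(self):
        x, y = self.make_clouds(n=80)
        p1 = train_classifier(x, y, seed=5).predict_proba(x)
        p2 = train_classifier(x, y, seed=5).predict_proba(x)
        np.testing.assert_array_equal(p1, p2)

    def test_save_load_round_trip(self, tmp_path):
        x, y = self.make_clouds(n=60)
        model = train_classifier(x, y, seed=0)
        path = model.save(tmp_path / "model.pkl")
        back = WalkClassifier.load(path)
        np.testing.assert_array_equal(back.predict_proba(x), model.predict_proba(x))


def make_subject_dataset(n_subjects=5, n_per=40, gap=8.0, seed=0):
    gen = np.random.default_rng(seed)
    rows, ys, subs = [], [], []
    for s in range(n_subjects):
        y = gen.random(n_per) < 0.5
        rows.append(
            pd.DataFrame(
                {
                    "f1": np.where(y, 0.0, gap) + gen.normal(size=n_per),
                    "f2": gen.normal(size=n_per),
                }
            )
        )
        ys.append(y)
        subs.extend([f"S{s}"] * n_per)
    return pd.concat(rows, ignore_index=True), np.concatenate(ys), np.array(subs)


class TestLoso:
    def test_separable_is_perfect(self):
        x, y, subs = make_subject_dataset(gap=10.0)
        res = loso_cross_validate(x, y, subs)
        assert res.accuracy == 1.0
        assert res.auc == 1.0

    def test_label_shuffle_gives_chance_auc(self):
        x, y, subs = make_subject_dataset(gap=8.0, seed=1)
        gen = np.random.default_rng(9)
        res = loso_cross_validate(x, gen.permutation(y), subs)
        assert 0.4 <= res.auc <= 0.6

    def test_known_bayes_rate(self):
        # 1D equal-variance Gaussians at separation d: Bayes accuracy = Phi(d/2)
        from scipy.stats import norm

        d = 2 * norm.ppf(0.95)
        x, y, subs = make_subject_dataset(n_subjects=12, n_per=60, gap=d, seed=2)
        res = loso_cross_validate(x, y, subs)
        assert res.accuracy == pytest.approx(0.95, abs=0.03)

    def test_single_subject_rejected(self):
        x, y, subs = make_subject_dataset(n_subjects=1)
        with pytest.raises(TrainingError):
            loso_cross_validate(x, y, subs)

    def test_no_leakage_of_held_out_subject(self):
        # corrupting a held-out subject must not change that fold's model
        x, y, subs = make_subject_dataset(n_subjects=4, seed=3)
        probe = x.iloc[:20]
        clean = loso_cross_validate(x, y, subs)
        for victim in ("S0", "S2"):
            poisoned = x.copy()
            poisoned.loc[subs == victim] = poisoned.loc[subs == victim] * 100 + 7
            res = loso_cross_validate(poisoned, y, subs)
            np.testing.assert_array_equal(
                clean.fold_models[victim].predict_proba(probe),
                res.fold_models[victim].predict_proba(probe),
            )

    def test_per_subject_confusions_account_for_all(self):
        x, y, subs = make_subject_dataset(n_subjects=4)
        res = loso_cross_validate(x, y, subs)
        assert sum(c.sum() for c in res.per_subject_confusion.values()) == len(y)


class TestProbabilityThreshold:
    def test_perfect_point(self):
        roc = (np.array([0.0, 0.3, 1.0]), np.array([0.0, 1.0, 1.0]), np.array([0.9, 0.5, 0.1]))
        assert select_probability_threshold(roc) == 0.5

    def test_hand_computed_distances(self):
        roc = (np.array([0.0, 0.2, 1.0]), np.array([0.0, 0.9, 1.0]), np.array([0.9, 0.5, 0.1]))
        assert select_probability_threshold(roc) == 0.5

    def test_tie_breaks_high(self):
        # both points at distance 0.25 from (0, 1); exact in binary floats
        roc = (np.array([0.0, 0.25]), np.array([0.75, 1.0]), np.array([0.8, 0.4]))
        assert select_probability_threshold(roc) == 0.8

    def test_order_invariance(self):
        gen = np.random.default_rng(3)
        fpr = np.sort(gen.random(10))
        tpr = np.sort(gen.random(10))
        thr = gen.random(10)
        base = select_probability_threshold((fpr, tpr, thr))
        perm = gen.permutation(10)
        assert select_probability_threshold((fpr[perm], tpr[perm], thr[perm])) == base

    def test_oracle_equivalence_random(self):
        gen = np.random.default_rng(7)
        for _ in range(100):
            n = int(gen.integers(2, 15))
            fpr, tpr, thr = gen.random(n), gen.random(n), gen.random(n)
            got = select_probability_threshold((fpr, tpr, thr))
            # brute force: scan every point
            best = None
            for i in range(n):
                d = np.hypot(fpr[i], 1 - tpr[i])
                if best is None or d < best[0] - 1e-15 or (abs(d - best[0]) <= 1e-15 and thr[i] > best[1]):
                    best = (d, thr[i])
            assert got == pytest.approx(best[1])


def make_windows(n):
    return [AnalysisWindow(index=i, start=4.0 * i, end=4.0 * (i + 1), accel={}) for i in range(n)]


class TestBuildWalkingBouts:
    def test_wwnw_fixture(self):
        labels = [True, True, False, True]
        post = [0.9, 0.85, 0.95, 0.99]
        bouts, walk_s = build_walking_bouts(labels, post, make_windows(4))
        assert len(bouts) == 1
        assert bouts[0].window_indices == [0, 1]
        assert walk_s == 8.0

    def test_low_posterior_breaks_bout(self):
        bouts, walk_s = build_walking_bouts([True, True], [0.9, 0.7], make_windows(2))
        assert bouts == []
        assert walk_s == 0.0

    def test_long_run_merges(self):
        bouts, walk_s = build_walking_bouts(
            [True] * 10, [0.9] * 10, make_windows(10)
        )
        assert len(bouts) == 1
        assert walk_s == 40.0
        assert bouts[0].duration == pytest.approx(40.0)

    def test_walking_time_formula(self):
        labels = [True, True, False, True, True, True, False]
        post = [0.9] * 7
        bouts, walk_s = build_walking_bouts(labels, post, make_windows(7))
        assert walk_s == 4.0 * sum(b.n_windows for b in bouts)
        assert [b.window_indices for b in bouts] == [[0, 1], [3, 4, 5]]

    def test_idempotent_and_ordered(self):
        labels = [True, True, False, True, True]
        post = [0.95, 0.85, 0.9, 0.9, 0.9]
        first = build_walking_bouts(labels, post, make_windows(5))
        second = build_walking_bouts(labels, post, make_windows(5))
        assert [b.window_indices for b in first[0]] == [b.window_indices for b in second[0]]
        starts = [b.start for b in first[0]]
        assert starts == sorted(starts)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_all_bouts_meet_rules_property(self, seed):
        gen = np.random.default_rng(seed)
        n = int(gen.integers(1, 30))
        labels = gen.random(n) < 0.6
        post = gen.random(n)
        bouts, walk_s = build_walking_bouts(labels, post, make_windows(n))
        for b in bouts:
            assert b.n_windows >= 2
            assert all(p >= 0.8 for p in b.posteriors)
            idx = b.window_indices
            assert idx == list(range(idx[0], idx[-1] + 1))
        assert walk_s == 4.0 * sum(b.n_windows for b in bouts)
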