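"""MI ranking, cross-validated random forests and rank-sum comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import f1_score

from affecteeg import model as md

FAST_CV = md.CVConfig(n_trees=50, seed=0)


def make_dataset(rng, n=300, signal=2.0, n_noise=3, prefix="f"):
    y = np.array(["a", "b"])[rng.integers(0, 2, n)]
    X = pd.DataFrame({f"{prefix}_sig": (y == "a") * signal
                      + rng.standard_normal(n)})
    for i in range(n_noise):
        X[f"{prefix}_n{i}"] = rng.standard_normal(n)
    return X, y


class TestMutualInformation:
    def test_label_copy_ranked_first_with_h_y(self, rng):
        y = rng.integers(0, 2, 1000)
        X = pd.DataFrame({
            "noise": rng.standard_normal(1000),
            "copy": y.astype(float),
        })
        ranked = md.mi_rank(X, y)
        assert ranked[0] == "copy"
        p = y.mean()
        h_y = -p * np.log(p) - (1 - p) * np.log(1 - p)
        assert md.mutual_information(X["copy"].to_numpy(), y) == pytest.approx(
            h_y, rel=1e-9)

    def test_independent_feature_near_zero(self, rng):
        n = 10_000
        y = rng.integers(0, 2, n)
        noise = rng.standard_normal(n)
        informative = y + 0.5 * rng.standard_normal(n)
        mi_noise = md.mutual_information(noise, y)
        # permutation baseline for estimator bias
        baseline = np.mean([
            md.mutual_information(noise, rng.permutation(y)) for _ in range(10)])
        assert mi_noise < baseline + 3 * 0.001
        assert md.mutual_information(informative, y) > 10 * mi_noise

    def test_monotone_transform_invariance(self, rng):
        y = rng.integers(0, 2, 500)
        x = rng.standard_normal(500)
        mi = md.mutual_information(x, y)
        assert md.mutual_information(np.exp(x), y) == pytest.approx(mi, abs=1e-12)
        assert md.mutual_information(3 * x - 7, y) == pytest.approx(mi, abs=1e-12)

    def test_constant_feature_zero(self):
        assert md.mutual_information(np.ones(100), np.arange(100) % 2) == 0.0


class TestRunCV:
    def test_separable_dataset_perfect_f1(self, rng):
        y = np.array(["a", "b"])[rng.integers(0, 2, 200)]
        X = pd.DataFrame({
            "sep": (y == "a") * 10.0,
            "noise": rng.standard_normal(200),
        })
        rep = md.run_cv(X, y, "valence", "single", FAST_CV)
        assert rep.mean_f1 == 1.0
        lo, hi = rep.ci95
        assert lo <= rep.mean_f1 <= hi

    def test_fold_sizes_differ_by_at_most_one(self, rng):
        y = np.array(["a", "b"])[rng.integers(0, 2, 103)]
        sizes = [len(te) for _, te in md._folds(y, FAST_CV)]
        assert max(sizes) - min(sizes) <= 1

    def test_permuted_labels_chance_level(self):
        rng = np.random.default_rng(2024)
        X, y = make_dataset(rng, n=400)
        means = []
        for rep in range(20):
            y_perm = rng.permutation(y)
            r = md.run_cv(X, y_perm, "valence", "single",
                          md.CVConfig(n_trees=50, seed=rep))
            means.append(r.mean_f1)
        assert 0.45 <= np.mean(means) <= 0.55

    def test_single_class_rejected(self, rng):
        X, _ = make_dataset(rng, n=50)
        with pytest.raises(ValueError, match="single class"):
            md.run_cv(X, np.repeat("a", 50), "valence", "single", FAST_CV)

    def test_missing_values_rejected(self, rng):
        X, y = make_dataset(rng, n=50)
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            md.run_cv(X, y, "valence", "single", FAST_CV)

    def test_in_fold_selection_avoids_leakage_inflation(self):
        """Selecting features on the full dataset inflates F1 on pure
        noise; the wired-in in-fold path stays at chance."""
        rng = np.random.default_rng(12345)
        n, p = 60, 300
        y = np.array(["a", "b"])[np.arange(n) % 2]
        X = pd.DataFrame(rng.standard_normal((n, p)),
                         columns=[f"f{i}" for i in range(p)])
        cfg = md.CVConfig(n_trees=50, seed=1)
        honest = md.run_cv(X, y, "valence", "single", cfg).mean_f1
        # leaky alternative: rank once on everything, then CV on the top set
        top = md.mi_rank(X, y)[: cfg.n_top]
        leaky = md.run_cv(X[top], y, "valence", "single", cfg).mean_f1
        assert leaky > honest + 0.1
        assert honest < 0.65

    def test_weighted_f1_matches_confusion_matrix_formula(self, rng):
        """Constant predictor on unbalanced labels: weighted F1 equals the
        closed-form support-weighted harmonic mean."""
        y_true = np.array(["a"] * 70 + ["b"] * 30)
        y_pred = np.repeat("a", 100)
        # class a: precision 0.7, recall 1 -> F1 = 2*.7/1.7; class b: 0
        expected = 0.7 * (2 * 0.7 / 1.7) + 0.3 * 0.0
        assert f1_score(y_true, y_pred, average="weighted") == pytest.approx(expected)


class TestRunCombined:
    def test_disjoint_top_sets_union_30(self, rng):
        n = 200
        y = np.array(["a", "b"])[rng.integers(0, 2, n)]
        fams = {}
        for fam in ("single", "pair", "mse"):
            fams[fam] = pd.DataFrame(
                rng.standard_normal((n, 10)),
                columns=[f"{fam}_{i}" for i in range(10)])
        rep = md.run_combined(fams, y, "valence", FAST_CV)
        assert all(len(sel) == 30 for sel in rep.selected)

    def test_split_signal_combined_not_worse(self, rng):
        """Signal split across two families: combined within 0.02 of the
        best individual family, averaged over seeds."""
        diffs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 240
            y = np.array(["a", "b"])[r.integers(0, 2, n)]
            half = (y == "a") * 1.0
            fams = {
                "power": pd.DataFrame({
                    "p_sig": half + r.standard_normal(n),
                    "p_n": r.standard_normal(n)}),
                "entropy": pd.DataFrame({
                    "e_sig": half + r.standard_normal(n),
                    "e_n": r.standard_normal(n)}),
            }
            cfg = md.CVConfig(n_trees=50, seed=seed, n_top=2)
            best = max(
                md.run_cv(fams[f], y, "valence", f, cfg).mean_f1 for f in fams)
            comb = md.run_combined(fams, y, "valence", cfg).mean_f1
            diffs.append(comb - best)
        assert np.mean(diffs) >= -0.02

    def test_uninformative_family_tolerated(self, rng):
        f1s = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            X, y = make_dataset(r, n=240, signal=3.0)
            dead = pd.DataFrame(r.standard_normal((240, 5)),
                                columns=[f"d{i}" for i in range(5)])
            cfg = md.CVConfig(n_trees=50, seed=seed, n_top=3)
            single = md.run_cv(X, y, "valence", "single", cfg).mean_f1
            comb = md.run_combined({"s": X, "dead": dead}, y, "valence",
                                   cfg).mean_f1
            f1s.append((single, comb))
        s_mean = np.mean([s for s, _ in f1s])
        c_mean = np.mean([c for _, c in f1s])
        assert abs(c_mean - s_mean) < 0.05

    def test_mismatched_keys_rejected(self, rng):
        a = pd.DataFrame({"x": rng.standard_normal(10)})
        b = pd.DataFrame({"y": rng.standard_normal(10)}, index=range(1, 11))
        with pytest.raises(ValueError, match="row keys"):
            md.run_combined({"a": a, "b": b}, np.repeat(["u", "v"], 5),
                            "valence", FAST_CV)


def ranksum_enumeration(a, b):
    """Exact one-sided p: P(rank sum of a >= observed) over all splits."""
    pooled = list(a) + list(b)
    ranks = stats.rankdata(pooled)
    obs = ranks[: len(a)].sum()
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), len(a)):
        total += 1
        if ranks[list(idx)].sum() >= obs:
            count += 1
    return count / total


class TestCompareReports:
    @staticmethod
    def _rep(scores, family="x"):
        return md.ModelReport("arousal", family, list(scores))

    def test_fully_separated_five_vs_five(self):
        a = self._rep([0.9] * 5)
        b = self._rep([0.5] * 5)
        assert md.compare_reports(a, b) == pytest.approx(1 / 252, rel=1e-6)

    def test_identical_samples(self):
        a = self._rep([0.7, 0.7, 0.7, 0.7, 0.7])
        assert md.compare_reports(a, a) >= 0.5

    def test_exact_matches_enumeration_4v4(self, rng):
        for _ in range(5):
            a = self._rep(rng.uniform(0.4, 0.9, 4))
            b = self._rep(rng.uniform(0.4, 0.9, 4))
            assert md.compare_reports(a, b) == pytest.approx(
                ranksum_enumeration(a.fold_f1, b.fold_f1), abs=1e-12)

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError, match="3 fold"):
            md.compare_reports(self._rep([0.5, 0.6]), self._rep([0.4] * 5))
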