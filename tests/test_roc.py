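"""ROC machinery: curve construction, AUC oracles, cutoffs and intervals."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cmets.roc import (
    YoudenCutpoint,
    auc,
    bootstrap_cutoff_ci,
    confidence_intervals,
    delong_auc_ci,
    optimal_cutoff,
    roc_curve,
    stratified_validation,
    wald_ci,
)


def brute_force_auc(scores, labels):
    """Pair-counting oracle: concordant pairs + half the ties, over all pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))


def brute_force_cutoff(scores, labels):
    """Exhaustive scan over every unique score for the max sens+spec threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    best_t, best_j = None, -np.inf
    for t in np.unique(scores):
        sens = (scores[labels == 1] >= t).mean()
        spec = (scores[labels == 0] < t).mean()
        if sens + spec > best_j + 1e-12:
            best_j, best_t = sens + spec, t
    return best_t


def _random_instance(rng, max_n=20):
    while True:
        n = rng.integers(4, max_n + 1)
        scores = rng.integers(0, 6, n) / 2.0  # coarse grid: ties are common
        labels = rng.integers(0, 2, n)
        if 0 < labels.sum() < n:
            return scores, labels


class TestRocCurve:
    def test_perfect_separation(self):
        c = roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        i = np.where(c.thresholds == 3)[0][0]
        assert c.sensitivity[i] == 1.0 and c.specificity[i] == 1.0
        assert auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_endpoints(self):
        c = roc_curve([0.2, 0.5, 0.9, 0.4], [0, 1, 1, 0])
        assert (c.sensitivity[0], c.specificity[0]) == (1.0, 0.0)
        assert (c.sensitivity[-1], c.specificity[-1]) == (0.0, 1.0)

    def test_all_tied_scores_degenerate_curve(self):
        c = roc_curve([2, 2, 2, 2], [0, 1, 0, 1])
        assert len(c.thresholds) == 2  # the tied value and the sentinel
        assert (c.sensitivity[0], c.specificity[0]) == (1.0, 0.0)
        assert (c.sensitivity[-1], c.specificity[-1]) == (0.0, 1.0)
        assert auc([2, 2, 2, 2], [0, 1, 0, 1]) == 0.5

    def test_monotone_operating_points(self):
        rng = np.random.default_rng(0)
        s, y = _random_instance(rng)
        c = roc_curve(s, y)
        assert np.all(np.diff(c.sensitivity) <= 0)
        assert np.all(np.diff(c.specificity) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="positive and"):
            roc_curve([1, 2, 3], [1, 1, 1])


class TestAucOracles:
    def test_exhaustive_three_vs_three(self):
        """Every arrangement of 3 positives among scores 1..6 matches pair counting."""
        scores = np.arange(1, 7, dtype=float)
        for pos_idx in itertools.combinations(range(6), 3):
            labels = np.zeros(6, dtype=int)
            labels[list(pos_idx)] = 1
            assert auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-15
            )

    def test_random_instances_with_ties(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            s, y = _random_instance(rng)
            a = auc(s, y)
            assert a == pytest.approx(brute_force_auc(s, y), abs=1e-12)
            assert roc_curve(s, y).trapezoid_auc() == pytest.approx(a, abs=1e-12)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(7)
        s = rng.normal(size=2000)
        y = rng.integers(0, 2, 2000)
        assert auc(s, y) == pytest.approx(0.5, abs=0.03)

    def test_label_swap_reflects_auc(self):
        rng = np.random.default_rng(5)
        s, y = _random_instance(rng)
        assert auc(s, 1 - y) == pytest.approx(1.0 - auc(s, y), abs=1e-12)

    def test_against_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(13)
        for _ in range(50):
            s, y = _random_instance(rng)
            assert auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(st.data())
    def test_auc_invariant_under_monotone_transform(self, data):
        n = data.draw(st.integers(4, 15))
        s = np.array(data.draw(st.lists(
            st.integers(0, 8), min_size=n, max_size=n)), dtype=float)
        y = np.array(data.draw(st.lists(
            st.integers(0, 1), min_size=n, max_size=n)))
        if y.sum() in (0, n):
            return
        t = np.exp(s / 4.0) + 2.0 * s  # strictly increasing
        assert auc(t, y) == pytest.approx(auc(s, y), abs=1e-12)


class TestOptimalCutoff:
    def test_perfect_split(self):
        assert optimal_cutoff([1, 2, 3, 4], [0, 0, 1, 1]) == 3.0

    def test_tie_broken_to_smallest_threshold(self):
        s = [1, 2, 3, 4, 5, 6]
        y = [0, 1, 0, 1, 0, 1]  # thresholds 2, 4, 6 all reach sens+spec = 4/3
        assert optimal_cutoff(s, y) == 2.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(99)
        for _ in range(500):
            s, y = _random_instance(rng)
            assert optimal_cutoff(s, y) == brute_force_cutoff(s, y)

    def test_dominates_every_listed_threshold(self):
        rng = np.random.default_rng(17)
        s, y = _random_instance(rng)
        c = roc_curve(s, y)
        t = optimal_cutoff(c)
        i = np.where(c.thresholds == t)[0][0]
        best = c.sensitivity[i] + c.specificity[i]
        finite = np.isfinite(c.thresholds)
        assert best >= (c.sensitivity[finite] + c.specificity[finite]).max() - 1e-12

    def test_maps_through_monotone_transform(self):
        rng = np.random.default_rng(23)
        s, y = _random_instance(rng)
        t = optimal_cutoff(s, y)
        assert optimal_cutoff(2.0 * s + 1.0, y) == pytest.approx(2.0 * t + 1.0)

    def test_all_tied_scores_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            optimal_cutoff([3, 3, 3], [0, 1, 0])


class TestIntervals:
    def test_wald_half_width(self):
        lo, hi = wald_ci(0.5, 100)
        assert hi - lo == pytest.approx(2 * 0.0979981992, abs=1e-6)

    def test_wald_clipped(self):
        lo, hi = wald_ci(1.0, 50)
        assert (lo, hi) == (1.0, 1.0)

    def test_delong_matches_pROC_reference(self):
        # frozen output of an independent DeLong implementation (R pROC)
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.55, 0.9, 0.25, 0.7, 0.65, 0.3,
                           0.45, 0.5, 0.5, 0.85, 0.15, 0.6, 0.75, 0.2, 0.95, 0.05])
        labels = np.array([0, 0, 1, 1, 0, 1, 0, 1, 1, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1, 0])
        a, ci, var = delong_auc_ci(scores, labels)
        assert a == pytest.approx(0.905, abs=1e-12)
        assert var == pytest.approx(0.004272222222, abs=1e-10)
        assert ci[0] == pytest.approx(0.776892366584, abs=1e-9)
        assert ci[1] == 1.0

    def test_bootstrap_seeded_determinism(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=400)
        y = (s + rng.normal(size=400) > 0).astype(int)
        a = bootstrap_cutoff_ci(s, y, B=250, seed=42)
        b = bootstrap_cutoff_ci(s, y, B=250, seed=42)
        assert a == b
        c = bootstrap_cutoff_ci(s, y, B=250, seed=43)
        assert a != c

    def test_bootstrap_requires_enough_replicates(self):
        with pytest.raises(ValueError, match="at least 200"):
            bootstrap_cutoff_ci([1, 2, 3, 4], [0, 0, 1, 1], B=50)

    def test_boundary_and_unstable_flags(self):
        s = np.concatenate([np.zeros(50), np.ones(5)])
        y = np.concatenate([np.zeros(50, int), np.ones(5, int)])
        res = confidence_intervals(s, y, B=250, seed=1)
        assert res.sensitivity == 1.0
        assert res.sensitivity_ci == (1.0, 1.0)
        assert "boundary" in res.flags and "unstable" in res.flags


class TestStratifiedValidation:
    def test_layout_twelve_rows(self, scored50k):
        res = stratified_validation(scored50k.iloc[:20_000], B=250, seed=5)
        names = [r.stratum for r in res]
        assert len(names) == 12
        assert names[-3:] == ["7-18/male", "7-18/female", "7-18/total"]
        assert sum(n.endswith("/total") for n in names) == 4

    def test_construction_gives_strong_discrimination(self, scored50k):
        """Score and label share components, so every stratum separates well."""
        res = stratified_validation(scored50k, B=250, seed=5)
        for r in res:
            assert r.auc > 0.85

    def test_single_class_stratum_emits_placeholder(self):
        rng = np.random.default_rng(1)
        n = 600
        df = pd.DataFrame({
            "age": rng.uniform(7, 11, n),  # one band only
            "sex": ["male"] * (n // 2) + ["female"] * (n // 2),
            "cmets": rng.normal(size=n),
        })
        df["mets"] = (df["cmets"] > 1.2).astype(int)
        df.loc[df["sex"] == "female", "mets"] = 0  # girls: single class
        res = stratified_validation(df, B=250, seed=2)
        by_name = {r.stratum: r for r in res}
        assert "single_class" in by_name["7-10/female"].flags
        assert np.isnan(by_name["7-10/female"].auc)
        assert by_name["7-10/male"].auc > 0.5


class TestYoudenCutpoint:
    def test_fit_predict_round_trip(self):
        rng = np.random.default_rng(8)
        s = rng.normal(size=500)
        y = (s + rng.normal(scale=0.5, size=500) > 0.5).astype(int)
        est = YoudenCutpoint(B=250, seed=9).fit(s, y)
        pred = est.predict(np.array([est.cutoff_ - 1e-9, est.cutoff_]))
        assert list(pred) == [0, 1]  # inclusive at the threshold
        assert 0.5 < est.auc_ <= 1.0
        assert est.result_.cutoff == est.cutoff_

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = YoudenCutpoint(B=300, seed=4, compute_ci=False)
        assert clone(est).get_params() == est.get_params()

    def test_balanced_accuracy_score(self):
        s = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([0, 0, 1, 1])
        est = YoudenCutpoint(compute_ci=False).fit(s, y)
        assert est.score(s, y) == 1.0
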