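"""Visual Turing-test statistics: rates, Fleiss' kappa, confidence AUC."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats import inter_rater

from ecgforge.turing import (
    RatingTableError,
    accuracy_metrics,
    confidence_auc,
    fleiss_kappa,
    load_ratings,
    signed_scores,
    turing_summary,
)


def make_table(rows):
    return pd.DataFrame(rows, columns=["item_id", "truth", "rater_id", "vote", "confidence"])


def simulated_table(n_items, n_raters, rng, p_correct=0.5):
    rows = []
    for i in range(n_items):
        truth = "real" if i % 2 == 0 else "synthetic"
        other = "synthetic" if truth == "real" else "real"
        for r in range(n_raters):
            vote = truth if rng.random() < p_correct else other
            rows.append((f"item{i}", truth, f"rater{r}", vote, int(rng.integers(1, 6))))
    return make_table(rows)


class TestAccuracyMetrics:
    def test_all_correct_gives_unit_rates(self):
        rows = [(f"i{k}", t, "r0", t, 3)
                for k, t in enumerate(["real"] * 5 + ["synthetic"] * 5)]
        out = accuracy_metrics(make_table(rows))
        assert out["accuracy"].point == 1.0
        assert out["true_recognition_rate"].point == 1.0
        assert out["false_recognition_rate"].point == 1.0

    def test_hand_counted_single_rater_round(self):
        """30 real (20 correct) + 30 synthetic (12 correct): accuracy 32/60,
        TRR 20/30, FRR 12/30 -- counted by hand."""
        rows = []
        for i in range(30):
            vote = "real" if i < 20 else "synthetic"
            rows.append((f"re{i}", "real", "r0", vote, 3))
        for i in range(30):
            vote = "synthetic" if i < 12 else "real"
            rows.append((f"sy{i}", "synthetic", "r0", vote, 3))
        out = accuracy_metrics(make_table(rows))
        assert out["accuracy"].point == pytest.approx(32 / 60)
        assert out["true_recognition_rate"].point == pytest.approx(20 / 30)
        assert out["false_recognition_rate"].point == pytest.approx(12 / 30)
        acc = out["accuracy"]
        assert acc.ci_low <= acc.point <= acc.ci_high
        # Wald interval: p +- 1.96 sqrt(pq/n)
        p = 32 / 60
        half = 1.959963984540054 * np.sqrt(p * (1 - p) / 60)
        assert acc.ci_low == pytest.approx(p - half, abs=1e-9)
        assert acc.ci_high == pytest.approx(p + half, abs=1e-9)

    def test_truth_independent_votes_hover_at_half(self):
        """Votes independent of truth give accuracy ~ 0.5 on average."""
        rng = np.random.default_rng(0)
        accs = [
            accuracy_metrics(simulated_table(40, 2, rng))["accuracy"].point
            for _ in range(50)
        ]
        assert np.mean(accs) == pytest.approx(0.5, abs=0.03)

    def test_accuracy_is_response_weighted_mean_of_trr_frr(self):
        rng = np.random.default_rng(3)
        table = simulated_table(31, 3, rng, p_correct=0.7)
        out = accuracy_metrics(table)
        trr, frr = out["true_recognition_rate"], out["false_recognition_rate"]
        pooled = (trr.point * trr.n + frr.point * frr.n) / (trr.n + frr.n)
        assert out["accuracy"].point == pytest.approx(pooled, abs=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(RatingTableError):
            accuracy_metrics(make_table([]))


class TestFleissKappa:
    def test_unanimous_raters_kappa_one(self):
        rows = []
        for i in range(6):
            vote = "real" if i % 2 == 0 else "synthetic"
            for r in range(4):
                rows.append((f"i{i}", "real", f"r{r}", vote, 3))
        est = fleiss_kappa(make_table(rows))
        assert est.point == pytest.approx(1.0)

    def test_null_simulation_near_zero(self):
        """i.i.d. uniform votes, 200 items x 10 raters -> kappa within 0.05 of 0."""
        rng = np.random.default_rng(42)
        table = simulated_table(200, 10, rng)
        est = fleiss_kappa(table)
        assert abs(est.point) <= 0.05
        assert est.ci_low <= est.point <= est.ci_high

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(7)
        table = simulated_table(24, 5, rng, p_correct=0.8)
        counts = table.pivot_table(
            index="item_id", columns="vote", aggfunc="size", fill_value=0
        ).to_numpy()
        expected = inter_rater.fleiss_kappa(counts, method="fleiss")
        assert fleiss_kappa(table).point == pytest.approx(expected, abs=1e-12)

    def test_matches_exhaustive_pairwise_oracle(self):
        """Chance-corrected mean pairwise agreement, counted pair by pair."""
        rng = np.random.default_rng(11)
        table = simulated_table(6, 3, rng, p_correct=0.6)
        votes = {
            item: list(grp["vote"])
            for item, grp in table.groupby("item_id")
        }
        agree = []
        all_votes = []
        for vs in votes.values():
            pairs = list(itertools.combinations(vs, 2))
            agree.append(np.mean([a == b for a, b in pairs]))
            all_votes.extend(vs)
        p_obs = np.mean(agree)
        p_real = np.mean([v == "real" for v in all_votes])
        p_exp = p_real**2 + (1 - p_real) ** 2
        oracle = (p_obs - p_exp) / (1 - p_exp)
        assert fleiss_kappa(table).point == pytest.approx(oracle, abs=1e-12)

    def test_two_raters_bruteforce_agreement(self):
        rows = []
        pattern = ["real", "synthetic", "real", "real", "synthetic"]
        for i, v in enumerate(pattern):
            rows.append((f"i{i}", "real", "a", v, 3))
            rows.append((f"i{i}", "real", "b", v if i != 4 else "real", 3))
        table = make_table(rows)
        est = fleiss_kappa(table)
        counts = table.pivot_table(
            index="item_id", columns="vote", aggfunc="size", fill_value=0
        ).to_numpy()
        expected = inter_rater.fleiss_kappa(counts, method="fleiss")
        assert est.point == pytest.approx(expected, abs=1e-12)

    def test_degenerate_single_category_rejected(self):
        rows = [(f"i{k}", "real", f"r{r}", "real", 3)
                for k in range(5) for r in range(3)]
        with pytest.raises(RatingTableError, match="one category"):
            fleiss_kappa(make_table(rows))

    def test_unbalanced_rater_counts_are_subset_with_warning(self):
        rows = [(f"i{k}", "real", f"r{r}", ["real", "synthetic"][k % 2], 3)
                for k in range(6) for r in range(3)]
        rows.append(("i0", "real", "r9", "real", 3))  # 4th rating on one item
        with pytest.warns(UserWarning, match="dropping"):
            fleiss_kappa(make_table(rows))


class TestConfidenceAUC:
    def test_separable_scores_auc_one(self):
        rows = []
        for i in range(8):
            rows.append((f"re{i}", "real", "r0", "real", 4))
        for i in range(8):
            rows.append((f"sy{i}", "synthetic", "r0", "synthetic", 4))
        est = confidence_auc(make_table(rows))
        assert est.point == 1.0

    def test_four_response_exhaustive_pair_count(self):
        """Signed scores (+5, +1, -1, -5) vs truths (R, R, S, S): all 4
        real-synthetic pairs concordant -> AUC 1.0."""
        rows = [
            ("a", "real", "r0", "real", 5),
            ("b", "real", "r0", "real", 1),
            ("c", "synthetic", "r0", "synthetic", 1),
            ("d", "synthetic", "r0", "synthetic", 5),
        ]
        est = confidence_auc(make_table(rows))
        assert est.point == pytest.approx(1.0)

    def test_truth_independent_scores_near_half(self):
        rng = np.random.default_rng(1)
        table = simulated_table(300, 4, rng)  # votes independent of truth
        est = confidence_auc(table)
        assert est.point == pytest.approx(0.5, abs=0.05)
        assert est.ci_low <= est.point <= est.ci_high

    def test_below_half_auc_not_flipped(self):
        rows = []
        for i in range(6):
            rows.append((f"re{i}", "real", "r0", "synthetic", 4))
            rows.append((f"sy{i}", "synthetic", "r0", "real", 4))
        est = confidence_auc(make_table(rows))
        assert est.point == 0.0

    def test_missing_confidence_rejected(self):
        rows = [("a", "real", "r0", "real", None),
                ("b", "synthetic", "r0", "real", 3)]
        with pytest.raises(RatingTableError, match="confidence"):
            confidence_auc(make_table(rows))

    def test_signed_score_mapping(self):
        rows = [("a", "real", "r0", "real", 5),
                ("b", "synthetic", "r0", "synthetic", 2)]
        score, y = signed_scores(make_table(rows))
        assert list(score) == [5.0, -2.0]
        assert list(y) == [True, False]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(1, 5), min_size=4, max_size=20))
    def test_auc_invariant_under_monotone_transform(self, confs):
        """AUC depends only on score ranks, so any strictly increasing
        transform of the signed score leaves it unchanged."""
        from scipy import stats

        rng = np.random.default_rng(len(confs))
        votes = rng.integers(0, 2, len(confs))
        truths = np.array(["real", "synthetic"])[
            np.r_[np.zeros(len(confs) // 2, int), np.ones(len(confs) - len(confs) // 2, int)]
        ]
        rows = [
            (f"i{k}", truths[k], "r0", ["real", "synthetic"][votes[k]], confs[k])
            for k in range(len(confs))
        ]
        table = make_table(rows)
        score, y = signed_scores(table)
        if y.all() or not y.any():
            return

        def auc(s):
            ranks = stats.rankdata(s)
            n1, n0 = y.sum(), (~y).sum()
            return (ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

        assert auc(np.exp(score)) == pytest.approx(auc(score), abs=1e-12)
        assert confidence_auc(table).point == pytest.approx(auc(score), abs=1e-12)


class TestTableValidation:
    def test_duplicate_item_rater_rejected(self):
        rows = [("a", "real", "r0", "real", 3), ("a", "real", "r0", "synthetic", 2)]
        with pytest.raises(RatingTableError, match="duplicate"):
            load_ratings(make_table(rows))

    def test_conflicting_truth_rejected(self):
        rows = [("a", "real", "r0", "real", 3), ("a", "synthetic", "r1", "real", 3)]
        with pytest.raises(RatingTableError, match="conflicting"):
            load_ratings(make_table(rows))

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        table = simulated_table(10, 3, rng)
        path = tmp_path / "ratings.csv"
        table.to_csv(path, index=False)
        loaded = load_ratings(str(path))
        assert len(loaded) == 30
        summary = turing_summary(loaded)
        assert set(summary) >= {"accuracy", "true_recognition_rate",
                                "false_recognition_rate", "fleiss_kappa", "auc"}
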