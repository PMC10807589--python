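import numpy as np
import pandas as pd
import pytest

from crcrisk.scoring import (
    DEFAULT_GENE_SET,
    ConfusionMetrics,
    G8Model,
    ScoreModel,
    classify_and_metrics,
    compute_g8,
    compute_g8plus,
    roc_auc,
    select_cutoff,
)
from conftest import make_cohort


def pair_counting_auc(scores, labels, positive="R"):
    """AUC oracle: concordant/discordant/tied pair counting (ties = 1/2).

    Positive class is recurrence and low scores indicate recurrence, so a
    pair is concordant when the positive sample scores lower.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive
    pos, neg = s[y], s[~y]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 0.5 if a == b else float(a < b)
    return total / (len(pos) * len(neg))


class TestComputeG8:
    def _matrix(self, mutated):
        row = {g: int(g in mutated) for g in DEFAULT_GENE_SET}
        return pd.DataFrame([row], index=["S1"])

    def test_counts_mutated_panel_genes(self):
        mat = self._matrix({"CUL9", "DCX", "AATK"})
        assert compute_g8(mat).loc["S1"] == 3

    def test_zero_and_full(self):
        assert compute_g8(self._matrix(set())).loc["S1"] == 0
        assert compute_g8(self._matrix(set(DEFAULT_GENE_SET))).loc["S1"] == 8

    def test_missing_genes_listed_in_error(self):
        mat = pd.DataFrame({"CUL9": [1]}, index=["S1"])
        with pytest.raises(ValueError, match="SORCS2"):
            compute_g8(mat)

    def test_never_mutated_gene_changes_no_score(self):
        mat = self._matrix({"CUL9"})
        mat["EXTRA"] = 0
        base = compute_g8(mat, DEFAULT_GENE_SET)
        extended = compute_g8(mat, list(DEFAULT_GENE_SET) + ["EXTRA"])
        assert (base == extended).all()


class TestComputeG8Plus:
    @pytest.mark.parametrize(
        "g8,tmb_high,msi_h,expected",
        [
            (3, True, False, 1),    # TMB-high & MSS: two points off
            (3, True, True, 3),     # MSI-H exempt
            (3, False, False, 3),
            (0, True, False, -2),   # no floor on negative scores
        ],
    )
    def test_penalty_rule(self, g8, tmb_high, msi_h, expected):
        assert compute_g8plus(g8, tmb_high, msi_h) == expected

    def test_vectorized_over_series(self):
        g8 = pd.Series([3, 3, 0], index=list("abc"))
        out = compute_g8plus(
            g8,
            pd.Series([True, True, True], index=list("abc")),
            pd.Series([False, True, False], index=list("abc")),
        )
        assert list(out) == [1, 3, -2]


class TestRocAuc:
    def test_perfect_separation(self):
        scores = pd.Series([0, 0, 0, 5, 6, 7])
        labels = pd.Series(["R"] * 3 + ["NR"] * 3)
        assert roc_auc(scores, labels).auc == pytest.approx(1.0)

    def test_all_tied_scores_give_half(self):
        scores = pd.Series([2.0] * 6)
        labels = pd.Series(["R"] * 3 + ["NR"] * 3)
        assert roc_auc(scores, labels).auc == pytest.approx(0.5)

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(pd.Series([1, 2]), pd.Series(["R", "R"]))

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            scores = rng.integers(0, 5, 15).astype(float)
            labels = np.where(rng.random(15) < 0.5, "R", "NR")
            if len(set(labels)) < 2:
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                pair_counting_auc(scores, labels), abs=1e-12
            )

    def test_auc_antisymmetric_for_tie_free_scores(self):
        rng = np.random.default_rng(19)
        scores = rng.permutation(14).astype(float)
        labels = np.array(["R"] * 7 + ["NR"] * 7)
        a = roc_auc(scores, labels).auc
        b = roc_auc(-scores, labels).auc
        assert a + b == pytest.approx(1.0)


class TestSelectCutoff:
    def test_perfect_separation_returns_gap_midpoint(self):
        scores = pd.Series([0, 0, 4, 4], index=list("abcd"))
        labels = pd.Series(["R", "R", "NR", "NR"], index=list("abcd"))
        roc = roc_auc(scores, labels)
        assert select_cutoff(roc) == pytest.approx(2.0)

    def test_degenerate_all_tied_predicts_nobody(self):
        scores = pd.Series([1.0] * 6)
        labels = pd.Series(["R"] * 3 + ["NR"] * 3)
        roc = roc_auc(scores, labels)
        cut = select_cutoff(roc)
        assert roc.youden().max() == pytest.approx(0.0)
        assert (scores < cut).sum() == 0  # sentinel: no positive predictions

    def test_simulated_cohorts_classify_observed_mutated_samples_high(self):
        """Panel mutation (score >= 1) implies a low-risk call in >=90% of seeds."""
        from crcrisk.simulate import simulate_cohort

        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            cohort, _ = simulate_cohort(seed=seed)
            mat = cohort.mutation_matrix.reindex(
                columns=sorted(set(cohort.mutation_matrix.columns) | set(DEFAULT_GENE_SET)),
                fill_value=0,
            )
            g8 = compute_g8(mat, DEFAULT_GENE_SET)
            cut = select_cutoff(roc_auc(g8, cohort.labels()))
            if ((g8 >= 1) & (g8 < cut)).sum() == 0:
                hits += 1
        assert hits / n_seeds >= 0.9


class TestConfusionMetrics:
    def test_reconstructed_published_confusion(self):
        """tp=21 fp=0 fn=2 tn=24: PPV 1.0, NPV 24/26, accuracy 45/47."""
        m = ConfusionMetrics(tp=21, fp=0, fn=2, tn=24)
        assert m.ppv == pytest.approx(1.0)
        assert m.npv == pytest.approx(0.9231, abs=5e-5)
        assert m.accuracy == pytest.approx(45 / 47)

    def test_one_error_in_47(self):
        m = ConfusionMetrics(tp=22, fp=0, fn=1, tn=24)
        assert m.accuracy == pytest.approx(0.9787, abs=5e-5)

    def test_zero_denominator_reports_missing(self):
        m = ConfusionMetrics(tp=0, fp=0, fn=3, tn=4)
        assert m.ppv is None
        assert m.accuracy == pytest.approx(4 / 7)

    def test_classification_rule_is_score_below_cutoff(self):
        scores = pd.Series([0, 1, 2, 3])
        labels = pd.Series(["R", "R", "NR", "NR"])
        m = classify_and_metrics(scores, 1.5, labels)
        assert (m.tp, m.fp, m.fn, m.tn) == (2, 0, 0, 2)
        assert m.n == 4


class TestScoreModelAndG8Model:
    def test_frozen_model_predicts_with_cutoff(self):
        ids = ["a", "b"]
        mat = pd.DataFrame(
            {g: [1, 0] for g in DEFAULT_GENE_SET}, index=ids
        )
        cohort = make_cohort(mat, {"a": "NR", "b": "R"})
        frozen = ScoreModel(cutoff=0.5)
        pred = frozen.predict(cohort)
        assert not pred["a"] and pred["b"]

    def test_predict_without_cutoff_is_error(self):
        model = ScoreModel(cutoff=None)
        with pytest.raises(ValueError, match="cutoff"):
            model.predict(None)  # fails before touching the cohort

    def test_fit_on_simulated_cohort(self, default_cohort):
        cohort, truth = default_cohort
        res = G8Model(cohort).fit()
        assert 0.5 < res.roc_g8.auc <= 1.0
        assert set(truth.signal_genes) & set(res.gene_set)
        assert "Gene panel" in res.summary()
        trace_aucs = res.trace.to_frame()["auc"]
        assert trace_aucs.is_monotonic_increasing

    def test_frozen_gene_set_skips_screening(self, default_cohort):
        cohort, _ = default_cohort
        mat_cols = sorted(set(cohort.mutation_matrix.columns) | set(DEFAULT_GENE_SET))
        cohort2 = make_cohort(
            cohort.mutation_matrix.reindex(columns=mat_cols, fill_value=0),
            {c.sample_id: c.group.value for c in cohort.clinical},
            tmb=cohort.flags["tmb"].tolist(),
            tmb_high=cohort.flags["tmb_high"].tolist(),
            msi_h=cohort.flags["msi_h"].tolist(),
        )
        res = G8Model(cohort2, gene_set=DEFAULT_GENE_SET).fit()
        assert res.screen is None and res.trace is None
        assert res.gene_set == DEFAULT_GENE_SET


class TestRocProperties:
    """Score-scale invariances of the empirical ROC."""

    from hypothesis import given, settings, strategies as st

    scores = st.lists(st.integers(min_value=-5, max_value=5), min_size=4, max_size=20)

    @given(scores=scores, split=st.integers(min_value=1, max_value=19))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_auc_bounded_and_shift_invariant(self, scores, split):
        n = len(scores)
        split = min(split, n - 1)
        labels = np.array(["R"] * split + ["NR"] * (n - split))
        s = np.asarray(scores, dtype=float)
        auc = roc_auc(s, labels).auc
        assert 0.0 <= auc <= 1.0
        # shifting and positively scaling the score changes nothing
        assert roc_auc(3.0 * s + 7.0, labels).auc == pytest.approx(auc, abs=1e-12)
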