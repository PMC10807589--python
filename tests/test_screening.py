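import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crcrisk.scoring import roc_auc
from crcrisk.screening import (
    co_occurrence,
    fisher_exact_2x2,
    iterative_subtraction,
    screen_genes,
    select_top_k,
)
from conftest import make_cohort


def fisher_enumeration_oracle(table):
    """Two-sided Fisher p by full enumeration over the observed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            stats.hypergeom.pmf(x, n, r1, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[15, 7], [7, 14]], 0.034),   # tumor location, published contingency
            ([[21, 3], [13, 10]], 0.024),  # differentiation, published contingency
        ],
    )
    def test_published_contingency_rows_to_3dp(self, table, expected):
        assert round(fisher_exact_2x2(table), 3) == expected

    def test_symmetric_table_is_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [[[0, 0], [3, 7]], [[0, 4], [0, 6]]])
    def test_zero_margin_is_one(self, table):
        assert fisher_exact_2x2(table) == pytest.approx(1.0)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError, match="non-negative"):
            fisher_exact_2x2([[-1, 2], [3, 4]])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            table = rng.integers(0, 16, size=(2, 2))
            if table.sum() > 60:
                continue
            assert fisher_exact_2x2(table) == pytest.approx(
                fisher_enumeration_oracle(table), abs=1e-12
            )


def _toy_cohort(nr_exclusive=8, noise=0, n_r=10, n_nr=10, seed=0):
    """nr_exclusive genes mutated in all NR / no R; noise genes at equal rates."""
    rng = np.random.default_rng(seed)
    ids = [f"R{i}" for i in range(n_r)] + [f"N{i}" for i in range(n_nr)]
    cols = {}
    for k in range(nr_exclusive):
        cols[f"SIG{k}"] = [0] * n_r + [1] * n_nr
    for k in range(noise):
        cols[f"NOISE{k}"] = list(rng.integers(0, 2, n_r + n_nr))
    mat = pd.DataFrame(cols, index=ids)
    groups = {s: ("R" if s.startswith("R") else "NR") for s in ids}
    return make_cohort(mat, groups)


class TestScreenGenes:
    def test_extreme_gene_gets_minimal_p_and_top_rank(self):
        cohort = _toy_cohort(nr_exclusive=1, noise=3, seed=1)
        screen = screen_genes(cohort)
        assert screen.loc["SIG0", "rank"] == 1
        assert screen["fisher_p"].min() == screen.loc["SIG0", "fisher_p"]

    def test_equal_frequency_gene_ranks_bottom_with_p_one(self):
        ids = [f"R{i}" for i in range(5)] + [f"N{i}" for i in range(5)]
        mat = pd.DataFrame(
            {"EQ": [1, 0, 1, 0, 1, 1, 0, 1, 0, 1], "SIG": [0] * 5 + [1] * 5},
            index=ids,
        )
        cohort = make_cohort(mat, {s: ("R" if s.startswith("R") else "NR") for s in ids})
        screen = screen_genes(cohort)
        assert screen.loc["EQ", "fisher_p"] == pytest.approx(1.0)
        assert screen.loc["EQ", "rank"] == 2

    def test_counts_sum_to_cohort_size(self):
        cohort = _toy_cohort(nr_exclusive=2, noise=2)
        screen = screen_genes(cohort)
        totals = screen[["mut_R", "wt_R", "mut_NR", "wt_NR"]].sum(axis=1)
        assert (totals == len(cohort.sample_ids)).all()

    def test_invariant_to_sample_and_gene_order(self):
        cohort = _toy_cohort(nr_exclusive=2, noise=4, seed=3)
        shuffled_samples = list(reversed(cohort.sample_ids))
        shuffled = make_cohort(
            cohort.mutation_matrix.loc[shuffled_samples, ::-1],
            {s: ("R" if s.startswith("R") else "NR") for s in shuffled_samples},
        )
        a = screen_genes(cohort)
        b = screen_genes(shuffled)
        pd.testing.assert_frame_equal(a, b.loc[a.index])

    def test_unlabeled_samples_rejected(self):
        cohort = _toy_cohort(nr_exclusive=1)
        cohort.clinical[0] = type(cohort.clinical[0])(
            sample_id=cohort.clinical[0].sample_id, rfs_time=30.0, rfs_event=0,
            msisensor_score=0.0,
        )
        with pytest.raises(ValueError, match="unlabeled"):
            screen_genes(cohort)


class TestSelectTopK:
    def test_k_zero_and_k_all(self):
        screen = screen_genes(_toy_cohort(nr_exclusive=2, noise=3))
        assert select_top_k(screen, 0) == []
        assert set(select_top_k(screen, 5)) == set(screen.index)

    def test_k_exceeding_gene_count_warns_and_returns_all(self):
        screen = screen_genes(_toy_cohort(nr_exclusive=1, noise=1))
        with pytest.warns(UserWarning, match="returning all"):
            out = select_top_k(screen, 99)
        assert len(out) == 2


class TestIterativeSubtraction:
    def test_single_candidate_unchanged(self):
        cohort = _toy_cohort(nr_exclusive=1)
        final, trace = iterative_subtraction(cohort, ["SIG0"])
        assert final == ["SIG0"] and len(trace.steps) == 1

    def test_pure_noise_gene_removed_first(self):
        """Equal-frequency noise gene leaves first; AUC verified by brute force."""
        ids = [f"R{i}" for i in range(8)] + [f"N{i}" for i in range(8)]
        cols = {f"SIG{k}": [0] * 8 + [1] * 8 for k in range(8)}
        cols["NOISE"] = [1, 0, 1, 0, 1, 0, 1, 0] * 2  # identical rate in R and NR
        mat = pd.DataFrame(cols, index=ids)
        cohort = make_cohort(mat, {s: ("R" if s.startswith("R") else "NR") for s in ids})
        final, trace = iterative_subtraction(cohort, list(cols))
        assert trace.steps[1].removed == "NOISE"
        # brute-force AUC oracle at every accepted step
        labels = cohort.labels()
        for step in trace.steps:
            score = mat[list(step.gene_set)].sum(axis=1).to_numpy()
            y = (labels == "R").to_numpy()
            pos, neg = score[y], score[~y]
            pairs = [(0.5 if a == b else float(a < b)) for a in pos for b in neg]
            assert step.auc == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_trace_auc_nondecreasing_and_subset(self):
        cohort = _toy_cohort(nr_exclusive=4, noise=6, seed=9)
        candidates = list(cohort.mutation_matrix.columns)
        final, trace = iterative_subtraction(cohort, candidates)
        aucs = [s.auc for s in trace.steps]
        assert all(b >= a - 1e-12 for a, b in zip(aucs, aucs[1:]))
        assert set(final) <= set(candidates)

    def test_greedy_beats_most_subsets_exhaustively(self):
        """Greedy final AUC >= the AUC of 95% of all non-empty subsets."""
        rng = np.random.default_rng(21)
        ids = [f"R{i}" for i in range(12)] + [f"N{i}" for i in range(12)]
        mat = pd.DataFrame(
            {f"G{k}": rng.integers(0, 2, 24) for k in range(9)}, index=ids
        )
        for k in range(3):  # give a few genes real signal
            mat[f"G{k}"] = [0] * 12 + list(rng.integers(0, 2, 11)) + [1]
        cohort = make_cohort(mat, {s: ("R" if s.startswith("R") else "NR") for s in ids})
        labels = cohort.labels()
        final, _ = iterative_subtraction(cohort, list(mat.columns))
        greedy_auc = roc_auc(mat[final].sum(axis=1), labels).auc
        all_aucs = []
        genes = list(mat.columns)
        for r in range(1, len(genes) + 1):
            for sub in itertools.combinations(genes, r):
                all_aucs.append(roc_auc(mat[list(sub)].sum(axis=1), labels).auc)
        frac_beaten = np.mean([greedy_auc >= a - 1e-12 for a in all_aucs])
        assert frac_beaten >= 0.95

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError, match="empty"):
            iterative_subtraction(_toy_cohort(), [])


class TestCoOccurrence:
    def test_identical_columns_give_infinite_or(self):
        ids = [f"S{i}" for i in range(10)]
        col = [1, 1, 1, 0, 0, 1, 0, 1, 0, 1]
        mat = pd.DataFrame({"A": col, "B": col}, index=ids)
        cohort = make_cohort(mat, {s: "R" for s in ids[:5]} | {s: "NR" for s in ids[5:]})
        out = co_occurrence(cohort, ["A", "B"])
        assert np.isinf(out.loc[0, "odds_ratio"])

    def test_anticorrelated_columns_give_or_below_one(self):
        ids = [f"S{i}" for i in range(10)]
        a = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        b = [0, 0, 0, 0, 1, 1, 1, 1, 1, 1]
        mat = pd.DataFrame({"A": a, "B": b}, index=ids)
        cohort = make_cohort(mat, {s: "R" for s in ids[:5]} | {s: "NR" for s in ids[5:]})
        out = co_occurrence(cohort, ["A", "B"])
        assert out.loc[0, "odds_ratio"] < 1

    def test_independent_columns_rarely_significant(self):
        """Null simulation: BH q stays above 0.1 in >=90% of seeds."""
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            ids = [f"S{i}" for i in range(30)]
            mat = pd.DataFrame(
                {g: rng.integers(0, 2, 30) for g in ["A", "B", "C", "D"]}, index=ids
            )
            cohort = make_cohort(
                mat, {s: "R" for s in ids[:15]} | {s: "NR" for s in ids[15:]}
            )
            out = co_occurrence(cohort, ["A", "B", "C", "D"])
            if (out["q"] > 0.1).all():
                hits += 1
        assert hits / n_seeds >= 0.9

    def test_missing_gene_is_error(self):
        with pytest.raises(ValueError, match="ZZZ"):
            co_occurrence(_toy_cohort(), ["SIG0", "ZZZ"])


class TestFisherProperties:
    """Symmetry properties of the two-sided exact test."""

    from hypothesis import given, settings, strategies as st

    counts = st.integers(min_value=0, max_value=12)

    @given(a=counts, b=counts, c=counts, d=counts)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_invariant_to_transpose_and_row_swap(self, a, b, c, d):
        p = fisher_exact_2x2([[a, b], [c, d]])
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(fisher_exact_2x2([[a, c], [b, d]]), abs=1e-12)
        assert p == pytest.approx(fisher_exact_2x2([[c, d], [a, b]]), abs=1e-12)
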