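"""Recurrence-gene screening: Fisher tests, top-K ranking, iterative subtraction.

The discovery path mirrors how the score panel is built: every gene gets a
two-sided Fisher exact test on mutated-vs-not x relapse(R)-vs-non-relapse(NR);
the top K genes by p-value enter greedy backward elimination ("iterative
subtraction") that at each step drops the gene whose removal best improves —
or at least preserves — the ROC AUC of the summed mutation-count score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import Cohort

__all__ = [
    "fisher_exact_2x2",
    "screen_genes",
    "select_top_k",
    "SubtractionStep",
    "SelectionTrace",
    "iterative_subtraction",
    "co_occurrence",
]


def fisher_exact_2x2(table: Sequence[Sequence[float]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table of counts.

    Probability-mass method: sum over all tables with the observed margins
    whose hypergeometric probability does not exceed the observed table's.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.equal(np.mod(arr, 1), 0).all():
        raise ValueError("counts must be integers")
    return float(stats.fisher_exact(arr.astype(int), alternative="two-sided")[1])


def _screen_counts(cohort: Cohort) -> tuple[pd.DataFrame, pd.Series]:
    labels = cohort.labels()
    if labels.isna().any():
        bad = list(labels.index[labels.isna()])
        raise ValueError(
            f"unlabeled samples present (exclude them first, e.g. via "
            f"Cohort.labeled_subset()): {bad}"
        )
    return cohort.mutation_matrix, labels


def screen_genes(cohort: Cohort) -> pd.DataFrame:
    """Per-gene Fisher screen of mutation frequency, R vs NR.

    Returns a DataFrame indexed by gene with 2x2 counts (``mut_R``,
    ``wt_R``, ``mut_NR``, ``wt_NR``), per-group frequencies, the two-sided
    Fisher p and the rank. Ranking is ascending p, ties broken by larger
    absolute frequency difference, then alphabetically — the ordering
    ``select_top_k`` consumes.
    """
    matrix, labels = _screen_counts(cohort)
    is_r = (labels == "R").to_numpy()
    n_r, n_nr = int(is_r.sum()), int((~is_r).sum())
    if n_r == 0 or n_nr == 0:
        raise ValueError("screening requires samples in both the R and NR groups")

    mut = matrix.to_numpy()
    mut_r = mut[is_r].sum(axis=0)
    mut_nr = mut[~is_r].sum(axis=0)
    rows = []
    for j, gene in enumerate(matrix.columns):
        a, b = int(mut_r[j]), int(mut_nr[j])
        p = fisher_exact_2x2([[a, b], [n_r - a, n_nr - b]])
        freq_r, freq_nr = a / n_r, b / n_nr
        rows.append(
            {
                "gene": gene,
                "mut_R": a,
                "wt_R": n_r - a,
                "mut_NR": b,
                "wt_NR": n_nr - b,
                "freq_R": freq_r,
                "freq_NR": freq_nr,
                "freq_diff": freq_nr - freq_r,
                "fisher_p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["_negabs"] = -out["freq_diff"].abs()
    out = (
        out.sort_values(["fisher_p", "_negabs", "gene"], kind="mergesort")
        .drop(columns="_negabs")
        .set_index("gene")
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def select_top_k(screen: pd.DataFrame, k: int = 30) -> list[str]:
    """First ``k`` genes by screen rank; all genes (with a warning) if k > G."""
    if k < 0:
        raise ValueError("k must be >= 0")
    ordered = screen.sort_values("rank").index.tolist()
    if k > len(ordered):
        import warnings

        warnings.warn(
            f"requested top {k} of {len(ordered)} genes; returning all", stacklevel=2
        )
        return ordered
    return ordered[:k]


@dataclass(frozen=True)
class SubtractionStep:
    """One accepted elimination: the gene removed and the resulting set/AUC."""

    removed: str | None
    gene_set: tuple[str, ...]
    auc: float


@dataclass
class SelectionTrace:
    """Accepted steps of the backward elimination, AUC non-decreasing."""

    steps: list[SubtractionStep] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": range(len(self.steps)),
                "removed": [s.removed for s in self.steps],
                "n_genes": [len(s.gene_set) for s in self.steps],
                "auc": [s.auc for s in self.steps],
                "gene_set": [",".join(s.gene_set) for s in self.steps],
            }
        )


def iterative_subtraction(
    cohort: Cohort,
    candidates: Sequence[str],
    fisher_p: pd.Series | None = None,
) -> tuple[list[str], SelectionTrace]:
    """Greedy backward elimination of the candidate panel under the AUC objective.

    At each step the gene whose removal yields the highest AUC of the summed
    mutation score is dropped, provided the AUC does not decrease; ties are
    broken by removing the gene with the larger screening p-value (then
    alphabetically). Stops when no removal is acceptable or one gene remains.
    """
    from .scoring import roc_auc  # local import to avoid a cycle

    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list is empty")
    missing = sorted(set(candidates) - set(cohort.mutation_matrix.columns))
    if missing:
        raise ValueError(f"candidates absent from mutation matrix: {missing}")
    matrix, labels = _screen_counts(cohort)
    if fisher_p is None:
        fisher_p = screen_genes(cohort)["fisher_p"]

    def panel_auc(genes: Sequence[str]) -> float:
        score = matrix[list(genes)].sum(axis=1)
        return roc_auc(score, labels).auc

    current = sorted(candidates)
    current_auc = panel_auc(current)
    trace = SelectionTrace([SubtractionStep(None, tuple(current), current_auc)])
    while len(current) > 1:
        best: tuple[float, float, str] | None = None  # (-auc, -p, gene)
        for g in current:
            reduced_auc = panel_auc([x for x in current if x != g])
            key = (-reduced_auc, -float(fisher_p.get(g, 1.0)), g)
            if best is None or key < best:
                best = key
        assert best is not None
        best_auc, removed = -best[0], best[2]
        if best_auc < current_auc:
            break
        current = [x for x in current if x != removed]
        current_auc = best_auc
        trace.steps.append(SubtractionStep(removed, tuple(current), current_auc))
    return current, trace


def co_occurrence(cohort: Cohort, genes: Sequence[str]) -> pd.DataFrame:
    """Pairwise co-mutation: odds ratio, Fisher p and BH q per gene pair.

    The 2x2 table crosses the mutation status of the two genes across all
    samples. An infinite odds ratio (empty off-diagonal) is reported as
    ``inf``; BH adjustment is across all pairs tested.
    """
    genes = list(genes)
    missing = sorted(set(genes) - set(cohort.mutation_matrix.columns))
    if missing:
        raise ValueError(f"genes absent from mutation matrix: {missing}")
    m = cohort.mutation_matrix[genes].to_numpy()
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a = int(((m[:, i] == 1) & (m[:, j] == 1)).sum())
            b = int(((m[:, i] == 1) & (m[:, j] == 0)).sum())
            c = int(((m[:, i] == 0) & (m[:, j] == 1)).sum())
            d = int(((m[:, i] == 0) & (m[:, j] == 0)).sum())
            odds = np.inf if b * c == 0 and a * d > 0 else (
                np.nan if b * c == 0 else a * d / (b * c)
            )
            rows.append(
                {
                    "gene_a": genes[i],
                    "gene_b": genes[j],
                    "both": a,
                    "a_only": b,
                    "b_only": c,
                    "neither": d,
                    "odds_ratio": odds,
                    "fisher_p": fisher_exact_2x2([[a, b], [c, d]]),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["fisher_p"], method="fdr_bh")[1]
    return out
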