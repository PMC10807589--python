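"""G8 / G8plus recurrence scores, ROC cutoffs and classification metrics.

The G8 score of a patient is the number of mutated genes among an 8-gene
panel (CUL9, PCDHA12, HECTD3, DCX, SMARCA2, FAM193A, AATK, SORCS2 by
default); because these genes are mutated almost exclusively in
non-relapsing tumors, a HIGH score means LOW recurrence risk. The G8plus
score subtracts two points from patients that are TMB-high yet
microsatellite-stable — the hypermutator (POLE-exonuclease-like) phenotype
that otherwise produces false low-risk calls.

Classification orientation throughout: the positive class is recurrence,
and a patient is predicted to recur when the score falls BELOW the cutoff.

The statsmodels-style entry point is :class:`G8Model` /
:class:`G8Results`: build the model from a cohort, ``fit()`` runs the
discovery pipeline (screen, subtract, cutoff) and returns results carrying
scores, ROC curves, confusion metrics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .screening import SelectionTrace, iterative_subtraction, screen_genes, select_top_k

__all__ = [
    "DEFAULT_GENE_SET",
    "DEFAULT_PENALTY_POINTS",
    "compute_g8",
    "compute_g8plus",
    "RocResult",
    "roc_auc",
    "select_cutoff",
    "ConfusionMetrics",
    "classify_and_metrics",
    "ScoreModel",
    "G8Model",
    "G8Results",
]

#: The published 8-gene recurrence panel.
DEFAULT_GENE_SET = (
    "CUL9",
    "PCDHA12",
    "HECTD3",
    "DCX",
    "SMARCA2",
    "FAM193A",
    "AATK",
    "SORCS2",
)

#: Points subtracted for TMB-high & MSS patients in the G8plus score.
DEFAULT_PENALTY_POINTS = 2


def compute_g8(matrix: pd.DataFrame, gene_set: Sequence[str] = DEFAULT_GENE_SET) -> pd.Series:
    """Per-sample count of mutated panel genes (0 .. len(gene_set))."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("gene_set is empty")
    missing = sorted(set(gene_set) - set(matrix.columns))
    if missing:
        raise ValueError(f"gene_set members absent from matrix: {missing}")
    return matrix[gene_set].sum(axis=1).rename("g8")


def compute_g8plus(
    g8: pd.Series | int,
    tmb_high: pd.Series | bool,
    msi_h: pd.Series | bool,
    penalty_points: int = DEFAULT_PENALTY_POINTS,
) -> pd.Series | int:
    """G8 minus ``penalty_points`` for TMB-high & MSS samples.

    No floor is applied: negative scores are legal and handled by the
    cutoff logic downstream.
    """
    if penalty_points < 0:
        raise ValueError("penalty_points must be >= 0")
    penalized = np.logical_and(tmb_high, np.logical_not(msi_h))
    out = g8 - penalty_points * penalized
    if isinstance(out, pd.Series):
        out = out.rename("g8plus")
    else:
        out = int(out)
    return out


# ---------------------------------------------------------------------------
# ROC machinery (score scale; prediction rule "score < cutoff -> recurrence")


@dataclass
class RocResult:
    """Threshold sweep of the score-below-cutoff classifier.

    ``cutoffs`` are candidate score cutoffs (midpoints between adjacent
    distinct scores, plus one below the minimum and one above the maximum);
    ``sensitivity[i]`` / ``specificity[i]`` are for recurrence prediction at
    ``cutoffs[i]``. ``auc`` is the trapezoidal area under the empirical ROC,
    identical to the normalized Mann-Whitney U with ties counted half.
    """

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    chosen_cutoff: float | None = None
    positive_label: str = "R"

    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


def roc_auc(
    scores: pd.Series | Sequence[float],
    labels: pd.Series | Sequence[str],
    positive: str = "R",
) -> RocResult:
    """ROC of a low-risk score against recurrence labels.

    High score means low recurrence risk, so recurrence risk is the negated
    score; the AUC reported is for discriminating the positive (recurrence)
    class with that orientation.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive
    if y.all() or not y.any():
        raise ValueError("labels must contain both classes")

    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    cutoffs = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    sens = np.array([(s[y] < c).mean() for c in cutoffs])
    spec = np.array([(s[~y] >= c).mean() for c in cutoffs])

    # trapezoid over the staircase == pair counting with ties at 1/2
    order = np.argsort(cutoffs)
    fpr = 1.0 - spec[order]
    tpr = sens[order]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(
        cutoffs=cutoffs, sensitivity=sens, specificity=spec, auc=auc,
        positive_label=positive,
    )


def select_cutoff(roc: RocResult, method: str = "youden") -> float:
    """Cutoff maximizing Youden's J (sensitivity + specificity - 1).

    Ties are resolved toward higher specificity for recurrence. In the
    fully degenerate case (all scores tied, max J = 0) the lowest candidate
    is returned, under which no sample is predicted to recur.
    """
    if method != "youden":
        raise ValueError(f"unknown cutoff method {method!r}")
    if roc.cutoffs.size == 0:
        raise ValueError("empty ROC")
    j = roc.youden()
    best = max(
        range(len(roc.cutoffs)),
        key=lambda i: (j[i], roc.specificity[i], -roc.cutoffs[i]),
    )
    return float(roc.cutoffs[best])


@dataclass(frozen=True)
class ConfusionMetrics:
    """Counts and derived rates with positive = predicted recurrence.

    A rate whose denominator is zero is reported as None (missing), never 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @staticmethod
    def _ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    @property
    def ppv(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def accuracy(self) -> float | None:
        return self._ratio(self.tp + self.tn, self.n)

    @property
    def sensitivity(self) -> float | None:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._ratio(self.tn, self.tn + self.fp)

    def to_dict(self) -> dict[str, float | int | None]:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "ppv": self.ppv, "npv": self.npv, "accuracy": self.accuracy,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
        }


def classify_and_metrics(
    scores: pd.Series | Sequence[float],
    cutoff: float,
    labels: pd.Series | Sequence[str],
    positive: str = "R",
) -> ConfusionMetrics:
    """Classify (recurrence iff score < cutoff) and tabulate the confusion."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels) == positive
    pred = s < cutoff
    return ConfusionMetrics(
        tp=int((pred & y).sum()),
        fp=int((pred & ~y).sum()),
        fn=int((~pred & y).sum()),
        tn=int((~pred & ~y).sum()),
    )


# ---------------------------------------------------------------------------
# frozen score model + statsmodels-style Model/Results


@dataclass(frozen=True)
class ScoreModel:
    """A frozen, applicable scorer: gene panel, penalty rule and cutoff."""

    gene_set: tuple[str, ...] = DEFAULT_GENE_SET
    penalty_points: int = DEFAULT_PENALTY_POINTS
    use_penalty: bool = True
    cutoff: float | None = None

    def __post_init__(self) -> None:
        if not self.gene_set:
            raise ValueError("gene_set must be non-empty")
        if self.penalty_points < 0:
            raise ValueError("penalty_points must be >= 0")

    def score(self, cohort: Cohort) -> pd.Series:
        g8 = compute_g8(cohort.mutation_matrix, self.gene_set)
        if not self.use_penalty:
            return g8
        return compute_g8plus(
            g8, cohort.flags["tmb_high"], cohort.flags["msi_h"], self.penalty_points
        )

    def predict(self, cohort: Cohort) -> pd.Series:
        """Boolean 'predicted recurrence' per sample (score < cutoff)."""
        if self.cutoff is None:
            raise ValueError("model has no cutoff; fit one or set it explicitly")
        return (self.score(cohort) < self.cutoff).rename("predicted_recurrence")


class G8Model:
    """Recurrence-score discovery on a labeled cohort.

    Parameters
    ----------
    cohort
        Cohort whose samples all carry an R/NR label (use
        ``cohort.labeled_subset()`` first otherwise).
    gene_set
        Freeze the panel instead of discovering it (skips screening and
        subtraction; this is the "apply a published panel" mode).
    top_k
        Number of top screening genes fed to iterative subtraction.
    penalty_points
        Points subtracted for TMB-high & MSS samples in the G8plus score.
    """

    def __init__(
        self,
        cohort: Cohort,
        gene_set: Sequence[str] | None = None,
        top_k: int = 30,
        penalty_points: int = DEFAULT_PENALTY_POINTS,
        cutoff_method: str = "youden",
    ):
        labels = cohort.labels()
        if labels.isna().any():
            raise ValueError(
                "all samples must be labeled R/NR; use cohort.labeled_subset()"
            )
        self.cohort = cohort
        self.gene_set = tuple(gene_set) if gene_set is not None else None
        self.top_k = top_k
        self.penalty_points = penalty_points
        self.cutoff_method = cutoff_method

    @classmethod
    def from_tables(
        cls,
        variant_path: str,
        clinical_path: str,
        dialect=None,
        region_size_mb: float = 38.0,
        tmb_threshold: float = 10.0,
        **kwargs,
    ) -> "G8Model":
        """Build the model straight from variant + clinical TSV files."""
        from .cohort import build_cohort, read_clinical_table, read_variant_table

        variants, errors = read_variant_table(variant_path, dialect=dialect)
        if errors:
            raise ValueError(f"variant table has {len(errors)} bad rows: {errors[:5]}")
        clinical = read_clinical_table(clinical_path)
        cohort = build_cohort(
            variants, clinical, region_size_mb=region_size_mb, tmb_threshold=tmb_threshold
        )
        return cls(cohort.labeled_subset(), **kwargs)

    def fit(self) -> "G8Results":
        """Run screening, subtraction and cutoff selection; return results."""
        cohort = self.cohort
        labels = cohort.labels()

        screen = trace = None
        if self.gene_set is None:
            screen = screen_genes(cohort)
            candidates = select_top_k(screen, self.top_k)
            gene_set, trace = iterative_subtraction(
                cohort, candidates, fisher_p=screen["fisher_p"]
            )
        else:
            gene_set = list(self.gene_set)

        g8 = compute_g8(cohort.mutation_matrix, gene_set)
        g8plus = compute_g8plus(
            g8, cohort.flags["tmb_high"], cohort.flags["msi_h"], self.penalty_points
        )
        roc_g8 = roc_auc(g8, labels)
        roc_g8.chosen_cutoff = select_cutoff(roc_g8, self.cutoff_method)
        roc_g8plus = roc_auc(g8plus, labels)
        roc_g8plus.chosen_cutoff = select_cutoff(roc_g8plus, self.cutoff_method)
        tmb_roc = roc_auc(cohort.tmb, labels)  # high TMB tracks the NR group

        return G8Results(
            model=self,
            gene_set=tuple(gene_set),
            screen=screen,
            trace=trace,
            g8=g8,
            g8plus=g8plus,
            roc_g8=roc_g8,
            roc_g8plus=roc_g8plus,
            tmb_roc=tmb_roc,
            metrics_g8=classify_and_metrics(g8, roc_g8.chosen_cutoff, labels),
            metrics_g8plus=classify_and_metrics(g8plus, roc_g8plus.chosen_cutoff, labels),
        )


@dataclass
class G8Results:
    """Fitted recurrence-score results: panel, scores, ROC and metrics."""

    model: G8Model
    gene_set: tuple[str, ...]
    screen: pd.DataFrame | None
    trace: SelectionTrace | None
    g8: pd.Series
    g8plus: pd.Series
    roc_g8: RocResult
    roc_g8plus: RocResult
    tmb_roc: RocResult
    metrics_g8: ConfusionMetrics
    metrics_g8plus: ConfusionMetrics

    def frozen_model(self, which: str = "g8plus") -> ScoreModel:
        """Export a frozen ScoreModel applicable to new cohorts."""
        if which == "g8plus":
            return ScoreModel(
                gene_set=self.gene_set,
                penalty_points=self.model.penalty_points,
                use_penalty=True,
                cutoff=self.roc_g8plus.chosen_cutoff,
            )
        if which == "g8":
            return ScoreModel(
                gene_set=self.gene_set,
                use_penalty=False,
                cutoff=self.roc_g8.chosen_cutoff,
            )
        raise ValueError(f"unknown score {which!r}")

    def scores_frame(self) -> pd.DataFrame:
        cohort = self.model.cohort
        return pd.DataFrame(
            {
                "group": cohort.labels(),
                "g8": self.g8,
                "g8plus": self.g8plus,
                "tmb": cohort.tmb,
                "tmb_high": cohort.flags["tmb_high"],
                "msi_h": cohort.flags["msi_h"],
                "pole_exo": cohort.flags["pole_exo"],
                "predicted_recurrence_g8plus": self.g8plus
                < self.roc_g8plus.chosen_cutoff,
            }
        )

    def summary(self) -> str:
        def fmt(x):
            return "NA" if x is None else f"{x:.4f}"

        lines = [
            "Recurrence score model (positive class = recurrence)",
            "=" * 56,
            f"Samples: {len(self.g8)}  "
            f"(R={int((self.model.cohort.labels() == 'R').sum())}, "
            f"NR={int((self.model.cohort.labels() == 'NR').sum())})",
            f"Gene panel ({len(self.gene_set)}): {', '.join(self.gene_set)}",
            f"Penalty: -{self.model.penalty_points} if TMB-high & MSS",
            "",
            f"{'':10s}{'AUC':>8s}{'cutoff':>9s}{'PPV':>8s}{'NPV':>8s}{'acc':>8s}",
            f"{'TMB':10s}{self.tmb_roc.auc:8.3f}{'':>9s}{'':>8s}{'':>8s}{'':>8s}",
            f"{'G8':10s}{self.roc_g8.auc:8.3f}{self.roc_g8.chosen_cutoff:9.2f}"
            f"{fmt(self.metrics_g8.ppv):>8s}{fmt(self.metrics_g8.npv):>8s}"
            f"{fmt(self.metrics_g8.accuracy):>8s}",
            f"{'G8plus':10s}{self.roc_g8plus.auc:8.3f}{self.roc_g8plus.chosen_cutoff:9.2f}"
            f"{fmt(self.metrics_g8plus.ppv):>8s}{fmt(self.metrics_g8plus.npv):>8s}"
            f"{fmt(self.metrics_g8plus.accuracy):>8s}",
        ]
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """ROC curves for TMB, G8 and G8plus on one axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, roc in (("TMB", self.tmb_roc), ("G8", self.roc_g8), ("G8plus", self.roc_g8plus)):
            order = np.argsort(roc.cutoffs)
            ax.plot(
                1 - roc.specificity[order], roc.sensitivity[order],
                drawstyle="steps-post", label=f"{name} (AUC={roc.auc:.3f})",
            )
        ax.plot([0, 1], [0, 1], ls=":", c="grey")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax
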