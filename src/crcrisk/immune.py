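"""Immune profiling: expression normalization, ssGSEA, TLS score, FDR tests.

ssGSEA here is the standard single-sample rank-based enrichment statistic:
per sample, genes are ranked by expression; the score of a gene set is the
sum over the ranked list of the difference between the weighted in-set
ECDF (weights rank^alpha, alpha = 0.25) and the unweighted out-of-set ECDF.
The tertiary-lymphoid-structure (TLS) score is the mean normalized
expression of 12 chemokine genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionProfile",
    "normalize_expression",
    "GeneSetCollection",
    "read_gmt",
    "bundled_immune_sets",
    "tls_chemokine_genes",
    "ssgsea_scores",
    "tls_score",
    "compare_groups_fdr",
]


@dataclass
class ExpressionProfile:
    """Genes x samples expression matrix with a normalization-state tag."""

    matrix: pd.DataFrame
    normalization: str = "raw"

    def __post_init__(self) -> None:
        if self.matrix.index.duplicated().any():
            dupes = sorted(set(self.matrix.index[self.matrix.index.duplicated()]))
            raise ValueError(f"duplicate gene ids: {dupes}")


def normalize_expression(
    profile: ExpressionProfile | pd.DataFrame, mode: str = "log2_zscore"
) -> ExpressionProfile:
    """log2(x+1) then per-gene z-score across samples (default), or rank.

    z-scores use the n-1 (sample) standard deviation; a constant gene row
    maps to all-zero z-scores rather than NaN. Re-normalizing an already
    normalized profile is an error (the state tag guards against it).
    """
    if isinstance(profile, pd.DataFrame):
        profile = ExpressionProfile(profile)
    if profile.normalization != "raw":
        raise ValueError(f"profile already normalized ({profile.normalization})")
    x = profile.matrix.astype(float)
    if (x.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    if mode == "log2_zscore":
        lg = np.log2(x + 1.0)
        mu = lg.mean(axis=1)
        sd = lg.std(axis=1, ddof=1)
        z = lg.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
        return ExpressionProfile(z, normalization="log2_zscore")
    if mode == "rank":
        r = x.rank(axis=0, method="average")
        return ExpressionProfile(r, normalization="rank")
    raise ValueError(f"unknown normalization mode {mode!r}")


class GeneSetCollection(Mapping[str, tuple]):
    """Named gene sets (immune-cell markers, TLS chemokines, ...)."""

    def __init__(self, sets: Mapping[str, Sequence[str]]):
        clean = {}
        for name, genes in sets.items():
            genes = tuple(dict.fromkeys(genes))  # dedupe, keep order
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = genes
        self._sets = clean

    def __getitem__(self, name: str) -> tuple:
        return self._sets[name]

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from GMT (name <tab> description <tab> genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = fields[2:]
    return GeneSetCollection(sets)


def bundled_immune_sets() -> GeneSetCollection:
    """The 28 immune-cell-type marker sets bundled with the package.

    These are synthetic stand-in marker lists (one per published cell-type
    name) intended for simulation and testing; substitute the published
    marker GMT for real analyses.
    """
    return read_gmt(Path(__file__).parent / "data" / "immune_cell_sets.synthetic.gmt")


def tls_chemokine_genes() -> tuple[str, ...]:
    """The 12 chemokine genes of the TLS signature."""
    path = Path(__file__).parent / "data" / "tls_chemokines.txt"
    return tuple(path.read_text().split())


def _ssgsea_one_sample(
    expr: np.ndarray, in_set: np.ndarray, alpha: float
) -> float:
    """Running-sum ssGSEA statistic for one sample.

    expr: expression vector; in_set: boolean membership mask.
    """
    n = expr.size
    m = int(in_set.sum())
    ranks = stats.rankdata(expr)  # 1 = lowest expression
    order = np.lexsort((np.arange(n), -ranks))  # descending rank, stable
    in_ordered = in_set[order]
    w = np.where(in_ordered, ranks[order] ** alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_ordered) / (n - m)
    return float(np.sum(p_in - p_out))


def ssgsea_scores(
    profile: ExpressionProfile,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    min_genes: int = 2,
    minmax_normalize: bool = False,
) -> pd.DataFrame:
    """Sets x samples matrix of single-sample enrichment scores.

    Sets with fewer than ``min_genes`` members present in the matrix are
    skipped with a warning. ``minmax_normalize`` rescales each set's scores
    to [0, 1] across samples (off by default).
    """
    mat = profile.matrix
    genes = mat.index
    rows = {}
    for name in sets:
        members = [g for g in sets[name] if g in genes]
        if len(members) < min_genes:
            warnings.warn(
                f"gene set {name!r}: only {len(members)} gene(s) in matrix; skipped",
                stacklevel=2,
            )
            continue
        mask = np.asarray(genes.isin(members))
        if mask.all():
            raise ValueError(
                f"gene set {name!r} covers every gene in the matrix; "
                "the out-of-set ECDF is undefined"
            )
        rows[name] = [
            _ssgsea_one_sample(mat.iloc[:, j].to_numpy(dtype=float), mask, alpha)
            for j in range(mat.shape[1])
        ]
    out = pd.DataFrame(rows, index=mat.columns).T
    if minmax_normalize and len(out):
        rng = out.max(axis=1) - out.min(axis=1)
        out = out.sub(out.min(axis=1), axis=0).div(rng.replace(0.0, np.nan), axis=0).fillna(0.0)
    return out


def tls_score(
    profile: ExpressionProfile, chemokine_set: Sequence[str] | None = None
) -> pd.Series:
    """Mean normalized expression of the TLS chemokine genes, per sample.

    Genes absent from the matrix are dropped with a warning naming them;
    no gene matching at all is an error.
    """
    if chemokine_set is None:
        chemokine_set = tls_chemokine_genes()
    if profile.normalization == "raw":
        profile = normalize_expression(profile)
    present = [g for g in chemokine_set if g in profile.matrix.index]
    missing = [g for g in chemokine_set if g not in profile.matrix.index]
    if not present:
        raise ValueError("none of the TLS chemokine genes are in the matrix")
    if missing:
        warnings.warn(f"TLS genes missing from matrix: {missing}", stacklevel=2)
    return profile.matrix.loc[present].mean(axis=0).rename("tls_score")


def compare_groups_fdr(
    scores: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    fdr_threshold: float = 0.10,
) -> pd.DataFrame:
    """Per-set Wilcoxon rank-sum high-vs-low comparison with BH control.

    ``scores`` is sets x samples; ``groups`` maps sample -> 'high'/'low'.
    A set is flagged enriched when its BH q-value is at or below the
    threshold AND its median score is higher in the high group.
    """
    g = pd.Series(groups).reindex(scores.columns)
    if g.isna().any():
        raise ValueError(f"samples without group: {list(g.index[g.isna()])}")
    hi = scores.loc[:, (g == "high").to_numpy()]
    lo = scores.loc[:, (g == "low").to_numpy()]
    if hi.shape[1] < 3 or lo.shape[1] < 3:
        raise ValueError("each group needs at least 3 samples")
    rows = []
    for name in scores.index:
        a, b = hi.loc[name].to_numpy(), lo.loc[name].to_numpy()
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append(
            {
                "set": name,
                "median_high": float(np.median(a)),
                "median_low": float(np.median(b)),
                "wilcoxon_p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = multipletests(out["wilcoxon_p"], method="fdr_bh")[1]
    out["enriched"] = (out["q"] <= fdr_threshold) & (out["median_high"] > out["median_low"])
    return out
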