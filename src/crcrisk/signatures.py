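"""96-trinucleotide-context mutation spectra and catalog cosine matching.

Single-base substitutions are collapsed to the pyrimidine strand: a purine
reference (A/G) variant is reverse-complemented, together with its flanking
context, before binning. The 96 bins are ordered substitution-major
(C>A, C>G, C>T, T>A, T>C, T>G), then 5' flank, then 3' flank, each flank in
A, C, G, T order, labelled COSMIC-style ("A[C>A]A", ..., "T[T>G]T").

De-novo signature extraction is out of scope here: hypermutator aetiology
(e.g. a POLE-exonuclease, SBS10b-like spectrum) is identified by cosine
similarity against a reference catalog.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import VariantRecord

__all__ = [
    "SUBSTITUTIONS",
    "context96_labels",
    "context96_profile",
    "SignatureCatalog",
    "read_catalog",
    "bundled_catalog",
    "match_signature",
    "cosine_similarity",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def context96_labels() -> list[str]:
    """The fixed 96-bin index, substitution-major then 5' then 3' flank."""
    return [
        f"{five}[{sub}]{three}"
        for sub in SUBSTITUTIONS
        for five in _BASES
        for three in _BASES
    ]


_LABELS = context96_labels()
_LABEL_POS = {lab: i for i, lab in enumerate(_LABELS)}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def context96_profile(variants: Sequence[VariantRecord]) -> pd.Series:
    """Bin SNVs with trinucleotide context into the 96-context spectrum.

    Non-SNVs and SNVs without context are ignored; a context whose middle
    base disagrees with the reference allele is excluded with a warning.
    The returned counts sum to the number of valid binned SNVs.
    """
    counts = np.zeros(96, dtype=np.int64)
    for v in variants:
        if not v.is_snv or v.context3 is None:
            continue
        ctx = v.context3.upper()
        ref, alt = v.ref.upper(), v.alt.upper()
        if any(b not in _COMPLEMENT for b in ctx):
            warnings.warn(f"non-ACGT context {ctx!r} at {v.chrom}:{v.pos}; excluded", stacklevel=2)
            continue
        if ctx[1] != ref:
            warnings.warn(
                f"context middle base {ctx[1]!r} != ref {ref!r} at {v.chrom}:{v.pos}; excluded",
                stacklevel=2,
            )
            continue
        if ref in ("A", "G"):  # collapse to pyrimidine strand
            ctx = _revcomp(ctx)
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        counts[_LABEL_POS[f"{ctx[0]}[{ref}>{alt}]{ctx[2]}"]] += 1
    return pd.Series(counts, index=_LABELS, name="count")


class SignatureCatalog:
    """Named reference spectra, each a 96-vector summing to one."""

    def __init__(self, spectra: pd.DataFrame):
        if list(spectra.index) != _LABELS:
            spectra = spectra.reindex(_LABELS)
            if spectra.isna().any().any():
                raise ValueError("catalog is missing contexts from the 96-bin index")
        if (spectra.to_numpy() < 0).any():
            raise ValueError("catalog spectra must be non-negative")
        sums = spectra.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = list(sums.index[~np.isclose(sums, 1.0, atol=1e-6)])
            raise ValueError(f"catalog spectra must sum to 1: {bad}")
        self.spectra = spectra

    @property
    def names(self) -> list[str]:
        return list(self.spectra.columns)

    def __getitem__(self, name: str) -> pd.Series:
        return self.spectra[name]


def read_catalog(path: str | Path) -> SignatureCatalog:
    """Read a catalog TSV: first column context labels, one column per signature."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureCatalog(df)


def bundled_catalog() -> SignatureCatalog:
    """The small synthetic COSMIC-style catalog shipped with the package.

    These spectra are constructed stand-ins (see data/signature_catalog.synthetic.tsv),
    not the COSMIC reference; supply a full COSMIC TSV for real analyses.
    """
    path = Path(__file__).parent / "data" / "signature_catalog.synthetic.tsv"
    return read_catalog(path)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def match_signature(
    profile: pd.Series, catalog: SignatureCatalog
) -> list[tuple[str, float]]:
    """Rank catalog entries by cosine similarity to the observed spectrum.

    Sorted descending by similarity, ties broken alphabetically. A zero
    profile carries no information and is an error.
    """
    p = profile.reindex(_LABELS).to_numpy(dtype=float)
    if p.sum() <= 0:
        raise ValueError("cannot match an empty (zero-count) spectrum")
    sims = [
        (name, cosine_similarity(p, catalog[name].to_numpy(dtype=float)))
        for name in catalog.names
    ]
    return sorted(sims, key=lambda t: (-t[1], t[0]))
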