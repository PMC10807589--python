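"""Tumor mutational burden, MSI calling and POLE exonuclease-domain flags.

TMB is the count of non-synonymous somatic mutations per megabase of the
captured exome. MSI-H is called from a laboratory label when present,
otherwise from MSIsensor (>= 3.5) or MANTIS (> 0.4) scores. A sample is
POLE-exonuclease-flagged when it carries a non-synonymous POLE variant
inside the proofreading domain (default residues 268-471).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .cohort import (
    NONSYNONYMOUS_CLASSES,
    ClinicalRecord,
    MsiLabel,
    VariantClass,
    VariantRecord,
)

__all__ = [
    "MSISENSOR_THRESHOLD",
    "MANTIS_THRESHOLD",
    "POLE_EXONUCLEASE_DOMAIN",
    "DEFAULT_REGION_SIZE_MB",
    "DEFAULT_TMB_THRESHOLD",
    "compute_tmb",
    "call_msi",
    "flag_tmb_high",
    "tmb_threshold_from_percentile",
    "flag_pole_exo",
    "region_size_from_bed",
]

MSISENSOR_THRESHOLD = 3.5  # MSI-H iff score >= threshold
MANTIS_THRESHOLD = 0.4  # MSI-H iff score > threshold (strict)
POLE_EXONUCLEASE_DOMAIN = (268, 471)  # inclusive protein residues
DEFAULT_REGION_SIZE_MB = 38.0  # human exome capture
DEFAULT_TMB_THRESHOLD = 10.0  # mut/Mb, common clinical convention


def compute_tmb(
    variants: Sequence[VariantRecord],
    region_size_mb: float = DEFAULT_REGION_SIZE_MB,
    qualifying_classes: frozenset[VariantClass] = NONSYNONYMOUS_CLASSES,
) -> float:
    """Non-synonymous mutation count per megabase for one sample."""
    if region_size_mb <= 0:
        raise ValueError(f"region_size_mb must be > 0, got {region_size_mb}")
    n = sum(1 for v in variants if v.variant_class in qualifying_classes)
    return n / region_size_mb


def call_msi(record: ClinicalRecord) -> bool:
    """True iff MSI-H. Lab label wins; else MSIsensor >= 3.5 or MANTIS > 0.4."""
    if record.msi_label is not None:
        return record.msi_label is MsiLabel.MSI_H
    if record.msisensor_score is None and record.mantis_score is None:
        raise ValueError(
            f"{record.sample_id}: no MSI evidence (label, MSIsensor or MANTIS required)"
        )
    if record.msisensor_score is not None and record.msisensor_score >= MSISENSOR_THRESHOLD:
        return True
    if record.mantis_score is not None and record.mantis_score > MANTIS_THRESHOLD:
        return True
    return False


def flag_tmb_high(tmb: float, threshold: float = DEFAULT_TMB_THRESHOLD) -> bool:
    """Inclusive comparison: TMB-high iff tmb >= threshold."""
    return tmb >= threshold


def tmb_threshold_from_percentile(tmb_values: Sequence[float], percentile: float) -> float:
    """Cohort-percentile alternative to the fixed mut/Mb threshold."""
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must be in [0, 100]")
    return float(np.percentile(np.asarray(tmb_values, dtype=float), percentile))


def flag_pole_exo(
    variants: Sequence[VariantRecord],
    domain: tuple[int, int] = POLE_EXONUCLEASE_DOMAIN,
    gene: str = "POLE",
) -> bool:
    """True iff a non-synonymous POLE variant falls inside the domain.

    Variants lacking a protein position cannot be placed and are skipped
    with a warning rather than guessed at.
    """
    lo, hi = domain
    for v in variants:
        if v.gene != gene or v.variant_class not in NONSYNONYMOUS_CLASSES:
            continue
        if v.protein_pos is None:
            warnings.warn(
                f"{v.sample_id}: {gene} variant at {v.chrom}:{v.pos} lacks protein_pos; "
                "not counted for exonuclease-domain flagging",
                stacklevel=2,
            )
            continue
        if lo <= v.protein_pos <= hi:
            return True
    return False


def region_size_from_bed(path: str | Path) -> float:
    """Summed interval length (Mb) of a 0-based half-open BED capture file."""
    total = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            start, end = int(fields[1]), int(fields[2])
            if end < start:
                raise ValueError(f"BED interval end < start: {line!r}")
            total += end - start
    return total / 1e6
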