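"""Cohort assembly: somatic variant and clinical tables.

The pipeline's universal currency is a :class:`Cohort`: clinical records, a
binary samples x genes mutation matrix, per-sample tumor mutational burden
(TMB) and the derived flags (TMB-high, MSI-H, POLE exonuclease-domain).

Input tables are MAF-like, UTF-8, tab-delimited; ``.`` or an empty field
means missing. Column names are mapped through a :class:`VariantDialect`
so arbitrary supplementary-table exports can be absorbed via configuration.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantClass",
    "NONSYNONYMOUS_CLASSES",
    "VariantRecord",
    "ClinicalRecord",
    "Cohort",
    "VariantDialect",
    "RowError",
    "read_variant_table",
    "write_variant_table",
    "read_clinical_table",
    "write_clinical_table",
    "build_mutation_matrix",
    "build_cohort",
]


class VariantClass(str, enum.Enum):
    """Functional consequence classes recognised for somatic variants."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT_INS = "frameshift_ins"
    FRAMESHIFT_DEL = "frameshift_del"
    SPLICE_SITE = "splice_site"
    STOP_LOSS = "stop_loss"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Classes that count as non-synonymous: they set a gene "mutated" for
#: scoring and contribute to TMB. Synonymous and unclassifiable calls do not.
NONSYNONYMOUS_CLASSES: frozenset[VariantClass] = frozenset(
    {
        VariantClass.MISSENSE,
        VariantClass.NONSENSE,
        VariantClass.FRAMESHIFT_INS,
        VariantClass.FRAMESHIFT_DEL,
        VariantClass.SPLICE_SITE,
        VariantClass.STOP_LOSS,
        VariantClass.INFRAME_INDEL,
    }
)

# common MAF "Variant_Classification" spellings mapped onto our enum
_CLASS_ALIASES: dict[str, VariantClass] = {
    "missense_mutation": VariantClass.MISSENSE,
    "missense": VariantClass.MISSENSE,
    "nonsense_mutation": VariantClass.NONSENSE,
    "nonsense": VariantClass.NONSENSE,
    "frame_shift_ins": VariantClass.FRAMESHIFT_INS,
    "frameshift_ins": VariantClass.FRAMESHIFT_INS,
    "frame_shift_del": VariantClass.FRAMESHIFT_DEL,
    "frameshift_del": VariantClass.FRAMESHIFT_DEL,
    "splice_site": VariantClass.SPLICE_SITE,
    "nonstop_mutation": VariantClass.STOP_LOSS,
    "stop_loss": VariantClass.STOP_LOSS,
    "in_frame_ins": VariantClass.INFRAME_INDEL,
    "in_frame_del": VariantClass.INFRAME_INDEL,
    "inframe_indel": VariantClass.INFRAME_INDEL,
    "silent": VariantClass.SYNONYMOUS,
    "synonymous": VariantClass.SYNONYMOUS,
}


def _parse_variant_class(raw: str) -> VariantClass:
    return _CLASS_ALIASES.get(raw.strip().lower(), VariantClass.OTHER)


_SNV_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantRecord:
    """One somatic call: sample, gene, position, alleles, consequence.

    ``context3`` is the reference trinucleotide centred on the variant
    position (only meaningful for SNVs); ``protein_pos`` the 1-based
    residue of the protein change when annotated.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass
    protein_pos: int | None = None
    context3: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.context3 is not None:
            if len(self.context3) != 3:
                raise ValueError(f"context3 must have length 3, got {self.context3!r}")
            if self.is_snv and self.context3[1].upper() != self.ref.upper():
                raise ValueError(
                    f"context3 middle base {self.context3[1]!r} != ref {self.ref!r}"
                )

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref.upper() in _SNV_BASES
            and self.alt.upper() in _SNV_BASES
        )


class Group(str, enum.Enum):
    R = "R"  # relapsed within 2 years
    NR = "NR"  # relapse-free beyond 5 years


class Stage(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


class MsiLabel(str, enum.Enum):
    MSI_H = "MSI-H"
    MSS = "MSS"


def derive_group(rfs_time: float | None, rfs_event: int | None) -> Group | None:
    """R if relapse (event) before 24 months; NR if relapse-free past 60."""
    if rfs_time is None:
        return None
    if rfs_event == 1 and rfs_time < 24:
        return Group.R
    if rfs_time > 60:
        return Group.NR
    return None


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient clinical data: outcome grouping, stage, MSI evidence."""

    sample_id: str
    group: Group | None = None
    rfs_time: float | None = None
    rfs_event: int | None = None
    stage: Stage | None = None
    msi_label: MsiLabel | None = None
    msisensor_score: float | None = None
    mantis_score: float | None = None

    def __post_init__(self) -> None:
        if self.group is None and self.rfs_time is None:
            raise ValueError(
                f"{self.sample_id}: need group or (rfs_time, rfs_event)"
            )
        if self.rfs_time is not None and self.rfs_time < 0:
            raise ValueError(f"{self.sample_id}: negative rfs_time")
        for name in ("msisensor_score", "mantis_score"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{self.sample_id}: negative {name}")
        derived = derive_group(self.rfs_time, self.rfs_event)
        if self.group is not None and derived is not None and self.group != derived:
            raise ValueError(
                f"{self.sample_id}: group {self.group.value} contradicts "
                f"rfs_time={self.rfs_time}, rfs_event={self.rfs_event}"
            )


@dataclass
class Cohort:
    """Clinical records + binary mutation matrix + TMB + per-sample flags.

    ``mutation_matrix`` rows are samples (aligned with ``clinical``),
    columns genes, entries 0/1. ``flags`` carries boolean columns
    ``tmb_high``, ``msi_h``, ``pole_exo`` and a real column ``tmb``.
    """

    clinical: list[ClinicalRecord]
    mutation_matrix: pd.DataFrame
    flags: pd.DataFrame
    variants: list[VariantRecord] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        ids = [c.sample_id for c in self.clinical]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        if list(self.mutation_matrix.index) != ids:
            raise ValueError("mutation_matrix rows must match clinical sample ids")
        vals = self.mutation_matrix.to_numpy()
        if not np.isin(vals, [0, 1]).all():
            raise ValueError("mutation_matrix entries must be 0/1")
        if list(self.flags.index) != ids:
            raise ValueError("flags rows must match clinical sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return [c.sample_id for c in self.clinical]

    @property
    def tmb(self) -> pd.Series:
        return self.flags["tmb"]

    def labels(self) -> pd.Series:
        """Group label per sample ('R'/'NR'; None when unlabeled)."""
        return pd.Series(
            [c.group.value if c.group else None for c in self.clinical],
            index=self.sample_ids,
            name="group",
        )

    def labeled_subset(self) -> "Cohort":
        """Restrict to samples carrying an R/NR label."""
        keep = [c.sample_id for c in self.clinical if c.group is not None]
        return self.subset(keep)

    def subset(self, sample_ids: Sequence[str]) -> "Cohort":
        wanted = set(sample_ids)
        clin = [c for c in self.clinical if c.sample_id in wanted]
        order = [c.sample_id for c in clin]
        return Cohort(
            clinical=clin,
            mutation_matrix=self.mutation_matrix.loc[order],
            flags=self.flags.loc[order],
            variants=[v for v in self.variants if v.sample_id in wanted],
        )


# ---------------------------------------------------------------------------
# table dialects and parsing


@dataclass(frozen=True)
class VariantDialect:
    """Column mapping for MAF-like variant tables."""

    sample_id: str = "sample"
    gene: str = "gene"
    chrom: str = "chrom"
    pos: str = "pos"
    ref: str = "ref"
    alt: str = "alt"
    variant_class: str = "variant_class"
    protein_pos: str | None = "protein_pos"
    context3: str | None = "context3"

    def required(self) -> list[str]:
        return [
            self.sample_id,
            self.gene,
            self.chrom,
            self.pos,
            self.ref,
            self.alt,
            self.variant_class,
        ]


#: Column mapping for standard MAF exports.
MAF_DIALECT = VariantDialect(
    sample_id="Tumor_Sample_Barcode",
    gene="Hugo_Symbol",
    chrom="Chromosome",
    pos="Start_Position",
    ref="Reference_Allele",
    alt="Tumor_Seq_Allele2",
    variant_class="Variant_Classification",
    protein_pos=None,
    context3=None,
)


@dataclass(frozen=True)
class RowError:
    """Diagnostic for a rejected input row (0-based data row index)."""

    row: int
    message: str


def _is_missing(value: object) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or str(value).strip() in ("", ".")


def read_variant_table(
    path: str | Path,
    dialect: VariantDialect | None = None,
) -> tuple[list[VariantRecord], list[RowError]]:
    """Parse a variant TSV into records plus row-indexed diagnostics.

    Unknown columns are ignored; unknown variant classes map to ``other``.
    A missing required column is a hard error; a malformed row is rejected
    into the diagnostics list, never silently dropped.
    """
    dialect = dialect or VariantDialect()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    missing_cols = [c for c in dialect.required() if c not in df.columns]
    if missing_cols:
        raise ValueError(f"variant table missing required column(s): {missing_cols}")

    records: list[VariantRecord] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        try:
            pos_raw = row_d[dialect.pos]
            try:
                pos = int(pos_raw)
            except ValueError as exc:
                raise ValueError(f"unparseable pos {pos_raw!r}") from exc
            protein_pos = None
            if dialect.protein_pos and not _is_missing(row_d.get(dialect.protein_pos)):
                protein_pos = int(row_d[dialect.protein_pos])
            context3 = None
            if dialect.context3 and not _is_missing(row_d.get(dialect.context3)):
                context3 = str(row_d[dialect.context3]).upper()
            records.append(
                VariantRecord(
                    sample_id=str(row_d[dialect.sample_id]),
                    gene=str(row_d[dialect.gene]),
                    chrom=str(row_d[dialect.chrom]),
                    pos=pos,
                    ref=str(row_d[dialect.ref]).upper(),
                    alt=str(row_d[dialect.alt]).upper(),
                    variant_class=_parse_variant_class(str(row_d[dialect.variant_class])),
                    protein_pos=protein_pos,
                    context3=context3,
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(RowError(row=i, message=str(exc)))
    return records, errors


def write_variant_table(
    records: Iterable[VariantRecord],
    path: str | Path,
    dialect: VariantDialect | None = None,
) -> None:
    """Write records as TSV using the dialect's column names ('.' = missing)."""
    dialect = dialect or VariantDialect()
    rows = []
    for r in records:
        row = {
            dialect.sample_id: r.sample_id,
            dialect.gene: r.gene,
            dialect.chrom: r.chrom,
            dialect.pos: r.pos,
            dialect.ref: r.ref,
            dialect.alt: r.alt,
            dialect.variant_class: r.variant_class.value,
        }
        if dialect.protein_pos:
            row[dialect.protein_pos] = r.protein_pos if r.protein_pos is not None else "."
        if dialect.context3:
            row[dialect.context3] = r.context3 if r.context3 is not None else "."
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_CLINICAL_COLUMNS = [
    "sample",
    "group",
    "rfs_time",
    "rfs_event",
    "stage",
    "msi_label",
    "msisensor_score",
    "mantis_score",
]


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    """Parse the clinical TSV; group is derived from RFS when absent.

    Derivation: relapse (event=1) before 24 months -> R; relapse-free past
    60 months -> NR; anything else stays unlabeled and is excluded from
    screening downstream.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample" not in df.columns:
        raise ValueError("clinical table missing required column 'sample'")
    records = []
    for _, row in df.iterrows():
        get = lambda c: None if c not in df.columns or _is_missing(row[c]) else row[c]
        rfs_time = get("rfs_time")
        rfs_event = get("rfs_event")
        rfs_time = float(rfs_time) if rfs_time is not None else None
        rfs_event = int(rfs_event) if rfs_event is not None else None
        group_raw = get("group")
        group = Group(group_raw) if group_raw else derive_group(rfs_time, rfs_event)
        stage = get("stage")
        msi = get("msi_label")
        msis = get("msisensor_score")
        mantis = get("mantis_score")
        records.append(
            ClinicalRecord(
                sample_id=str(row["sample"]),
                group=group,
                rfs_time=rfs_time,
                rfs_event=rfs_event,
                stage=Stage(stage) if stage else None,
                msi_label=MsiLabel(msi) if msi else None,
                msisensor_score=float(msis) if msis is not None else None,
                mantis_score=float(mantis) if mantis is not None else None,
            )
        )
    return records


def write_clinical_table(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["sample"] = d.pop("sample_id")
        for k, v in d.items():
            if isinstance(v, enum.Enum):
                d[k] = v.value
            elif v is None:
                d[k] = "."
        rows.append({c: d[c] for c in _CLINICAL_COLUMNS})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def build_mutation_matrix(
    variants: Sequence[VariantRecord],
    samples: Sequence[str],
    gene_universe: Sequence[str] | None = None,
    qualifying_classes: frozenset[VariantClass] = NONSYNONYMOUS_CLASSES,
) -> pd.DataFrame:
    """Binary samples x genes matrix: 1 iff >=1 qualifying variant.

    Samples with no variants appear as all-zero rows; a variant naming an
    unknown sample is an error (it would silently vanish otherwise).
    """
    known = set(samples)
    unknown = sorted({v.sample_id for v in variants} - known)
    if unknown:
        raise ValueError(f"variants reference unknown sample ids: {unknown}")
    if gene_universe is None:
        genes = sorted({v.gene for v in variants if v.variant_class in qualifying_classes})
    else:
        genes = list(gene_universe)
    arr = np.zeros((len(samples), len(genes)), dtype=np.int8)
    srow = {s: i for i, s in enumerate(samples)}
    gcol = {g: j for j, g in enumerate(genes)}
    for v in variants:
        if v.variant_class in qualifying_classes and v.gene in gcol:
            arr[srow[v.sample_id], gcol[v.gene]] = 1
    return pd.DataFrame(arr, index=list(samples), columns=genes)


def build_cohort(
    variants: Sequence[VariantRecord],
    clinical: Sequence[ClinicalRecord],
    region_size_mb: float = 38.0,
    tmb_threshold: float = 10.0,
    gene_universe: Sequence[str] | None = None,
    pole_domain: tuple[int, int] = (268, 471),
) -> Cohort:
    """Assemble the full cohort: matrix, TMB, MSI/TMB-high/POLE flags."""
    from . import tmb_msi  # late import: tmb_msi depends on this module's types

    clinical = list(clinical)
    ids = [c.sample_id for c in clinical]
    matrix = build_mutation_matrix(variants, ids, gene_universe=gene_universe)
    by_sample: dict[str, list[VariantRecord]] = {i: [] for i in ids}
    for v in variants:
        by_sample[v.sample_id].append(v)
    tmb = pd.Series(
        {i: tmb_msi.compute_tmb(by_sample[i], region_size_mb) for i in ids},
        name="tmb",
    ).loc[ids]
    flags = pd.DataFrame(
        {
            "tmb": tmb,
            "tmb_high": [tmb_msi.flag_tmb_high(t, tmb_threshold) for t in tmb],
            "msi_h": [tmb_msi.call_msi(c) for c in clinical],
            "pole_exo": [
                tmb_msi.flag_pole_exo(by_sample[i], domain=pole_domain) for i in ids
            ],
        },
        index=ids,
    )
    return Cohort(clinical=clinical, mutation_matrix=matrix, flags=flags, variants=list(variants))
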