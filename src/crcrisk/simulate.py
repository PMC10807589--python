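"""Seeded synthetic cohorts with the structure the recurrence analysis assumes.

The generator emulates a two-arm discovery cohort (R: relapse within two
years; NR: relapse-free beyond five) the size of the study it mirrors
(23 R / 24 NR by default), with:

* eight "signal" genes mutated frequently in NR and almost never in R,
  co-mutating through a shared per-sample latent Bernoulli;
* a background of passenger genes mutated at a group-independent rate;
* per-sample non-synonymous variant counts drawn lognormally per stratum,
  so TMB is computed from actual variant lists, never written directly;
* MSI-H hypermutators (high MSIsensor/MANTIS scores) and, optionally,
  POLE-exonuclease-like confounders planted in the R group: G8-high,
  TMB-high, MSS, a POLE exonuclease-domain variant, and trinucleotide
  contexts drawn from an SBS10b-like spectrum — the phenotype the G8plus
  penalty exists to catch;
* expression matrices whose immune-marker and TLS chemokine genes are
  shifted upward in score-high samples.

Every generator is a pure function of (params, seed); the planted truth is
returned alongside the data and nothing downstream may read it except tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import (
    ClinicalRecord,
    Cohort,
    Group,
    Stage,
    VariantClass,
    VariantRecord,
    build_cohort,
)
from .immune import ExpressionProfile, GeneSetCollection, bundled_immune_sets, tls_chemokine_genes
from .signatures import bundled_catalog

__all__ = [
    "SimulationParams",
    "ExpressionParams",
    "Truth",
    "simulate_cohort",
    "simulate_rfs",
    "simulate_expression",
]

_DEFAULT_SIGNAL_GENES = (
    "CUL9",
    "PCDHA12",
    "HECTD3",
    "DCX",
    "SMARCA2",
    "FAM193A",
    "AATK",
    "SORCS2",
)

_SNV_CLASSES = (
    VariantClass.MISSENSE,
    VariantClass.NONSENSE,
    VariantClass.SPLICE_SITE,
    VariantClass.STOP_LOSS,
)
_SNV_CLASS_CUM = np.cumsum((0.80, 0.10, 0.07, 0.03))


@dataclass(frozen=True)
class ExpressionParams:
    """Controls for the synthetic expression matrix."""

    effect_size_sd: float = 1.0  # upward shift of immune/TLS genes, in SDs
    n_noise_genes: int = 500
    base_log2_mean: float = 5.0
    log2_sd: float = 1.0


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the synthetic cohort.

    Defaults are sized to the mirrored study: 23 relapsing and 24
    non-relapsing patients, eight signal genes mutated in half the NR arm
    but almost never in R, ~150 non-synonymous variants per exome
    (TMB ~ 4 mut/Mb over a 38 Mb capture) for ordinary tumors, ~29 mut/Mb
    for MSI-H hypermutators (an MSI-H fraction of 4/47), and, when
    ``penalty_confounder`` is enabled, two POLE-like ultramutated penalty
    confounders planted in the R arm.
    """

    n_R: int = 23
    n_NR: int = 24
    signal_genes: tuple[str, ...] = _DEFAULT_SIGNAL_GENES
    p_signal_NR: float = 0.5
    p_signal_R: float = 0.02
    comutation_strength: float = 0.55  # P(gene mutated | latent on)
    p_signal_pole: float = 0.35  # per-gene passenger hit rate in POLE ultramutators
    n_background_genes: int = 300
    background_rate: float = 0.15
    # non-hypermutated baselines per arm: NR tumors carry modestly more
    # mutations (median ratio ~1.2, a weak discriminator on its own); the
    # tight sigma keeps baseline tumors below the TMB-high threshold, so
    # TMB-high & MSS stays specific to the hypermutator phenotype
    tmb_lognormal_R: tuple[float, float] = (float(np.log(150.0)), 0.25)
    tmb_lognormal_NR: tuple[float, float] = (float(np.log(180.0)), 0.25)
    tmb_lognormal_msi: tuple[float, float] = (float(np.log(1100.0)), 0.25)
    tmb_lognormal_pole: tuple[float, float] = (float(np.log(6000.0)), 0.3)
    synonymous_fraction: float = 0.3  # extra synonymous variants, vs non-syn count
    frac_msi_h: float = 4 / 47
    frac_pole: float = 2 / 23  # fraction of the R arm planted as confounders
    penalty_confounder: bool = False  # opt in to plant POLE confounders
    region_size_mb: float = 38.0
    tmb_threshold: float = 10.0
    rfs_hazards: Mapping[str, float] = field(
        default_factory=lambda: {"R": 1 / 10.0, "NR": 1 / 400.0}
    )  # per month; R median ~7 months, NR mostly censored
    censor_time: float = 84.0
    expression: ExpressionParams = ExpressionParams()

    def __post_init__(self) -> None:
        if self.n_R < 1 or self.n_NR < 1:
            raise ValueError("n_R and n_NR must be >= 1")
        for name in (
            "p_signal_NR",
            "p_signal_R",
            "comutation_strength",
            "background_rate",
            "frac_msi_h",
            "frac_pole",
            "synonymous_fraction",
            "p_signal_pole",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.comutation_strength < max(self.p_signal_NR, self.p_signal_R):
            raise ValueError(
                "comutation_strength must be >= the marginal signal probabilities"
            )


@dataclass
class Truth:
    """Planted ground truth, for tests only."""

    signal_genes: tuple[str, ...]
    latent: pd.Series  # per-sample co-mutation latent indicator
    pole_confounders: list[str]
    msi_h_samples: list[str]


def _draw_context(rng: np.random.Generator, spectrum: np.ndarray, labels: list[str]):
    # spectrum is passed as a cumulative distribution for speed
    lab = labels[min(int(np.searchsorted(spectrum, rng.random())), len(labels) - 1)]
    five, rest = lab[0], lab[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return five + ref + three, ref, alt


def _make_snv(
    rng: np.random.Generator,
    sample_id: str,
    gene: str,
    spectrum: np.ndarray,
    labels: list[str],
    variant_class: VariantClass | None = None,
    protein_pos: int | None = None,
) -> VariantRecord:
    ctx, ref, alt = _draw_context(rng, spectrum, labels)
    if variant_class is None:
        k = min(int(np.searchsorted(_SNV_CLASS_CUM, rng.random())), len(_SNV_CLASSES) - 1)
        variant_class = _SNV_CLASSES[k]
    return VariantRecord(
        sample_id=sample_id,
        gene=gene,
        chrom=f"chr{int(rng.integers(1, 23))}",
        pos=int(rng.integers(1, 100_000_000)),
        ref=ref,
        alt=alt,
        variant_class=variant_class,
        protein_pos=protein_pos,
        context3=ctx,
    )


def simulate_cohort(
    params: SimulationParams = SimulationParams(), seed: int = 0
) -> tuple[Cohort, Truth]:
    """Generate a labeled cohort (variants, clinical, flags) plus the truth.

    Reproducible: the same (params, seed) yields an identical cohort.
    """
    rng = np.random.default_rng(seed)
    catalog = bundled_catalog()
    labels96 = list(catalog.spectra.index)
    spec_normal = np.cumsum(catalog["SBS5like"].to_numpy())
    spec_pole = np.cumsum(catalog["SBS10blike"].to_numpy())

    sample_ids = [f"R{i + 1:02d}" for i in range(params.n_R)] + [
        f"NR{i + 1:02d}" for i in range(params.n_NR)
    ]
    groups = [Group.R] * params.n_R + [Group.NR] * params.n_NR

    n_pole = round(params.frac_pole * params.n_R) if params.penalty_confounder else 0
    pole_ids = sample_ids[:n_pole]  # planted in the R arm
    msi_flags = rng.random(len(sample_ids)) < params.frac_msi_h
    # POLE confounders are MSS by construction (that is the phenotype)
    msi_flags[:n_pole] = False
    msi_ids = [s for s, f in zip(sample_ids, msi_flags) if f]

    bg_genes = [f"BG{i + 1:03d}" for i in range(params.n_background_genes)]
    r = params.comutation_strength
    latent: dict[str, int] = {}
    variants: list[VariantRecord] = []
    clinical: list[ClinicalRecord] = []

    for sid, grp, is_msi in zip(sample_ids, groups, msi_flags):
        is_pole = sid in pole_ids
        p_signal = params.p_signal_NR if grp is Group.NR else params.p_signal_R
        q_latent = p_signal / r if r > 0 else 0.0
        z = 0 if is_pole else int(rng.random() < q_latent)
        latent[sid] = z
        spectrum = spec_pole if is_pole else spec_normal

        mutated: list[str] = []
        for g in params.signal_genes:
            # confounders hit panel genes as hypermutation passengers, not
            # through the co-mutation phenotype
            p_hit = params.p_signal_pole if is_pole else (r if z == 1 else 0.0)
            if rng.random() < p_hit:
                mutated.append(g)
        for g in bg_genes:
            if rng.random() < params.background_rate:
                mutated.append(g)

        if is_pole:
            mu, sigma = params.tmb_lognormal_pole
        elif is_msi:
            mu, sigma = params.tmb_lognormal_msi
        elif grp is Group.NR:
            mu, sigma = params.tmb_lognormal_NR
        else:
            mu, sigma = params.tmb_lognormal_R
        n_target = int(round(rng.lognormal(mu, sigma)))

        sample_variants = [
            _make_snv(rng, sid, g, spectrum, labels96) for g in mutated
        ]
        if is_pole:
            sample_variants.append(
                _make_snv(
                    rng,
                    sid,
                    "POLE",
                    spectrum,
                    labels96,
                    variant_class=VariantClass.MISSENSE,
                    protein_pos=286,  # recurrent exonuclease-domain hotspot
                )
            )
        # filler variants land in genes already mutated in this sample, so
        # the binary matrix is untouched while TMB reaches its lognormal target
        n_filler = n_target - len(sample_variants)
        if n_filler > 0:
            pool = mutated if mutated else [bg_genes[int(rng.integers(len(bg_genes)))]]
            for g in rng.choice(pool, size=n_filler):
                sample_variants.append(_make_snv(rng, sid, str(g), spectrum, labels96))
        n_syn = rng.binomial(len(sample_variants), params.synonymous_fraction)
        for g in rng.choice(bg_genes, size=n_syn):
            sample_variants.append(
                _make_snv(
                    rng, sid, str(g), spectrum, labels96,
                    variant_class=VariantClass.SYNONYMOUS,
                )
            )
        variants.extend(sample_variants)

        if is_msi:
            msisensor = float(rng.uniform(5.0, 20.0))
            mantis = float(rng.uniform(0.45, 0.8))
        else:
            msisensor = float(rng.uniform(0.0, 2.0))
            mantis = float(rng.uniform(0.05, 0.35))
        clinical.append(
            ClinicalRecord(
                sample_id=sid,
                group=grp,
                stage=Stage.III,
                msisensor_score=round(msisensor, 3),
                mantis_score=round(mantis, 3),
            )
        )

    cohort = build_cohort(
        variants,
        clinical,
        region_size_mb=params.region_size_mb,
        tmb_threshold=params.tmb_threshold,
    )
    truth = Truth(
        signal_genes=params.signal_genes,
        latent=pd.Series(latent, name="latent").loc[sample_ids],
        pole_confounders=list(pole_ids),
        msi_h_samples=msi_ids,
    )
    return cohort, truth


def simulate_rfs(
    cohort: Cohort,
    hazards: Mapping[str, float] | None = None,
    censor_time: float = 84.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential recurrence times per risk group with administrative censoring.

    Returns a DataFrame indexed by sample with ``rfs_time`` (months) and
    ``rfs_event`` (1 = relapse observed before ``censor_time``).
    """
    hazards = dict(hazards or {"R": 1 / 10.0, "NR": 1 / 400.0})
    for g, h in hazards.items():
        if h <= 0:
            raise ValueError(f"hazard for group {g!r} must be > 0, got {h}")
    if censor_time < 0:
        raise ValueError("censor_time must be >= 0")
    rng = np.random.default_rng(seed)
    labels = cohort.labels()
    times, events = [], []
    for sid in cohort.sample_ids:
        grp = labels.loc[sid]
        if grp not in hazards:
            raise ValueError(f"no hazard specified for group {grp!r} (sample {sid})")
        t = rng.exponential(1.0 / hazards[grp])
        if t < censor_time:
            times.append(t)
            events.append(1)
        else:
            times.append(censor_time)
            events.append(0)
    return pd.DataFrame(
        {"rfs_time": times, "rfs_event": events}, index=cohort.sample_ids
    )


def simulate_expression(
    cohort: Cohort,
    params: SimulationParams = SimulationParams(),
    immune_sets: GeneSetCollection | None = None,
    seed: int = 0,
) -> ExpressionProfile:
    """Raw-scale expression with immune/TLS genes shifted in score-high samples.

    A sample is "score-high" when it carries at least one signal-gene
    mutation; its immune-marker and TLS chemokine genes are shifted upward
    by ``params.expression.effect_size_sd`` standard deviations on the log2
    scale. All other genes are exchangeable noise.
    """
    ep = params.expression
    rng = np.random.default_rng(seed)
    if immune_sets is None:
        immune_sets = bundled_immune_sets()
    immune_genes = sorted({g for name in immune_sets for g in immune_sets[name]})
    tls_genes = list(tls_chemokine_genes())
    noise_genes = [f"NOISE{i + 1:04d}" for i in range(ep.n_noise_genes)]
    overlap = set(immune_genes + tls_genes) & set(noise_genes)
    if overlap:
        raise ValueError(f"immune/TLS genes overlap background genes: {sorted(overlap)}")
    genes = immune_genes + tls_genes + noise_genes

    present_signal = [g for g in params.signal_genes if g in cohort.mutation_matrix.columns]
    score = cohort.mutation_matrix[present_signal].sum(axis=1)
    high = (score >= 1).to_numpy()

    shifted = np.isin(genes, immune_genes + tls_genes)
    log2 = rng.normal(ep.base_log2_mean, ep.log2_sd, size=(len(genes), len(cohort.sample_ids)))
    log2[np.ix_(shifted, high)] += ep.effect_size_sd * ep.log2_sd
    matrix = pd.DataFrame(
        np.exp2(log2), index=pd.Index(genes, name="gene"), columns=cohort.sample_ids
    )
    return ExpressionProfile(matrix, normalization="raw")
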