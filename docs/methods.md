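# Methods

This note records the statistical procedures `crcrisk` implements, the
modelling choices made where the design was genuinely open, and what the
synthetic-data tests do and do not establish.

## Cohort model and scoring

A cohort is a set of patients with (i) a binary mutation matrix over genes
(a gene is "mutated" when it carries at least one non-synonymous call:
missense, nonsense, frameshift insertion/deletion, splice site, stop loss
or in-frame indel; synonymous and unclassifiable calls never qualify),
(ii) per-patient TMB = non-synonymous count / capture size in Mb (default
38 Mb, a standard human exome; a capture BED can override it), and (iii)
flags: TMB-high (TMB ≥ 10 mut/Mb by default — the common clinical
convention, as no cohort-specific threshold is fixed; a cohort-percentile
mode is provided), MSI-H (lab label if present, else MSIsensor ≥ 3.5 or
MANTIS > 0.4; the MSIsensor comparison is inclusive, MANTIS strict), and
POLE-exonuclease (any non-synonymous POLE variant with protein position in
268–471, the standard exonuclease-domain annotation; both interval and
gene are configurable).

The **G8 score** is the count of mutated genes among an 8-gene panel
(default CUL9, PCDHA12, HECTD3, DCX, SMARCA2, FAM193A, AATK, SORCS2).
Because panel mutations concentrate in non-relapsing tumors, high score =
low recurrence risk. The **G8plus score** subtracts 2 points when a
patient is TMB-high *and* microsatellite-stable: that combination marks
POLE-exonuclease-like ultramutators whose panel hits are passengers of a
genome-wide mutation excess rather than the protective phenotype. Negative
G8plus values are allowed (no floor); the cutoff logic handles them
naturally.

Classification orientation: recurrence is the positive class, predicted
when score < cutoff. This is the only orientation under which a
perfect-PPV / high-NPV regime is coherent for a score whose high values
mark low risk.

## Screening and panel reduction

Per-gene association uses the two-sided Fisher exact test
(probability-mass definition: sum of hypergeometric probabilities of all
tables with the observed margins no more likely than the observed one;
delegated to `scipy.stats.fisher_exact` and verified against a full
margin-enumeration oracle to 1e-12). Genes are ranked by ascending p,
ties broken by larger absolute frequency difference, then alphabetically;
the top K (default 30) enter reduction.

"Iterative subtraction" is implemented as greedy backward elimination: at
each step, remove the gene whose removal maximizes the ROC AUC of the
summed score; accept only if the AUC does not decrease; on AUC ties remove
the gene with the larger screening p-value (then alphabetically); stop
otherwise or at one gene. The full trace (removed gene, panel, AUC per
accepted step) is returned; accepted AUCs are non-decreasing by
construction. The AUC objective is cutoff-free; the classification cutoff
is derived once, after the panel is fixed. In-sample greedy selection on
~47 patients overfits (it can reach AUC 1.0); the frozen-panel "apply"
mode exists precisely so a panel can be evaluated on data that did not
select it.

Co-occurrence between panel genes is reported as pairwise 2×2 odds ratios
(infinite ratios reported as `inf`, undefined as NaN) with Fisher p and
Benjamini–Hochberg q across all pairs (the correction choice is ours; the
source analyses report co-mutation without naming one).

## ROC, cutoff and metrics

The ROC sweeps candidate cutoffs at midpoints between adjacent distinct
scores (plus sentinels beyond the extremes); sensitivity =
P(score < c | R), specificity = P(score ≥ c | NR). AUC is the trapezoidal
area, identical to the Mann–Whitney U statistic normalized with ties
counted ½ (verified against a pair-counting oracle). The cutoff maximizes
Youden's J = sensitivity + specificity − 1; J-ties resolve toward higher
specificity (favouring the lower cutoff); under perfect separation this
yields the midpoint of the gap, and with fully tied scores (max J = 0) the
lowest sentinel, under which nobody is predicted to recur. Ratios with
zero denominators (e.g. PPV with no positive predictions) are reported as
missing, never as zero.

## Survival

Kaplan–Meier estimation, the log-rank test and Cox proportional hazards
are delegated to lifelines; Cox uses the Efron tie approximation
(lifelines' default and the widely preferred one). Non-convergence and
monotone-likelihood/separation problems are surfaced as a flagged result,
never silently. The multivariate covariate list is caller-supplied; no
fixed covariate set is baked in.

## Mutational signatures

SNVs with a trinucleotide context are binned into the 96 COSMIC-style
contexts (substitution-major order C>A, C>G, C>T, T>A, T>C, T>G; flanks in
A, C, G, T order), collapsing purine-reference calls to the pyrimidine
strand by reverse complement. Aetiology is assigned by cosine similarity
against a catalog of reference spectra, ties broken alphabetically.
De-novo extraction (e.g. NMF) is deliberately out of scope — with a
handful of samples the catalog-matching formulation is the robust choice.
The bundled catalog is a constructed, clearly-synthetic stand-in holding
five COSMIC-like spectra including an SBS10b-like POLE-exonuclease entry;
real analyses should load a full COSMIC TSV
(`read_catalog`, first column context labels, one column per signature).

## Immune profiling

Expression is normalized as log2(x+1) followed by per-gene z-scores across
samples with the n−1 divisor (constant genes map to 0, not NaN). The
normalization behind published "normalized values" is not pinned down
anywhere we could find; log2 + z-score is the default and the mode is
pluggable (`rank` provided). A state tag prevents double normalization.

ssGSEA follows the standard single-sample weighted-Kolmogorov–Smirnov
formulation: per sample, genes are ranked by expression; walking the list
from highest to lowest, the in-set running fraction advances by
rank^α (α = 0.25, the conventional exponent), the out-of-set fraction by
1/(N−m); the enrichment score is the *sum* of the running difference (not
the maximum), making scores smooth in rank changes. Scores are invariant
to any strictly increasing per-sample transform. Per-set min–max rescaling
across samples is available but off by default, since it changes only
cross-set comparability, not within-set tests. Sets with fewer than two
genes matched in the matrix are skipped with a warning.

The TLS score is the arithmetic mean of the normalized values of 12
chemokine genes (CCL2/3/4/5/8/18/19/21, CXCL9/10/11/13); missing genes are
dropped with a warning naming them. Group comparisons use the two-sided
Wilcoxon rank-sum test per set with BH adjustment across sets; a set is
"enriched" at FDR ≤ 10% when additionally its median is higher in the
high-score group. The 28 immune-cell marker sets ship as an editable GMT —
the bundled file is a synthetic stand-in (placeholder marker symbols under
the published cell-type names) adequate for simulation and testing only.

## Synthetic cohorts

The generator emulates the two-arm discovery design: 23 R / 24 NR
patients. Eight signal genes mutate with marginal probability 0.5 per gene
in NR and 0.02 in R; co-mutation is induced by a per-sample latent
Bernoulli (the "protective phenotype"): a sample draws the latent with
probability p/r and, given it, each signal gene mutates independently with
r = 0.55. The value of r trades co-mutation strength against panel
coverage of the NR arm; 0.55 keeps the pairwise association positive while
letting the panel cover ~90% of NR samples, the regime a
perfect-PPV panel implies. Passenger genes (300) mutate at rate 0.15 in
both arms.

TMB is never written directly: each sample draws a target non-synonymous
variant count from a stratum-specific lognormal — ln N(ln 150, 0.25) for
baseline R tumors and ln N(ln 180, 0.25) for NR (~4–5 mut/Mb over 38 Mb; the
modest NR excess reproduces the weak TMB discrimination, AUC ≈ 0.65–0.70),
ln N(ln 1100, 0.25) for MSI-H hypermutators (~29 mut/Mb; MSI-H fraction
4/47, drawn per sample, with matching MSIsensor/MANTIS scores), and
ln N(ln 6000, 0.3) (~160 mut/Mb) for POLE-like confounders — and actual
variant records are generated to meet it, so TMB computation is exercised
end to end. Filler variants land in genes already mutated in the sample,
leaving the binary matrix untouched. Variant contexts are drawn from the
bundled spectra (SBS10b-like for POLE samples, a flat SBS5-like spectrum
otherwise), so signature matching also runs end to end.

POLE confounders are opt-in (`penalty_confounder=True`): a fixed fraction
(default 2/23) of the R arm becomes ultramutated, microsatellite-stable,
carries a POLE exonuclease-domain missense variant (residue 286), and hits
each panel gene with passenger probability 0.35 (≈ the per-gene hit rate
implied by ~6000 mutated genes among ~20k). These are exactly the samples
the G8plus penalty corrects. With confounders planted, the G8plus AUC is
never below the G8 AUC: the penalty only ever moves R-arm samples down.

RFS times are exponential per arm with administrative censoring (defaults:
R hazard 1/10 per month, NR 1/400, censor 84 months); the CLI's `simulate`
command draws arm-consistent times (R truncated below 24 months, NR
shifted past 60) to honour the retrospective arm definitions. Expression
matrices shift immune-marker and TLS genes upward by a configurable effect
size (default 1 SD on log2 scale) in samples carrying at least one signal
gene.

What the synthetic tests do **not** show: the generator has independent
passenger genes, exchangeable noise expression, exact exponential
survival and a single co-mutation latent — real cohorts have linkage,
subclonality, batch effects, covariate-dependent censoring and richer
co-mutation structure. Passing tests demonstrate the *procedures* are
implemented correctly and recover planted truth under the stated
conditions, not that the published panel generalizes.

## Numerical choices and degenerate inputs

* Fisher p-values use exact hypergeometric mass; tables with a zero margin
  give p = 1.
* AUC candidate thresholds are score-scale midpoints; ROC curves are
  step functions, integrated by trapezoid.
* z-scores use the n−1 SD; 0/0 maps to 0.
* Odds ratios with an empty off-diagonal cell report `inf` (or NaN when
  the numerator is also degenerate) rather than applying a continuity
  correction.
* Problem sizes in the test-suite and acceptance script Monte-Carlos
  (e.g. 100 screening seeds, 100 Cox replicates, 300–500 log-rank
  replicates, 10–50 cohort replicates elsewhere) were chosen to make the
  checked frequencies stable at the asserted thresholds while keeping the
  default run fast on a single CPU.
* All generators take explicit integer seeds and are pure functions of
  (parameters, seed); pipeline outputs are byte-identical across reruns
  with the same config and seed.

## Known limitations

Greedy subtraction optimizes in-sample AUC and will happily absorb noise
genes on small cohorts; treat discovered panels as hypotheses for external
validation (the apply mode). The MSI caller consumes precomputed
MSIsensor/MANTIS scores or labels — it does not analyse microsatellite
loci. Signature matching reports similarity to catalog entries, not
exposure decomposition. The bundled immune sets and signature catalog are
synthetic stand-ins, and the TLS normalization choice (log2 + z-score) is
one of several defensible readings.
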