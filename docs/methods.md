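# Methods

## Signature derivation

The pipeline operates entirely on gene-level CPM matrices and up-regulated
gene lists; differential-expression calling for real datasets is assumed
to have happened upstream. A gene is *ATFS-1-dependent up-regulated* in a
background when it appears in that background's up-list but not in the
up-list of the matching *atfs-1*-null double mutant — a set difference,
taken after alias normalization. The consensus signature is the three-way
intersection of (i) the *nuo-6*-dependent list, (ii) the *spg-7*
RNAi-dependent list, and (iii) the intersection of the *et15* and *et17*
constitutive-activation up-lists. Only up-regulation enters the
definition; down-regulated genes are ignored. Whether the *spg-7* input
arrives already dependence-filtered or as a pair of lists is the caller's
choice: `derive-signature` treats the *spg-7;atfs-1* list as optional.

Gene IDs are canonicalized to sequence names (`C07G1.7`); locus names
(`clec-17`) are aliases. Un-mappable IDs pass through unchanged with a
logged count rather than being dropped — silent drops would corrupt the
consensus size. A duplicate ID *after* normalization is a hard error.

## Scoring

Normalization is per replicate: each CPM is scaled to
`100 × CPM / mean(WT CPM)` for its gene, so the WT mean is exactly 100 and
both the per-genotype mean and the per-genotype SD are defined on the same
percent-of-WT scale. The SD is the sample standard deviation (n−1) of the
per-replicate normalized values; a ratio-of-means variant would leave the
SD without a natural definition, which is why per-replicate normalization
is used. Genes with a WT mean of zero get a pseudocount of 0.5 CPM added
to every replicate value before scaling (logged); this avoids division by
zero while preserving ordering.

The composite score is
`S = E(nuo-6) + E(et15) + E(et17) − 3·E(nuo-6;atfs-1)`. The 3×
subtraction is the operational definition used here: it makes the
all-baseline profile score exactly 0, which is the self-consistent choice.
A 1× variant is available behind `formula="1x"` for sensitivity analysis.
The variability-corrected score divides S by the mean of the six per-strain
SDs (WT, *atfs-1*, *nuo-6*, *nuo-6;atfs-1*, *et15*, *et17*); a zero mean SD
yields a missing value, never infinity. Rankings are descending with
lexicographic gene-ID tie-break, so outputs are bit-stable; "higher score
than the reference" uses strict inequality.

## ChIP annotation and validation

ATFS-1 binding is consumed as a gene list (the upstream ChIP study's own
peak-to-gene assignments); this package performs only the overlap. The
validation up-list (e.g. genes up in *isp-1*) is likewise an input; its
significance criterion belongs to the upstream analysis and is therefore
parameterized, not fixed. When only a matrix is available, the stand-in DE
caller (below) produces both with documented defaults. Both annotations
only toggle boolean flags — scores and ranks are untouched and the
operations are idempotent.

## qPCR quantification

ΔCt = Ct(target) − Ct(reference) per replicate; ΔΔCt subtracts the control
strain's mean ΔCt; fold = 2^(−ΔΔCt). Per-replicate folds are averaged
arithmetically (the usual bar-plot presentation) and every strain's folds
are then rescaled by the control strain's mean fold so the control reports
exactly 1 — without this, Jensen's inequality puts the control's
arithmetic mean slightly above 1 under noise. Fold changes are invariant
under adding a constant to all Ct values of a replicate (plate shift).
No amplification-efficiency correction (standard curves, Pfaffl) is
applied. Group comparisons use Welch's t-test on ΔCt values.

Dunnett many-to-one comparisons are computed by Monte-Carlo: the null
max-|t| distribution (shared control, pooled variance, many-to-one
contrasts) is sampled `n_mc` times from its exact representation
(independent group-mean normals plus a chi-square variance draw), and the
adjusted p-value for each comparison is the fraction of null draws whose
max-|t| exceeds the observed |t|. This handles arbitrary group counts and
sizes and degenerates to the pooled two-sample t-test when there is a
single comparison (the convergence is tested at n_mc = 200,000, and the
procedure is cross-checked against an independent multivariate-t
implementation). Default n_mc is 20,000, giving a Monte-Carlo standard
error near 0.0015 on a p-value of 0.05.

## Stand-in DE caller

For synthetic end-to-end runs only: per-gene Welch t on log2(CPM + 0.5)
with Benjamini–Hochberg adjustment (default FDR 0.05), returning genes
with adjusted p ≤ FDR and positive log2 fold-change. It is a deliberately
simple, documented caller and explicitly **not** a claim of equivalence to
any published DE pipeline. Zero-variance edge cases are resolved by
convention: equal means give p = 1, separated means p = 0, which is what
makes noiseless synthetic calls exact.

## Synthetic study design

The generator emulates the experimental design the analysis assumes:
eight genotypes (WT, *atfs-1*, *nuo-6*, *nuo-6;atfs-1*, *et15*, *et17*,
*spg-7* RNAi, *isp-1*) with six expression replicates each and three qPCR
replicates. Defaults, chosen once as the study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 500 | gene universe (keeps runs fast; counts scale freely) |
| `n_signature` | 61 | planted ATFS-1-dependent target genes |
| `n_decoys_per_class` | 10 | per decoy class (7 classes) |
| `activation_fold` | 4 | fold induction in activating conditions |
| `suppression` | 0 | fraction of activation retained in the double mutant |
| `cv` | 0.2 | coefficient of variation of multiplicative noise |
| `baseline_log_mean`, `baseline_log_sd` | 3, 1 | log-normal baseline CPM |
| `chip_fraction` | 22/61 | planted genes marked ChIP-bound |
| `n_isp1_nonresponders` | 4 | planted genes not induced in *isp-1* |
| `hsp6_fold` | 2.5 | induction of the *hsp-6* analogue |
| `ct_jitter_sd` | 0.2 | Gaussian Ct noise (cycles) |

Planted genes are induced in *nuo-6*, *et15*, *et17*, *spg-7i* and
*isp-1* (minus the non-responders) and suppressed in the double mutant.
Decoy classes are induced in exactly one or two of the three consensus
inputs, plus a "nondependent" class induced in both *nuo-6* and the double
mutant (which must be removed by the epistasis call, not the
intersection). The *hsp-6* analogue is induced everywhere except the
*spg-7i* condition, so — as with the real gene — it scores but never
enters the consensus, making it a natural reference for the ranking. A
flat `act-3` provides the qPCR reference; Ct values are back-computed from
the expression ground truth (one cycle per doubling) plus jitter.

Noise is multiplicative log-normal on CPM (mean-preserving,
σ = √ln(1+cv²)) rather than negative-binomial counts: the pipeline
consumes CPM and its statistics are plain means/SDs of normalized values,
so count-level dispersion modelling is out of scope. Consequences for
interpretation: passing tests demonstrate correctness of the set logic,
scoring arithmetic, calibration and recovery under idealized multiplicative
noise — they do not establish performance under count overdispersion,
library-size artefacts, batch effects or correlated genes, none of which
the generator emulates. Ground-truth memberships depend only on the counts,
never on the seed, so different seeds are replicate "studies" of the same
design.

## Problem sizes and determinism

All simulations are sized for interactive use: the default universe is 500
genes × 48 samples; recovery is evaluated over 20 seeds; Dunnett
calibration uses 1000 null trials at n_mc = 4000 with the two-group
degeneracy checked at n_mc = 200,000. The full test suite runs in a few
seconds and `scripts/acceptance.py` in a few seconds more. Every random
draw flows from an explicit seed through `numpy.random.default_rng`; the
CLI records the seed in each summary, and two runs at the same seed are
byte-identical.

## Known limitations

- The consensus is as good as its input up-lists; with real data the
  FDR thresholds of the upstream DE analyses dominate the result.
- The 2^(−ΔΔCt) model assumes perfect amplification efficiency.
- The Monte-Carlo Dunnett p-values carry sampling error O(1/√n_mc); for
  publication-grade tables raise `n_mc`.
- Scores compare genotype means only; no uncertainty is propagated into
  S beyond the variability correction.
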