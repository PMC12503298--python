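# Methods

## The question and the statistic

During male meiosis, unsynapsed sex chromosomes are transcriptionally
silenced in many lineages (meiotic sex chromosome inactivation, MSCI).
Whether a given species shows MSCI is answered here by a ratio statistic:
each sex-linked gene's per-cluster pseudobulk count is divided by the median
count of *expressed* autosomal genes in the same cluster (count ≥ 1; an
`include_zeros` flag exposes the all-genes reading), then averaged,
unweighted, over the clusters belonging to each major stage. Averaging over
clusters rather than pooling cells keeps the statistic robust to unequal
cluster sizes and mirrors how stage summaries are usually reported. A gene
enters a stage's distribution only when it has a count ≥ 1 in at least one
of that stage's clusters, and its stage ratio averages only the clusters
where it is expressed — so the per-stage gene sets legitimately differ in
size, and an unexpressed gene contributes absence, not a zero.

MSCI predicts the meiotic ratio distribution falls below the pre-meiotic
one. Stage pairs are compared with two-sided Mann-Whitney U tests, reported
raw by default (each pairwise comparison is of standalone interest; a
Bonferroni flag exists). Group sizes ≤ 8 per side use exhaustive
enumeration of all label assignments — exact even under ties — larger
samples the tie-corrected normal approximation with continuity correction.

## Companion analyses

**Dosage compensation.** X-linked genes that lost their Y partner (X-only
gametologs) are contrasted against X+Y gametologs per stage. All
stage×class groups of a panel enter one Kruskal-Wallis test; Dunn's
post-hoc z-tests on the shared pooled ranking are reported for the
within-stage X-only vs X+Y pairs, Bonferroni-scaled by the number of
reported pairs in the call (4 for the pooled panel, 12 when run per
stratum). Full compensation makes X-only genes approach the autosomal level
rather than half of it, and the effect should concentrate in the oldest
stratum, where the Y has degenerated longest.

**Mono-allelic expression.** For each ancestral gametolog pair and stage,
the pair is X-only-expressed when the X copy has a stage count ≥ 1 and the
Y copy exactly 0 (symmetrically Y-only), retained only when at least one
testis bulk replicate shows the same pattern (count > 1 on the expressed
copy, ≤ 1 on the silent copy). Stage enrichment uses a hypergeometric urn;
the parameterisation is explicit because "observed vs expected given
expression" admits several readings: N = pairs expressed in ≥ 1 stage,
K = pairs mono-allelic in ≥ 1 stage, n = pairs expressed in the focal
stage, k = mono-allelic pairs in the focal stage. The signed fold is
k/expected at or above expectation and −expected/k below it (k = 0 prints
as −Inf), matching the field's "−3.15×" notation; the tail (over/under)
follows the sign.

**Induced genes.** A gene is induced in a stage when its library-size-
normalised stage pseudobulk strictly exceeds 2× the median of the other
three stages; when several stages fire, the maximum-expression stage wins
and exact ties yield none (logged). A `max_vs_overall` variant (top stage
vs 2× the median of all four) is provided because the two phrasings of this
rule circulating in the literature differ on borderline genes; the
inequality is strict and a zero median of the others makes any positive
expression induced — both behaviours are deliberate and tested.

**Faster-X.** Per-gene dN/dS is the mean over transcripts after removing
the sentinel value 99 (emitted when a gene has no synonymous substitutions
and the ratio is meaningless); genes with no surviving transcript are
dropped, and the operation is idempotent. Classes (autosome, X-hemizygous,
X and Y members of surviving pairs, Y-hemizygous) are contrasted against
autosomes by rank-sum tests — overall and restricted to
spermatogenesis-induced genes — alongside a Kruskal-Wallis + Dunn panel,
plus a per-class comparison of induced genes across their induced stages.
Classes with fewer than 2 genes are flagged untestable rather than tested.

**Amplicons and retrocopies.** Multi-copy Y family expression is the
library-size-normalised sum over all paralogs per cluster, averaged per
stage; a family is expressed in a stage when its summed raw count ≥ 1 (the
same retention threshold applied to single genes). A retrocopy candidate is
a single-block (intronless) alignment of a ≥ 2-exon parent at a locus
disjoint from the parent (≥ 1 bp overlap rejects), with secondary loci
deduplicated by 50% reciprocal overlap keeping the top score, and no
single-block outgroup alignment overlapping the orthologous locus (same
chromosome name and span by default; a liftover table can replace this).
An outgroup hit means the insertion predates the species split and the
event is rejected. The stricter orthologous-locus reading (rather than
absence from the whole outgroup genome) is the default because it is the
verifiable contract.

## Quality control and markers

Cells are kept when their detected-feature count lies in the inclusive band
[min_features, max_features] (defaults 200 and 3000 — the bounds themselves
are retained, since the removal rule is "fewer than 200 or more than
3000") and their mitochondrial count fraction is ≤ 5%; without annotated
mitochondrial genes that filter is skipped with a warning. Markers are
one-vs-rest rank-sum tests on per-cell library-size-normalised expression,
Bonferroni-corrected over genes×clusters (BH behind a flag), with a gene
called a marker at ≥ 25% in-cluster detection, log2 fold change > 0.25
(pseudocount 1 on normalised means — the pseudocount choice is ours) and
adjusted p < 0.01. Cross-sample concordance is the Spearman correlation of
stage-level normalised profiles over the union of each pair's 2000
highest-expressed genes.

## The synthetic generator

The generator (`mscix.simulate`) emulates a stage-synchronised testis 10x
run; it exists so every detector can be validated against planted truth,
not to model any particular genome.

Count law: counts are gamma-Poisson, `count ~ Pois(Γ(1/φ, φ·μ_gs·L_c))`,
with quadratic overdispersion φ (default 0.3, typical of droplet data) and
a mean-one log-normal per-cell library factor `L_c` (σ = 0.3). Per-gene
stage means `μ_gs` are drawn **independently across stages** (log-normal
around `base_mean` = 0.5 counts/cell, σ = 0.3). The independence is a
deliberate design choice: the stage-comparison tests treat the two stage
samples as independent draws, and a shared per-gene baseline would make
them positively dependent and the tests conservative; modelling the
near-complete turnover of transcriptional programs between spermatogenic
stages as independent redraws keeps the null calibration exact. The σ of
0.3 was chosen so that the 2×-median induction rule fires for ~10% of
unplanted genes; with the 20% planted induced fraction (boost ×4) the total
induced share lands near the ~20–30% seen in real testis atlases.

Biology dials: `msci_multiplier` ∈ (0,1] multiplies meiotic-stage means of
non-PAR sex-linked genes (1 = no silencing); `dosage_factor` ∈ [1,2]
multiplies X-only means in the strata listed in `dosage_strata` (default:
stratum 1 only, doubling — i.e. full gene-by-gene compensation confined to
the oldest stratum); Y-linked means carry a 0.5 attenuation; 15% of X+Y
pairs have a silenced Y copy; 10 of 30 Y families are meiotic-only;
chromosome layout assigns sex-linked genes to strata {1,2,3} by the
configured proportions, with PAR genes emitted as a separate recombining
class. Bulk tables plant 20 testis-specific X-linked genes whose
counts are > 1 only in testis (guaranteed by construction: one testis
replicate floored at 2, brain/liver capped at 1). Alignment fixtures give
every gene a parent record with block count = exon count and plant 9
lineage-specific intronless copies plus 3 shared with the outgroup. The
dN/dS table elevates Y-hemizygous genes (×1.5), reduces gametologs (×0.7)
and shifts induced X-hemizygous genes (×1.5), with 5% sentinel-99
transcripts.

Everything derives from independent child streams of one seed, so counts,
bulk, dN/dS and alignments share an identical gene universe and fixed seeds
give bit-identical outputs.

What the generator does **not** emulate: transcriptome-wide co-expression
structure, doublets, ambient RNA, batch effects between samples, or any
cross-stage correlation of gene expression. Passing tests therefore
demonstrate correctness of the statistics under the stated count law, not
robustness to those artefacts in real droplet data — on real data the
stage tests are expected to be somewhat conservative because the same genes
are measured in every stage.

## Calibration scale and numerical choices

The validation battery (`mscix.validation`, run by
`scripts/acceptance.py`) uses 500 X-linked genes against an 800-gene
autosomal background with 200 cells in each compared stage — the per-stage
gene counts a single stickleback-like testis dataset yields — with 200
replicates for the null rate, 100 for power, 50 for dosage recovery.
Observed characteristics: type-I ≈ 0.04, power 1.0 at multiplier 0.1 with
the recovered quotient ≈ 0.10, dosage pattern recovery ≥ 0.94, retrocopy
precision = recall = 1.

Numerics: exact rank-sum enumeration up to 8 per group (C(16,8) = 12,870
assignments); hypergeometric tails via scipy's distribution (validated
against combinatorial sums for N ≤ 30); Kruskal-Wallis on an all-tied
pooled sample returns H = 0, p = 1; Dunn adjusted p-values are clipped at 1
and never smaller than raw; clusters whose expressed-autosome median is 0
are excluded from ratios with a log entry; coordinates are 0-based
half-open throughout with conversion at the GFF3 boundary; counting treats
each gene as one collapsed feature, unstranded.

## Limitations

Cluster labels and their stage assignment are inputs (human judgment in
practice); the pipeline does not cluster. Mono-allelic calls operate on
gene-level counts from separately annotated X and Y copies, not on
allele-resolved reads, so cross-mapping between highly similar gametologs
is invisible to it. The enrichment urn treats pairs, not genes, and uses
stage-specific expressed-pair counts; other readings are configurable but
not defaulted. dN/dS values are ingested, never computed. The orthologous-
locus convention for outgroup verification assumes shared chromosome naming
unless a liftover table is supplied.
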