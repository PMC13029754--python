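# Methods

## Setting and data model

A dual-transcriptome nodule experiment compares two inoculation treatments —
rhizobial strains WE2 and WWL2 — with three biological replicates each,
sampled once at nodule maturity. Each sample yields two gene-level count
matrices: one for the plant host and one for the bacterial symbiont. Host
transcripts dominate the mixed library; the share of the symbiont is tracked
as the *mapped rate*, `partner-mapped reads / total clean reads × 100 %`,
which is a composition measure, not an alignment-quality figure.

All fold changes in the package are oriented `log2(WWL2/WE2)`: negative
values mean higher expression under WE2, the high-fixation strain.

## Filtering and normalization

Low-count genes are removed with a group-aware CPM rule: keep gene *g* iff
CPM ≥ C in at least *k* samples and the total count of *g* is ≥ 15, where
C = 10 / (median library size in millions) and *k* is the smaller treatment
group size. The constants 10 and 15 are the conventional defaults for this
style of filter; the principle being encoded is that the evidence threshold
adapts to sequencing depth and to the replication available.

Between-sample factors use the trimmed mean of M-values. Against a reference
sample (the one whose upper quartile of nonzero CPM is closest to the mean of
those quartiles; lowest index on ties), per-gene log-ratios
`M = log2((y_k/N_k)/(y_r/N_r))` and abundances `A = ½·log2((y_k/N_k)(y_r/N_r))`
are computed over genes nonzero in both samples (no pseudocounts — a zero
count carries no usable ratio information). The most extreme 30 % of genes on
each side by M and 5 % by A are discarded; the surviving M values are averaged
with inverse-variance (delta-method binomial) weights
`w = [(N_k−y_k)/(N_k·y_k) + (N_r−y_r)/(N_r·y_r)]⁻¹`, and the factor is
2^(weighted mean). Factors are rescaled to geometric mean 1 (enforced to
1e-12).

Two practical notes. The M/A statistics, the trim set and the reference
choice are exactly invariant to rescaling any one sample's counts, but the
precision weights are not, so factors move slightly (at most a few percent on
small matrices) when a library is scaled; and the filter is idempotent only
up to the count share of the removed genes, which is negligible at sequencing
depth. Both behaviors are consequences of the definitions and are covered by
tests at the appropriate tolerance.

FPKM (host) and RPKM (symbiont) are `1e9·y/(N·f·len)`; both raw-library and
TMM-corrected variants can be produced by passing or omitting factors, and
the pipeline uses the TMM-corrected form. Descriptive units (CPM/FPKM) feed
only scoring and reporting — tests run on raw counts.

## Differential expression

Counts are modelled per gene as negative binomial with mean μ and variance
μ + φμ². The dispersion φ is estimated by method of moments on
effective-library-normalized counts — within-group variances pooled by their
degrees of freedom, group means averaged — as
`φ_g = max(0, (s²_g − μ̂_g)/μ̂_g²)`, then shrunk toward the median of the
positive per-gene values: `φ*_g = 0.7·φ_g + 0.3·φ̄`. The shrinkage weight
0.3 moderates the instability of a 6-sample moment estimate without erasing
per-gene signal; with all genes Poisson the estimator's mean settles near
zero, and with φ = 0.4 planted it recovers the median to well within a factor
of two (both checked by simulation in the test suite).

The test is a conditional exact test chosen to be auditable by enumeration.
Counts are first equalized to the geometric mean of the effective library
sizes, rounding to the nearest integer so the enumeration stays on integers.
Conditional on a gene's total t, the group-A sum under the null is the sum of
n_A i.i.d. NB(μ̂, φ*) variables — itself NB with mean n_A·μ̂ and dispersion
φ*/n_A — and similarly for B; the two-sided p-value sums the normalized
probabilities of all splits (s, t−s) no more probable than the observed one
(log-space comparison with a 1e-8 tie tolerance). At φ* = 0 this reduces
exactly to the conditional binomial test, which an independent enumeration
oracle verifies to 1e-10 for every split with t ≤ 50.

BH step-up FDR is applied across genes; DEGs are calls with FDR < 0.05 and
|log₂FC| ≥ 1 (inclusive). The reported log₂FC adds a 0.5-CPM pseudocount to
each group mean — stabilizing display values for near-zero means — while the
test itself uses raw counts; the DEG gate is applied to this pseudo-counted
value. Sample QC is PCA on log2(CPM+1) over all filtered genes with genes
centered and no variance pre-selection.

## Module scores and coupling

For a predefined gene set (GMT format, one module per line), expression is
transformed `t_ij = log2(x_ij + 1)`, each gene is z-scored across samples
with the sample SD (n−1; configurable — the ± mirror structure below holds
either way), and the module score of sample j is the mean z over the module's
genes. Genes with zero variance are excluded with a warning rather than
imputed at z = 0, which would silently dilute the score; a module whose genes
are all constant has no defined score and errors. Because each gene's
z-scores sum to zero, module scores sum to zero across samples, and with
equal group sizes the two treatment means are exact negatives — the
antisymmetry is structural, so only the magnitude and the replicate scatter
are informative. Group means are annotated with significance letters from a
two-tailed Welch test at α = 0.05.

Coupling between a host module and a symbiont module is the Pearson
correlation of their per-sample scores with the exact transform
`t = r√(n−2)/√(1−r²)` against Student t with n−2 df (two-sided). At the
reference operating point r = 0.923, n = 6 this gives p = 0.00867–0.00868
(the final digit depends on the rounding of r). Collinear score vectors are
flagged and reported with p = 0.

## Enrichment

Over-representation of a DEG list in each term is the one-sided
hypergeometric upper tail P(X ≥ k) with universe N = the filter-surviving
genes (configurable), term size K after intersection with the universe, and
list size n. The BH family is all terms with K ≥ 1. Only over-representation
is tested; direction-specific runs ("up"/"down") partition the full list.

## Phenotypes and qPCR

Replicate-level traits (shoot fresh weight of 15-plant pools; nitrogenase
activity as ethylene production rate per gram nodule fresh weight per hour,
`amount/(h·g)`, with units supplied by the caller) are compared by Welch's
t-test with the Satterthwaite df. qPCR uses 2^−ΔΔCt: technical triplicates
are averaged first, ΔCt = Ct_target − Ct_reference per biological replicate,
ΔΔCt subtracts the calibrator treatment's mean ΔCt (WE2 by default; RQ ratios
are calibrator-invariant), and results are mean ± SEM over biological
replicates. Concordance with RNA-seq is the fraction of shared genes whose
qPCR log-ratio (calibrator over other treatment) has the sign of −log₂FC.
Amplification-efficiency corrections and multi-reference normalization are
out of scope.

## The synthetic-data generator

`simulate_experiment` draws a complete experiment from

    y_gj ~ NB(μ_gj, φ_g),   μ_gj ∝ L_j · q_g · 2^(β_g·x_j + ρ·γ_g·u_j)

with x_j the WWL2 indicator, q_g a log-uniform relative abundance over 9
log₂ units, φ_g log-normal with median 0.1 (σ = 0.5), library sizes normal
with CV 5 % around 2×10⁶ (host) and 3×10⁵ (symbiont), and u_j ~ N(0,1) a
per-sample latent factor entering multiplicatively on the log2 scale so
counts stay NB conditional on u. Planted effects β are concentrated in five
modules of 30 genes — host supply/microaerobic and symbiont
N-fixation/respiration higher in WE2 (γ = 1, coupled through u with default
strength ρ = 0.9), and symbiont nodulation/surface, chemotaxis/motility and
transport/nutrient modules higher in WWL2 — with |β| ~ N(2, 0.5) and the
remaining DE budget (10 % of host genes, 15 % of symbiont genes, enough to
cover all module genes plus background) assigned to random genes with random
signs. With the DE fraction and ρ set to zero nothing is planted.

Read accounting is generated exactly: each sample's symbiont mapped-rate is
drawn uniformly in 1.64–5.04 %, and the total clean reads are set so the
realized symbiont column sum accounts for exactly that share (a configuration
whose band cannot accommodate both partners' mapped reads errors out).
Phenotypes are drawn per treatment from normal distributions with WE2 means
0.243 g (shoot FW) and 23.4 (ARA) and SDs converted from the n = 3 SEMs
(SD = SEM·√3: 0.015 and 1.0 respectively); the WWL2 means (0.180 g, 15.6)
are the generator's choice of a clearly weaker strain at similar relative
noise, since only the direction of the contrast is specified. qPCR Ct values
derive from the model transcript concentration `q_g·2^(β x + ργu)` — what a
reference-gene-normalized assay actually measures — as
Ct = 34 − log2(concentration) + N(0, 0.15) per technical replicate, for three
marker genes per coupled module plus the highest-expressed null gene as the
constant reference. All randomness flows from one seed; identical
configurations reproduce bit-identical outputs.

What the generator does *not* emulate: GC/length biases, batch effects,
outlier samples, developmental asynchrony between strains (a single
time-point snapshot is modelled), strain-unique genes absent from a shared
reference, or qPCR efficiency differences. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated model,
not robustness to those artifacts.

Defaults of 5000 host and 1500 symbiont genes keep a full run in seconds on
one core; the real joint gene universe is an order of magnitude larger but
adds nothing to verification. Test-suite problem sizes follow the same logic:
parameter-recovery checks use 2000 genes with 20 % planted effects at
|log₂FC| = 2 (recall ≥ 60 %, empirical FDR ≤ 0.15), the coupling-recovery
check uses 100 seeds at 600+300 genes, and null-calibration checks use
800-gene experiments with nothing planted.

## Pipeline and candidate screening

`run_all` executes simulate-or-load → filter → TMM → exact-test DE →
enrichment → FPKM/RPKM module scores → coupling → phenotype/qPCR statistics,
writing one TSV per stage plus `summary.json` (stage counts, thresholds,
seed, config hash, library versions) and a run log. Candidate genes
operationalize pathway-node screening as an intersection: a gene is a
candidate iff it is a DEG, belongs to a scored module, and the sign of its
log₂FC matches the sign of its module's WWL2 group-mean score. Tightening
the FDR threshold can only shrink the DEG set on fixed input, and reruns
with an identical configuration are deterministic.

The five shipped module definitions are synthetic reconstructions named for
the functional themes they emulate; they are generated by the simulator, not
curated gene sets, and real analyses should supply their own GMT catalogs
(the enrichment universe, GO term propagation, and database versions are
likewise the caller's responsibility).

## Known limitations

- The exact test enumerates all splits of a gene's total; genes with very
  large totals dominate runtime (linear in total count). At the shipped
  depths a full run takes a few seconds.
- The method-of-moments dispersion with 3+3 replicates is noisy per gene;
  the 0.3 shrinkage is a pragmatic stabilizer, not an empirical-Bayes fit.
- Module scores are descriptive summaries; their antisymmetry is structural
  and their scale depends on module size and gene correlation, so only
  comparisons within a dataset are meaningful.
- Coupling with n = 6 samples has little power and is sensitive to single
  samples; the exact-t p-value assumes bivariate normal scores.
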