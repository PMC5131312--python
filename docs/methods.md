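# Methods

## Scientific setting

Fibroblasts sense the stiffness of their substrate, and part of that signal
reaches the genome through the LINC complex, the protein bridge (SUN proteins
in the inner nuclear membrane bound to KASH-domain nesprins in the outer
membrane) that couples the cytoskeleton to the nucleus. The experimental
design this package analyzes is a balanced 2x2 factorial: substrate rigidity
(soft, 1 kPa vs stiff, 308 kPa polyacrylamide) crossed with genotype (KDEL, an
ER-retained control construct, vs SUN1L, a dominant-negative SUN1 lumenal
domain that disrupts LINC), with three biological replicates per cell.
Optional treatment arms add blebbistatin (non-muscle myosin II inhibitor) and
Y27632 (Rho-kinase inhibitor) to control cells on the stiff substrate.

The central statistic is per-gene mechanosensitivity,

    MS_gene = signed stiff-over-soft fold change,

where a fold change below 1 is re-expressed as -1/fold so |MS| >= 1 and the
sign carries the direction of regulation. Computing MS separately in the two
genotypes and taking the ratio R = MS_SUN1L / MS_KDEL classifies how LINC
disruption changed a gene's rigidity response: R > 1 gained, 0 < R < 1 lost,
R < 0 reversed direction. A reversed call is algebraically equivalent to
MS_KDEL and MS_SUN1L having opposite signs (2nd/4th quadrants of the MS
plane). Because the classification is only meaningful for genes whose rigidity
response demonstrably depends on genotype, it is restricted to the hits of a
genome-wide two-way ANOVA interaction screen.

## Pipeline stages and their assumptions

**TMM normalization.** Between-sample scaling factors are trimmed means of
M-values: per-gene log2 ratios of library-size-scaled counts against a
reference sample (the one whose 75th-percentile count fraction is closest to
the across-sample mean), trimmed 30% from each tail of M and 5% from each tail
of A, averaged with precision weights 1/((N_s-y_s)/(N_s y_s) +
(N_r-y_r)/(N_r y_r)), and rescaled to geometric mean 1. Genes with a zero in
either sample are excluded from factor estimation but kept in the matrix.
Trim-boundary ties are broken by a stable sort on (value, gene id) so output
is deterministic. The method assumes most genes are not differentially
expressed between samples; on simulations with a large planted fraction the
factors legitimately move away from 1.

**Expression scale.** All downstream statistics use log2(CPM + 1) on
TMM-adjusted effective library sizes. The pseudocount of 1 CPM keeps zeros
finite and stabilizes variance at low counts; it is applied after CPM scaling
(log2(CPM + c)), the simplest monotone zero-safe convention.

**Differential expression.** Group contrasts are summarized by the signed
fold change of group-mean log2 CPM and tested with a Welch z statistic
against a standard normal, two-sided, with Benjamini-Hochberg FDR control. A
gene is called significant only when both q < 0.05 and |signed fold| >= 2.
The normal reference (rather than a t or count model) is a deliberate,
simple operationalization; with n = 3 per group its p-values are
anti-conservative in the extreme tail, which is why genome-wide error control
is delegated to the interaction screen's Bonferroni correction rather than to
the z test. miRNA-mode analyses differ only by first removing features with
fewer than 10 total raw counts.

**Interaction screen.** Each gene gets a balanced two-way ANOVA on log2 CPM
over the untreated 2x2 samples (closed-form sums of squares, identical across
SS types because the design is balanced; F against the residual mean square
with df (1, n-4)). The interaction p-value is Bonferroni-corrected over the
family G of testable genes: those with mean CPM >= 1 across samples and
nonzero residual variance. All-zero or constant genes cannot carry evidence
and are excluded from G rather than consuming family-wise budget; they are
flagged in the output. Only balanced designs are accepted — the study design
is balanced, and unbalanced data would reintroduce SS-type ambiguity.
Response on the log scale makes the homoscedastic normal model a reasonable
approximation for negative-binomial counts; residual non-normality leaves a
mild anti-conservative bias in the extreme F tail (measured FWER ≈ 0.04-0.08
at a nominal 0.05 under the global null, within the Monte-Carlo acceptance
band).

**Mechanosensitivity classification.** MS is computed from group-mean log2
CPM (matching the fold-change convention used elsewhere), with the
stiff-over-soft orientation fixed; the reversal class is invariant to that
orientation choice, gained/lost labels are not. An explicit "unchanged" class
(|R - 1| <= 1e-9 and exact boundaries) makes the classification exhaustive.

**Directional intersections.** Genes responding to several perturbations
"similarly" are those present in every significant list with |signed fold| >=
the threshold (default 2) and identical sign; no further magnitude-similarity
requirement is imposed. Over-representation of annotation sets (GMT format)
in a gene list uses the upper-tail hypergeometric test against a finite
universe (default: all genes passing the expression filter), BH-adjusted
across terms — a desk-scale stand-in for interactive annotation services,
labeled as such.

**Auxiliary estimators.** Nuclear height is the full width at half maximum of
an axial intensity profile: half of the global maximum, crossings located by
linear interpolation, width spanning the outermost ascending to the outermost
descending crossing (deterministic on noisy or multi-peaked profiles).
Aspect ratios are height/major-axis (x-z) and minor/major (x-y); the x-z
convention is a package choice — the published summary magnitudes are
consistent with it, but they do not uniquely determine the in-plane
denominator. qPCR fold changes use 2^-ddCT with target CT normalized to an
endogenous reference in both sample and calibrator. Group summaries report
mean ± s.e.m. (SD/sqrt(n)) with pairwise two-group one-way ANOVA flags at
p < 0.05, mirroring the published table's conventions.

## The synthetic-data generator

The simulator is first-class, tested code; every calibration claim in this
package is a claim about data it generates. Per gene, expected expression on
the log2 scale is

    b0 + beta_rig*[stiff] + beta_gen*[SUN1L] + beta_int*[stiff][SUN1L],

relative abundances are normalized over genes, scaled by a log-normal library
size (default mean 1e6, CV 0.2 — large enough to make TMM non-trivial), and
counts are drawn gamma-Poisson (negative binomial, Var = mu + phi mu^2) with
per-gene dispersion phi log-uniform on a configurable range (default
0.05-0.5, the span typical of bulk RNA-seq; phi constant across a gene's
samples). Baseline abundances b0 are Normal(4, 2^2) on the log2 relative
scale, giving a realistic several-hundred-fold abundance spread.

Class labels (null / rigidity_only / gained / lost / reversed) are assigned
before any count is drawn — sampling never relabels a gene — with effect
magnitudes uniform on [effect_floor, effect_floor + 1.5] per genotype arm and
signs constrained by the class (opposite arm signs for reversed; same sign
with ordered magnitudes for gained/lost). With treatment arms enabled, an
exact, deterministically chosen fraction of the SUN1L-on-stiff-responsive
genes also responds to both inhibitors with the same sign, so intersection
recovery can be scored against a known overlap.

Two named scenarios freeze the study conditions used by the calibration
analyses: the **global null** (2,000 genes, all effects zero, dispersions
0.05-0.5) for family-wise error measurement, and the **class-recovery
scenario** (300 planted genes per class among 1,100 nulls, effects >= 1.5
log2 units per arm, dispersions 0.01-0.05, planted baselines uniform on
[7, 10] so every planted gene's mean CPM exceeds 100 by construction) for
recovery scoring. The problem sizes (2,000 genes, 200 null replicates) are
the package's chosen desk-scale study conditions.

What the generator does **not** emulate: GC/length bias, batch effects,
correlated genes or co-regulated modules, read-level artifacts, miRNA
biology, or library-preparation effects. Passing recovery tests therefore
demonstrates the statistical machinery is correct under the stated model, not
that real libraries meet those assumptions.

## Numerical and design choices

- Counts are gamma-Poisson sampled; phi = 0 falls back to exact Poisson.
- Degenerate inputs are explicit: zero residual variance gives flagged NaN
  F/p; zero-variance z tests give z = 0, p = 1 at equal means and the
  smallest positive double with a flag otherwise; constant sample vectors
  have undefined Spearman correlation, reported missing.
- BH adjustment wraps the standard step-up implementation
  (statsmodels); Spearman uses midranks; hypergeometric tails come from
  scipy. The two-way ANOVA and TMM are implemented in-package (vectorized
  closed forms) and are cross-checked in the test suite against independent
  brute-force recomputations and, for the ANOVA, against an OLS fit.
- All randomness flows from a single integer seed through
  numpy's Generator; identical configuration and seed reproduce byte-identical
  TSV outputs.
- Class apportionment to genes uses largest-remainder rounding, so realized
  class counts match requested proportions within one gene.

## Known limitations

- The Welch z with a normal reference is anti-conservative at n = 3; its
  per-contrast gene lists should be read together with the fold-change
  cutoff, as the pipeline enforces.
- The Bonferroni family size G depends on the expression filter (mean CPM >=
  1); published analyses on other platforms will use different families, so
  absolute hit counts are not transferable across platforms.
- Gained/lost classes with nearly equal arm magnitudes have small interaction
  terms and are intrinsically hard to detect at n = 3; recovery claims are
  conditional on screen significance.
- The x-z aspect-ratio convention and the stiff-over-soft MS orientation are
  documented choices; only reversal calls are invariant to the latter.
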