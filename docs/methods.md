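# Methods

## Workflow and assumptions

`condqtl` formalizes a two-stage view of regulatory variation: a variant in
a transcription-factor binding site can only influence its target gene in
patients where the factor is present and active. The workflow therefore (1)
partitions the cohort by regulator activity, (2) maps cis-eQTLs separately
per group, (3) keeps pairs significant only in the active group, (4)
requires the target gene to respond to regulator knockdown, (5) expands
candidate SNPs to their strong-LD partners and scores allele-specific motif
disruption, and (6) checks spatial plausibility (shared TAD, promoter
binding peak) and clinical correlates.

The statistical model is deliberately the simplest one consistent with the
design: per-pair ordinary least squares of expression on additive allele
dosage with an intercept and no covariates, which is exactly what a
Matrix-eQTL-style linear scan computes. Assumptions: expression is
approximately Gaussian within genotype classes on the analysis scale
(log2-transformed input is expected), dosages are 0/1/2 alt-allele counts,
patients are exchangeable within a group, and confounding (ancestry, batch,
tumor purity) is either negligible or handled upstream. A
residualize-then-scan hook (`eqtl.residualize`) is provided for known
covariates but is off by default.

## Stratification

A patient is active iff all three hold: regulator expression **strictly
greater** than the threshold (default: the cohort mean of the regulator's
expression, computed over the patients in the analysis set), CNV segment
mean **strictly greater** than 0.5, and promoter methylation β **at most**
0.4. Boundary conventions follow the printed criteria exactly (>, >, ≤).
Promoter methylation is summarized across the supplied promoter CpGs by an
unweighted mean; no aggregation rule is canonical for this step, so median
and all-CpGs-pass variants are selectable (`Thresholds.meth_agg`). The
partition is enforced to be exactly two-way (inactive = complement); the
source analyses report active/inactive counts that do not sum to their
cohort size, an inconsistency this package does not reproduce. CNV input is
one pre-extracted segment-mean row for the regulator locus; mapping
segments to genes is out of scope.

## cis scan and multiple testing

Candidates are all same-chromosome pairs with |SNP pos − TSS| ≤ 1 Mb
(signed distance = SNP − TSS, strand-agnostic; gene position = supplied
TSS). Within a group, SNPs monomorphic in that group are skipped (logged,
and still testable in the other group); missing dosages are dropped
pairwise per fit. BH-FDR is computed over **all** pairs tested in the
group, not only those below the 0.05 output threshold — the output
threshold is a reporting filter, the FDR denominator is the full test
count. Group-uniqueness is judged symmetrically at the FDR threshold
(default 0.01) in both groups; judging the second group at raw p instead is
a configuration choice. Genotype-class comparisons are also available as
one-way ANOVA and pairwise Welch t-tests (`fit_anova`,
`pairwise_t_tests`), since "ANOVA t-test" style reporting is common but
ambiguous; both readings are implemented.

Degenerate fits: a numerically perfect fit (zero residual) reports
t = ±inf and the smallest positive float as p, keeping p in (0, 1];
fewer than 3 complete observations or a constant dosage raise.

## Knockdown filter

Samples (one control and one siRNA profile per cell line) are mean-centered
per sample — "normalized to 0" is read as per-sample mean-centering, with
median-centering selectable. The per-gene effect is the **sum** over cell
lines of (control − siRNA); summation is the reading of "combined" that
reproduces a single fixed cutoff, with mean selectable. Genes with combined
difference strictly > 1.0 are downregulated. When rows are probes, probes
collapse to genes by the maximum combined difference, so any strongly
responding probe keeps its gene. The cutoff is applied to the values as
given (units are opaque to the package). This is a fixed-difference rule,
not a significance test, matching the upstream design.

## LD and EM

From phased haplotypes: D = p_AB − p_A·p_B; D′ = D/D_max with
D_max = min(p_A(1−p_B), (1−p_A)p_B) for D > 0 and
min(p_A p_B, (1−p_A)(1−p_B)) for D < 0; r² = D²/(p_A(1−p_A)p_B(1−p_B)).
Monomorphic loci are an explicit error (LD undefined). From unphased
dosages, two-locus haplotype frequencies are estimated by EM; only the
double heterozygote is phase-ambiguous and its cis/trans split is
re-weighted each E-step. Initialization is at linkage equilibrium (product
of allele frequencies) — deterministic, and the documented tie-break when
the data are entirely double-heterozygous (reported with an ambiguity
flag). Convergence: max frequency change < 1e-8 or 1000 iterations, with
the log-likelihood trajectory returned and checked non-decreasing in tests.
Strong-LD partners default to r² > 0.8 within 250 kb; alleles are defined
on alt dosage and multi-allelic sites are rejected.

## Motif scoring

PWM probabilities use a pseudocount of 0.8 split in proportion to the
background (a common motif-library convention):
p = (count + 0.8·bg) / (total + 0.8); scores are summed log2(p/bg), with N
contributing 0. `scan_best` maximizes over all offsets on both strands
(reverse-strand score = score of the window's reverse complement), ties
broken to the smallest offset, forward strand first. Allele deltas re-scan
the full substituted sequence rather than adjusting per-position scores,
because an indel shifts every downstream placement. By default only
placements overlapping the variant are eligible (`require_overlap=True`),
matching the convention that a reported motif change must cover the
variant. Score scales differ between motif databases (log base,
pseudocount, background), so deltas are comparable only within this
package's convention; externally published PWM scores for the same variant
are not expected to match numerically.

## Annotation

Coordinates are 0-based half-open internally; VCF positions and TSSs
(1-based) are converted in the I/O layer, BED is native. TAD membership
uses point queries (a boundary point belongs to the interval whose
half-open range contains it); a gene is located by its TSS because the
single-point rule is unambiguous (full-body overlap is a trivial extension
via `IntervalSet.overlapping`). Promoter windows default to 2 kb upstream /
500 bp downstream of the TSS, strand-aware. The minor allele is fixed
cohort-wide (ties to alt) before per-subgroup frequencies are computed, so
subgroup MAFs are comparable. Clinical association uses dominant coding
(carrier of ≥ 1 minor allele) with Pearson chi-square (no continuity
correction), falling back to Fisher's exact test for 2×2 tables with any
expected count < 5; age uses a Welch t-test and stage a chi-square, since
no canonical test is attached to those comparisons.

## Synthetic data: what it emulates, what it does not

The generator plants exactly the structure the analysis is built to find.
Genotypes are Hardy–Weinberg (two independent Bernoulli(maf) haplotypes per
patient), with one tag SNP and one motif SNP sharing an identical haplotype
vector (perfect LD, r² = 1) and the motif SNP carrying a one-base insertion
(T → TA). Activity criteria observe a shared binary activity state through
independent per-criterion noise, which reproduces the partial overlap of
the three criteria seen in real cohorts (some patients meet only one or
two). The regulator's own expression is one row of the expression matrix
and its cohort mean defines the default expression threshold. The target
gene's expression adds β·dosage only in truly active patients plus a mean
shift for the active group; all other genes are pure noise. Knockdown
profiles give the target gene a per-line control−siRNA difference of 0.75
(combined 1.5); the PWM is a sharply peaked 7-mer (consensus CATTGTT,
within the HMG-box family's binding-site length range) embedded in a 59-nt
flank so that the reference allele completes the motif — verified
constructively at generation time. TADs tile the chromosome disjointly with
the planted SNP and target TSS inside one TAD; one peak covers the target
promoter.

Reference design (the defaults): 300 patients, 50% active (150 per group),
planted MAF 0.3 (the midpoint of `maf_range`), effect 0.8·noise_sd,
noise_sd 1, 30 SNPs and 15 genes on a 10-Mb chromosome. The 366-patient /
43.4%-active configuration mirrors the motivating cohort's design. The
null-calibration configuration (`null_config`) zeroes every effect and
packs 25 SNPs × 80 genes into 1 Mb so ≥ 2000 cis pairs are tested. These
sizes keep each simulated scan well under a second while leaving the
planted effect at ~6 standard errors in the active group, i.e. the power
regime the defaults are meant to represent.

What the generator does **not** emulate: realistic LD block structure
beyond the one perfect-LD pair, population stratification or any
confounding, copy-number influence on expression, probe-level array
artifacts, multi-chromosome genomes (single chromosome by default), or
read-level ChIP-seq/Hi-C data. Passing tests therefore demonstrate
correctness of the statistical machinery and calibration under the stated
model — not robustness to the confounders of real tumor cohorts.
Genotype missingness exists behind `missing_rate` (pairwise-complete fits
downstream) and is off by default.

Reproducibility: all randomness flows from `SimConfig.seed` through
per-layer `numpy` generators (seed offsets per layer), so identical configs
give bit-identical studies, and the pipeline writes byte-identical reports
on reruns of the same inputs.

## Known limitations

- No covariate, ancestry or purity correction in the default scan; the
  residualization hook is the only mitigation.
- FDR is computed within each group's own test universe; comparing FDR
  values across groups assumes similar test counts (true by construction
  here, approximate in real data).
- The EM LD route assumes HWE and random mating within the cohort.
- Clinical association tests treat patients as independent and use
  dominant coding by default.
- PWM deltas have no associated significance estimate; they rank, not test.
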