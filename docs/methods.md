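# Methods

This note records the models, parameter choices and numerical conventions
behind `mirqtl`, and what the synthetic cohort does and does not emulate.

## Seed-site model

A mature miRNA's seed is anchored at position 2 (1-based along the mature
sequence); seeds of length 6, 7 and 8 therefore span positions 2–7, 2–8 and
2–9.  A UTR window of the same length is paired antiparallel (seed position
i against window position L−1−i); each pair is Watson–Crick, G:U wobble
(seed G against target U, or seed U against target G), or mismatch.  The
admission rules per length are 6-mer: no wobble, no mismatch; 7-mer: one
wobble, no mismatch; 8-mer: one wobble and one mismatch, independently
allowed.  Gaps/loops are never permitted, and windows containing N never
match.

Scanning tests every window start at every length.  At one start, only the
longest matching length is reported; nested registers of one physical
duplex (an 8-mer at s, the 7-mer at s+1, the 6-mer at s+2 sharing its 3'
edge) are distinct starts and are reported individually — downstream
consumers treat "any overlapping site" as site presence, so this costs
nothing and keeps the scan contract trivially checkable against a window
enumerator.

## Duplex energy

Site stability is scored with a nearest-neighbor stacking model on the
seed-anchored duplex: the seed pairs its window, pairing is then extended
3'-ward along the miRNA (one gapless base per step toward the UTR 5' side)
while pairs remain Watson–Crick or wobble, and the free energy is the
duplex-initiation term plus one stack term per adjacent pair of paired
positions.  A mismatch inside an 8-mer seed contributes no stack and breaks
the stacking run.  The mature 5'-terminal nucleotide is never paired — the
seed anchor starts at position 2 — so a fully complementary 22-nt target
yields 21 paired positions and 20 stacks.

Parameters live in `src/mirqtl/resources/stack_energies.tsv` (36 stacks +
initiation, kcal/mol at 37 °C).  Watson–Crick values are the standard
Turner/Xia set; wobble-containing stacks carry literature-scale values.
The table is deliberately an editable resource: the pipeline uses only the
single −15 kcal/mol pass/fail threshold, so swapping parameter sets changes
individual energies but not the analysis logic.  Secondary-structure
accessibility corrections are out of scope; the threshold is applied to the
seed-anchored hybrid.

## SNP gain/loss classification

For each (SNP, miRNA) the scanner is run on both alleles, restricted to the
windows overlapping the SNP (classification is local to ±7 nt by
construction, which the tests verify).  A site under the genomic (UTR)
allele but not the other means the MRESS is *destroyed* (effect allele =
the no-site allele); the symmetric case is a *created* illegitimate site
(effect allele = the allele carrying it).  Because the call is a function
of the UTR sequence and the two alleles, swapping which allele the variant
table labels REF changes nothing.  A SNP destroying one miRNA's site while
creating another's yields two rows.

Classification defaults to seed-rule site presence without the energy
filter.  Rationale: the 8-mer allowance of one wobble *plus* one mismatch
means a single substitution can never remove an energy-passing extended
duplex — the in-register 8-mer window simply absorbs the new mismatch — so
an energy-gated definition of "site" would make single-base gain/loss
undecidable.  Gain/loss of an MRESS is a seed-complementarity property; the
energy threshold belongs to target calling (the scan stage applies it and
reports the flag).  An `energy_cutoff` argument is still accepted for
callers who want the stricter definition.

## Pooled imbalance screen

Variant filters use the strict inequalities total reads > 10, minor allele
count > 4, MAF > 0.05, applied to depths pooled over groups.  The
imbalance ratio is the effect-allele frequency in the high-ranked pool over
the low-ranked pool, flagged amplification at ≥ 2.0 and loss of
heterozygosity at ≤ 0.5; the inclusive forms are the default and an
exclusive (`strict`) variant is provided, since both conventions appear in
practice.  A zero denominator with nonzero numerator is an amplification
with an infinite ratio, serialized as the sentinel "f/0" so it stays
distinguishable; 0/0 is undefined and never flagged.  Candidates must have
a non-none impact class *and* an imbalance flag, and must pass the filters.

## Differential expression

With a single pooled library per family group, no dispersion is estimable,
so the test is the conditional exact binomial on pooled counts: given the
total for one miRNA, its split is Binomial(total, L_h/(L_h+L_l)) under the
null (minimum-likelihood two-sided p).  CPM normalization precedes fold
changes; the signed convention reports r when r ≥ 1 and −1/r otherwise, and
a 0.5 pseudocount is added to both group means only when one of them is
zero, so well-covered ratios stay exact.  BH adjustment is per contrast.
Significance: q < 0.05 and |fold change| > 2.

The test's type-I calibration is evaluated under its own conditional null
(Poisson counts, equal expected proportions), where 5000-rep rejection at
α = 0.05 sits in [0.04, 0.06].  Under biological overdispersion the test is
anticonservative — single pooled libraries cannot distinguish biological
from sampling variation — which is why the pipeline's default simulation
(dispersion 0.1) produces a few extra DE calls beyond the planted ones.
This is a faithful property of pooled designs, not a defect of the test.

## Association stage

Traits are Blom rank-inverse-normal transformed, Φ⁻¹((r−3/8)/(n+1/4)) with
average ranks for ties; the output is invariant to strictly monotone
transforms of the input and passes Shapiro–Wilk/Kolmogorov–Smirnov
screening for continuous inputs.  Single-predictor association is OLS of
the transformed trait on additive dosage 0/1/2 (or on qPCR ΔCt = Ct_target
− Ct_U6; lower ΔCt means higher expression, so signs invert on the
expression scale).  Tables carry sign(slope)·r² — the sign-bearing
"correlation (R²)" convention — plus r, p and BH q within each trait's
panel.  Conditional independence of a focal SNP is covariate-adjusted
linear regression (a logistic model is not well-posed for a quantitative
outcome); collinear covariates are dropped with a warning.  Multi-predictor
explained variance is plain multiple-regression R².  Stratification is
classical (Torgerson) MDS — double-centering of squared distances and an
eigendecomposition — on the identity-by-state distance 1 − (mean shared
alleles)/2.  Group contrasts use Welch's t.

## Synthetic cohort

The generator emulates the study design the pipeline targets: ~98 full-sib
families of ~5 fish, the top/bottom families pooled into one small-RNA
library per group, pooled allele depths for the same contrast, and an
association cohort (786 fish when parameterized as 131 families × 6).
Defaults: mature lengths 20–24 nt (mean ≈ 22); read depth 20 000 per pool
with 15 % isomiR reads (1-nt end shifts or one substitution) and the 3'
adapter appended to a 36-cycle read; counts negative-binomial with variance
μ + dμ² at d = 0.1; planted fold changes ±4; pooled depths 80–200 reads at
effect-allele frequencies 0.7 vs 0.1 (truth ratio 7, safely beyond the 2.0
flag under binomial noise) and 0.4/0.4 for neutral SNPs; Hardy–Weinberg
genotypes at MAF 0.3; family and residual SDs 0.5 and 0.866 on the latent
scale (variance 1), mapped to realistic trait units (WBW 860 ± 190 g,
muscle yield 47 ± 3 %, crude fat 7 ± 2.2 %, shear force 420 ± 90 gf/g,
whiteness 43 ± 1.5, with L*/a*/b* back-computed to be exactly consistent
with the whiteness column).

Planted sites/SNPs use a dedicated construction: the planted region
complements mature positions 2–9 except that the base pairing position 9 is
a hard (non-wobble) mismatch, pre-consuming the in-register 8-mer's
mismatch budget so that one core substitution (pairing seed positions 3–7)
removes the 6-, 7- and 8-mer calls simultaneously.  Destroy-SNPs carry the
intact site on the genomic allele; create-SNPs carry the broken one.
Every placement is verified through the actual classifier — intended class
for the intended miRNA, nothing else called — with up to 1000 retries
before failing loudly, so downstream class recovery is exact by
construction rather than by luck.

What the generator does **not** emulate: sequencing error profiles,
mapping/reference bias, linkage disequilibrium between SNPs, genotypes
segregating within families (dosages are i.i.d., so family structure and
genotype are independent), or per-fish small-RNA replication (one library
per pool, as in the pooled design).  Passing tests therefore demonstrate
the correctness of the algorithms and the calibration of the statistics
under the stated models, not robustness to real-data artifacts.

## Problem sizes and determinism

Test and acceptance experiments use desk-scale sizes chosen to make the
Monte-Carlo bands tight at interactive runtimes: 1000 scanner-oracle pairs
per seed length, 150 planted SNPs for recovery, 5000 replicates for the
two null calibrations, 200 miRNAs with 20 planted 4-fold changes for DE
recovery, and n = 786 for the planted-5 %-variance association.  All
randomness flows from `numpy.random.default_rng` seeds (spawned per stage
from one seed sequence); a repeated run with the same seed is byte
identical, including every emitted table.  Emitted coordinates are 1-based
closed (VCF convention); internal arithmetic is 0-based half-open.
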