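# Methods

This note documents the models, defaults and numerical choices behind
`wildpopsig`, and what the synthetic data generator does and does not
emulate.

## The synthetic study design

The generator reproduces the statistical structure of a two-site wild
*C. elegans* panel. Strains are clonal homozygous lines, so each strain is
one haplotype and one array (DNA branch) or one replicate pair (RNA
branch).

**Strains.** 48 strains in five genetic groups: O (20, orchard site),
S1 (14), S2 (3), S3 (4) (woodland site) and 7 out-group strains. One S3
strain is flagged as site-crossing: it clusters genetically with S3 but
was isolated at the orchard, giving 21 orchard / 20 woodland site labels.
Group labels drive the planted group effects; site labels drive the site
effects; the two are deliberately not identical.

**Genes and probes.** 20,000 genes allocated across the six chromosomes
in proportion to the array's per-chromosome gene totals, placed uniformly;
two probes per gene, positioned within the gene span and sorted by
genomic coordinate. The probes-per-gene count is configurable because the
real 4×44K design's probe-to-gene multiplicity is not fixed.

**Polymorphisms.** A gene is polymorphic with base probability 0.30,
multiplied inside hotspot regions (chromosome II left arm ×4, central
chromosome V ×2.5). Inclusion is independent Bernoulli per gene: with a
30% genome-wide rate, weighted sampling without replacement would saturate
the hotspots and compress the configured rate ratio, whereas Bernoulli
inclusion preserves it exactly. Carrier patterns:

- 66% *private*: 1–3 uniformly chosen carrier strains;
- 6% *group-linked*: carriers are one whole genetic group (these genes
  are drawn with a ×5 weight for the environment-responsive gene classes,
  planting the class enrichment);
- the rest: 4–8 random carriers.

Carriers shift the test channel by the deletion effect (−1.5 log2 units).
A further 400 genes carry *minor* site-linked shifts (−0.4, below the call
threshold) across an entire site — detectable by the linear model but not
by the ratio call, which is exactly the regime the linkage screen exists
for. Planted counts are calibrated to the 20,000-gene default and scale
proportionally when `n_genes` is changed; explicitly configured counts are
taken verbatim.

**Channel model.** Per probe, log2 baseline ~ N(10, 1.5); test channel
= 2^(baseline + effect + dye bias + ε_t) + background, reference channel
= 2^(baseline + ε_r) + background, with channel noise ε chosen so the
per-probe M-value noise SD is the configured 0.2. The dye bias is a smooth
quadratic function of intensity (amplitude 0.2) so the LOESS step has a
real trend to remove; the additive background is stored per probe so
background subtraction can be exact. Detectability arithmetic: two probes
per gene give a per-(gene, strain) ratio noise SD of 0.2/√2 ≈ 0.14, so a
−1.5 carrier sits ≈7 SD beyond the −0.5 threshold (sensitivity ≳0.99)
while a null cell sits 3.5 SD inside it (false-call rate ≲0.001). The
realized per-cell false-call rate (~0.5%) is dominated not by noise but by
*anti-carrier* cells: when a whole 20-strain group carries a deletion, the
non-carriers' ratio to the gene mean is +0.625 and legitimately crosses
+0.5. These cells are counted as false against the carrier truth, which
makes the reported false-call rate conservative.

**Expression.** Two replicates per strain, replicate 1 in batch 0 and
replicate 2 in batch 1 (balanced, so the batch term is orthogonal to all
strain-constant terms). Per-gene drivers (counts at the default universe):
DNA (200; expression = 0.8 × the gene's planted DNA ratio), site (300) and
group (300) with level means ~ N(0, 0.5), batch (500; ±0.3 by batch),
genotype (250; per-strain effects ~ N(0, 0.5)); all other genes are pure
noise. No background is added on the RNA branch.

**Organismal data.** Phenotype replicates ~ N(strain mean, within-SD) with
strain means ~ N(site mean, between-SD); defaults mirror the magnitudes of
the measured fitness traits (population size, development/generation time,
body dimensions). Food-choice counts are multinomial over (A, B, neither)
with per-site preference triples, including the 85.7/5.5/8.8 split whose
Choice Index is 0.802. Microsatellites: six loci, five alleles, each group
concentrating 0.8 frequency on its own modal allele per locus.

**What the generator does not emulate:** sequence-level variation, probe
thermodynamics, cross-hybridization, spatial array artifacts, dye swaps,
realistic ontology structure, or correlated gene neighborhoods beyond the
hotspot rate. Passing recovery tests therefore show that the pipeline's
statistics behave as designed under the study's noise and effect-size
regime — not that they would be equally calibrated under artifact classes
the simulator omits.

## Normalization

DNA branch: exact background subtraction (floored at 0.5 to keep logs
finite), LOESS of M on A per array, then scale normalization (each array
divided by its median absolute deviation and rescaled by the geometric
mean of all arrays' MADs). RNA branch: no background correction, LOESS,
then quantile normalization (every array mapped onto the mean sorted
vector; ties receive the value at their average rank by interpolation).

LOESS uses span 0.3, three robustness iterations, local linear fits, and
an interpolation grid (`delta` = 0.3% of the A range) for speed; the
method itself is named by the study but its parameters are not, so these
are surfaced in the run configuration. Two degenerate regimes are handled
explicitly: a constant-A array falls back to median-centering with a
warning, and on *noise-free* data the robust weighting is degenerate at
the extreme-intensity boundary, where a window dominated by shifted probes
can absorb part of a planted effect. This affects a handful of boundary
probes only in zero-noise tests and is invisible at realistic noise.

## Polymorphism calls

Probe values are averaged per gene (unweighted; the aggregation order —
call-then-aggregate versus aggregate-then-call — is not dictated by the
source analysis, and gene-level averaging is the variance-optimal choice
under the two-probe model). The ratio is the log2-scale deviation from the
gene's across-strain mean, so rows sum to zero by construction; thresholds
are strict inequalities (a ratio of exactly 0.5 is not called). The
moving-average profile uses a centered nine-probe window, trimmed at
chromosome ends; its region-call threshold defaults to ±0.25 (the original
figures draw the threshold but never print it; it is configurable).
Coordinates are 1-based inclusive internally and 0-based half-open in BED
exports.

## Population structure

Distances are Euclidean over the polymorphic-gene ratio vectors (the
source names no metric; Euclidean matches the PCA geometry and is recorded
as a package choice). Neighbor joining follows the Saitou–Nei Q-criterion
with deterministic tie-breaking (lowest label pair); negative branch
lengths are clamped to zero with the deficit moved to the sibling edge, so
additive matrices are still reproduced exactly through path lengths. The
minimum spanning network uses Kruskal's MST over distinct multilocus
genotypes with distance = number of differing loci (an infinite-alleles
choice; stepwise size differences would need allele sizes the tables do
not carry), plus every non-tree edge whose weight ties the maximum edge
weight on the tree path between its endpoints as an "alternative"
connection.

## Linkage screens and permutation FDR

Per-gene models are fitted by sequential (Type I) sums of squares in the
fixed order batch → DNA covariate → factor → genotype, all terms F-tested
against the residual of the full model; −log10(p) is capped at 300. The
factor screens are one-vs-rest recodings per level (site: Orsay,
Santeuil; group: each wild group against the out-group strains only).

Thresholds are calibrated by permutation: sample labels are shuffled
jointly across all genes (preserving the between-gene correlation
structure), est-FDR(θ) = (mean permuted positives at θ) / (observed
positives at θ), and the chosen threshold is the smallest observed
−log10(p) with est-FDR < 0.05. The "false positives / true positives"
phrase is interpreted as this standard permutation estimate; at a 0.05
target the difference from FP/(all positives) is second order. On fully
null data the chosen threshold is +∞ — though with finitely many
permutations the observed maximum occasionally outranks all permuted
values (probability ≈ 1/(n_perm+1)), so a lone spurious positive is within
the estimator's contract. Validation on planted signals (41 strains,
2,000 genes, 200 effects of 1.0 SD on noise 0.25, 100 permutations) gives
a realized FP/TP of ≈0.049 averaged over ten seeds at full sensitivity,
with calibrated thresholds around −log10(p) ≈ 2.3–2.5.

The expression decomposition exploits the balanced replicate-per-batch
layout: the batch term is orthogonal to every strain-constant term, so
DNA, site/group and genotype sums of squares are computed in strain-mean
space and the genotype term is the leftover between-strain variation,
tested against the within-replicate residual. Permutations shuffle whole
arrays over the genotype × batch layout, nullifying every term at once;
each term gets its own calibrated threshold, and a gene whose attribution
set is exactly {DNA} is flagged DNA-only and excluded from the expression
tree input. Because the fitted DNA covariate is the *measured* ratio, a
DNA-driven gene carries a small residual between-strain component; at
lenient calibrated thresholds some of it surfaces in the genotype term,
which is why the DNA-only count (160 at the default run) sits slightly
below the planted 200.

## Enrichment

The hypergeometric upper tail is summed in log space via log-gamma, exact
to enumeration at 1e-10 relative error, and cross-checked against an
independent library implementation in the tests. The decision rule is
fixed — overlap > 3 AND −log10(p) > 2.5 — with no further multiple-testing
correction, faithful to the source procedure. The default universe is all
genes assayed on the array and is configurable per annotation kind,
because the original universe is ambiguous: recomputing the printed
per-class significances under the 20,881-gene universe is exposed as a
logged diagnostic rather than a hard test. Environment-study gene sets are
plain term → gene-list inputs; the shipped generator produces synthetic
stand-ins with 60% of each set drawn from the environment-responsive
classes.

## Phenotype statistics

Strain ANOVA is a one-way F-test on replicate values. The site comparison
is a two-sided Welch test on *strain means* — replicates within a strain
are pseudo-replicates for a between-site question; the source is ambiguous
on this point and the strain-mean choice is the conservative one.
Broad-sense heritability uses the one-way random-effects components,
V_g = (MSB − MSW)/n₀ with the standard unbalanced-design effective
replicate number n₀, clamped to [0, 1]. The Choice Index keeps
non-choosers in the denominator, making the three preference fractions of
an assay CI-consistent.

## Problem sizes and determinism

Default problem sizes (48 strains × 20,000 genes × 2 probes; 96 expression
arrays; 100 permutations for the DNA screens, 50 for the expression
decomposition) complete an end-to-end run in about a minute on one CPU;
the validation experiment in `scripts/acceptance.py` uses the 41 × 2,000
screen at 100 permutations over ten seeds. All randomness flows from one
master seed through fixed per-component offsets, so any data product can
be regenerated independently and identical configuration + seed yields
byte-identical outputs.

## Known limitations

- The simulator's polymorphisms are gene-level shifts; it cannot probe
  breakpoint-level region calling, so the moving-average region calls are
  validated only structurally.
- Sequential (Type I) attribution is order-dependent by design; terms
  earlier in the order absorb shared variance (e.g., the DNA covariate
  absorbs part of a group effect when a gene's DNA ratio is itself
  group-structured).
- The per-class enrichment significances of the original study are not
  reproducible without its universe definition; only internal consistency
  is checked.
- PCA variance fractions depend strongly on the private-to-shared
  polymorphism mix; with the default 66% private mass, PC1–2 capture ~14%
  of the variance while still separating the sites (silhouette ≈ 0.6).
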