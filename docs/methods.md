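# Methods

This note documents the models implemented in `strainmap`, the synthetic
panel that exercises them, the numerical choices, and the package's known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The mixed model

Replicate-level phenotypes follow

    y = X beta + Z u + e,   u ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I),

where `Z` (n animals x s strains) maps each animal to its strain and `K`
is the strain kinship. With `delta = sigma_e^2 / sigma_g^2` and one
eigendecomposition of `H = Z K Z'`, the restricted likelihood becomes a
1-D function of `delta`:

    l_R(delta) = -1/2 [ (n-q)(log 2*pi*sigma_g^2 + 1) + log|H + delta I|
                        + log|X'(H + delta I)^-1 X| - log|X'X| ],

with `sigma_g^2` profiled out as `y'Py/(n-q)`. The optimizer evaluates a
101-point grid over `log10(delta) in [-5, 5]` (batched linear algebra over
the whole grid) and refines the best interior interval with bounded
Brent to 1e-8; a maximum at either grid edge is returned capped and
flagged (`boundary=True`) rather than treated as an error, since
`sigma_g^2 -> 0` legitimately drives `delta` to the upper edge. Eigen
coordinates are cached per `(Z, K)` so per-marker exact REML costs
O(n q^2) per likelihood evaluation.

Markers are scored by a Wald F test of the SNP coefficient (strain-level
dosage expanded through `Z`) with `(1, n - rank(X))` degrees of freedom.
Two modes exist: `exact` re-estimates `delta` with the marker in the
model (the default for clinical traits); `approx` reuses the null-model
`delta`, the standard trade-off for scans over thousands of expression
traits, and agrees with `exact` at correlation >= 0.99 on panel-scale
scans (verified in the test suite).

### Kinship and LOCO

`K` is pairwise-complete identity-by-state allele sharing over filtered
SNPs (unit diagonal, `1e-6 I` jitter for downstream factorizations).
Genome scans default to leave-one-chromosome-out (LOCO): markers on
chromosome c are tested against a kinship built from the other
chromosomes. At this package's desk scale (5 chromosomes) each chromosome
is ~20% of the genome, so including the tested marker's own LD block in
`K` (proximal contamination) costs far more power than at a 19-autosome
scale; LOCO restores the full-scale behavior. The flip side, also a
known LOCO property, is that the focal chromosome's *polygenic
background* goes unmodeled, which inflates null statistics when a
chromosome carries a large share of the background. Calibration under a
polygenic null is therefore a property of the whole-genome-K mode
(`loco=False`), and that is how the calibration experiment runs; mapping
experiments use LOCO. At realistic chromosome counts the two modes
coincide in both respects.

### Filters and thresholds

SNPs enter a scan with minor-allele frequency >= 0.05 (inclusive) and
missing fraction < 0.20. The genome-wide significance threshold defaults
to -log10 P = 5.39 and the locus confidence interval to peak +/- 1.3 Mb;
both are consumed as configuration (they derive from panel-specific
simulation studies upstream of this package). Local eQTL significance is
Bonferroni-corrected at alpha / (number of probes tested across loci in
the run); per-locus correction is available by flag.

## Locus calling and candidate genes

Significant SNPs on one chromosome within 2 x half-width of each other
form one locus; the peak is the most significant SNP with ties broken to
the lowest position; CIs clip to [1, chromosome length]. Genes overlap a
locus by >= 1 bp to count. Probes whose genomic footprint contains any
panel SNP are excluded before eQTL testing (hybridization-artifact
guard). A functional candidate is a gene with a significant local eQTL
or a damaging (Possibly/Probably Damaging, Nonsense) non-synonymous SNP
in the CI; each coding variant carries its LD r^2 to the peak SNP,
computed by default within the classical-strain subset (RI mosaics of two
founders make r^2 in the RI subset nearly binary and uninformative about
historical LD). Ranking: peak-coincident damaging variants first, then
r^2 to peak, then eQTL evidence.

## Co-expression networks

Unsigned adjacency `|cor(x_i, x_j)|^beta` (Pearson; a signed variant
`((1+cor)/2)^beta` behind a flag), `a_ii = 0`. The soft power is the
smallest integer in 1..20 whose connectivity distribution reaches a
signed scale-free fit R^2 >= 0.8 (log10 bin frequency regressed on log10
bin mean over 10 equal-width bins; sign flipped when the slope is
positive); when nothing qualifies — which is the expected behavior for
strongly modular, non-scale-free synthetic data — the argmax power is
used with a warning. Topological overlap

    w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),  l_ij = sum_u a_iu a_uj

with `w_ii = 1`; `d = 1 - w` feeds average-linkage clustering.

Module detection is a deterministic three-stage branch cut, a transparent
stand-in for the published dynamic branch-cutting algorithm, whose many
internal parameters are not reproducible from the outside: (1) static cut
at the `cut_height_q` (default 0.99) quantile of merge heights, branches
below `min_size` (default 30) unassigned; (2) each unassigned gene joins
the module with the smallest mean dissimilarity to its members, provided
that mean is below the gene's mean dissimilarity to all assigned genes;
(3) module eigengenes (first principal component of standardized module
expression, sign-oriented so mean member correlation is positive) drive
iterative merging of any pair at eigengene dissimilarity < `merge_diss`
(default 0.25, a field convention), to a fixed point. Labels are colors
in a fixed size-ordered list; "grey" is unassigned. Connectivities:
`k_total` sums a gene's adjacency to all network genes, `k_in` only to
same-module genes; grey genes have `k_in = 0` by convention.

Edge views rank within-module pairs by TOM (lexicographic tie-break) and
report neighbor lists, degree-1 genes with their unique partners, and
second-order neighborhoods — the machinery behind guilt-by-association
readings of a hub-adjacent gene.

Probe filtering for network construction runs detection P < 0.05 in >=
95% of samples (all-pass when no detection matrix exists, as for the
synthetic data), top 8000 by variance, soft-power selection on that set,
then the top 3600 by `k_total` with one probe per gene (the most
connected); caps clip to the probes available.

## Enrichment

For a query of n genes against a set of X in a background of N with
overlap x: nominal P is the hypergeometric upper tail P(overlap >= x);
EASE mode (default, the conservative variant used by popular annotation
servers) takes the tail from x-1. Bonferroni multiplies by the number of
sets tested (x >= 1). Fold enrichment is (x/n)/(X/N). Term clustering:
Cohen's kappa on the 2x2 gene-membership table over the background seeds
pairs at kappa >= 0.35; groups sharing >= 50% of the smaller group's
terms merge to a fixed point; each cluster's enrichment score is the mean
-log10 nominal P of its terms (ES > 3 flags a significant theme). The
kappa and linkage defaults follow the annotation-clustering convention;
the enrichment background is the network-filtered gene list, not the
genome. Neighborhood enrichment re-runs the same machinery with a module
(not the array) as background and reports the captured fraction x/X.

## Phenotype summaries and the knockout comparison

Strain summaries report n, mean, SEM (= SD/sqrt(n); flagged undefined at
n = 1) and the panel fold range max/min of strain means, raw and rounded
to one decimal. The knockout comparison regresses the trait on nuisance
covariates (age, weight) by OLS with intercept across all animals of one
sex — residualization is deliberately fit across genotypes so the
genotype contrast survives in the residuals — then compares residuals
between two genotype groups with a two-sided pooled-variance Student's
t-test (small groups; pooled variance rather than Welch). Constant
covariate columns are dropped (absorbed by the intercept), making the
degenerate case exactly the plain two-sample t-test.

## The synthetic panel

The generator emulates a hybrid diversity panel with known truth at every
stage. Defaults (one scenario, used by tests and the acceptance script):
100 strains (30 classical + 70 RI), 5,000 SNPs on 5 chromosomes at ~20 kb
spacing, 9 replicates per strain, 600 genes in 5 expression modules, one
array per strain.

* **Genotypes.** Classical strains pick one of 12 ancestral haplotypes
  per 10-SNP block, preferring their group's block-specific haplotype
  with probability 0.6 (6 groups; preferred haplotypes distinct across
  groups within a block). This induces kinship structure and LD without
  modeling actual breeding history. RI strains are Poisson-breakpoint
  mosaics (mean 8 crossovers per chromosome) of the first two classical
  strains. Block length and crossover density were chosen so the panel
  has several hundred independent LD blocks, the regime of a real
  genome; with long blocks an infinitesimal polygenic background
  aggregates into spurious locus-sized effects.
* **Phenotypes.** On the strain-mean scale (total variance 1): the causal
  SNP explains exactly `causal_frac` (default 0.15; the polygenic draw is
  orthogonalized against the causal direction so the label is exact in
  every realization), the polygenic term `h2 - causal_frac`, and averaged
  replicate noise `1 - h2`. `h2` (default 0.7, within the range commonly
  reported for skeletal traits) is thus the heritability of strain
  means. The polygenic term is infinitesimal — i.i.d. small effects on
  every common SNP except the causal one — so no background marker
  carries more than a sliver of genetic variance. The causal SNP is
  drawn mid-chromosome with MAF in [0.15, 0.45] and must segregate
  between the two RI founders (a variant on which they agree would be
  monomorphic across the entire RI subpanel, an artifact of the
  two-founder design; real RI sets descend from multiple founder pairs).
* **Expression.** One latent eigengene per module per strain; gene =
  sqrt(within_cor) x eigengene + sqrt(1 - within_cor) x noise
  (within_cor default 0.7). Thirty genes get a cis-eQTL: 1.5
  noise-SD x standardized genotype at the common SNP nearest the gene
  center within 1 Mb. Probe footprints (50 bp) are placed to avoid panel
  SNPs so the overlap filter does not silently remove planted signal.
* **Annotations.** Genes tile the chromosomes evenly; the gene nearest
  the causal SNP is re-centered on it, and the causal SNP is recorded as
  a Probably Damaging coding variant of that gene; decoy coding SNPs are
  Benign. One gene set of 40 genes is planted at 75% concentration in
  module 0, plus random decoy sets; the universe is the annotated gene
  list.

What the generator does **not** emulate: real mouse recombination maps
and chromosome sizes, allele-frequency spectra shaped by bottlenecks,
multiple RI founder pairs, missing genotypes (present only when
introduced explicitly), array batch structure, detection-P patterns, and
distant (trans) eQTL hotspots. Passing recovery tests therefore shows the
pipeline's statistics behave correctly under honest confounding, not that
any particular biological dataset would yield the same numbers.

## Benchmark experiments and problem sizes

The `experiments` module (also driven by `scripts/acceptance.py`) runs:

* **REML oracle** — 50 random instances (<= 20 animals): the
  eigendecomposition optimum vs direct dense-matrix likelihood
  maximization on a 10,000-point delta grid (dense-route Brent refinement
  around the best grid point, since a raw grid's discretization error can
  exceed the 1e-6 comparison tolerance).
* **Null calibration** — 1,000-SNP structured panel, polygenic null
  (causal_frac 0), six phenotype draws pooled (~5.7k tests, whole-genome
  K): type-I error at alpha = 0.01 and median-based genomic inflation,
  against strain-mean OLS on the same data. Six draws because tests are
  correlated across SNPs and the inflation factor needs ~5k tests for a
  Monte-Carlo sd comfortably inside a +/-0.1 band.
* **Causal recovery** — 20 seeds of the full default scenario through
  scan -> loci -> eQTL -> candidates, reporting the rates at which the
  planted SNP is the top genome-wide SNP above threshold, its signal
  alone clears the threshold, the top SNP falls inside the causal CI, and
  the causal gene is the top-ranked candidate. These are distinct
  quantities by design: in any panel with realistic LD, a proxy SNP at
  r^2 close to 1 trails the causal by an R^2 deficit of only
  causal_frac x (1 - r^2), which sits inside the sampling noise of the
  non-causal strain variance at 100 strains, so exact top-SNP identity is
  a coin flip against each near-perfect proxy while locus- and gene-level
  recovery remain stable.
* **Module recovery** — 10 seeds of the 5-module scenario through probe
  filtering and network construction, scored by adjusted Rand index
  against the planted assignment.
* **Oracle checks** — TOM vs a triple-loop implementation on 100 random
  adjacencies (<= 25 genes); hypergeometric/EASE tails vs exhaustive
  enumeration; the Bonferroni eQTL threshold at 98 probes printing as
  5.1e-04.

All experiment sizes are the package's own desk-scale choices; every
random quantity derives from the single `--seed` argument.

## Known limitations

* The locus CI half-width and genome-wide threshold are fixed
  configuration, not derived from the data; a permutation-based
  threshold estimator exists only implicitly through the null experiment.
* Exact per-marker REML across probes-by-SNPs eQTL grids would be
  expensive; eQTL scans use the EMMAX-style approximation.
* The three-stage module cut reproduces the qualitative behavior of
  dynamic branch cutting (size-guarded branches, rescue of near-branch
  genes, eigengene merging) but not its exact labels.
* Kappa clustering is greedy and order-dependent by construction; the
  order is fixed (nominal P, then term name) to keep it deterministic.
* VCF input is read minimally (biallelic, GT field, plain text);
  heterozygous calls become missing by design in an inbred panel.
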