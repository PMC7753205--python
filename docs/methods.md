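# Methods

## Model and procedure

The unit of observation is a gene's bi-parental allele counts in two RNA
samples — the F1 hybrid and an *in-silico hybrid* (an equal-amount
computational mixture of the two parents' reads, i.e. the additive
mid-parent expectation) — plus a mixed parental DNA control. Reads are
assigned to a parent at SNP sites that distinguish the parental genotypes,
and counts are summed over all retained SNPs in the gene body.

Writing the cis effect c and the trans effect t in log2 units, the expected
parent-1 allele fraction is

- F1: p_F1 = 2^c / (1 + 2^c) — both alleles share one trans environment, so
  only cis differences show;
- mix: p_mix = 2^(c+t) / (1 + 2^(c+t)) — the parental log ratio is the sum
  of cis and trans contributions (t is defined as the parental log ratio
  minus the F1 log ratio).

Three exact tests are computed per gene: a two-sided binomial test of the
mix counts against 1:1 (P), of the F1 counts against 1:1 (H), and a
two-sided Fisher exact test of the 2×2 table [F1; mix] (T). Binomial
two-sidedness follows the minimum-likelihood rule (sum of all outcomes no
more probable than the observed one); at p = 0.5 this equals
min(1, 2·CDF(min(k, n−k))) and is validated against `scipy.stats.binomtest`
in the test suite. p-values are BH-adjusted *within each comparison* across
all tested genes, and a gene is significant in a comparison at q < 0.05.
The seven-way category is a total function of the significance pattern and,
when all three comparisons are significant, the sign agreement of the two
log2 allelic ratios (computed with a 0.5 pseudocount; an exactly-zero ratio
counts as agreement and is logged).

## Filters

- Variants: bi-allelic SNPs only, parents homozygous for different alleles,
  GQ > 20 and DP > 5 in both parents (strict inequalities).
- Mapping-bias control: a SNP is removed when its mixed-DNA counts reject
  1:1 at a raw two-sided binomial p < 0.05. No FDR here: the filter is
  deliberately aggressive, since a biased SNP contaminates every downstream
  ratio. Being an exact test at integer depth, its true size is below the
  nominal 5% (≈4.3% at depth 30); the calibration test checks the removal
  rate against this exact size, not against the unattainable nominal level.
- Genes: at least 2 retained SNPs; mean total count across the two RNA
  samples strictly between 10 and 1,000 (both bounds configurable, the
  filter can be disabled). The expression filter is applied before
  classification.

## Duplication modes

From all-vs-all protein homology (blast tabular; e-value ≤ 1e-10, top 5
non-self hits per query — MCScanX-like defaults, configurable) and gene
rank order per chromosome:

- singleton: no non-self hit;
- tandem: a paralog at rank distance 1 on the same chromosome;
- proximal: a same-chromosome paralog at rank distance 2–20 ("fewer than 20
  intervening genes"; the boundary is a config knob since "fewer than 20"
  can be read on either the intervening count or the rank distance);
- WGD: member of a collinear-block anchor pair;
- dispersed: any other gene with a hit.

Priority is wgd > tandem > proximal > dispersed, mirroring MCScanX's
override order. Collinear blocks are either read from an MCScanX-style
`.collinearity` file or detected by a simplified greedy chaining: anchors
monotonically ordered in both genomes' rank space (parallel or
antiparallel), per-step gap ≤ 25 ranks on both sides, ≥ 5 anchor pairs.
Same-chromosome anchor pairs closer than 25 ranks are excluded from
chaining before block detection — these are tandem/proximal-type local
duplicates, and without the exclusion a run of adjacent tandem pairs would
chain into a spurious "block" (MCScanX collapses tandem arrays for the same
reason). The chaining is validated against exhaustive maximal-chain
enumeration on small planted instances.

WGD ages: per-block mean Ks (synonymous substitutions per synonymous site,
averaged over the block's anchor pairs) is clustered into k = 3 groups; a
gene is *young* iff every block containing it falls in the lowest-Ks
cluster. The 1-D k-means is solved exactly by a contiguous-partition
dynamic program (optimal 1-D clusters are contiguous in sorted order),
which is deterministic and globally optimal — a seeded Lloyd iteration
would add a dependence on initialization for no benefit, and the exact
solution provably coincides with exhaustive partition search. With fewer
than k distinct Ks values the clustering degenerates to grouping by value
(logged).

## Cross-tabulation and enrichment

The mode × category table reports counts and row percentages (rounded
half-up to 2 decimals, matching how such tables are printed). Two
chi-squared constructions are exposed, both without continuity correction:
a 1-df goodness-of-fit of (cis-only, trans-only) counts against 1:1 within
a mode, and a 2×2 test of a mode's cis-only rate against the rest of the
genome (genome minus the mode's genes).

Enrichment: upper-tail hypergeometric P(X ≥ k) per term, with the universe
taken as the expressed genes (configurable), terms annotating fewer than 5
universe genes removed before testing, and BH across the retained terms of
one annotation source (GO and Pfam are adjusted separately when supplied as
separate files). No GO-DAG propagation.

## Synthetic data

`simulate_dataset` draws, per gene: a total depth from a negative binomial
parameterized by mean μ and dispersion φ (variance μ + φμ²), the standard
RNA-seq overdispersion model; parent-1 reads binomial(total, p); and a
multinomial split of each allele's reads over the gene's SNPs with equal
weights (relative SNP coverage is irrelevant downstream because counts are
re-summed). The DNA control draws binomial(depth, 0.5) per SNP except a
configurable fraction of mapping-biased SNPs with a skewed success
probability. Each sample type has its own RNG stream spawned from the
master seed, with genes drawn sequentially within a stream, so extending a
dataset never perturbs existing genes; a fixed seed gives bit-identical
output.

Defaults (all configurable): 2–5 SNPs per gene, mean depth 300 reads/gene
in both RNA samples (within the 100–1,000 band the expression filter
targets), φ = 0.1, DNA depth 30 per SNP, 5% biased SNPs at probability 0.8,
effect magnitudes uniform on [0.5, 2] log2 with random sign, and a category
mix of 55% conserved / 9% cis-only / 21% trans-only / 6% cis+trans / 4%
cis×trans / 5% compensatory — roughly the category frequencies reported for
interspecific plant hybrids, with trans-only about twice cis-only.

Architecture semantics: conserved c = t = 0; cis-only t = 0; trans-only
c = 0; cis+trans same signs; compensatory t = −c exactly (parents balanced,
F1 skewed). For cis×trans the generating draw enforces |t| > |c| with
opposite signs: the category is *observable* only when the parental ratio
(sign of c+t) opposes the F1 ratio (sign of c) — |t| = |c| is exactly the
compensatory architecture, and |t| < |c| presents as cis+trans under the
published rule. Without this constraint the planted truth would be
unrecoverable in principle, not merely underpowered.

`simulate_genome_layout` plants duplication modes that the assigner
recovers exactly: each collinear block occupies its own chromosome pair
(odd blocks antiparallel) so blocks cannot merge; tandem pairs are adjacent
on the main chromosome; proximal pairs are separated by hit-less filler
genes; dispersed partners are scattered over chromosomes holding fewer than
5 genes each, so they can never reach block length. Block Ks values cycle
over three well-separated tiers (0.08–0.15, 0.5–0.7, 1.2–1.6 — recent WGD,
older WGD, ancient polyploidy scales), giving planted young/old age truth.

## What the generator does and does not emulate

It reproduces the count-level statistical structure the analysis consumes:
overdispersed depths, binomial allelic sampling, per-SNP splitting, a
biased-SNP DNA control, and planted genomic layouts. It does not simulate
reads, alignment artifacts, read-level mapping bias (bias is modeled
directly as skewed DNA-control probabilities), double-counting of reads
spanning adjacent SNPs, replicate structure, or realistic collinearity
noise (inversions, deletions inside blocks). Passing tests therefore
demonstrate correctness of the statistical machinery and the closed loop
between generator and estimators — not robustness to alignment pathologies
of real data.

## Numerical choices and problem sizes

Pseudocount 0.5 for ratio signs; half-up rounding only at the presentation
layer; BH via statsmodels with monotonicity enforcement; Fisher tests via
scipy per gene (the only per-gene Python loop that matters; 2,000 genes in
a few seconds). The test suite and the acceptance script use 2,000-gene
simulations at depth 10,000 for recovery/calibration checks, 400-gene
layouts for mode recovery, and 1,000 replicates for the enrichment null —
sizes at which every stochastic bound holds with wide margin while the
whole suite stays in the tens of seconds.

## Known limitations

- Replicates are pooled into single count tables before testing; no
  overdispersed (e.g. beta-binomial) per-gene test.
- No effect-size estimation or shrinkage; categories only.
- The greedy chaining is not the MCScanX dynamic program; on dense,
  noisy real hit tables it may fragment blocks that MCScanX would join
  (reading MCScanX's own `.collinearity` output is the supported path for
  real data).
- SNPs in overlapping genes count toward each gene (logged), which double
  counts a small number of reads in compact genomes.
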