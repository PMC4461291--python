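# Methods

`cubkit` quantifies codon usage bias (CUB) in sets of coding sequences and
compares it across genomes. This note records the statistical definitions
implemented, the conventions chosen where the literature is ambiguous, what
the synthetic-data generator does and does not emulate, and the numerical
choices that affect results.

## Input handling and codon counting

Input is one nucleotide FASTA record per CDS. Sequences are upper-cased and
U is converted to T. Quality filtering keeps a CDS only if it is at least
300 bp long (shorter genes make per-gene indices such as ENc and RSCU
unacceptably noisy), its length is a multiple of three, and it contains no
in-frame internal stop codon (the terminal stop is allowed). Each drop is
reported with its reason; filtering is total and idempotent. Annotation
pipelines do occasionally emit out-of-frame or internally stopped CDS;
dropping them keeps all downstream arithmetic well defined rather than
guessing a reading frame.

Codons are counted in frame, non-overlapping. Triplets containing IUPAC
ambiguity codes are skipped and tallied, never imputed — imputation would
bias composition estimates in an unquantifiable direction. The terminal
stop codon is counted by default so genome-level RSCU tables can include
the stop family; a flag excludes it for annotation conventions that strip
stops. Codon positions are labelled 1/2/3.

## Composition statistics

For each gene the package computes, over explicitly different codon
universes:

* **GC_cds** — GC fraction over all counted codon positions, no exclusions.
* **P1, P2** — GC fraction at codon positions 1 and 2, excluding the
  single-codon amino acids Met (AUG) and Trp (UGG), whose bases are fixed
  by the protein sequence and carry no usage signal.
* **P3** — GC at position 3, additionally excluding the three stop codons
  and the three Ile codons, whose third-position substitution dynamics are
  asymmetric (transition/transversion rate inequality); **P12** =
  (P1 + P2)/2.
* **GC3s** — GC at third positions of *synonymous* (degenerate sense)
  codons: Met, Trp and stops excluded but Ile included. P3 and GC3s are
  deliberately distinct statistics; they coincide exactly on genes with no
  Ile codons (a property test asserts this).
* **A3/U3/G3/C3** and the PR2 coordinates AU-bias = A3/(A3+U3), GC-bias =
  G3/(G3+C3). By default these use the same universe as P3, so one
  third-position universe feeds both the neutrality and PR2 plots; the
  classic PR2 restriction to fourfold-degenerate families is available via
  `pr2_universe="fourfold"`. Under composition-only evolution both biases
  sit at 0.5; displacement indicates strand- or selection-driven asymmetry.

Ratios with an empty denominator propagate as NaN, never 0, so correlations
and regressions use complete pairs only. Genome-level values are per-gene
means over defined entries (the pooled-counts alternative is available by
pooling first and computing once).

## Indices

**RSCU.** For codon *j* in a synonymous family of size *k* with family
total *N*: RSCU_j = count_j · k / N. Values within an observed family sum
to *k*; unobserved families are reported missing (a gene that never uses
Gly is not "unbiased about Gly"). Single-codon amino acids print 1.0.

**CAI.** Relative adaptiveness on a reference set:
w_j = RSCU_j / max-family-RSCU, with a 0.5 pseudocount for zero-count
reference codons so every weight is positive. CAI of a gene is the
geometric mean of w over its weighted codons (Met, Trp, stops carry no
weight): CAI = exp(Σ n_j ln w_j / Σ n_j). Three reference choices:

* `yeast` (default) — the S. cerevisiae w table of Sharp & Li (1987), the
  reference distributed with CodonW, shipped as packaged data (sourced from
  the seqinr `caitab` dataset).
* a FASTA of reference genes — weights computed from its pooled counts.
* `self` — weights from the analysed genome's own pooled usage. Useful when
  no homologous high-expression set exists, but note the caveat below.

A caveat the synthetic experiments make vivid: CAI ranks genes by
resemblance to the *reference*, so tail-based "high-expression" sets are
only meaningful when the reference's preference direction matches the true
translational preference of the organism. Self-referenced weights recover a
planted high-expression tier only when the genome's pooled usage leans the
same way as the tier; an external reference with no homology to the
organism (e.g. yeast weights on an unrelated synthetic genome) may rank the
tier arbitrarily.

**ENc.** Wright's effective number of codons. Per observed family with
total n > 1, the codon homozygosity is F = (n·Σp_i² − 1)/(n − 1); with
F̄_k the mean F over families of degeneracy k,

    ENc = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6.

Families with n ≤ 1 or F = 0 are dropped from their class mean. If the
threefold class (Ile only) is unmeasurable, 1/F̄3 is estimated as the
9:5-weighted mean of 1/F̄2 and 1/F̄4 — a variant of Wright's suggestion to
interpolate the missing class, weighted by class sizes. If the two-, four-
or sixfold class is unmeasurable the index is undefined. Finite samples can
push the raw sum outside the theoretical range, so the reported value is
clipped to [20, 61]; the cap is why unbiased genes read exactly 61. The
expected value under composition alone is ENc* = 2 + s + 29/(s² + (1−s)²)
at GC3s = s (spot value 60.5 at s = 0.5); genes far below the curve are
shaped by more than composition.

## Genome-level inference

**Expression tails and optimal codons.** High- and low-expression proxy
sets are the upper and lower 5% of CAI (⌈0.05·N⌉ genes each, ties broken by
gene id for reproducibility). For each codon of a degenerate family, a 2×2
table — this codon vs the rest of its family, high pool vs low pool — is
tested with Pearson's chi-squared, no continuity correction, no
multiple-testing adjustment (raw 0.05/0.01 thresholds are the convention
for this analysis; an FDR variant would be a trivial extension but changes
the published semantics). The codon-vs-rest-of-family construction is used
because it is the only 2×2 reduction under which "frequency significantly
higher" aligns with RSCU; a whole-family k×2 variant is available via
`construction="family"`. A codon is *optimal* when p < 0.05 **and** its
family-conditional frequency is higher in the high pool ("\*" below 0.01,
"@" otherwise); *preferred* when genome RSCU > 1; *rare* when genome
RSCU < 0.1. Summaries count each class by third base (A/U vs G/C).

**Neutrality plot.** OLS of P12 on P3 over complete pairs, with Spearman's
ρ for the association. Slope ≈ 1 is compatible with undirected mutation
pressure acting equally on all positions; slope ≈ 0 indicates directional
pressure or selective constraint on positions 1–2. The slope × 100 is
reported as "relative neutrality (%)".

**Correlations and group tests.** Spearman ρ with two-sided p for every
pair among {GC_cds, P1, P2, P12, P3, ENc}, pairwise-complete. Across-genome
contrasts use one-way ANOVA on per-gene CAI and ENc pooled by species (the
magnitude of published F statistics implies per-gene, not per-genome-mean,
observations) and Welch's t between a designated species group and the
rest (variances across genomes of very different composition cannot be
assumed equal).

**Clustering.** Genomes are clustered on their pooled RSCU vectors over the
59 informative codons: Euclidean distance, average linkage, species
processed in name order so ties resolve deterministically; output as a
dendrogram (Newick with branch heights).

## Correspondence analysis

CA is run on the genes × 59 informative codons RSCU matrix, as stated for
this analysis tradition, not on raw counts (a count-based CA weights long
genes more; the RSCU variant weights genes by usage profile). Cells of
unobserved families are imputed with the family-neutral value 1.0 and
tallied. The matrix is scaled to proportions; with row masses r and column
masses c the standardized residuals S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2} are
decomposed by SVD; coordinates are reported in principal coordinates and
axis k explains σ_k²/Σσ² of the inertia. Because RSCU values are
constrained to sum to the family size within each of the 18 families, at
most 59 − 18 = 41 axes carry inertia (verified numerically to 1e−10). Four
axes are retained by default. SVD axis signs are arbitrary: each axis is
oriented so its largest-magnitude codon loading is positive, and axis 1 is
re-oriented, when composition data are present, to correlate non-negatively
with GC3s — pure relabelling that makes outputs reproducible across BLAS
implementations.

Exact axis-inertia percentages from other CA implementations (e.g.
CodonW's internal COA) may differ by small amounts because row-weighting
conventions for RSCU input are not fully standardized; agreement should be
treated as approximate.

## Synthetic-data generator

The generator produces seeded, reproducible CDS sets with the statistical
structure the analyses assume, so every stage is testable against planted
truth without downloads.

*What it emulates.* Gene counts and lengths at the scale of small parasite
genomes (default 2,000 genes, lognormal codon counts with mean 330 ≈ 1 kb,
minimum 300 bp); genome-wide within-family codon preferences (one Dirichlet
draw per genome, concentration 20, optionally tilted towards A/U- or
G/C-ending codons, default A/U at odds 1.5 with genome GC3 target 0.35 —
the leanings of an AT-rich reduced genome); a per-gene third-position GC
drift (uniform ±0.15); an optional mutational-pressure coupling m that
shifts P12 together with P3; and a 5% high-expression tier drawn from a
4:1 A/U-favouring codon distribution. Genes always start ATG, end with a
single stop, and contain no internal stops, so generated genomes pass the
CDS filter unchanged.

*Slope coupling.* A latent drift δ ~ U(−w, w) sets each gene's P3 target.
The same δ shifts the gene's P12 target by c·δ with

    c = m · (Var(δ) + Var(e3) + Var(tier)) / Var(δ),

where Var(e3) is the binomial sampling variance of the realised P3
estimate (estimated from the drawn gene lengths and the fraction of codons
in the P3 universe) and Var(tier) the variance contributed by the tier
genes' systematic third-base offset. The inflation compensates exactly the
regression attenuation caused by P3-variance the drift does not explain,
so the expected OLS slope of P12 on P3 equals m. Recovery is verified at
2,000 genes for m ∈ {0, 0.2, 0.4} within ±0.05 (observed errors ≤ 0.01).

Both composition targets are met by numerically inverting the realised
composition maps on a grid: third-base GC as a function of the
within-family re-weighting parameter s (E[GC3 | family, s] = s under
uniform preferences by construction), and P12 as a function of an
exponential tilt β on amino-acid frequencies weighted by each family's
GC content at positions 1–2. An infeasible genome-wide GC3 target raises
before any gene is generated; per-gene drifted targets are clipped to the
realisable range.

*What it does not emulate.* Nucleotide-level mutation processes (generation
is codon-wise — the analyses only observe codons), amino-acid composition
differences driven by protein function, gene structure (introns, UTRs),
lineage structure along a tree, and expression-correlated gene length.
Passing tests on this generator therefore validate the statistical
machinery and its calibration, not any claim about real genomes' biology.

`generate_biased_pair` produces two genomes identical except for opposite
third-base preference: the strength acts as an odds shift on the GC3
composition target and as within-family preference odds, in opposite
directions, with a shared seed so strength 1 yields byte-identical genomes.
This emulates the contrast between a G/C-leaning genome pair and an
A/U-leaning background for clustering and summary tests.

## Numerical choices and degenerate inputs

* All tolerances/thresholds (0.05/0.01 significance, RSCU > 1 preferred,
  RSCU < 0.1 rare, 5% tails, 300 bp) are configuration with these defaults.
* Undefined values are NaN throughout; JSON manifests render them as null.
* Chi-squared tables with a zero row or column are marked untestable.
* CA on a rank-0 residual (all gene profiles proportional) returns zero
  coordinates and zero inertia rather than failing.
* CAI weights of exactly zero (possible in external tables for codons the
  reference never uses) are floored at 0.01 inside the geometric mean so a
  single codon cannot send CAI to zero.
* Analysis problem sizes: the test-suite genomes use 60–2,000 genes and the
  shipped cohort drivers 600 genes per genome — large enough for stable
  5% tails and slope fits at the documented tolerances.

## Known limitations

* The ENc missing-class substitution (threefold only) matches short-gene
  behaviour of the classic implementation in spirit, but the exact
  interpolation used by any given CodonW build is not published; per-gene
  ENc on genes lacking Ile may differ slightly between tools.
* The chi-squared construction for optimal codons is stated ambiguously in
  much of the literature; both supported constructions are documented and
  selectable, and they can classify borderline codons differently.
* PR2 universes differ between authors (all degenerate third positions vs
  fourfold families only); both are provided, default `p3`.
* CAI depends entirely on the reference; see the caveat under *Indices*.
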