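# Methods

`cistrans` implements the statistical pipeline used to connect fixed genetic
variation to gene-expression divergence between two recently diverged
populations (called A and B throughout; in the motivating system these are a
molluscivore and a scale-eating pupfish): genome-wide divergence scans,
variant–gene association, differential expression, allele-specific
expression (ASE) in F1 hybrids, cis/trans regulatory-mechanism
classification, inheritance-mode classification, and allele-dependent
motif scanning. Everything is exercised end to end on synthetic data with
planted ground truth.

## Divergence scan

Per-site differentiation uses the Weir & Cockerham (1984) estimator. For
two populations with sample sizes n1, n2 (called diploid genotypes),
alt-allele frequencies p1, p2 and observed heterozygote frequencies h1, h2,
the among-population (a), among-individual (b) and within-individual (c)
variance components are computed exactly as in the original paper and
θ̂ = a/(a+b+c). This matches the vcftools `--weir-fst-pop` convention:
negative estimates are reported as-is, a site with a+b+c = 0 is flagged
undefined, and windowed Fst is the ratio of sums Σa/Σ(a+b+c) over analyzed
sites. A population with fewer than two called genotypes makes the site
undefined, not fatal.

Fixation is decided from genotypes, never from θ̂ rounding: a site is fixed
iff every called genotype is homozygous and the two populations carry
opposite alleles. On fully called sites θ̂ = 1 exactly when this rule
holds (property-tested over random configurations).

Windowed Dxy is the mean over analyzed variant sites of
p1(1−p2) + p2(1−p1). The denominator is the number of analyzed variant
sites (the variant-only VCF convention), not window length; absolute Dxy
thresholds are therefore convention-dependent, so the published outlier
threshold (0.0083, a genome-wide 90th percentile) is config-exposed and the
realized 90th percentile can be recomputed from the window table. Windows
tile each scaffold from coordinate 1 (non-overlapping by default; a step
smaller than the window gives sliding windows). Whether the original
analysis used tiled or sliding windows, or included invariant sites in the
denominator, is not stated in the source; these defaults are our choices.

Structural variants arrive as per-comparison call sets (emulating one
caller output file per individual-vs-population comparison). Two records
describe the same variant iff they have the same type and scaffold, both
breakpoints within 50 bp, and reciprocal overlap ≥ 0.8 (both tolerances
config-exposed). A matched variant is *fixed* iff a record is present in
every call set and, in every record, all individuals of one population
carry the alternate allele while all of the other are homozygous reference
— the "shared across all files" rule. Output is invariant to call-set
ordering.

## Variant–gene association

A variant links to a gene iff its full span intersects the gene span
(first-exon start to last-exon end) padded by the window on both sides,
with inclusive bounds: "within 10 kb" means ≤ 10,000 bp. Distances are
signed genomic distances (negative upstream of the first exon, positive
downstream of the last, 0 on overlap); strand is recorded separately and
never folded into the sign. The defaults are 10 kb (near) and 20 kb — the
distance at which linkage disequilibrium decays in the motivating system.
Context labels: exonic (intersects an exon; fully contained exons are
reported, which is how an exon-spanning deletion is recognized), intronic
(inside the span, no exon), proximal_noncoding (within the near window),
else intergenic. Distal regulatory action beyond these windows is out of
scope by construction.

## Differential expression

A deliberately minimal negative-binomial Wald test stands in for a full DE
framework: median-of-ratios size factors (geometric-mean reference over
genes with no zero count; lower-median convention for ties), a pooled
method-of-moments dispersion per gene
α̂ = max((s² − μ̄)/μ̄², 10⁻⁸) from group-mean-centered normalized counts,
log2 fold change log2((μ̂2+ε)/(μ̂1+ε)) with zero-guard
ε = min(0.5, 0.5·smallest positive normalized group mean) (override:
`lfc_epsilon`), a Wald standard error from the NB variance μ + α̂μ² of the
group means, two-sided normal p-values and Benjamini–Hochberg control at
FDR 0.01. There is no dispersion shrinkage, no fold-change shrinkage and no
independent filtering, so we claim calibration properties (null rejection
rate, power at planted effects), not numeric equality with any particular
DE package. Multifactor designs (batch covariates) are out of scope; the
synthetic generator does not generate batches.

Size factors are defined only up to the reference, so the scale-equivariance
property holds for factor *ratios*: multiplying one sample's column by c
multiplies its factor by c relative to every other sample and leaves fold
changes unchanged.

## Allele-specific expression

Informative sites are SNPs at which the two parents of a cross are
homozygous for different alleles and the F1 is heterozygous; an F1 that is
homozygous at such a site is excluded and counted as a Mendelian
inconsistency. Read counts at informative sites (the upstream counter's
depth filter, ≥ 20, applies at load; mapping/base-quality filters are
upstream-tool concerns) are aggregated per gene and hybrid sample.

The gene-level test is a 1-sample, majority-vote pseudo-phasing test with a
simulated null: per SNV the "major" allele is the parental allele with the
higher count (ties to maternal), the gene's major-allele frequency (MAF)
is Σ major / Σ total over SNVs with ≥ 10× coverage, and the null
distribution is obtained by redrawing each SNV's maternal count from
beta-binomial(total, 0.5, ρ) and re-applying the same pseudo-phasing.
The empirical p-value (1 + #{sim ≥ obs})/(1 + n_sims) can never be zero.
ρ defaults to 0 (binomial null) and n_sims to 1,000,000, matching the
published setting; the test suite and the bundled experiment drivers run at
10,000 simulations, which bounds attainable p-values at 1/10,001 — ample
for an α = 0.05 decision. Because observation and null undergo the same
pseudo-phasing, the test is nominal-to-conservative; the measured
false-positive rate at α = 0.05 over 2,000 balanced genes stays ≤ 0.06.
Isoform-level ASE and haplotype-resolved phasing are not modeled.

## Regulatory-mechanism classification

Per gene, cross and stage (requiring ≥ 2 informative SNVs at ≥ 10×):

* H = (Σ maternal + 0.5)/(Σ paternal + 0.5), summed over SNVs and hybrid
  replicates;
* P = (mean normalized purebred count of the maternal population + 0.5) /
  (same, paternal population + 0.5);
* T: two-sided Fisher's exact test on
  [[hybrid maternal, hybrid paternal], [parental maternal, parental
  paternal]] against the null that the parental expression ratio equals
  the hybrid allelic ratio. A zero margin gives p = 1 by convention.

For the parental row of the 2×2 table we use the **rounded mean** normalized
count per population (config `fisher_parent_counts`, "sum" available).
Summing normalized counts across n replicates would make the implied
multinomial variance of the parental ratio n-fold smaller than its actual
replicate-level sampling variance, making the trans test strongly
anticonservative and stripping genuinely cis-regulated genes of their
classification; the per-sample-scale mean keeps the implied variance at or
above the replicate-level variance, giving a conservative-to-nominal test.

Categories (each testable gene receives exactly one):

| category | ASE | DE | T | signs |
|---|---|---|---|---|
| cis | in all hybrids | yes | no | — |
| trans | none | yes | yes | — |
| cis×trans (compensatory) | in all hybrids | no | yes | sign(log2 H) ≠ sign(log2 P) |
| cis+trans (reinforcing) | in all hybrids | no | yes | sign(log2 H) = sign(log2 P) |
| conserved | none | no | — | — |
| ambiguous | anything else | | | |

"Shows ASE" means significant in every hybrid of the cross. "No ASE"
defaults to the complement of that single gene-level flag
(`ase_none_rule="not_all"`; the stricter "no hybrid individually
significant" is available as `"no_hybrid"`). With k hybrids and a nominal
per-hybrid test, the strict rule caps trans sensitivity at 0.95^k (85.7%
at k = 3) for purely mechanical reasons, so the complement reading is the
default. A |log2 ratio| within ±0.05 of zero counts as sign zero and can
satisfy neither sign clause (such genes fall to ambiguous), which prevents
sign flips from sampling noise.

Note that the compensatory/reinforcing rules as specified require *no*
parental DE together with a nonzero sign of log2 P — with exactly
compensating planted effects log2 P is centred on zero, so such genes
mostly classify ambiguous; with strong reinforcing effects DE is almost
always significant, again giving ambiguous. The classifier implements the
rules as stated; recovery guarantees are therefore claimed for cis, trans
and conserved regimes only.

Inheritance modes come from the four pairwise DE contrasts (A vs B, A vs
hybrid, B vs hybrid, pooled parents vs hybrid), evaluated in precedence
order transgressive > dominant > additive: overdominant/underdominant when
the hybrid differs significantly from both parents in the same direction;
dominant (toward the parent it matches) when it differs from exactly one;
additive when the parents differ and the hybrid mean lies strictly between
the parental means; otherwise undetermined. The precedence order and the
strict-betweenness reading of "intermediate" are our choices; the source
does not state them.

## Motif scanning

PWMs are JASPAR-format count matrices column-normalized to probabilities.
Windows are scored with Σ log(p/bg) against a uniform background
(config-exposed); probabilities are floored with ε = 10⁻⁴ before the log so
minimum/maximum scores stay finite, and the score is min–max rescaled to a
relative profile score in [0, 1]. The consensus window still scores exactly
1 and the per-column-minimum window exactly 0. Hits are windows on either
strand with relative score ≥ 0.95. For a variant, the reference- and
alternate-allele sequences (variant ± 20 bp) are scanned against every PWM;
a motif is *lost_in_alt* / *gained_in_alt* when a hit spans the variant
region in one allele but not the other (threshold crossing, not mere score
change). For deletions the alternate allele removes the deleted span and a
hit must straddle the deletion junction to count. No motif database is
bundled; the analysis driver builds a labelled synthetic PFM panel to
demonstrate the calls.

## Synthetic data generator

The generator emulates the study conditions, not any particular dataset:

* **Genotype panel** — 8 individuals per population; 157 fixed SNPs and
  87 deletions fixed in population B by default (the published counts, used
  as fixture sizing), 300 highly differentiated SNPs (frequencies
  0.08/0.92), 2,000 shared background SNPs. Differentiated and background
  sites are redrawn if they come out accidentally fixed, so planted counts
  are exact. One fixed deletion (91 bp) is planted ending 7,384 bp upstream
  of one cis-regime gene and one fixed SNP 1,808 bp downstream of another —
  the two "top candidate" configurations — and up to ten trans-regime genes
  get a fixed SNP 2–4 kb upstream; everything else lives in gene-free
  desert scaffolds. Guards on gene spacing and neighbour regimes ensure each
  planted candidate variant reaches exactly one cis gene within 10 kb.
* **Expression** — for a gene with baseline μ (log-uniform in 50–500) and
  planted cis/trans effects c, t (log2, B relative to A): purebred A mean
  μ, purebred B mean μ·2^(c+t); hybrid alleles share a midparent trans
  environment, A-allele mean (μ/2)·2^(t/2), B-allele mean (μ/2)·2^c·2^(t/2).
  Counts are negative binomial with dispersion 0.01 and per-sample
  library factors log-uniform in (0.7, 1.4) to exercise normalization.
  Trans dominance is deliberately out of generative scope: the midparent
  model is what makes balanced hybrid alleles the defining trans signature.
* **Allelic counts** — per SNV (2–6 per gene, placed in exons), coverage
  Poisson(100) and maternal count beta-binomial with
  p_maternal = 2^c/(1+2^c) for a B mother, ρ = 0 by default.
* **Crosses** — cross 1 has a B mother, cross 2 an A mother, so the
  maternal/paternal symmetry of H and P is exercised. Purebred sample sizes
  per stage default to the published design (2 dpf: 6 vs 6; 8 dpf: 8 vs 10)
  with 3 hybrids per cross.
* **Effect sizes** — |c| = |t| = 1.5 log2 with random sign; reinforcing
  genes get same-sign, compensatory genes opposite-sign effects of equal
  magnitude.

Dispersion, coverage, library-size range and SNV counts are not reported
quantities of the motivating system; they are modelling choices picked once
for realistic low-noise embryo RNA-seq and documented here. All randomness
flows from a single seed; an identical seed reproduces the serialized
dataset byte for byte.

What the generator does **not** emulate: read-level noise and mapping bias
(the concern WASP addresses upstream), linkage disequilibrium beyond the
planted variant–gene proximity, batch structure, isoform usage, and
dominance in trans. Passing recovery tests therefore demonstrates the
statistical machinery is correct and calibrated under the stated model —
not that real data meet these assumptions.

## Validation experiments

`cistrans.validation` recomputes key quantities through independent routes:
Fisher's exact p against exact big-integer enumeration (≤ 10⁻¹⁰ over
random tables with total ≤ 500), BH against the step-up definition, the
PWM scanner against window-by-window rescoring, variant–gene links against
all-pairs intersection, θ̂ = 1 against the genotype-level fixation rule,
ASE and DE false-positive rates under known nulls, DE power at a planted
2-fold change, planted-regime recovery at the reference conditions
(2,000 genes, 90/4/2/2/2% regime mix) and the paper-shaped end-to-end
fixture (157 + 87 fixed variants among 80,012 SVs, exactly two planted
cis candidates). `scripts/acceptance.py` runs all of these from scratch
and writes the numbers as JSON; the problem sizes above are the package's
reference experiment sizes.

## Known limitations

* The NB Wald stage is a stand-in: per-gene method-of-moments dispersion is
  noisy at small n, and p-values lean on a normal approximation with
  ~10 effective degrees of freedom. The null-calibration experiment bounds
  the practical consequence.
* The Fisher trans test treats the parental mean ratio as one multinomial
  observation; biological overdispersion beyond the per-sample scale makes
  it anticonservative in principle. With the mean-based table and the
  generator's dispersion this is measured, not assumed, via the cis
  recovery rate.
* Compensatory/reinforcing categories are structurally hard to satisfy as
  specified (see above) and carry no recovery guarantee.
* The motif scanner makes sequence-level claims only; a hit is a predicted
  binding site with high sensitivity and very low selectivity.
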