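# Methods

`meqtlseq` implements a complete methylation-QTL (meQTL) mapping pipeline
for enrichment-sequencing data (MBD-seq), together with a synthetic-data
generator that plants known truth so that every stage can be validated
end to end. This note records the models, the defaults and why they were
chosen, and what the synthetic validation does and does not establish.

## The methylation measure

MBD-seq captures the methylated genomic fraction; sequencing the captured
fragments yields relative methylation as fragment coverage. Because capture
depends on any methylated CpG in the *fragment* — not just the sequenced
50 bp read — the locus-specific measure is the **expected number of
fragments covering each CpG**:

    measure(CpG) = Σ_fragments  P(fragment covers the CpG)

A read whose sequenced part covers the CpG contributes a full unit. A read
whose 5' start lies d ≥ read_len bp before the CpG (in the fragment's
3' direction; − strand mirrored) contributes the survival probability
S(d) = P(fragment length > d).

**S(d) estimation.** S is estimated from the pile-up of read starts around
*isolated* CpGs (no neighbouring CpG within the isolation gap, default
500 bp): every captured fragment near such a CpG must have covered it, so
the offset histogram of read starts is proportional to S(d), plus a flat
floor from non-specific capture. The floor is estimated from *wrong-side*
reads — 5' starts past the CpG, whose implied fragments cannot cover it —
using only small offsets (d < read_len), where spillover from the next CpG
cluster cannot reach. After floor subtraction the histogram is normalized
so the certain region (d < read_len) averages to one, constrained
non-increasing by isotonic regression, and clipped to [0, 1].

**No CpG-density normalization.** Coverage at a CpG also depends on the
local density of methylated CpGs. The scan correlates genotype with
*quantile-normalized* values, which are invariant to per-site monotone
transformations, so a density normalization would not change any
association statistic and is deliberately omitted. (The invariance is to
per-site or global monotone transforms — not to subject-specific rescaling,
which reranks subjects within a site; the property suite tests the form
that actually holds.)

**Site reduction.** Adjacent CpG columns are collapsed left-to-right: a CpG
joins the open block iff its Pearson correlation with the block's running
mean is ≥ `r_min` (default 0.90) and the gap to the previous member is
≤ `max_gap` (default 500 bp). These two defaults are exposed in the config;
they are method parameters with no single canonical value. The site value
is the arithmetic mean of its member columns. Sites whose across-subject
mean does not *strictly* exceed the 97.5th percentile (linear-interpolation
definition) of background coverage — measured at loci ≥ 400 bp from any
CpG, subsampled to `n_background` — are flagged unmethylated. The
percentile is taken over per-locus subject means by default; a pooled
per-subject variant is config-selectable. Sites in pericentromeric
(centromere ± 5 Mb), subtelomeric (1 Mb from either end) or
mappability-masked intervals are excluded; the mappability mask is consumed
as an input, never computed.

## The association scan

Per site, values are transformed by the inverse quantile normal
Φ⁻¹((rank − ½)/n) with average ranks for ties; the (rank − ½)/n offset is
one of several common conventions and is fixed here. Covariates are sex,
batch (one-hot), laboratory assay variables, four ancestry (MDS)
dimensions, and the top `n_pcs` = 7 principal components of the site
matrix, which absorb cell-type-mixture confounding. A per-PC GWAS
(`pc_genotype_check`) verifies the PCs are not under genetic control,
reporting genomic inflation λ_GC = median(χ²)/0.4549 and Bonferroni-adjusted
minimum p.

Both dosages and transformed methylation are residualized on the covariates
(with intercept, via QR); the test statistic for each SNP × site pair is

    t = r · sqrt(df / (1 − r²)),   df = n − n_covariates − 2,

where r is the correlation of the residuals. This is algebraically the OLS
t for the genotype term with all covariates in the model (the suite checks
agreement to |Δt| < 1e-8) but costs one matrix product per chromosome pair.
p-values use the t distribution; with hundreds of subjects the normal
approximation would be indistinguishable. Only additive dosage coding is
supported.

Pairs are stratified by distance from the SNP to the nearest site edge
(0 inside the site): **local** (same chromosome, ≤ 1 Mb, inclusive),
**distant same-chromosome** (> 1 Mb), **cross-chromosome**. Benjamini–
Hochberg runs within each stratum with that stratum's own test count m:
the largest k with P(k) ≤ (k/m)α, α = 0.01. At scale the scan materializes
only pairs with p ≤ `p_keep` (default 1e-3) while keeping exact per-stratum
m; this is lossless for BH as long as the realized threshold lies below
`p_keep`, which holds by orders of magnitude in every configuration here.
Replication is summarized by π1 = 1 − π̂0 with
π̂0 = #{p > λ}/((1 − λ)m), λ = 0.5.

## Enrichment

CpG-SNPs are called from sequence context: each allele is substituted into
the ±1 bp context and flagged when a CpG dinucleotide exists under exactly
one allele. Overlap conventions: interval intersection; point-in-site
(half-open); and point within site ± 250 bp — 250 bp being the approximate
maximum fragment length, i.e. the farthest a polymorphic CpG can sit from a
site and still perturb its measure.

Each (annotation × meQTL set) pair is tested twice. Fisher's exact test
(two-sided, cross-product odds ratio a·d/b·c) assumes independent sites and
is anticonservative under the serial correlation of neighbouring sites. The
**circular-shift permutation** rotates the annotation vector along the
genome ordering (chromosomes concatenated in name-sorted order) by every
offset B that moves it at least 1% of the sites in both directions,
optionally evenly subsampled (`subsample_frac`, mirroring a
one-in-ten-offsets second phase); all offsets are evaluated at once via FFT
cross-correlation. A normal distribution is fitted to the rotated overlap
counts and the observed overlap is reported as z, with a two-sided normal
p — the fitted-normal convention rather than an empirical rank. Direction
is carried by the odds ratio. BH q-values are computed across the whole
batch of permutation p-values; q < 0.01 marks calls. The calibration
contrast (Fisher's size inflates several-fold under blocky flags while the
shift test stays within 1.5× nominal) is verified by simulation in the
acceptance suite — it is the reason the second layer exists.

Stratified design: all meQTLs vs the full site universe; CpG-SNP meQTLs vs
all sites with a CpG-SNP (± 250 bp); non-CpG-SNP meQTLs vs all sites
without one. A generic exclusion BED (copy-number variants, duplications,
pseudogenes in the real data) can pre-filter the universe.

## The synthetic-data generator

The generator is first-class, tested code. Its defaults are the study
conditions of the validation suite; none of them is tuned per run.

**Reference.** Chromosome sequences are random ACGT with CG dinucleotides
planted at a configured density (default 0.02/bp — enrichment assays
oversample CpG-dense territory); all accidental CGs are destroyed, so the
CpG map is exact by construction. A small fraction (0.2%) of CpGs is placed
as deliberately isolated singletons with 1 kb of enforced CpG-free
clearance on each side — the CpG-desert loci that both the fragment-size
estimator and the background filter rely on (the clearance exceeds the
400 bp background gap plus measurement reach). Chromatin states use the
18-label alphabet (TssA … Quies) in contiguous exponential blocks (mean
10 kb) with quiescent chromatin dominant, one independent segmentation per
cell type; every base carries exactly one label. A GWAS-catalog-like point
track is scattered at 50 points/Mb.

**Genotypes.** A founder-haplotype mosaic: per chromosome, `n_founders`
(12) founder haplotypes carry each SNP's alternate allele on a carrier
subset sized to a Uniform(maf_range) target; each subject haplotype copies
founders with switch probability 1 − exp(−rate·d/block_len) between
adjacent SNPs. This yields r² ≈ 1 at zero recombination (two founders),
monotone LD decay with distance, and realistic MAF spectra — sufficient for
the LD-tagging phenomena of interest without a coalescent simulator. 30%
of SNPs are placed on CpGs with the alternate allele abolishing the CpG;
the `is_cpg_snp` flag is re-derived from sequence context rather than
trusted from construction.

**Methylation truth.** Methylation is piecewise-constant over *regions* of
up to 5 CpGs within 300 bp — matching the fragment-scale resolution of the
assay. Baselines are state-dependent Beta draws: heavily methylated in
quiescent/heterochromatin (mean ≈ 0.8), low at promoters/enhancers,
intermediate elsewhere. Two planted mechanisms:

* `cpg_snp` — the region's methylated-fragment rate is
  baseline × (CpG-bearing allele copies)/2: the substrate itself is
  polymorphic. Planted in quiescent-state regions containing a common
  CpG-SNP within ± 250 bp.
* `binding` — rate is clip(baseline + β(dosage − 1), 0, 1) with per-allele
  shift |β| ∈ [0.15, 0.30] and random sign, the chromatin-factor-binding
  mechanism; planted in TssA/EnhA1 regions (allocated round-robin) with a
  mid-range baseline (0.25–0.55), where a contested methylation level is
  biologically plausible and the shift has room in both directions.

Causal SNPs are drawn from variants with MAF ≥ 0.2 and planted only in the
assayable genome (outside the pericentromeric/subtelomeric exclusions), so
"planted effect" means an effect of at least ~1 SD of site-level noise that
the pipeline has a chance to see — power then measures the scan, not the
mask. No empirical effect-size distribution is available for this assay,
so `effect_size_dist` is a config hook and the default is a deliberate
choice, not an estimate.

**Fragments.** Each subject's expected yield per region is proportional to
methylation × CpG count, scaled to a Poisson total around `depth`
(default 400,000 fragments/subject — chosen to give clearly detectable
planted effects at n = 100; it corresponds to a much higher per-base depth
than a genome-wide study because the simulated genome is 4 Mb). Fragment
lengths follow a discretized gamma truncated to [50, 500] bp with the
scale solved so the truncated median is exactly 125 bp. A fragment anchored
on a chosen CpG draws its length **length-biased** (pmf ∝ l·f(l)) and its
offset uniformly over covering placements: under uniform shearing a longer
fragment is proportionally more likely to cover a fixed point, and only
with the length-biased draw does the read-start histogram at isolated CpGs
reproduce S(d). Reads are single-end 50 bp from the fragment's 5' end;
− strand fragments extend toward lower coordinates. A `background_frac`
(5%) of depth is emitted uniformly over the genome regardless of
methylation — the non-specific capture floor that gives the background
filter a non-trivial threshold.

**Confounding.** A Dirichlet cell-type mixture (one dominant component)
loads onto a random 30% of regions through Gaussian loadings scaled by
`confounding_strength`; batch shifts hit 20% of regions; iid Gaussian noise
(SD 0.05) is added; all on the methylation scale, clipped to [0, 1]. This
low-rank structure is exactly what PCA removal assumes — by design, since
the point of the simulation is to validate that machinery, not to defeat it.

## What the synthetic validation shows — and what it cannot

The suite demonstrates, at 100 subjects × 2 × 2 Mb × 50 planted effects:
≥ 80% power at stratified FDR 1% with realized site-level FDP ≈ 1%;
recovery of the expected chromatin-state pattern (CpG-SNP meQTLs enriched
in quiescent chromatin with permutation q < 0.01 and depleted — odds ratio
below one — in active states; binding meQTLs the reverse); survival
recovery Ŝ(125) = 0.5 ± 0.05; and near-total replication (π1 ≈ 1) in a
second simulated cohort. With only 25 foreground regions per mechanism
class, a *depletion* cannot reach q < 0.01 — the hypergeometric floor for
an expected overlap of 1–3 is p ≳ 0.05 however extreme the observation —
so depletions are validated by sign, enrichments by sign and q.

The generator does not emulate: fine-scale recombination maps or realistic
human LD; bisulfite-resolution methylation or partial-methylation
chemistry; read-level error, mapping ambiguity (the mappability mask is an
input), or duplicate structure; sex chromosomes; disease status. Passing
tests therefore validate the *pipeline's statistics* under a faithful
generative caricature of MBD-seq, not the biology of any real cohort.

## Numerical and implementation choices

* Coordinates are 0-based half-open everywhere; BED on disk; chromosomes in
  name-sorted order define all concatenated indices, including the circular
  permutation ordering (recorded here since no canonical order exists).
* The masks scale with the genome: the 5 Mb / 1 Mb defaults apply at human
  scale, and validation runs on 2 Mb chromosomes use 50 kb / 20 kb — the
  same mechanism at the simulation's scale.
* Degenerate inputs fail loudly: constant site vectors (rank transform),
  constant annotation flags (σ = 0 permutation null), collinear covariates
  (named columns), empty MAF ranges, shortfalls of eligible regions.
* A zero-variance CpG column becomes a singleton site rather than poisoning
  a correlation block.
* All randomness flows from one top-level seed fanned out per stage with
  `SeedSequence.spawn`; the run manifest records the config hash and stage
  seeds, and reruns are byte-identical.
* Problem sizes in the validation suite (replicate counts, fragment counts,
  the 2 × 2 Mb genome) were sized so each check's own Monte-Carlo error is
  small against the property it asserts.
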