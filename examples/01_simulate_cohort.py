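"""Simulate a small methylome-plus-genotype cohort with planted meQTLs.

Builds a 2 x 800 kb reference, 60 subjects, and plants ten meQTLs of each
mechanism; prints what was planted and the realized fragment yield.
"""
import numpy as np

from meqtlseq import simulate as sim

ref = sim.simulate_reference({"chr1": 800_000, "chr2": 800_000},
                             cpg_density=0.02, seed=1)
print(f"reference: {len(ref.chrom_names)} chromosomes, "
      f"{sum(p.size for p in ref.cpg_positions.values()):,} CpGs")

geno = sim.simulate_genotypes(ref, n_subjects=60, n_snps=800, seed=2)
print(f"genotypes: {geno.n_snps} SNPs, "
      f"{geno.snps['is_cpg_snp'].mean():.0%} CpG-SNPs, "
      f"MAF {geno.snps['maf'].min():.2f}-{geno.snps['maf'].max():.2f}")

covt = sim.simulate_covariates(60, confounding_strength=1.0, seed=3)
truth = sim.plant_meqtls(ref, geno, n_cpg_snp_effects=10,
                         n_binding_effects=10, seed=4)
planted = truth[truth["is_meqtl"]]
print(f"planted {len(planted)} meQTLs:")
print(planted.groupby(["mechanism", "state"], observed=True)
      .size().to_string())

frags = sim.simulate_fragments(ref, truth, geno, covt, depth=100_000, seed=5)
per_subject = np.bincount(frags.subject, minlength=60)
print(f"fragments: {len(frags):,} total, "
      f"{per_subject.mean():,.0f} +- {per_subject.std():.0f} per subject, "
      f"median length {int(np.median(frags.length))} bp")
# The planted effect sizes are per-allele shifts in the expected
# methylated-fragment rate; a cpg_snp effect of -0.4 means each alternate
# allele removes ~40% of the region's capture yield.
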