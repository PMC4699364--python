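"""From read starts to methylation sites.

Estimates the fragment-size survival curve from isolated CpGs, computes the
expected-coverage methylation measure at every CpG, collapses correlated
neighbours into sites and applies the background / region filters.
"""
import numpy as np

from meqtlseq import coverage as cov
from meqtlseq import simulate as sim

ref = sim.simulate_reference({"chr1": 800_000}, cpg_density=0.02, seed=11)
geno = sim.simulate_genotypes(ref, n_subjects=40, n_snps=300, seed=12)
covt = sim.simulate_covariates(40, seed=13)
truth = sim.plant_meqtls(ref, geno, 5, 0, seed=14)
frags = sim.simulate_fragments(ref, truth, geno, covt, depth=120_000, seed=15)
reads = frags.to_reads()

iso = {c: cov.find_isolated_cpgs(ref.cpg_positions[c], 500)
       for c in ref.chrom_names}
model = cov.estimate_fragment_size_distribution(reads, iso, read_len=50,
                                                d_max=500)
print(f"fragment survival: S(50)={model.survival[50]:.2f} "
      f"S(125)={model.survival[125]:.2f} S(250)={model.survival[250]:.2f}")
# S(125) ~ 0.5 recovers the library's 125 bp median shear size.

matrix = cov.compute_methylation_measure(reads, ref.cpg_positions, model,
                                         ref.lengths)
print(f"coverage matrix: {matrix.values.shape[0]} subjects x "
      f"{matrix.n_cpgs:,} CpGs, mean measure "
      f"{matrix.values.mean():.2f} fragments")

sites, smat = cov.collapse_adjacent_cpgs(matrix, r_min=0.9, max_gap=500)
print(f"collapsed to {len(sites):,} sites "
      f"({sites['n_cpgs'].mean():.2f} CpGs, "
      f"{(sites['end'] - sites['start']).mean():.1f} bp on average)")

sites, thr = cov.background_filter(sites, smat, reads, model,
                                   ref.cpg_positions, ref.lengths,
                                   n_background=5_000, seed=16)
sites = cov.apply_region_masks(sites, ref.centromeres, ref.lengths,
                               peri=30_000, subtel=10_000)
keep = sites["passed_background_filter"] & ~sites["masked"]
print(f"background threshold {thr:.3f} (97.5th pct of non-CpG coverage); "
      f"{keep.sum():,}/{len(sites):,} sites pass all filters")
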