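"""Compare a region's MDS ordination against random length-matched regions.

An inversion region produces an IBS/MDS configuration dominated by the
haplotype classes; random control regions of identical length do not. The
Procrustes correlation (with a permutation test) quantifies how unlike
the inversion-region ordination each control region is.
"""

import admixscan as a

region = a.RegionInterval("1", 5_000_000, 10_000_000)
cfg = a.SimConfig(
    seed=6, cohort_size=100,
    chromosomes=(a.ChromSpec("1", 20_000_000, 20.0, 1000),
                 a.ChromSpec("2", 20_000_000, 20.0, 1000)),
    inversion=a.InversionSpec(region, (0.25, 0.5, 0.05), divergence=0.3),
)
panels, cohort, calls, truth = a.simulate_study(cfg)


def mds_of(reg):
    idx = cohort.snp_indices(reg)
    ibs = a.ibs_matrix(cohort.dosages()[:, idx].astype(float))
    return a.classical_mds(1.0 - ibs.values, k=2)


base = mds_of(region)
length = region.end_bp - region.start_bp
controls = a.sample_random_regions(cohort.snps, length, n=7,
                                   exclude=region, seed=42)

print("inversion region vs 7 random length-matched regions "
      f"({length / 1e6:.1f} Mb each), 10,000 permutations:")
for reg in controls:
    res = a.procrustes_protest(base.coords, mds_of(reg).coords,
                               n_perm=10_000, seed=7)
    print(f"  chr{reg.chrom}:{reg.start_bp}-{reg.end_bp}  "
          f"correlation {res.correlation:.3f}  p {res.p_value:.4g}")
print("low correlations say the inversion region's structure is not a "
      "generic feature of same-sized genomic windows")
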