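"""Genotype an inversion-like polymorphism by MDS + EM clustering.

Plants two deeply diverged haplotype classes (NI = non-inverted, I =
inverted, differing at 30% of in-region SNPs with recombination suppressed
between them), computes identity-by-state over the region, embeds
individuals by classical MDS, fits a three-component Gaussian mixture by
EM on axis 1, and compares the NI/NI, NI/I, I/I calls against the truth.
"""

import collections

import admixscan as a

region = a.RegionInterval("1", 5_000_000, 10_000_000)
cfg = a.SimConfig(
    seed=3, cohort_size=200,
    chromosomes=(a.ChromSpec("1", 20_000_000, 20.0, 1000),),
    inversion=a.InversionSpec(region, class_freqs=(0.25, 0.50, 0.05),
                              divergence=0.3),
)
panels, cohort, calls, truth = a.simulate_study(cfg)

idx = cohort.snp_indices(region)
ibs = a.ibs_matrix(cohort.dosages()[:, idx].astype(float))
emb = a.classical_mds(1.0 - ibs.values, k=2)
inv = a.em_inversion_genotypes(emb)

print(f"region: {idx.size} SNPs; EM converged={inv.converged} "
      f"after {inv.n_iter} iterations")
print("cluster means on MDS axis 1:", [f"{m:.3f}" for m in inv.means])
print("genotype calls:", dict(collections.Counter(inv.calls)))

accuracy = (inv.dosage == truth.inversion_genotypes("cohort")).mean()
print(f"agreement with simulated truth: {accuracy:.1%}")
print("three well-separated clusters along axis 1 are the two homozygote "
      "classes at the extremes and heterozygotes in between")
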