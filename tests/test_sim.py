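"""Synthetic-data generator: drift model, admixture process, planted signals."""

import numpy as np
import pytest
from scipy import stats

import admixscan as a

CHROM_50CM = (a.ChromSpec("1", 50_000_000, 50.0, 1000),)


def _freq_cfg(**kw):
    base = dict(seed=5, founders=None,
                chromosomes=(a.ChromSpec("1", 20_000_000, 20.0, 2000),))
    base.update(kw)
    return a.SimConfig(**base)


class TestReferencePanels:
    def test_determinism(self):
        cfg = a.SimConfig(seed=42)
        p1, t1 = a.simulate_reference_panels(cfg)
        p2, t2 = a.simulate_reference_panels(cfg)
        for k in p1:
            np.testing.assert_array_equal(p1[k].haplotypes, p2[k].haplotypes)
        np.testing.assert_array_equal(t1.pop_freqs, t2.pop_freqs)

    def test_zero_drift_shares_ancestral_frequency(self):
        cfg = _freq_cfg(drift=(0.0, 0.0, 0.0))
        _, truth = a.simulate_reference_panels(cfg)
        for i in range(3):
            np.testing.assert_array_equal(truth.pop_freqs[i], truth.ancestral_freq)

    def test_fst_recovers_drift_parameter(self):
        # frequency-level panels, F = 0.15, 2000 SNPs, 100 haplotypes per
        # pop; the genome-wide ratio-of-averages estimator recovers F
        from admixscan.selstats import hudson_fst_components

        cfg = _freq_cfg(drift=(0.15, 0.15, 0.15), panel_haplotypes=100)
        panels, _ = a.simulate_reference_panels(cfg)
        p1 = panels["EUR"].haplotypes.mean(axis=0)
        p2 = panels["AFR"].haplotypes.mean(axis=0)
        num, den = hudson_fst_components(p1, 100, p2, 100)
        assert abs(num.sum() / den.sum() - 0.15) < 0.03

    def test_panels_share_snps_and_are_ancestral_coded(self):
        cfg = a.SimConfig(seed=1)
        panels, truth = a.simulate_reference_panels(cfg)
        snps = panels["EUR"].snps
        assert all(p.snps is snps or p.snps == snps for p in panels.values())
        assert all(s.ancestral_allele == "ref" for s in snps)


class TestAdmixedCohort:
    def test_single_ancestry_degenerate(self):
        cfg = a.SimConfig(seed=2, admixture=(1.0, 0.0, 0.0), cohort_size=10)
        panels, truth = a.simulate_reference_panels(cfg)
        _, calls = a.simulate_admixed_cohort(panels, cfg, truth)
        assert (calls.codes == 0).all()
        assert all(t.ancestry == "EUR" for t in calls.tracts)

    def test_genomewide_proportions_near_admixture_vector(self):
        cfg = a.SimConfig(seed=3, admixture=(0.77, 0.14, 0.09), cohort_size=100,
                          chromosomes=CHROM_50CM)
        panels, truth = a.simulate_reference_panels(cfg)
        _, calls = a.simulate_admixed_cohort(panels, cfg, truth)
        n = calls.codes.size
        for k, target in enumerate((0.77, 0.14, 0.09)):
            observed = (calls.codes == k).mean()
            # 3 SD of the binomial count at the number of independent
            # tracts (~ g * L * n_hap); conservative: use SNP count / 50
            se = np.sqrt(target * (1 - target) / (n / 50))
            assert abs(observed - target) < max(3 * se, 0.03)

    def test_expected_switch_count(self):
        # E[switches per haplotype] = g * L_Morgan * (1 - sum pi^2)
        cfg = a.SimConfig(seed=4, cohort_size=500, generations=15,
                          chromosomes=CHROM_50CM)
        panels, truth = a.simulate_reference_panels(cfg)
        _, calls = a.simulate_admixed_cohort(panels, cfg, truth)
        pi = np.array(cfg.admixture)
        expected = 15 * 0.5 * (1 - (pi ** 2).sum())
        switches = (np.diff(calls.codes, axis=1) != 0).sum(axis=1)
        assert abs(switches.mean() - expected) / expected < 0.10

    def test_doubling_generations_doubles_switches(self):
        counts = {}
        for g in (10, 20):
            cfg = a.SimConfig(seed=6, cohort_size=500, generations=g,
                              chromosomes=CHROM_50CM)
            panels, truth = a.simulate_reference_panels(cfg)
            _, calls = a.simulate_admixed_cohort(panels, cfg, truth)
            counts[g] = (np.diff(calls.codes, axis=1) != 0).sum(axis=1).mean()
        assert 1.8 <= counts[20] / counts[10] <= 2.2

    def test_emission_matches_truth_ancestry(self, small_cohort):
        # every allele was copied from some panel haplotype of the truth
        # ancestry: per tract, the emitted slice equals one panel row
        cfg, panels, cohort, calls, truth = small_cohort
        rng = np.random.default_rng(0)
        for t in rng.choice(calls.tracts, size=50, replace=False):
            sl = slice(t.start_snp, t.end_snp + 1)
            emitted = cohort.haplotypes[t.haplotype, sl]
            pool = panels[t.ancestry].haplotypes[:, sl]
            assert (pool == emitted).all(axis=1).any()

    def test_empty_panel_with_positive_weight_errors(self):
        cfg = a.SimConfig(seed=2, cohort_size=5)
        panels, truth = a.simulate_reference_panels(cfg)
        del panels["NAT"]
        with pytest.raises(ValueError, match="NAT"):
            a.simulate_admixed_cohort(panels, cfg, truth)


class TestDeviationInjection:
    region = a.RegionInterval("1", 5_000_000, 8_000_000)

    def _study(self, target, seed=9, n=250):
        cfg = a.SimConfig(seed=seed, cohort_size=n, chromosomes=CHROM_50CM,
                          deviation=a.DeviationSpec(self.region, target))
        return cfg, *a.simulate_study(cfg)

    def test_high_target_realized(self):
        cfg, panels, cohort, calls, truth = self._study((0.025, 0.025, 0.95))
        idx = cohort.snp_indices(self.region)
        nat = (calls.codes[:, idx] == 2).mean()
        assert 0.93 <= nat <= 0.97  # binomial 99% interval at n = 500

    def test_null_target_indistinguishable(self):
        # reinjecting at the genome-wide admixture vector leaves the
        # in-region ancestry distribution at its null; per-haplotype
        # ancestry draws at the region midpoint are the exchangeable units
        cfg = a.SimConfig(seed=9, cohort_size=250, chromosomes=CHROM_50CM)
        panels, cohort0, calls0, truth0 = a.simulate_study(cfg)
        _, _, _, calls1, _ = self._study((0.77, 0.14, 0.09))
        idx = cohort0.snp_indices(self.region)
        mid = idx[idx.size // 2]
        table = np.stack([
            np.bincount(calls0.codes[:, mid], minlength=3),
            np.bincount(calls1.codes[:, mid], minlength=3),
        ])
        assert stats.chi2_contingency(table).pvalue > 0.01

    def test_target_must_sum_to_one(self):
        cfg = a.SimConfig(seed=1, cohort_size=10)
        panels, cohort, calls, truth = a.simulate_study(cfg)
        with pytest.raises(ValueError, match="sum to 1"):
            a.inject_ancestry_deviation(
                cohort, truth, panels, a.RegionInterval("1", 1, 2_000_000),
                (0.5, 0.2, 0.2), cfg,
            )

    def test_region_without_snps_is_noop(self):
        cfg = a.SimConfig(seed=1, cohort_size=10)
        panels, cohort, calls, truth = a.simulate_study(cfg)
        before = cohort.haplotypes.copy()
        empty = a.RegionInterval("1", 19_999_998, 19_999_999)
        assert cohort.snp_indices(empty).size == 0
        a.inject_ancestry_deviation(cohort, truth, panels, empty,
                                    (0.77, 0.14, 0.09), cfg)
        np.testing.assert_array_equal(cohort.haplotypes, before)


class TestInversionInjection:
    region = a.RegionInterval("1", 4_000_000, 9_000_000)

    def _study(self, class_freqs, d=0.3, seed=13, n=250):
        cfg = a.SimConfig(
            seed=seed, cohort_size=n, chromosomes=CHROM_50CM,
            inversion=a.InversionSpec(self.region, class_freqs, divergence=d),
        )
        return cfg, *a.simulate_study(cfg)

    def test_zero_frequency_means_all_nini(self):
        cfg, panels, cohort, calls, truth = self._study((0.0, 0.0, 0.0))
        assert (truth.inversion_genotypes("cohort") == 0).all()

    def test_within_class_ibs_exceeds_between(self):
        cfg, panels, cohort, calls, truth = self._study((0.4, 0.4, 0.4))
        idx = cohort.snp_indices(self.region)
        hap = cohort.haplotypes[:, idx]
        cls = truth.inversion_classes["cohort"]
        same = hap[cls == 0]
        other = hap[cls == 1]
        within = np.mean([ (same[i] == same[j]).mean()
                           for i in range(20) for j in range(i + 1, 21) ])
        between = np.mean([ (same[i] == other[j]).mean()
                            for i in range(20) for j in range(20) ])
        assert within - between >= 0.2

    def test_genotype_counts_match_admixture_weighted_hwe(self):
        class_freqs = (0.2, 0.5, 0.02)
        cfg, panels, cohort, calls, truth = self._study(class_freqs, n=500)
        dosage = truth.inversion_genotypes("cohort")
        # haplotype-level inverted frequency weighted by local ancestry at
        # the region; genotype = product of two independent haplotypes
        idx = cohort.snp_indices(self.region)
        mid = idx[idx.size // 2]
        anc = truth.cohort_ancestry[:, mid]
        q = np.asarray(class_freqs)[anc].mean()
        exp = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2]) * cfg.cohort_size
        obs = np.bincount(dosage, minlength=3)
        assert stats.chisquare(obs, exp * obs.sum() / exp.sum()).pvalue > 0.01


def test_study_determinism_end_to_end():
    cfg = dict(seed=21, cohort_size=30,
               chromosomes=(a.ChromSpec("1", 10_000_000, 10.0, 400),),
               inversion=a.InversionSpec(
                   a.RegionInterval("1", 2_000_000, 5_000_000), (0.3, 0.3, 0.3)))
    runs = []
    for _ in range(2):
        panels, cohort, calls, truth = a.simulate_study(a.SimConfig(**cfg))
        runs.append((cohort.haplotypes.copy(), calls.codes.copy(),
                     truth.inversion_classes["cohort"].copy()))
    for x, y in zip(runs[0], runs[1]):
        np.testing.assert_array_equal(x, y)
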