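"""IBS, classical MDS, EM inversion genotyping, random regions, Procrustes."""

import numpy as np
import pytest

import admixscan as a


class TestIbs:
    def test_identical_individuals(self):
        g = np.tile([0, 1, 2, 1], (3, 1))
        ibs = a.ibs_matrix(g)
        np.testing.assert_allclose(ibs.values, 1.0)

    def test_opposite_homozygotes(self):
        g = np.array([[0, 0, 0], [2, 2, 2]])
        assert a.ibs_matrix(g).values[0, 1] == 0.0

    def test_hand_value(self):
        g = np.array([[0, 1, 2], [0, 1, 0]])
        assert a.ibs_matrix(g).values[0, 1] == pytest.approx(2 / 3)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, (15, 40)).astype(float)
        ibs = a.ibs_matrix(g)
        np.testing.assert_allclose(ibs.values, ibs.values.T)
        assert (ibs.values >= 0).all() and (ibs.values <= 1).all()
        np.testing.assert_allclose(np.diag(ibs.values), 1.0)

    def test_missing_excluded_pairwise(self):
        g = np.array([[0.0, np.nan, 2.0], [0.0, 1.0, 0.0]])
        ibs = a.ibs_matrix(g)
        assert ibs.values[0, 1] == pytest.approx((1.0 + 0.0) / 2)
        assert ibs.n_snps[0, 1] == 2

    def test_no_shared_snps_errors(self):
        g = np.array([[np.nan, 1.0], [2.0, np.nan]])
        with pytest.raises(ValueError, match="share"):
            a.ibs_matrix(g)


class TestClassicalMds:
    def test_collinear_points(self):
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        emb = a.classical_mds(d, k=1)
        x = emb.coords[:, 0]
        x = x - x[1]
        if x[0] > 0:
            x = -x
        np.testing.assert_allclose(x, [-1.0, 0.0, 1.0], atol=1e-10)

    def test_reproduces_euclidean_distances(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        emb = a.classical_mds(d, k=2)
        d2 = np.sqrt(((emb.coords[:, None] - emb.coords[None]) ** 2).sum(-1))
        np.testing.assert_allclose(d2, d, atol=1e-8)

    def test_recovers_planted_cloud_up_to_procrustes(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(30, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        emb = a.classical_mds(d, k=2)
        res = a.procrustes_protest(pts, emb.coords, n_perm=99, seed=0)
        assert res.correlation > 0.999

    def test_duplicate_rows_coincide(self):
        pts = np.array([[0.0, 0], [1, 0], [1, 0], [0, 1]])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        emb = a.classical_mds(d, k=2)
        np.testing.assert_allclose(emb.coords[1], emb.coords[2], atol=1e-10)

    def test_matches_scikit_bio_pcoa(self):
        # independent implementation cross-check
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        emb = a.classical_mds(d, k=2)
        ref = skbio.stats.ordination.pcoa(d, number_of_dimensions=2)
        for axis in range(2):
            ours = emb.coords[:, axis]
            theirs = ref.samples.values[:, axis]
            sign = np.sign(ours @ theirs)
            np.testing.assert_allclose(ours, sign * theirs, atol=1e-8)


class TestEmGenotyping:
    def test_planted_clusters_recovered(self):
        rng = np.random.default_rng(5)
        n = 300
        q = 0.4
        dosage = rng.binomial(2, q, n)
        x = np.array([-1.0, 0.0, 1.0])[dosage] + rng.normal(0, 0.01, n)
        inv = a.em_inversion_genotypes(x[:, None])
        agree = (inv.dosage == dosage).mean()
        # orientation: majority homozygote labelled NI/NI; q < 0.5 keeps
        # the non-inverted class most frequent
        assert agree >= 0.99
        assert (inv.posteriors.max(axis=1) > 0.99).mean() >= 0.99

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(-1, 0.2, 40), rng.normal(0, 0.2, 40),
                            rng.normal(1, 0.2, 40)])
        inv = a.em_inversion_genotypes(x[:, None])
        ll = inv.log_likelihood
        assert all(b >= x - 1e-6 for x, b in zip(ll, ll[1:]))

    def test_degenerate_identical_points(self):
        inv = a.em_inversion_genotypes(np.zeros((10, 1)))
        assert inv.degenerate
        assert inv.calls == ["NI/NI"] * 10

    def test_posteriors_sum_to_one_and_argmax(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(50, 1))
        inv = a.em_inversion_genotypes(x)
        np.testing.assert_allclose(inv.posteriors.sum(axis=1), 1.0, atol=1e-9)
        lut = {lab: i for i, lab in enumerate(("NI/NI", "NI/I", "I/I"))}
        for i, c in enumerate(inv.calls):
            assert lut[c] == int(np.argmax(inv.posteriors[i]))

    def test_anchor_override_flips_orientation(self):
        rng = np.random.default_rng(8)
        dosage = rng.binomial(2, 0.3, 200)
        x = np.array([-1.0, 0.0, 1.0])[dosage] + rng.normal(0, 0.01, 200)
        free = a.em_inversion_genotypes(x[:, None])
        hom = int(np.flatnonzero(free.dosage == 0)[0])
        anchored = a.em_inversion_genotypes(
            x[:, None], anchor_calls={hom: "I/I"}
        )
        assert anchored.calls[hom] == "I/I"

    def test_simulated_inversion_recovery(self):
        region = a.RegionInterval("1", 3_000_000, 8_000_000)
        cfg = a.SimConfig(
            seed=31, cohort_size=200,
            chromosomes=(a.ChromSpec("1", 20_000_000, 20.0, 800),),
            inversion=a.InversionSpec(region, (0.25, 0.5, 0.05), divergence=0.3),
        )
        panels, cohort, calls, truth = a.simulate_study(cfg)
        idx = cohort.snp_indices(region)
        emb = a.classical_mds(
            1 - a.ibs_matrix(cohort.dosages()[:, idx].astype(float)).values, k=2
        )
        inv = a.em_inversion_genotypes(emb)
        accuracy = (inv.dosage == truth.inversion_genotypes("cohort")).mean()
        assert accuracy >= 0.95


class TestRandomRegions:
    def _snps(self):
        out = []
        for chrom, n in (("1", 50), ("2", 50)):
            for j in range(n):
                out.append(a.SnpMeta(chrom, 1 + j * 400_000, f"{chrom}_{j}",
                                     "A", "G", "ref"))
        return out

    def test_exact_length_and_determinism(self):
        snps = self._snps()
        r1 = a.sample_random_regions(snps, 1_883_857, n=7, seed=3)
        r2 = a.sample_random_regions(snps, 1_883_857, n=7, seed=3)
        assert r1 == r2
        assert all(r.end_bp - r.start_bp == 1_883_857 for r in r1)

    def test_exclusion_respected(self):
        snps = self._snps()
        exclude = a.RegionInterval("1", 1, 19_600_001)  # all of chromosome 1
        regions = a.sample_random_regions(
            snps, 1_000_000, n=10, exclude=exclude, seed=4
        )
        assert all(r.chrom == "2" for r in regions)

    def test_impossible_placement_errors(self):
        snps = self._snps()
        with pytest.raises(ValueError):
            a.sample_random_regions(snps, 10**9, n=1, seed=0)


class TestProcrustes:
    def test_transformed_copy_perfect(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(100, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        y = 3.2 * x @ rot + np.array([5.0, -2.0])
        res = a.procrustes_protest(x, y, n_perm=10_000, seed=1)
        assert res.correlation == pytest.approx(1.0, abs=1e-10)
        assert res.p_value == pytest.approx(1 / 10_001)

    def test_invariance_of_correlation(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(40, 2))
        y = rng.normal(size=(40, 2))
        base = a.procrustes_protest(x, y, n_perm=9, seed=0).correlation
        y2 = 0.5 * y + 7.0
        again = a.procrustes_protest(x, y2, n_perm=9, seed=0).correlation
        assert again == pytest.approx(base, abs=1e-10)

    def test_independent_configurations_null(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(20 + seed)
            x = rng.normal(size=(100, 2))
            y = rng.normal(size=(100, 2))
            res = a.procrustes_protest(x, y, n_perm=499, seed=seed)
            if res.correlation < 0.35 and res.p_value > 0.05:
                hits += 1
        assert hits >= 4

    def test_matches_scipy_disparity(self):
        # scipy's procrustes disparity equals our m^2 after its scaling
        from scipy.spatial import procrustes as scipy_procrustes

        rng = np.random.default_rng(11)
        x = rng.normal(size=(25, 2))
        y = rng.normal(size=(25, 2))
        _, _, disparity = scipy_procrustes(x, y)
        res = a.procrustes_protest(x, y, n_perm=9, seed=0)
        assert res.m_squared == pytest.approx(disparity, abs=1e-10)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            a.procrustes_protest(np.zeros((2, 2)), np.zeros((2, 2)))
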