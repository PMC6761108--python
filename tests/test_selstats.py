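"""Neutrality statistics: EHH/iHH against a brute-force oracle, iHS/XP-EHH
contracts, Hudson Fst and PBS closed forms."""

import numpy as np
import pytest

import admixscan as a
from admixscan.selstats import standardize_in_daf_bins
from conftest import tiny_panel


def ehh_oracle(hap, core, rows, extent_idx):
    """Fraction of carrier pairs with identical haplotypes over the span
    from the core (exclusive) to ``extent_idx`` inclusive, by direct pair
    counting. The core column itself is constant within an allele class so
    excluding it matches the extended-haplotype definition for every
    class, including 'all'."""
    if extent_idx > core:
        lo, hi = core + 1, extent_idx
    else:
        lo, hi = extent_idx, core - 1
    seqs = [tuple(hap[r, lo : hi + 1]) for r in rows]
    n = len(seqs)
    same = sum(
        1 for i in range(n) for j in range(i + 1, n) if seqs[i] == seqs[j]
    )
    return same / (n * (n - 1) / 2)


class TestEhh:
    def test_identical_carriers_full_span(self):
        # all carriers identical: EHH stays 1, iHH = full cM span, censored
        hap = np.tile([1, 0, 1, 1, 0], (6, 1)).astype(np.int8)
        panel = tiny_panel(hap, cm=[0.0, 0.1, 0.25, 0.3, 0.5])
        curve = a.ihh(panel, 2, "all")
        assert curve.censored_left and curve.censored_right
        assert all(e == 1.0 for _, e in curve.left + curve.right)
        assert curve.ihh == pytest.approx(0.5)

    def test_hand_computed_derived_ihh(self):
        # 4 haplotypes, 3 SNPs at 0 / 0.1 / 0.2 cM; derived carriers
        # (rows 0, 1) identical throughout: EHH_D = 1 both sides,
        # iHH_D = 0.2
        hap = np.array(
            [[1, 1, 1],
             [1, 1, 1],
             [0, 0, 1],
             [1, 0, 0]], dtype=np.int8)
        panel = tiny_panel(hap, cm=[0.0, 0.1, 0.2])
        curve = a.ihh(panel, 1, "derived")
        assert curve.ihh == pytest.approx(0.2)
        assert curve.censored_left and curve.censored_right

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_hap, m = 10, 12
        hap = (rng.random((n_hap, m)) < rng.uniform(0.2, 0.8, m)).astype(np.int8)
        panel = tiny_panel(hap)
        core = int(rng.integers(1, m - 1))
        for cls, rows in [
            ("all", np.arange(n_hap)),
            ("derived", np.flatnonzero(hap[:, core] == 1)),
            ("ancestral", np.flatnonzero(hap[:, core] == 0)),
        ]:
            if rows.size < 2:
                continue
            curve = a.ihh(panel, core, cls, ehh_floor=0.0)
            for k, (off, ehh) in enumerate(curve.right):
                if k == 0:
                    assert ehh == 1.0
                    continue
                assert ehh == pytest.approx(
                    ehh_oracle(hap, core, rows, core + k), abs=1e-12
                )
            for k, (off, ehh) in enumerate(curve.left):
                if k == 0:
                    continue
                assert ehh == pytest.approx(
                    ehh_oracle(hap, core, rows, core - k), abs=1e-12
                )

    @pytest.mark.parametrize("seed", range(4))
    def test_curves_monotone_nonincreasing(self, seed):
        rng = np.random.default_rng(100 + seed)
        hap = (rng.random((16, 20)) < 0.5).astype(np.int8)
        panel = tiny_panel(hap)
        curve = a.ihh(panel, 10, "all", ehh_floor=0.0)
        for side in (curve.left, curve.right):
            vals = [e for _, e in side]
            assert vals[0] == 1.0
            assert all(y <= x + 1e-12 for x, y in zip(vals, vals[1:]))

    def test_too_few_carriers(self):
        hap = np.zeros((4, 3), dtype=np.int8)
        hap[0, 1] = 1
        panel = tiny_panel(hap)
        with pytest.raises(ValueError, match="derived"):
            a.ihh(panel, 1, "derived")

    def test_gap_censoring(self):
        hap = np.tile([1, 1, 1], (4, 1)).astype(np.int8)
        panel = tiny_panel(hap, positions=[1000, 2000, 500_000])
        curve = a.ihh(panel, 0, "all")
        assert curve.censored_right  # 498 kb gap exceeds the 200 kb rule
        assert len(curve.right) == 2


class TestIntrapopScan:
    def test_symmetric_ihh_gives_zero(self):
        # ancestral and derived carriers have mirror-image structure
        hap = np.array(
            [[0, 0, 0, 0, 0],
             [0, 1, 0, 1, 0],
             [1, 0, 1, 0, 1],
             [1, 1, 1, 1, 1]], dtype=np.int8)
        panel = tiny_panel(hap)
        tracks = a.intrapop_scan(panel, maf_min=0.0, include_censored=True)
        j = 2
        if tracks["|iHS|"].missing_reason[j] is None:
            assert tracks["|iHS|"].raw[j] == pytest.approx(0.0)
            assert tracks["|diHH|"].raw[j] == pytest.approx(0.0)

    def test_bin_standardization_self_consistency(self):
        rng = np.random.default_rng(0)
        m = 6000
        values = rng.normal(0, 1 + np.linspace(0, 2, m))
        daf = rng.uniform(0.05, 0.95, m)
        mask = np.ones(m, dtype=bool)
        std = standardize_in_daf_bins(values, daf, mask, n_bins=10)
        edges = np.quantile(daf, np.linspace(0, 1, 11))
        for b in range(10):
            sel = (daf >= edges[b]) & (daf <= edges[b + 1])
            if sel.sum() >= 500:
                assert abs(std[sel].mean()) < 0.05
                assert abs(std[sel].std() - 1) < 0.05

    def test_planted_sweep_enriches_top_ihs(self):
        # sweep-like region: most derived carriers share one long haplotype;
        # standardization bins need enough SNPs each for extreme scores to
        # be expressible, hence the coarser binning here
        cfg = a.SimConfig(seed=77, cohort_size=80,
                          chromosomes=(a.ChromSpec("1", 20_000_000, 20.0, 1000),))
        panels, truth = a.simulate_reference_panels(cfg)
        cohort, _ = a.simulate_admixed_cohort(panels, cfg, truth)
        hap = cohort.haplotypes.copy()
        m = cohort.n_snps
        core, half = m // 2, 10
        span = slice(core - half, core + half)
        donor = hap[0, span].copy()
        donor[half] = 1  # the core allele itself is derived on the donor
        carriers = np.flatnonzero(np.random.default_rng(1).random(hap.shape[0]) < 0.4)
        for h in carriers:
            hap[h, span] = donor
            hap[h, core] = 1
        swept = a.HaplotypePanel(hap, cohort.individual_ids, cohort.snps)
        tracks = a.intrapop_scan(swept, n_bins=10)
        s = tracks["|iHS|"].standardized
        usable = ~np.isnan(s)
        assert usable.sum() > 100
        cutoff = np.nanquantile(s, 0.99)
        top = np.flatnonzero(usable & (s >= cutoff))
        in_region = ((top >= core - half) & (top < core + half)).mean()
        background = 2 * half / m
        assert in_region >= 10 * background


class TestInterpopScan:
    def test_identical_panels_zero_xpehh(self, small_panels):
        _, panels, _ = small_panels
        eur = panels["EUR"]
        tracks = a.interpop_scan(eur, eur, include_censored=True)
        raw = tracks["XP-EHH"].raw
        usable = ~np.isnan(raw)
        assert usable.any()
        np.testing.assert_allclose(raw[usable], 0.0, atol=1e-12)

    def test_antisymmetry(self, small_panels):
        _, panels, _ = small_panels
        x_ab = a.interpop_scan(panels["EUR"], panels["AFR"],
                               include_censored=True)["XP-EHH"].raw
        x_ba = a.interpop_scan(panels["AFR"], panels["EUR"],
                               include_censored=True)["XP-EHH"].raw
        both = ~np.isnan(x_ab) & ~np.isnan(x_ba)
        assert both.any()
        np.testing.assert_allclose(x_ab[both], -x_ba[both], atol=1e-10)

    def test_planted_long_haplotype_raises_xpehh(self):
        rng = np.random.default_rng(7)
        scores = []
        for seed in range(3):
            cfg = a.SimConfig(
                seed=200 + seed, panel_haplotypes=60,
                chromosomes=(a.ChromSpec("1", 10_000_000, 10.0, 600),),
            )
            panels, _ = a.simulate_reference_panels(cfg)
            tgt = panels["EUR"]
            hap = tgt.haplotypes.copy()
            core, half = 300, 40
            donor = hap[0, core - half : core + half].copy()
            for h in np.flatnonzero(rng.random(hap.shape[0]) < 0.6):
                hap[h, core - half : core + half] = donor
            swept = a.HaplotypePanel(hap, tgt.individual_ids, tgt.snps)
            tracks = a.interpop_scan(swept, panels["AFR"])
            s = tracks["XP-EHH"].standardized
            region = s[core - half : core + half]
            scores.append(np.nanmean(region))
        assert np.mean(scores) > 2.0


class TestHudsonFst:
    def test_fixed_difference(self):
        assert a.hudson_fst(1.0, 10, 0.0, 10) == pytest.approx(1.0)

    def test_printed_toy_value(self):
        assert a.hudson_fst(0.6, 10, 0.2, 10) == pytest.approx(0.2063, abs=5e-5)

    def test_exchangeability(self):
        rng = np.random.default_rng(0)
        p1, p2 = rng.random(50), rng.random(50)
        np.testing.assert_allclose(
            a.hudson_fst(p1, 30, p2, 44), a.hudson_fst(p2, 44, p1, 30)
        )

    def test_both_fixed_same_allele_nan(self):
        assert np.isnan(a.hudson_fst(0.0, 10, 0.0, 10))

    def test_windowed_recovers_drift(self):
        cfg = a.SimConfig(seed=5, founders=None, panel_haplotypes=100,
                          drift=(0.15, 0.15, 0.15),
                          chromosomes=(a.ChromSpec("1", 20_000_000, 20.0, 2000),))
        panels, _ = a.simulate_reference_panels(cfg)
        p1 = panels["EUR"].haplotypes.mean(axis=0)
        p2 = panels["NAT"].haplotypes.mean(axis=0)
        windows = a.hudson_fst_windows(
            p1, 100, p2, 100, panels["EUR"].chromosomes, panels["EUR"].positions
        )
        mean_fst = np.mean([w.fst for w in windows])
        assert abs(mean_fst - 0.15) < 0.03


class TestPbs:
    def test_zero_everywhere(self):
        assert a.pbs(0.0, 0.0, 0.0) == pytest.approx(0.0)

    def test_closed_forms(self):
        assert a.pbs(0.1, 0.1, 0.0) == pytest.approx(-np.log(0.9), abs=1e-10)
        assert a.pbs(0.1, 0.1, 0.1) == pytest.approx(-np.log(0.9) / 2, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_branch_additivity(self, seed):
        # T_AB = x + y, T_AC = x + z, T_BC = y + z  =>  PBS_A = x
        rng = np.random.default_rng(seed)
        x, y, z = rng.uniform(0.01, 0.5, 3)
        f = lambda t: 1 - np.exp(-t)  # invert T = -ln(1 - Fst)
        assert a.pbs(f(x + y), f(x + z), f(y + z)) == pytest.approx(x, abs=1e-10)

    def test_negative_fst_clipped(self):
        assert a.pbs(-0.05, -0.05, -0.05) == pytest.approx(0.0)
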