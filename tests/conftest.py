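import numpy as np
import pytest

import admixscan as a


@pytest.fixture(scope="session")
def small_panels():
    """Three small Balding-Nichols panels with mosaic LD (shared SNP set)."""
    cfg = a.SimConfig(seed=11, panel_haplotypes=40,
                      chromosomes=(a.ChromSpec("1", 10_000_000, 10.0, 500),))
    panels, truth = a.simulate_reference_panels(cfg)
    return cfg, panels, truth


@pytest.fixture(scope="session")
def small_cohort(small_panels):
    cfg, panels, truth = small_panels
    cohort, calls = a.simulate_admixed_cohort(panels, cfg, truth)
    return cfg, panels, cohort, calls, truth


def tiny_panel(haps, positions=None, chrom="1", cm=None, ids=None):
    """Hand-built HaplotypePanel from a 0/1 matrix (helper, not a fixture)."""
    haps = np.asarray(haps, dtype=np.int8)
    m = haps.shape[1]
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    if cm is None:
        cm = [p / 1e6 for p in positions]
    snps = [
        a.SnpMeta(chrom, int(positions[j]), f"s{j}", "A", "G",
                  ancestral_allele="ref", cm=float(cm[j]))
        for j in range(m)
    ]
    if ids is None:
        ids = [f"i{k}" for k in range(haps.shape[0] // 2)]
    return a.HaplotypePanel(haps, ids, snps)
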