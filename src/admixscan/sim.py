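"""Synthetic reference panels and admixed cohorts with planted ground truth.

The generator emulates a three-way admixed cohort of the kind produced by
recent European/African/Native-American admixture in the Americas:

* three ancestral populations drawn from the Balding-Nichols model around a
  shared ancestral allele frequency, with per-population drift parameter F
  (the model's expected pairwise Hudson Fst between populations 1 and 2 is
  approximately (F1 + F2) / 2);
* within-population LD built by composing each panel haplotype as a mosaic
  of K founder haplotypes with a founder-switch rate rho per Morgan
  (``founders=None`` disables the mosaic and samples haplotypes i.i.d.
  from the population frequencies — the frequency-level model);
* admixed haplotypes whose local ancestry follows a Markov process along
  the genetic map (switch probability 1 - exp(-g * dM) per map increment
  of dM Morgans, ancestry redrawn from the admixture proportions pi, so
  silent self-switches are allowed), alleles copied tract-wise from a
  uniformly chosen reference haplotype of the tract's ancestry;
* an optional planted locus where in-region tract ancestries are resampled
  to target proportions (the post-admixture ancestry-deviation signal);
* an optional inversion-like polymorphism: two deeply diverged haplotype
  classes (NI, I) differing at a fraction d of in-region SNPs, with
  recombination between classes suppressed and per-population class
  frequencies.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import zlib

import numpy as np

from .types import (
    ANCESTRIES,
    AncestryCalls,
    GeneticMap,
    HaplotypePanel,
    RegionInterval,
    SnpMeta,
)

# unambiguous ref/alt pairs (strand-resolvable); ambiguous ones used only
# for the fraction of SNPs meant to exercise the ambiguity filter
_UNAMBIGUOUS_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]
_AMBIGUOUS_PAIRS = [("A", "T"), ("C", "G")]


def child_rng(seed: int, tag: str) -> np.random.Generator:
    """Derive a stage RNG deterministically from a global seed and a tag."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(tag.encode())])


@dataclass
class ChromSpec:
    """One simulated chromosome; defaults give array-like SNP density
    (~13 kb spacing) at the standard 1 cM/Mb recombination rate."""

    label: str
    length_bp: int = 20_000_000
    length_cm: float = 20.0
    n_snps: int = 1500


@dataclass
class DeviationSpec:
    region: RegionInterval
    target_props: tuple[float, float, float]  # per ancestry, sums to 1


@dataclass
class InversionSpec:
    region: RegionInterval
    class_freqs: tuple[float, float, float]  # inverted-class freq per population
    divergence: float = 0.3  # fraction of region SNPs differing between classes
    within_class_flip: float = 0.02  # residual within-class diversity


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort."""

    pop_labels: tuple[str, ...] = ANCESTRIES
    drift: tuple[float, ...] = (0.10, 0.10, 0.20)  # Balding-Nichols F per pop
    panel_haplotypes: int = 60  # per reference population
    cohort_size: int = 100  # admixed individuals
    admixture: tuple[float, ...] = (0.77, 0.14, 0.09)  # pi, sums to 1
    generations: int = 15  # generations since admixture
    chromosomes: tuple[ChromSpec, ...] = (ChromSpec("1"), ChromSpec("2"))
    founders: int | None = 20  # K founder haplotypes per population
    founder_switch_rate: float = 1.0  # rho, per Morgan
    # residual per-site haplotype diversity accumulated since founding,
    # applied to mosaic panel haplotypes; keeps extended-haplotype
    # homozygosity decaying instead of plateauing at 1/K (ignored in
    # frequency-level mode, founders=None)
    panel_flip_rate: float = 0.02
    ambiguous_fraction: float = 0.02  # fraction of SNPs given A/T or C/G alleles
    deviation: DeviationSpec | None = None
    inversion: InversionSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.admixture) - 1.0) > 1e-12:
            raise ValueError("admixture proportions must sum to 1")
        for f in self.drift:
            if not 0.0 <= f < 1.0:
                raise ValueError("drift parameters must lie in [0, 1)")
        if self.generations < 1:
            raise ValueError("generations since admixture must be >= 1")


@dataclass
class SimTruth:
    """Ground truth accompanying a simulated data set."""

    snps: list[SnpMeta]
    ancestral_freq: np.ndarray  # per SNP
    pop_freqs: np.ndarray  # n_pops x n_snps
    cohort_ancestry: np.ndarray | None = None  # 2N x M int8 codes
    deviation_region: RegionInterval | None = None
    inversion_region: RegionInterval | None = None
    # inversion class (0 = NI, 1 = I) per haplotype, keyed by panel name
    inversion_classes: dict = field(default_factory=dict)

    def cohort_calls(self, ancestries=ANCESTRIES) -> AncestryCalls:
        if self.cohort_ancestry is None:
            raise ValueError("no cohort has been simulated")
        return AncestryCalls.from_matrix(
            self.cohort_ancestry, ancestries, snps=self.snps
        )

    def inversion_genotypes(self, panel_name: str = "cohort") -> np.ndarray:
        """Per-individual count of inverted haplotypes (0, 1 or 2)."""
        cls = self.inversion_classes[panel_name]
        return cls[0::2] + cls[1::2]


# ---------------------------------------------------------------------------
# SNP scaffold
# ---------------------------------------------------------------------------

def _make_snps(config: SimConfig, rng: np.random.Generator) -> list[SnpMeta]:
    snps: list[SnpMeta] = []
    for spec in config.chromosomes:
        pos = np.array([], dtype=np.int64)
        while pos.size < spec.n_snps:  # rejection-free unique draw
            cand = rng.integers(1, spec.length_bp, size=2 * spec.n_snps)
            pos = np.unique(np.concatenate([pos, cand]))
        pos = np.sort(rng.choice(pos, size=spec.n_snps, replace=False))
        rate = spec.length_cm / spec.length_bp
        for k, p in enumerate(pos):
            if rng.random() < config.ambiguous_fraction:
                ref, alt = _AMBIGUOUS_PAIRS[rng.integers(2)]
            else:
                ref, alt = _UNAMBIGUOUS_PAIRS[rng.integers(4)]
            snps.append(
                SnpMeta(
                    chrom=spec.label,
                    pos=int(p),
                    id=f"snp_{spec.label}_{k}",
                    ref_allele=ref,
                    alt_allele=alt,
                    ancestral_allele="ref",  # allele 0 is ancestral by construction
                    cm=float(p) * rate,
                )
            )
    return snps


def genetic_map_for(config: SimConfig) -> GeneticMap:
    """Linear bp->cM map matching the simulated chromosome specs."""
    anchors = {
        spec.label: (
            np.array([1.0, float(spec.length_bp)]),
            np.array([0.0, spec.length_cm]),
        )
        for spec in config.chromosomes
    }
    return GeneticMap(anchors)


# ---------------------------------------------------------------------------
# Reference panels
# ---------------------------------------------------------------------------

def simulate_reference_panels(
    config: SimConfig,
) -> tuple[dict[str, HaplotypePanel], SimTruth]:
    """Draw three reference panels under the Balding-Nichols model.

    Returns panels keyed by population label plus the :class:`SimTruth`
    carrying the ancestral and per-population allele frequencies.
    """
    rng = child_rng(config.seed, "panels")
    snps = _make_snps(config, child_rng(config.seed, "snps"))
    m = len(snps)
    p_anc = rng.uniform(0.05, 0.95, size=m)
    pop_freqs = np.empty((len(config.pop_labels), m))
    for i, f in enumerate(config.drift):
        if f == 0.0:
            pop_freqs[i] = p_anc  # exact sharing, no Beta degenerate division
        else:
            a = p_anc * (1.0 - f) / f
            b = (1.0 - p_anc) * (1.0 - f) / f
            pop_freqs[i] = rng.beta(a, b)
    cm = np.array([s.cm for s in snps])
    chroms = np.array([s.chrom for s in snps])
    panels: dict[str, HaplotypePanel] = {}
    for i, label in enumerate(config.pop_labels):
        n = config.panel_haplotypes
        if config.founders is None:
            hap = (rng.random((n, m)) < pop_freqs[i]).astype(np.int8)
        else:
            founders = (rng.random((config.founders, m)) < pop_freqs[i]).astype(np.int8)
            p_switch = _switch_probs(cm, chroms, config.founder_switch_rate)
            hap = np.empty((n, m), dtype=np.int8)
            for h in range(n):
                fidx = _mosaic_sources(p_switch, config.founders, rng)
                hap[h] = founders[fidx, np.arange(m)]
            if config.panel_flip_rate > 0:
                flips = rng.random((n, m)) < config.panel_flip_rate
                hap = np.where(flips, 1 - hap, hap).astype(np.int8)
        ids = [f"{label}_{k}" for k in range(n // 2)]
        panels[label] = HaplotypePanel(hap, ids, snps, population=label)
    return panels, SimTruth(snps=snps, ancestral_freq=p_anc, pop_freqs=pop_freqs)


def _switch_probs(cm: np.ndarray, chroms: np.ndarray, rate: float) -> np.ndarray:
    """Per-SNP probability of a state redraw for a Markov walk along the map.

    Entry 0 of every chromosome block is 1 (a fresh draw); entry k is
    1 - exp(-rate * dM_k) for the increment from SNP k-1 to k in Morgans.
    """
    m = cm.size
    p = np.empty(m)
    p[0] = 1.0
    d_morgan = np.diff(cm) / 100.0
    p[1:] = -np.expm1(-rate * d_morgan)
    p[np.flatnonzero(chroms[1:] != chroms[:-1]) + 1] = 1.0
    return p


def _markov_states(
    p_switch: np.ndarray,
    draw_state,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Markov walk: redraw points from ``p_switch``, states from ``draw_state``."""
    m = p_switch.size
    switch = rng.random(m) < p_switch
    switch[0] = True
    pts = np.flatnonzero(switch)
    states = draw_state(pts.size, rng)
    return np.repeat(states, np.diff(np.append(pts, m)))


def _mosaic_sources(
    p_switch: np.ndarray,
    n_sources: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Source index per SNP for a mosaic haplotype along the map."""
    return _markov_states(
        p_switch, lambda n, r: r.integers(n_sources, size=n), rng
    )


# ---------------------------------------------------------------------------
# Admixed cohort
# ---------------------------------------------------------------------------

def _markov_ancestry(
    p_switch: np.ndarray,
    pi: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Ancestry code per SNP for one admixed haplotype.

    Switch with probability 1 - exp(-g * dM) per map increment; on switch
    the ancestry is redrawn from pi (self-switches allowed).
    """
    cum = np.cumsum(pi)
    draw = lambda n, r: np.searchsorted(cum, r.random(n)).astype(np.int8)
    return _markov_states(p_switch, draw, rng).astype(np.int8)


def _copy_tracts(
    row_codes: np.ndarray,
    panels_hap: list[np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Copy alleles tract-wise from a random haplotype of each tract's pop."""
    m = row_codes.size
    out = np.empty(m, dtype=np.int8)
    change = np.flatnonzero(np.diff(row_codes)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [m]])
    for s, e in zip(starts, ends):
        pool = panels_hap[row_codes[s]]
        src = rng.integers(pool.shape[0])
        out[s:e] = pool[src, s:e]
    return out


def simulate_admixed_cohort(
    panels: dict[str, HaplotypePanel],
    config: SimConfig,
    truth: SimTruth,
) -> tuple[HaplotypePanel, AncestryCalls]:
    """Simulate the admixed cohort; truth calls carry posterior 1.0."""
    pi = np.asarray(config.admixture, dtype=float)
    for i, label in enumerate(config.pop_labels):
        if pi[i] > 0 and (label not in panels or panels[label].n_haplotypes == 0):
            raise ValueError(f"admixture weight for {label} > 0 but panel empty")
    rng = child_rng(config.seed, "cohort")
    snps = truth.snps
    cm = np.array([s.cm for s in snps])
    chroms = np.array([s.chrom for s in snps])
    panels_hap = [panels[label].haplotypes for label in config.pop_labels]
    p_switch = _switch_probs(cm, chroms, float(config.generations))
    n_hap = 2 * config.cohort_size
    codes = np.empty((n_hap, len(snps)), dtype=np.int8)
    hap = np.empty((n_hap, len(snps)), dtype=np.int8)
    for h in range(n_hap):
        codes[h] = _markov_ancestry(p_switch, pi, rng)
        hap[h] = _copy_tracts(codes[h], panels_hap, rng)
    ids = [f"ADM_{k}" for k in range(config.cohort_size)]
    cohort = HaplotypePanel(hap, ids, snps, population="ADMIXED")
    truth.cohort_ancestry = codes
    calls = AncestryCalls.from_matrix(codes, config.pop_labels, snps=snps)
    return cohort, calls


# ---------------------------------------------------------------------------
# Planted signals
# ---------------------------------------------------------------------------

def inject_ancestry_deviation(
    cohort: HaplotypePanel,
    truth: SimTruth,
    panels: dict[str, HaplotypePanel],
    region: RegionInterval,
    target_props,
    config: SimConfig,
) -> tuple[HaplotypePanel, AncestryCalls]:
    """Resample in-region tract ancestries toward ``target_props``.

    Each haplotype's ancestry over the region's SNPs is redrawn from
    ``target_props`` and its alleles re-copied from a random haplotype of
    the new ancestry's panel; SNPs outside the region are untouched.
    """
    target = np.asarray(target_props, dtype=float)
    if abs(target.sum() - 1.0) > 1e-9:
        raise ValueError("target proportions must sum to 1")
    idx = cohort.snp_indices(region)
    if idx.size == 0:
        return cohort, truth.cohort_calls(config.pop_labels)
    rng = child_rng(config.seed, "deviation")
    lo, hi = idx.min(), idx.max() + 1
    codes = truth.cohort_ancestry
    hap = cohort.haplotypes
    panels_hap = [panels[label].haplotypes for label in config.pop_labels]
    for h in range(hap.shape[0]):
        anc = rng.choice(len(target), p=target)
        codes[h, lo:hi] = anc
        pool = panels_hap[anc]
        src = rng.integers(pool.shape[0])
        hap[h, lo:hi] = pool[src, lo:hi]
    truth.deviation_region = region
    calls = AncestryCalls.from_matrix(codes, config.pop_labels, snps=truth.snps)
    return cohort, calls


def inject_inversion(
    panels: dict[str, HaplotypePanel],
    cohort: HaplotypePanel | None,
    truth: SimTruth,
    spec: InversionSpec,
    config: SimConfig,
) -> None:
    """Plant an inversion-like long-range-LD polymorphism, in place.

    Two class haplotypes (NI, I) differ at a fraction ``spec.divergence``
    of the region's SNPs; each reference haplotype is assigned a class by
    its population's inverted-class frequency, each cohort haplotype by the
    frequency of its local ancestry at the region. In-region alleles are
    overwritten with the class haplotype plus small within-class noise,
    which suppresses recombination between classes over the region.
    """
    region = spec.region
    any_panel = next(iter(panels.values()))
    idx = any_panel.snp_indices(region)
    if idx.size == 0:
        raise ValueError("inversion region overlaps no simulated SNPs")
    rng = child_rng(config.seed, "inversion")
    k = idx.size
    ni_core = (rng.random(k) < truth.ancestral_freq[idx]).astype(np.int8)
    flip = np.zeros(k, dtype=bool)
    n_div = max(1, int(round(spec.divergence * k)))
    flip[rng.choice(k, size=n_div, replace=False)] = True
    i_core = np.where(flip, 1 - ni_core, ni_core).astype(np.int8)
    cores = (ni_core, i_core)

    def overwrite(hap_matrix: np.ndarray, classes: np.ndarray) -> None:
        for h in range(hap_matrix.shape[0]):
            base = cores[classes[h]].copy()
            noise = rng.random(k) < spec.within_class_flip
            base[noise] = 1 - base[noise]
            hap_matrix[h, idx] = base

    for i, label in enumerate(config.pop_labels):
        panel = panels[label]
        classes = (rng.random(panel.n_haplotypes) < spec.class_freqs[i]).astype(np.int8)
        overwrite(panel.haplotypes, classes)
        truth.inversion_classes[label] = classes
    if cohort is not None:
        mid = idx[k // 2]
        anc_at = truth.cohort_ancestry[:, mid]
        freqs = np.asarray(spec.class_freqs)[anc_at]
        classes = (rng.random(cohort.n_haplotypes) < freqs).astype(np.int8)
        overwrite(cohort.haplotypes, classes)
        truth.inversion_classes["cohort"] = classes
    truth.inversion_region = region


# ---------------------------------------------------------------------------
# Convenience driver
# ---------------------------------------------------------------------------

def simulate_study(config: SimConfig):
    """Panels + cohort + truth calls, with any configured planted signals.

    Returns ``(panels, cohort, calls, truth)``.
    """
    panels, truth = simulate_reference_panels(config)
    cohort, calls = simulate_admixed_cohort(panels, config, truth)
    if config.inversion is not None:
        inject_inversion(panels, cohort, truth, config.inversion, config)
    if config.deviation is not None:
        cohort, calls = inject_ancestry_deviation(
            cohort, truth, panels, config.deviation.region,
            config.deviation.target_props, config,
        )
    return panels, cohort, calls, truth
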