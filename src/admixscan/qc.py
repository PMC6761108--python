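"""SNP- and individual-level quality-control filters with an audit ledger.

Site filters run in a fixed order (unmapped, non-autosomal, ambiguous,
Hardy-Weinberg, missingness, MAF), attributing each removed SNP to the
first filter it fails so category counts sum exactly to the total removed.
Individual filters cover heterozygosity outliers, identity-by-state
duplicates and greedy relatedness pruning. LD pruning uses the sliding
50-SNP / 5-SNP / r^2 window rule on dosage correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import AUTOSOMES, HaplotypePanel

SITE_CATEGORIES = (
    "unmapped",
    "non-autosomal",
    "ambiguous",
    "HWE",
    "missingness",
    "MAF",
    "LD-pruned",
)


@dataclass
class QcLedger:
    """Auditable removal ledger: ordered category counts plus individuals."""

    starting_count: int
    site_removals: dict[str, int] = field(default_factory=dict)
    individual_removals: list[tuple[str, str]] = field(default_factory=list)

    @property
    def remaining(self) -> int:
        return self.starting_count - sum(self.site_removals.values())

    def check(self) -> None:
        if any(v < 0 for v in self.site_removals.values()) or self.remaining < 0:
            raise ValueError("ledger counts inconsistent")

    def to_rows(self) -> list[tuple[str, int]]:
        rows = [("start", self.starting_count)]
        rows += [(c, self.site_removals.get(c, 0)) for c in SITE_CATEGORIES]
        rows.append(("remaining", self.remaining))
        return rows


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def _hwe_het_log_probs(n_a: int, n_b: int):
    """Log-probabilities of each possible heterozygote count given allele
    counts ``n_a`` (say ref) and ``n_b`` (alt) in n = (n_a + n_b) / 2
    diploids, under random union of gametes."""
    n = (n_a + n_b) // 2
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    from scipy.special import gammaln

    def lfact(x):
        return gammaln(np.asarray(x) + 1.0)

    # P(h) proportional to n! / (hom_a! h! hom_b!) * 2^h, normalised over h
    hom_a = (n_a - hets) // 2
    hom_b = (n_b - hets) // 2
    logw = lfact(n) - lfact(hom_a) - lfact(hets) - lfact(hom_b) + hets * np.log(2.0)
    logw -= logw.max()
    w = np.exp(logw)
    return hets, w / w.sum()


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    p is the total probability, given the allele counts, of heterozygote
    counts no more likely than the observed one.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotyped individuals")
    n_a = 2 * n_hom_ref + n_het
    n_b = 2 * n_hom_alt + n_het
    if n_a == 0 or n_b == 0:
        return 1.0  # monomorphic: single configuration
    hets, probs = _hwe_het_log_probs(n_a, n_b)
    p_obs = probs[np.flatnonzero(hets == n_het)[0]]
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_chisq_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """1-df chi-square alternative to the exact test."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotyped individuals")
    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_hom_ref, n_het, n_hom_alt])
    chi2 = ((obs - exp) ** 2 / exp).sum()
    return float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Site filters
# ---------------------------------------------------------------------------

def apply_site_filters(
    panel: HaplotypePanel,
    hwe_p: float = 0.01,
    max_missing: float = 0.02,
    maf_min: float = 0.01,
    missing_rates: np.ndarray | None = None,
    hwe_method: str = "exact",
) -> tuple[np.ndarray, QcLedger]:
    """Apply the ordered site filters; return kept SNP indices + ledger.

    Each SNP is attributed to the first filter it fails. ``missing_rates``
    (per SNP) defaults to zero — phased panels carry no missing calls; the
    category exists for externally supplied rates.
    """
    m = panel.n_snps
    ledger = QcLedger(starting_count=m)
    status = np.full(m, -1, dtype=int)  # -1 = kept, else category index
    dosage = panel.dosages()
    n_ind = panel.n_individuals
    if missing_rates is None:
        missing_rates = np.zeros(m)
    hwe = hwe_exact_test if hwe_method == "exact" else hwe_chisq_test
    for j, s in enumerate(panel.snps):
        if s.pos <= 0 or s.chrom in {"0", ".", ""}:
            status[j] = 0
        elif s.chrom not in AUTOSOMES:
            status[j] = 1
        elif s.is_ambiguous:
            status[j] = 2
        else:
            d = dosage[:, j]
            n_hom_ref = int((d == 0).sum())
            n_het = int((d == 1).sum())
            n_hom_alt = int((d == 2).sum())
            if hwe(n_hom_ref, n_het, n_hom_alt) < hwe_p:
                status[j] = 3
            elif missing_rates[j] > max_missing:
                status[j] = 4
            else:
                p_alt = d.sum() / (2 * n_ind)
                if min(p_alt, 1 - p_alt) < maf_min:
                    status[j] = 5
    for i, cat in enumerate(SITE_CATEGORIES[:6]):
        ledger.site_removals[cat] = int((status == i).sum())
    ledger.check()
    return np.flatnonzero(status == -1), ledger


# ---------------------------------------------------------------------------
# Individual filters
# ---------------------------------------------------------------------------

def heterozygosity_outliers(
    panel: HaplotypePanel, k: float = 2.0
) -> tuple[list[int], float, float]:
    """Individuals whose heterozygosity rate lies beyond k SDs of the mean.

    Returns (flagged individual indices, mean rate, SD). A zero SD flags
    nobody.
    """
    if panel.n_individuals < 2:
        raise ValueError("need at least two individuals")
    rates = (panel.dosages() == 1).mean(axis=1)
    mean, sd = float(rates.mean()), float(rates.std())
    if sd == 0.0:
        return [], mean, sd
    flagged = np.flatnonzero(np.abs(rates - mean) > k * sd)
    return [int(i) for i in flagged], mean, sd


def greedy_relatedness_prune(
    relatedness: np.ndarray,
    rel_threshold: float = 0.125,
    dup_threshold: float = 0.85,
    ibs: np.ndarray | None = None,
    missingness: np.ndarray | None = None,
) -> tuple[list[int], list[tuple[int, str]]]:
    """Remove duplicates then greedily break remaining relatedness edges.

    Pairs with IBS > ``dup_threshold`` are duplicates (the lower-index
    member is kept). Then, while any pair exceeds ``rel_threshold``
    (strictly), the individual with the most above-threshold edges is
    removed; ties prefer higher missingness, then higher index. Returns
    (kept indices, removals with reasons).
    """
    rel = np.asarray(relatedness, dtype=float)
    if rel.ndim != 2 or rel.shape[0] != rel.shape[1]:
        raise ValueError("relatedness matrix must be square")
    if not np.allclose(rel, rel.T):
        raise ValueError("relatedness matrix must be symmetric")
    n = rel.shape[0]
    if ibs is None:
        ibs = rel
    if missingness is None:
        missingness = np.zeros(n)
    removed: list[tuple[int, str]] = []
    alive = np.ones(n, dtype=bool)
    # duplicates first: keep the lower index of each offending pair
    for i in range(n):
        for j in range(i + 1, n):
            if alive[i] and alive[j] and ibs[i, j] > dup_threshold:
                alive[j] = False
                removed.append((j, f"duplicate of {i} (IBS={ibs[i, j]:.3f})"))
    adj = (rel > rel_threshold) & alive[:, None] & alive[None, :]
    np.fill_diagonal(adj, False)
    while adj.any():
        degree = adj.sum(axis=1)
        top = degree.max()
        cand = np.flatnonzero(degree == top)
        miss = missingness[cand]
        cand = cand[miss == miss.max()]
        victim = int(cand.max())
        alive[victim] = False
        removed.append((victim, f"relatedness degree {top}"))
        adj[victim, :] = False
        adj[:, victim] = False
    return [int(i) for i in np.flatnonzero(alive)], removed


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_prune(
    dosages: np.ndarray,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.5,
    chrom: np.ndarray | None = None,
) -> np.ndarray:
    """Sliding-window LD pruning on dosage (composite) correlation.

    Within each window of ``window`` SNPs (advanced by ``step``), whenever
    a retained pair has squared dosage correlation > ``r2_max`` the
    later-index SNP is dropped. Returns kept SNP indices. Windows never
    straddle chromosomes when ``chrom`` labels are given.
    """
    g = np.asarray(dosages, dtype=float)
    m = g.shape[1]
    keep = np.ones(m, dtype=bool)
    if chrom is None:
        chrom = np.zeros(m)
    blocks = []
    start = 0
    for j in range(1, m + 1):
        if j == m or chrom[j] != chrom[start]:
            blocks.append((start, j))
            start = j
    for b0, b1 in blocks:
        w0 = b0
        while True:
            w1 = min(w0 + window, b1)
            idx = [j for j in range(w0, w1) if keep[j]]
            if len(idx) > 1:
                sub = g[:, idx]
                sd = sub.std(axis=0)
                ok = sd > 0
                with np.errstate(invalid="ignore"):
                    corr = np.corrcoef(sub.T)
                for a in range(len(idx)):
                    if not keep[idx[a]] or not ok[a]:
                        continue
                    for b in range(a + 1, len(idx)):
                        if not keep[idx[b]] or not ok[b]:
                            continue
                        if corr[a, b] ** 2 > r2_max:
                            keep[idx[b]] = False
            if w1 >= b1:
                break
            w0 += step
    return np.flatnonzero(keep)
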