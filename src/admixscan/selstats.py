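"""Haplotype- and frequency-based neutrality statistics.

Five statistics feed the combined selection scan:

* |iHS|   — ln(iHH_ancestral / iHH_derived), standardized within
            derived-allele-frequency bins, absolute value;
* |diHH|  — iHH_ancestral - iHH_derived, standardized within DAF bins,
            absolute value;
* |diHH_derived| — iHH_derived(target) - iHH_derived(reference),
            standardized genome-wide, absolute value;
* XP-EHH  — ln(iHH_all(target) / iHH_all(reference)), standardized
            genome-wide, signed (positive = longer haplotypes in target);
* PBS     — population branch statistic from pairwise Hudson Fst,
            T = -ln(1 - Fst), PBS_A = (T_AB + T_AC - T_BC) / 2.

EHH at offset x is the probability that two random carriers of the core
allele are identical over the interval from the core to x; iHH is its
trapezoidal integral over centimorgans, truncated at an EHH floor and
censored at chromosome ends or large physical gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import HaplotypePanel, RegionInterval

EHH_FLOOR = 0.05
MAX_GAP_BP = 200_000
MAF_MIN = 0.05
N_DAF_BINS = 50

STAT_NAMES = ("|iHS|", "|diHH|", "|diHH_derived|", "XP-EHH", "PBS")


@dataclass
class EhhCurve:
    """EHH decay around one core SNP for one allele class."""

    core_snp: int
    allele_class: str  # "ancestral" | "derived" | "all"
    left: list[tuple[float, float]]  # (cM offset, EHH), offsets <= 0
    right: list[tuple[float, float]]  # offsets >= 0
    censored_left: bool
    censored_right: bool
    ihh: float


@dataclass
class StatTrack:
    """Per-SNP values of one named statistic under one reference config."""

    name: str
    config_label: str
    raw: np.ndarray
    standardized: np.ndarray
    missing_reason: list  # None where usable

    @property
    def missing(self) -> np.ndarray:
        return np.array([r is not None for r in self.missing_reason])


@dataclass
class FstWindow:
    region: RegionInterval
    fst: float
    n_snps: int


# ---------------------------------------------------------------------------
# EHH / iHH
# ---------------------------------------------------------------------------

def _ehh_value(gid: np.ndarray) -> float:
    """Fraction of carrier pairs identical given current group labels."""
    n = gid.size
    counts = np.bincount(gid)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def _walk_side(
    hap: np.ndarray,
    cm: np.ndarray,
    pos: np.ndarray,
    same_chrom: np.ndarray,
    core: int,
    step: int,
    ehh_floor: float,
    max_gap_bp: int,
) -> tuple[list[tuple[float, float]], float, bool]:
    n, m = hap.shape
    points = [(0.0, 1.0)]
    gid = np.zeros(n, dtype=np.int64)
    n_groups = 1
    pair_denom = n * (n - 1)
    ihh = 0.0
    prev_ehh = 1.0
    j = core
    while True:
        nxt = j + step
        if nxt < 0 or nxt >= m or not same_chrom[nxt]:
            return points, ihh, True  # ran off the chromosome: censored
        if abs(int(pos[nxt]) - int(pos[j])) > max_gap_bp:
            return points, ihh, True  # unbridgeable gap: censored
        # refine the identity partition by the next allele
        raw = 2 * gid + hap[:, nxt]
        counts = np.bincount(raw, minlength=2 * n_groups)
        live = np.flatnonzero(counts)
        remap = np.empty(2 * n_groups, dtype=np.int64)
        remap[live] = np.arange(live.size)
        gid = remap[raw]
        n_groups = live.size
        ehh = float((counts * (counts - 1)).sum()) / pair_denom
        offset = float(step * (cm[nxt] - cm[core]))
        if ehh < ehh_floor:
            points.append((offset, ehh))
            return points, ihh, False  # decayed below the floor
        ihh += 0.5 * (prev_ehh + ehh) * abs(cm[nxt] - cm[j])
        points.append((offset, ehh))
        prev_ehh = ehh
        j = nxt


def ihh(
    panel: HaplotypePanel,
    core_snp: int,
    allele_class: str,
    ehh_floor: float = EHH_FLOOR,
    max_gap_bp: int = MAX_GAP_BP,
) -> EhhCurve:
    """EHH curve and integrated haplotype homozygosity at one core SNP.

    ``allele_class`` selects the carriers: ancestral (allele 0), derived
    (allele 1) or all haplotypes. Raises ``ValueError`` with a reason when
    fewer than two carriers exist.
    """
    hap = panel.haplotypes
    if allele_class == "ancestral":
        rows = np.flatnonzero(hap[:, core_snp] == 0)
    elif allele_class == "derived":
        rows = np.flatnonzero(hap[:, core_snp] == 1)
    elif allele_class == "all":
        rows = np.arange(hap.shape[0])
    else:
        raise ValueError(f"unknown allele class {allele_class!r}")
    if rows.size < 2:
        raise ValueError(f"fewer than 2 {allele_class} carriers at SNP {core_snp}")
    sub = hap[rows]
    cm = panel.cm
    pos = panel.positions
    same_chrom = panel.chromosomes == panel.snps[core_snp].chrom
    left_pts, ihh_l, cens_l = _walk_side(
        sub, cm, pos, same_chrom, core_snp, -1, ehh_floor, max_gap_bp
    )
    right_pts, ihh_r, cens_r = _walk_side(
        sub, cm, pos, same_chrom, core_snp, +1, ehh_floor, max_gap_bp
    )
    return EhhCurve(
        core_snp, allele_class,
        left_pts, right_pts, cens_l, cens_r,
        ihh_l + ihh_r,
    )


def _ihh_scan(
    panel: HaplotypePanel,
    allele_class: str,
    ehh_floor: float,
    max_gap_bp: int,
) -> tuple[np.ndarray, np.ndarray, list]:
    """(iHH, censored, reason) per SNP for one allele class."""
    m = panel.n_snps
    out = np.full(m, np.nan)
    censored = np.zeros(m, dtype=bool)
    reasons: list = [None] * m
    for j in range(m):
        try:
            curve = ihh(panel, j, allele_class, ehh_floor, max_gap_bp)
        except ValueError:
            reasons[j] = "too_few_carriers"
            continue
        out[j] = curve.ihh
        censored[j] = curve.censored_left or curve.censored_right
    return out, censored, reasons


# ---------------------------------------------------------------------------
# Standardization helpers
# ---------------------------------------------------------------------------

def _standardize(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.full_like(values, np.nan, dtype=float)
    v = values[mask]
    if v.size >= 2 and v.std() > 0:
        out[mask] = (values[mask] - v.mean()) / v.std()
    elif v.size:
        out[mask] = 0.0
    return out


def standardize_in_daf_bins(
    values: np.ndarray,
    daf: np.ndarray,
    mask: np.ndarray,
    n_bins: int = N_DAF_BINS,
) -> np.ndarray:
    """Standardize within equal-count derived-allele-frequency bins.

    Bins with fewer than two usable SNPs are merged into their lower
    neighbour before standardizing.
    """
    out = np.full_like(values, np.nan, dtype=float)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    d = daf[idx]
    n_bins = max(1, min(n_bins, idx.size))
    edges = np.quantile(d, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    assign = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, len(edges) - 2)
    # merge undersized bins downward
    labels = np.unique(assign)
    counts = {b: (assign == b).sum() for b in labels}
    remap = {}
    prev = None
    for b in labels:
        if counts[b] < 2 and prev is not None:
            remap[b] = prev
        else:
            remap[b] = b
            prev = b
    assign = np.array([remap[b] for b in assign])
    for b in np.unique(assign):
        sel = idx[assign == b]
        v = values[sel]
        sd = v.std()
        out[sel] = (v - v.mean()) / sd if sd > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# Intrapopulation scan: |iHS| and |diHH|
# ---------------------------------------------------------------------------

def intrapop_scan(
    panel: HaplotypePanel,
    maf_min: float = MAF_MIN,
    n_bins: int = N_DAF_BINS,
    ehh_floor: float = EHH_FLOOR,
    max_gap_bp: int = MAX_GAP_BP,
    config_label: str = "",
    include_censored: bool = False,
) -> dict[str, StatTrack]:
    """|iHS| and |diHH| tracks for one (target) panel."""
    m = panel.n_snps
    daf = panel.haplotypes.mean(axis=0)
    ihh_a, cens_a, rea_a = _ihh_scan(panel, "ancestral", ehh_floor, max_gap_bp)
    ihh_d, cens_d, rea_d = _ihh_scan(panel, "derived", ehh_floor, max_gap_bp)
    raw_ihs = np.full(m, np.nan)
    raw_dihh = np.full(m, np.nan)
    reasons: list = [None] * m
    for j in range(m):
        if min(daf[j], 1 - daf[j]) < maf_min:
            reasons[j] = "maf"
        elif rea_a[j] or rea_d[j]:
            reasons[j] = "too_few_carriers"
        elif not include_censored and (cens_a[j] or cens_d[j]):
            reasons[j] = "censored"
        elif ihh_d[j] == 0 or ihh_a[j] == 0:
            reasons[j] = "zero_ihh"
        else:
            raw_ihs[j] = np.log(ihh_a[j] / ihh_d[j])
            raw_dihh[j] = ihh_a[j] - ihh_d[j]
    mask = np.array([r is None for r in reasons])
    std_ihs = np.abs(standardize_in_daf_bins(raw_ihs, daf, mask, n_bins))
    std_dihh = np.abs(standardize_in_daf_bins(raw_dihh, daf, mask, n_bins))
    return {
        "|iHS|": StatTrack("|iHS|", config_label, raw_ihs, std_ihs, list(reasons)),
        "|diHH|": StatTrack("|diHH|", config_label, raw_dihh, std_dihh, list(reasons)),
    }


# ---------------------------------------------------------------------------
# Interpopulation scan: XP-EHH and |diHH_derived|
# ---------------------------------------------------------------------------

def ihh_scan(
    panel: HaplotypePanel,
    allele_class: str,
    ehh_floor: float = EHH_FLOOR,
    max_gap_bp: int = MAX_GAP_BP,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Per-SNP (iHH, censored flag, missing reason) for one allele class."""
    return _ihh_scan(panel, allele_class, ehh_floor, max_gap_bp)


def interpop_scan(
    target: HaplotypePanel,
    reference: HaplotypePanel,
    ehh_floor: float = EHH_FLOOR,
    max_gap_bp: int = MAX_GAP_BP,
    config_label: str = "",
    include_censored: bool = False,
    absolute_xpehh: bool = False,
    target_cache: dict | None = None,
) -> dict[str, StatTrack]:
    """XP-EHH and |diHH_derived| between a target and a reference panel.

    Panels must share the SNP set. XP-EHH is signed by default (positive =
    longer haplotypes in the target); ``absolute_xpehh`` folds it.
    ``target_cache`` may hold precomputed ``ihh_scan`` results for the
    target keyed by allele class (reused across reference configurations).
    """
    if target.n_snps != reference.n_snps:
        raise ValueError("panels must share the SNP set")
    m = target.n_snps
    cache = target_cache if target_cache is not None else {}
    for cls in ("all", "derived"):
        if cls not in cache:
            cache[cls] = _ihh_scan(target, cls, ehh_floor, max_gap_bp)
    it_all, ct_all, rt_all = cache["all"]
    it_d, ct_d, rt_d = cache["derived"]
    ir_all, cr_all, rr_all = _ihh_scan(reference, "all", ehh_floor, max_gap_bp)
    ir_d, cr_d, rr_d = _ihh_scan(reference, "derived", ehh_floor, max_gap_bp)
    p_t = target.haplotypes.mean(axis=0)
    p_r = reference.haplotypes.mean(axis=0)
    raw_xp = np.full(m, np.nan)
    raw_dd = np.full(m, np.nan)
    reasons_xp: list = [None] * m
    reasons_dd: list = [None] * m
    for j in range(m):
        mono_both = (p_t[j] in (0.0, 1.0)) and (p_r[j] in (0.0, 1.0))
        if mono_both:
            reasons_xp[j] = reasons_dd[j] = "monomorphic"
            continue
        censored = ct_all[j] or cr_all[j]
        if rt_all[j] or rr_all[j]:
            reasons_xp[j] = "too_few_carriers"
        elif not include_censored and censored:
            reasons_xp[j] = "censored"
        elif it_all[j] == 0 or ir_all[j] == 0:
            reasons_xp[j] = "zero_ihh"
        else:
            raw_xp[j] = np.log(it_all[j] / ir_all[j])
        if rt_d[j] or rr_d[j]:
            reasons_dd[j] = "too_few_carriers"
        elif not include_censored and (ct_d[j] or cr_d[j]):
            reasons_dd[j] = "censored"
        else:
            raw_dd[j] = it_d[j] - ir_d[j]
    mask_xp = np.array([r is None for r in reasons_xp])
    mask_dd = np.array([r is None for r in reasons_dd])
    std_xp = _standardize(raw_xp, mask_xp)
    if absolute_xpehh:
        std_xp = np.abs(std_xp)
    std_dd = np.abs(_standardize(raw_dd, mask_dd))
    return {
        "XP-EHH": StatTrack("XP-EHH", config_label, raw_xp, std_xp, reasons_xp),
        "|diHH_derived|": StatTrack(
            "|diHH_derived|", config_label, raw_dd, std_dd, reasons_dd
        ),
    }


# ---------------------------------------------------------------------------
# Hudson Fst and PBS
# ---------------------------------------------------------------------------

def hudson_fst(
    p1: np.ndarray, n1, p2: np.ndarray, n2
) -> np.ndarray:
    """Per-SNP Hudson Fst estimator from allele frequencies and sample sizes.

    N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1);
    D = p1(1-p2) + p2(1-p1); Fst = N/D. Sample sizes are haplotype counts
    and may be scalars or arrays. SNPs with D = 0 (both populations fixed
    for the same allele) return NaN.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("need at least 2 sampled haplotypes per population")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return out


def hudson_fst_components(p1, n1, p2, n2) -> tuple[np.ndarray, np.ndarray]:
    """Numerator and denominator of the per-SNP Hudson estimator."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def hudson_fst_windows(
    p1, n1, p2, n2,
    chroms: np.ndarray,
    pos: np.ndarray,
    window_bp: int = 1_000_000,
) -> list[FstWindow]:
    """Ratio-of-averages Hudson Fst in fixed-width windows (default 1 Mb)."""
    num, den = hudson_fst_components(p1, n1, p2, n2)
    chroms = np.asarray(chroms)
    pos = np.asarray(pos)
    windows: list[FstWindow] = []
    for chrom in dict.fromkeys(chroms.tolist()):
        on = chroms == chrom
        tiles = (pos[on] - 1) // window_bp
        for t in np.unique(tiles):
            sel = on.copy()
            sel[on] = tiles == t
            d = den[sel].sum()
            if d <= 0:
                continue
            start = int(t) * window_bp + 1
            windows.append(
                FstWindow(
                    RegionInterval(str(chrom), start, start + window_bp - 1),
                    float(num[sel].sum() / d),
                    int(sel.sum()),
                )
            )
    return windows


def pbs(fst_ab, fst_ac, fst_bc) -> np.ndarray:
    """Population branch statistic for population A.

    Fst values are clipped to [0, 1 - 1e-6] before T = -ln(1 - Fst);
    PBS_A = (T_AB + T_AC - T_BC) / 2 and may be negative.
    """
    def t(f):
        f = np.clip(np.nan_to_num(np.asarray(f, dtype=float), nan=0.0), 0.0, 1.0 - 1e-6)
        return -np.log1p(-f)

    return (t(fst_ab) + t(fst_ac) - t(fst_bc)) / 2.0


def pbs_track(
    target: HaplotypePanel,
    reference: HaplotypePanel,
    outgroup: HaplotypePanel,
    config_label: str = "",
) -> StatTrack:
    """Per-SNP PBS of the target against a reference and an outgroup panel."""
    pa, na = target.haplotypes.mean(axis=0), target.n_haplotypes
    pb, nb = reference.haplotypes.mean(axis=0), reference.n_haplotypes
    pc, nc = outgroup.haplotypes.mean(axis=0), outgroup.n_haplotypes
    raw = pbs(
        hudson_fst(pa, na, pb, nb),
        hudson_fst(pa, na, pc, nc),
        hudson_fst(pb, nb, pc, nc),
    )
    mono = np.isnan(hudson_fst(pa, na, pb, nb)) & np.isnan(hudson_fst(pa, na, pc, nc))
    reasons: list = ["monomorphic" if mono[j] else None for j in range(raw.size)]
    raw = np.where(mono, np.nan, raw)
    mask = ~mono
    std = _standardize(raw, mask)
    return StatTrack("PBS", config_label, raw, std, reasons)
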