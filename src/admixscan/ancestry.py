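"""Per-SNP ancestry-proportion tracks and the genome-wide deviation scan.

The scan flags SNPs whose local-ancestry proportion lies more than a fixed
number of standard deviations (default 4.42, corresponding to a two-sided
normal tail below 1e-5) from that ancestry's genome-wide mean, merges
adjacent flags into candidate regions, audits tract posteriors over a
region, and supports rescans stratified by inversion genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import AncestryCalls, RegionInterval, SnpMeta

#: default threshold, in genome-wide SDs; a |z| above it corresponds to a
#: two-sided normal tail probability under 1e-5
DEVIATION_SD = 4.42


@dataclass
class AncestryProportionTrack:
    """Fraction of haplotypes assigned to each ancestry, per SNP."""

    ancestries: tuple[str, ...]
    props: np.ndarray  # n_ancestries x n_snps
    n_haplotypes: int
    snps: list[SnpMeta] | None = None

    def __post_init__(self) -> None:
        if self.props.size and not np.allclose(self.props.sum(axis=0), 1.0):
            raise ValueError("ancestry proportions must sum to 1 at every SNP")


@dataclass
class FlaggedInterval:
    region: RegionInterval
    ancestry: str
    direction: str  # "excess" | "deficit"
    n_snps: int
    peak_z: float


@dataclass
class DeviationScan:
    ancestries: tuple[str, ...]
    mean: np.ndarray  # per ancestry
    sd: np.ndarray
    z: np.ndarray  # n_ancestries x n_snps
    threshold_sd: float
    flags: np.ndarray  # bool, same shape as z (|z| > threshold)
    intervals: list[FlaggedInterval]


def ancestry_proportions(
    calls: AncestryCalls, subset: list[int] | None = None
) -> AncestryProportionTrack:
    """Per-SNP fraction of (selected) haplotypes carrying each ancestry.

    ``subset`` selects individuals; both haplotypes of each are included.
    """
    codes = calls.codes
    if subset is not None:
        if len(subset) == 0:
            raise ValueError("empty individual subset")
        rows = np.array([[2 * i, 2 * i + 1] for i in subset]).ravel()
        codes = codes[rows]
    n_hap = codes.shape[0]
    props = np.stack(
        [(codes == k).mean(axis=0) for k in range(len(calls.ancestries))]
    )
    return AncestryProportionTrack(calls.ancestries, props, n_hap, calls.snps)


def deviation_scan(
    track: AncestryProportionTrack, threshold_sd: float = DEVIATION_SD
) -> DeviationScan:
    """Two-sided genome-wide deviation scan on an ancestry track.

    Mean and SD are computed per ancestry over all SNPs of the analysis
    set. A zero SD yields no flags for that ancestry. Adjacent flagged SNPs
    of the same ancestry, direction and chromosome merge into intervals.
    """
    props = track.props
    if props.shape[1] < 2:
        raise ValueError("need at least two SNPs")
    mean = props.mean(axis=1)
    sd = props.std(axis=1)
    z = np.zeros_like(props)
    nonzero = sd > 0
    z[nonzero] = (props[nonzero] - mean[nonzero, None]) / sd[nonzero, None]
    flags = np.abs(z) > threshold_sd
    flags[~nonzero] = False
    intervals = _merge_flags(track, z, flags)
    return DeviationScan(
        track.ancestries, mean, sd, z, threshold_sd, flags, intervals
    )


def _merge_flags(
    track: AncestryProportionTrack, z: np.ndarray, flags: np.ndarray
) -> list[FlaggedInterval]:
    if track.snps is None:
        return []
    chroms = np.array([s.chrom for s in track.snps])
    pos = np.array([s.pos for s in track.snps])
    out: list[FlaggedInterval] = []
    for a, anc in enumerate(track.ancestries):
        sign = np.where(flags[a], np.sign(z[a]), 0).astype(int)
        j = 0
        m = len(sign)
        while j < m:
            if sign[j] == 0:
                j += 1
                continue
            k = j
            while (
                k + 1 < m
                and sign[k + 1] == sign[j]
                and chroms[k + 1] == chroms[j]
            ):
                k += 1
            peak = float(np.abs(z[a, j : k + 1]).max())
            start, end = int(pos[j]), int(pos[k])
            if end == start:  # single-SNP interval: widen by 1 bp for validity
                end = start + 1
            out.append(
                FlaggedInterval(
                    RegionInterval(chroms[j], start, end),
                    anc,
                    "excess" if sign[j] > 0 else "deficit",
                    k - j + 1,
                    peak,
                )
            )
            j = k + 1
    return out


def tract_posterior_audit(
    calls: AncestryCalls, region: RegionInterval, cutoff: float = 0.9
) -> tuple[int, int]:
    """Count tracts intersecting ``region`` and those below the posterior cutoff."""
    if calls.snps is None:
        raise ValueError("calls carry no SNP metadata")
    chroms = np.array([s.chrom for s in calls.snps])
    pos = np.array([s.pos for s in calls.snps])
    idx = np.flatnonzero(
        (chroms == region.chrom) & (pos >= region.start_bp) & (pos <= region.end_bp)
    )
    tracts = calls.tracts_in_region(idx)
    n_below = sum(1 for t in tracts if t.posterior < cutoff)
    return len(tracts), n_below


def global_local_concordance(
    local_means: np.ndarray, global_props: np.ndarray
) -> np.ndarray:
    """Per-ancestry Pearson correlation between per-individual mean local
    ancestry and externally supplied global ancestry vectors.

    Both inputs are (n_individuals x n_ancestries). Ancestries where either
    vector has zero variance get NaN (undefined, reported as such).
    """
    local_means = np.asarray(local_means, dtype=float)
    global_props = np.asarray(global_props, dtype=float)
    if local_means.shape != global_props.shape:
        raise ValueError("inputs must cover the same individuals/ancestries")
    out = np.empty(local_means.shape[1])
    for a in range(local_means.shape[1]):
        x, y = local_means[:, a], global_props[:, a]
        if x.std() == 0 or y.std() == 0:
            out[a] = np.nan
        else:
            out[a] = np.corrcoef(x, y)[0, 1]
    return out


def individual_mean_ancestry(calls: AncestryCalls) -> np.ndarray:
    """Genome-wide mean local-ancestry proportion per individual (n x k)."""
    codes = calls.codes
    n_ind = codes.shape[0] // 2
    out = np.empty((n_ind, len(calls.ancestries)))
    for i in range(n_ind):
        pair = codes[2 * i : 2 * i + 2]
        for k in range(len(calls.ancestries)):
            out[i, k] = (pair == k).mean()
    return out


def stratified_scan(
    calls: AncestryCalls,
    inversion_dosage: np.ndarray,
    stratum: str,
    threshold_sd: float = DEVIATION_SD,
) -> DeviationScan:
    """Deviation scan restricted to one inversion-genotype stratum.

    ``inversion_dosage`` counts inverted haplotypes per individual (0/1/2);
    ``stratum`` is ``"NI/NI"`` or ``"I/I"``. Heterozygous (NI/I)
    individuals are never included.
    """
    want = {"NI/NI": 0, "I/I": 2}
    if stratum not in want:
        raise ValueError(f"stratum must be NI/NI or I/I, got {stratum!r}")
    members = [int(i) for i in np.flatnonzero(inversion_dosage == want[stratum])]
    if not members:
        raise ValueError(f"stratum {stratum} is empty")
    track = ancestry_proportions(calls, subset=members)
    return deviation_scan(track, threshold_sd)
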