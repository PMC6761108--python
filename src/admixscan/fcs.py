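"""Fisher combined score scan: empirical p-values, outliers, block calls.

Each statistic is converted to an empirical p-value, the genomic rank
divided by the number of SNPs (rank 1 = most extreme; ties take the
maximum rank of the tie group, so p is always in (0, 1]); missing
statistic values contribute p = 1. The per-SNP Fisher combined score is

    FCS = sum_i -log10(p_i),  i = 1..k,

outlier SNPs are the top 1% by FCS, the genome is tiled into 100-SNP
blocks per chromosome, and blocks whose outlier proportion strictly
exceeds the higher-type 99.5th empirical percentile of all block
proportions are called selection regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import RegionInterval
from .selstats import StatTrack

BLOCK_SIZE = 100
OUTLIER_QUANTILE = 0.99
BLOCK_PERCENTILE = 99.5


def empirical_pvalues(
    values: np.ndarray, tail: str = "upper"
) -> np.ndarray:
    """Rank-based empirical p-values for one statistic.

    p_j = (# values at least as extreme as value_j) / N over non-missing
    values, where "extreme" follows ``tail`` ("upper" or "lower"). Missing
    (NaN) entries get p = 1. All-identical values all get p = 1.
    """
    v = np.asarray(values, dtype=float)
    usable = ~np.isnan(v)
    n = int(usable.sum())
    out = np.ones(v.size)
    if n == 0:
        return out
    x = v[usable]
    if tail == "lower":
        x = -x
    elif tail != "upper":
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")
    # max-rank ties: rank of x_j = #{x_i >= x_j}
    order = np.sort(x)
    ge = n - np.searchsorted(order, x, side="left")
    out[usable] = ge / n
    return out


def empirical_pvalue_matrix(tracks: list[StatTrack], tail: str = "upper") -> np.ndarray:
    """Stack per-track empirical p-values into an (n_snps x k) matrix."""
    cols = [empirical_pvalues(t.standardized, tail) for t in tracks]
    return np.column_stack(cols)


def fisher_combined_score(p: np.ndarray) -> np.ndarray:
    """FCS = sum over statistics of -log10(p_i), per SNP."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return -np.log10(p).sum(axis=1) if p.ndim == 2 else -np.log10(p).sum()


@dataclass
class Block:
    chrom: str
    start_bp: int
    end_bp: int
    first_snp: int
    size: int
    outlier_prop: float
    called: bool


@dataclass
class FcsResult:
    fcs: np.ndarray
    outlier: np.ndarray  # bool per SNP
    blocks: list[Block]
    block_threshold: float
    regions: list[RegionInterval]  # called blocks as intervals


def outlier_flags(fcs: np.ndarray, outlier_q: float = OUTLIER_QUANTILE) -> np.ndarray:
    """Top (1 - outlier_q) fraction of SNPs by FCS rank.

    Uses the max-rank rule: a SNP is an outlier when the number of SNPs
    with FCS >= its own is at most floor((1 - q) * N), so tie-free inputs
    with N divisible by 100 yield exactly 1% outliers and ties can only
    shrink the set.
    """
    n = fcs.size
    m = int(np.floor((1.0 - outlier_q) * n))
    order = np.sort(fcs)
    ge = n - np.searchsorted(order, fcs, side="left")
    return ge <= m


def outlier_block_scan(
    fcs: np.ndarray,
    chroms: np.ndarray,
    pos: np.ndarray,
    block_size: int = BLOCK_SIZE,
    outlier_q: float = OUTLIER_QUANTILE,
    block_pct: float = BLOCK_PERCENTILE,
) -> FcsResult:
    """Call selection regions from per-SNP FCS values.

    SNPs must be ordered by chromosome and position. Blocks tile each
    chromosome in order; the final partial block keeps its actual size.
    A block is called when its outlier proportion strictly exceeds the
    higher-type ``block_pct`` empirical percentile of all block
    proportions.
    """
    fcs = np.asarray(fcs, dtype=float)
    n = fcs.size
    if n < block_size:
        raise ValueError(f"need at least {block_size} SNPs genome-wide")
    chroms = np.asarray(chroms)
    pos = np.asarray(pos)
    out = outlier_flags(fcs, outlier_q)
    blocks: list[Block] = []
    for chrom in dict.fromkeys(chroms.tolist()):
        idx = np.flatnonzero(chroms == chrom)
        for s in range(0, idx.size, block_size):
            sel = idx[s : s + block_size]
            blocks.append(
                Block(
                    chrom=str(chrom),
                    start_bp=int(pos[sel[0]]),
                    end_bp=int(pos[sel[-1]]),
                    first_snp=int(sel[0]),
                    size=int(sel.size),
                    outlier_prop=float(out[sel].mean()),
                    called=False,
                )
            )
    props = np.array([b.outlier_prop for b in blocks])
    # higher-type empirical quantile
    k = int(np.ceil(block_pct / 100.0 * props.size)) - 1
    threshold = float(np.sort(props)[max(k, 0)])
    regions = []
    for b in blocks:
        b.called = b.outlier_prop > threshold
        if b.called:
            end = b.end_bp if b.end_bp > b.start_bp else b.start_bp + 1
            regions.append(RegionInterval(b.chrom, b.start_bp, end))
    return FcsResult(fcs, out, blocks, threshold, regions)


def combine_tracks(
    tracks: list[StatTrack],
    chroms: np.ndarray,
    pos: np.ndarray,
    tail: str = "upper",
    block_size: int = BLOCK_SIZE,
    outlier_q: float = OUTLIER_QUANTILE,
    block_pct: float = BLOCK_PERCENTILE,
) -> tuple[np.ndarray, FcsResult]:
    """Empirical p-values + FCS + block scan for one configuration."""
    p = empirical_pvalue_matrix(tracks, tail)
    fcs = fisher_combined_score(p)
    return p, outlier_block_scan(fcs, chroms, pos, block_size, outlier_q, block_pct)


def label_regions(
    per_config: dict[str, FcsResult]
) -> list[tuple[RegionInterval, str]]:
    """Label called blocks by the reference configuration(s) calling them.

    Blocks called under several configurations get a compound
    "X or Y" label. Configurations must share the block tiling.
    """
    tilings = {
        tuple((b.chrom, b.first_snp, b.size) for b in r.blocks)
        for r in per_config.values()
    }
    if len(tilings) > 1:
        raise ValueError("configurations do not share the block tiling")
    labelled: list[tuple[RegionInterval, str]] = []
    any_result = next(iter(per_config.values()))
    for i, block in enumerate(any_result.blocks):
        callers = [
            label for label, r in per_config.items() if r.blocks[i].called
        ]
        if callers:
            end = block.end_bp if block.end_bp > block.start_bp else block.start_bp + 1
            labelled.append(
                (RegionInterval(block.chrom, block.start_bp, end), " or ".join(callers))
            )
    return labelled
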