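"""Shared domain types for admixed-cohort selection scans.

Conventions used throughout the package:

* Positions are 1-based base pairs; genetic positions are centimorgans.
* Regions carry inclusive printed endpoints and their length is
  ``end_bp - start_bp`` (the convention behind published interval sizes
  such as "448.4 Kb").
* Haplotype alleles are coded 0/1 with 0 = ancestral-aligned allele
  whenever the ancestral state is known.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AUTOSOMES = {str(i) for i in range(1, 23)}

#: canonical ancestry labels, in fixed code order
ANCESTRIES = ("EUR", "AFR", "NAT")

_VALID_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class SnpMeta:
    """Metadata for a single biallelic SNP."""

    chrom: str
    pos: int
    id: str
    ref_allele: str
    alt_allele: str
    ancestral_allele: str = "unknown"  # one of {"ref", "alt", "unknown"}
    cm: float = 0.0

    def __post_init__(self) -> None:
        if self.ref_allele not in _VALID_BASES or self.alt_allele not in _VALID_BASES:
            raise ValueError(
                f"invalid alleles {self.ref_allele}/{self.alt_allele} at "
                f"{self.chrom}:{self.pos}"
            )
        if self.ancestral_allele not in {"ref", "alt", "unknown"}:
            raise ValueError(f"bad ancestral_allele {self.ancestral_allele!r}")

    @property
    def is_ambiguous(self) -> bool:
        """Strand-ambiguous pair (A/T or C/G)."""
        return {self.ref_allele, self.alt_allele} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class RegionInterval:
    """A genomic interval with 1-based inclusive printed endpoints."""

    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if not self.start_bp < self.end_bp:
            raise ValueError(
                f"degenerate region {self.chrom}:{self.start_bp}-{self.end_bp}"
            )

    def length(self, unit: str = "bp") -> float:
        """Interval length as end - start, optionally converted to kb/Mb.

        kb and Mb values are rounded to one decimal, matching how interval
        sizes are conventionally printed.
        """
        bp = self.end_bp - self.start_bp
        if unit == "bp":
            return bp
        if unit == "kb":
            return round(bp / 1e3, 1)
        if unit == "Mb":
            return round(bp / 1e6, 1)
        raise ValueError(f"unknown unit {unit!r}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start_bp <= pos <= self.end_bp


def region_length(region: RegionInterval, unit: str = "bp") -> float:
    """Length of ``region`` in ``unit`` ('bp', 'kb' or 'Mb')."""
    return region.length(unit)


class GeneticMap:
    """Piecewise-linear bp -> cM map, one set of anchors per chromosome."""

    def __init__(self, anchors: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in anchors.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.ndim != 1 or bp.shape != cm.shape or bp.size < 2:
                raise ValueError(f"chromosome {chrom}: need >= 2 (bp, cM) anchors")
            if not np.all(np.diff(bp) > 0):
                raise ValueError(f"chromosome {chrom}: bp anchors not increasing")
            if not np.all(np.diff(cm) >= 0):
                raise ValueError(f"chromosome {chrom}: cM anchors decreasing")
            self._anchors[chrom] = (bp, cm)

    @property
    def chroms(self) -> list[str]:
        return list(self._anchors)

    def anchors(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self._anchors[chrom]

    def cm_at(self, chrom: str, pos_bp) -> np.ndarray | float:
        """Interpolate genetic position at ``pos_bp``.

        Linear interpolation between anchors; beyond the terminal anchors,
        linear extrapolation at the chromosome's mean cM/bp rate.
        """
        if chrom not in self._anchors:
            raise KeyError(f"chromosome {chrom!r} not in genetic map")
        bp, cm = self._anchors[chrom]
        pos = np.asarray(pos_bp, dtype=float)
        out = np.interp(pos, bp, cm)
        rate = (cm[-1] - cm[0]) / (bp[-1] - bp[0])
        lo = pos < bp[0]
        hi = pos > bp[-1]
        out = np.where(lo, cm[0] + (pos - bp[0]) * rate, out)
        out = np.where(hi, cm[-1] + (pos - bp[-1]) * rate, out)
        return float(out) if np.isscalar(pos_bp) or out.ndim == 0 else out


def cm_at(genetic_map: GeneticMap, chrom: str, pos_bp):
    """Genetic position (cM) of ``pos_bp`` under ``genetic_map``."""
    return genetic_map.cm_at(chrom, pos_bp)


class HaplotypePanel:
    """Phased 0/1 haplotype matrix with SNP metadata.

    Rows are haplotypes (two consecutive rows per individual, in sample
    order); columns align with ``snps``. Allele 0 is the ancestral-aligned
    allele where the ancestral state is known.
    """

    def __init__(
        self,
        haplotypes: np.ndarray,
        individual_ids: list[str],
        snps: list[SnpMeta],
        population: str = "",
    ):
        hap = np.asarray(haplotypes, dtype=np.int8)
        if hap.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if hap.shape[0] % 2 != 0:
            raise ValueError("haplotype row count must be even (diploid pairs)")
        if hap.shape[0] != 2 * len(individual_ids):
            raise ValueError("row count does not match 2 x individuals")
        if hap.shape[1] != len(snps):
            raise ValueError("column count does not match SNP metadata")
        if hap.size and not np.isin(hap, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")
        self.haplotypes = hap
        self.individual_ids = list(individual_ids)
        self.snps = list(snps)
        self.population = population
        self._check_sorted()

    def _check_sorted(self) -> None:
        last: dict[str, int] = {}
        seen_order: list[str] = []
        for s in self.snps:
            if s.chrom in last:
                if s.pos <= last[s.chrom]:
                    raise ValueError(
                        f"positions not strictly increasing at {s.chrom}:{s.pos}"
                    )
                if seen_order[-1] != s.chrom:
                    raise ValueError(f"chromosome {s.chrom} blocks not contiguous")
            else:
                seen_order.append(s.chrom)
            last[s.chrom] = s.pos

    # -- basic accessors -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.snps])

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([s.chrom for s in self.snps])

    @property
    def cm(self) -> np.ndarray:
        return np.array([s.cm for s in self.snps])

    def dosages(self) -> np.ndarray:
        """Per-individual 0/1/2 counts of the alternative (allele-1) allele."""
        return self.haplotypes[0::2] + self.haplotypes[1::2]

    def snp_indices(self, region: RegionInterval) -> np.ndarray:
        """Column indices of SNPs falling inside ``region``."""
        chroms = self.chromosomes
        pos = self.positions
        return np.flatnonzero(
            (chroms == region.chrom)
            & (pos >= region.start_bp)
            & (pos <= region.end_bp)
        )

    def subset_snps(self, idx: np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return HaplotypePanel(
            self.haplotypes[:, idx],
            self.individual_ids,
            [self.snps[i] for i in idx],
            self.population,
        )

    def subset_individuals(self, which: list[int]) -> "HaplotypePanel":
        rows = np.array([[2 * i, 2 * i + 1] for i in which]).ravel()
        return HaplotypePanel(
            self.haplotypes[rows],
            [self.individual_ids[i] for i in which],
            self.snps,
            self.population,
        )


@dataclass
class Tract:
    """A run of SNPs on one haplotype assigned a single ancestry."""

    haplotype: int
    start_snp: int  # inclusive column index
    end_snp: int  # inclusive column index
    ancestry: str
    posterior: float = 1.0


class AncestryCalls:
    """Per-haplotype, per-SNP local-ancestry labels with tract posteriors.

    Internally stores an int8 code matrix (rows = haplotypes, columns =
    SNPs, codes index into ``ancestries``) plus the tract list. Every SNP
    of every haplotype belongs to exactly one tract.
    """

    def __init__(
        self,
        codes: np.ndarray,
        tracts: list[Tract],
        ancestries: tuple[str, ...] = ANCESTRIES,
        snps: list[SnpMeta] | None = None,
    ):
        self.codes = np.asarray(codes, dtype=np.int8)
        self.ancestries = tuple(ancestries)
        self.tracts = list(tracts)
        self.snps = snps
        self._validate()

    def _validate(self) -> None:
        n_hap, n_snp = self.codes.shape
        cover = np.zeros((n_hap, n_snp), dtype=np.int32)
        for t in self.tracts:
            if not 0.0 <= t.posterior <= 1.0:
                raise ValueError(f"posterior {t.posterior} outside [0, 1]")
            if t.ancestry not in self.ancestries:
                raise ValueError(f"unknown ancestry code {t.ancestry!r}")
            cover[t.haplotype, t.start_snp : t.end_snp + 1] += 1
        if (cover != 1).any():
            h, j = np.argwhere(cover != 1)[0]
            kind = "uncovered" if cover[h, j] == 0 else "multiply covered"
            raise ValueError(f"haplotype {h}, SNP {j} {kind} by tracts")

    @classmethod
    def from_matrix(
        cls,
        codes: np.ndarray,
        ancestries: tuple[str, ...] = ANCESTRIES,
        posteriors: np.ndarray | None = None,
        snps: list[SnpMeta] | None = None,
    ) -> "AncestryCalls":
        """Build calls from a code matrix, deriving tracts from runs.

        ``posteriors`` optionally gives one posterior per derived tract, in
        row-major tract order; defaults to 1.0.
        """
        codes = np.asarray(codes, dtype=np.int8)
        tracts: list[Tract] = []
        for h in range(codes.shape[0]):
            row = codes[h]
            change = np.flatnonzero(np.diff(row)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change - 1, [codes.shape[1] - 1]])
            for s, e in zip(starts, ends):
                tracts.append(Tract(h, int(s), int(e), ancestries[row[s]]))
        if posteriors is not None:
            if len(posteriors) != len(tracts):
                raise ValueError("posterior count does not match tract count")
            for t, p in zip(tracts, posteriors):
                t.posterior = float(p)
        return cls(codes, tracts, ancestries, snps)

    @property
    def n_haplotypes(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def tracts_in_region(self, snp_idx: np.ndarray) -> list[Tract]:
        """Tracts intersecting any SNP column index in ``snp_idx``."""
        if len(snp_idx) == 0:
            raise ValueError("region overlaps no SNPs")
        lo, hi = int(np.min(snp_idx)), int(np.max(snp_idx))
        return [t for t in self.tracts if t.start_snp <= hi and t.end_snp >= lo]

    def subset_haplotypes(self, rows: np.ndarray) -> "AncestryCalls":
        rows = np.asarray(rows)
        return AncestryCalls.from_matrix(
            self.codes[rows], self.ancestries, snps=self.snps
        )
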