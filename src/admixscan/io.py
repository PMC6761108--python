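"""Readers and writers for the formats the pipeline touches.

* phased VCF (cyvcf2 reader, plain-text writer; optional ``AA`` INFO field
  carries the ancestral allele and triggers re-orientation so that allele 0
  is ancestral),
* 3-column genetic map TSV (chrom, bp, cM),
* msp-style local-ancestry TSV (one row per tract span, one ancestry-code
  column per haplotype) with an optional companion posterior TSV,
* BED-like region TSV with 1-based inclusive endpoints.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (
    ANCESTRIES,
    AncestryCalls,
    GeneticMap,
    HaplotypePanel,
    RegionInterval,
    SnpMeta,
    Tract,
)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def parse_phased_vcf(path: str, drop_multiallelic: bool = False) -> HaplotypePanel:
    """Read a phased diploid VCF into a :class:`HaplotypePanel`.

    When the ``AA`` INFO field is present and matches REF or ALT, alleles
    are re-oriented so 0 = ancestral; otherwise 0 = REF and the ancestral
    allele is recorded as unknown.

    Raises ``ValueError`` for unphased genotypes (naming the record) and
    for multi-allelic records unless ``drop_multiallelic`` is set.
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    snps: list[SnpMeta] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            if drop_multiallelic:
                continue
            raise ValueError(
                f"multi-allelic record at {var.CHROM}:{var.POS}; "
                "pass drop_multiallelic=True to skip"
            )
        geno = np.array(var.genotypes)  # (n, 3): a0, a1, phased flag
        if not geno[:, 2].all():
            raise ValueError(f"unphased genotype at {var.CHROM}:{var.POS}")
        alleles = geno[:, :2].ravel().astype(np.int8)
        aa = var.INFO.get("AA")
        ancestral = "unknown"
        if aa is not None:
            aa = str(aa).upper()
            if aa == var.REF:
                ancestral = "ref"
            elif aa == var.ALT[0]:
                ancestral = "alt"
                alleles = (1 - alleles).astype(np.int8)
        snps.append(
            SnpMeta(
                chrom=var.CHROM,
                pos=var.POS,
                id=var.ID or f"{var.CHROM}:{var.POS}",
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
                ancestral_allele=ancestral,
            )
        )
        columns.append(alleles)
    vcf.close()
    hap = (
        np.column_stack(columns)
        if columns
        else np.zeros((2 * len(samples), 0), dtype=np.int8)
    )
    return HaplotypePanel(hap, samples, snps)


def write_phased_vcf(panel: HaplotypePanel, path: str) -> None:
    """Write a panel as a minimal phased VCF (inverse of the parser)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n'
        )
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.individual_ids)
            + "\n"
        )
        for j, s in enumerate(panel.snps):
            col = panel.haplotypes[:, j]
            if s.ancestral_allele == "alt":
                col = 1 - col  # back to REF coding
            info = "."
            if s.ancestral_allele == "ref":
                info = f"AA={s.ref_allele}"
            elif s.ancestral_allele == "alt":
                info = f"AA={s.alt_allele}"
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(panel.n_individuals)
            )
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.id}\t{s.ref_allele}\t{s.alt_allele}"
                f"\t.\t.\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

def read_genetic_map(path: str) -> GeneticMap:
    """Read a whitespace-delimited (chrom, bp, cM) table."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        names=["chrom", "bp", "cm"],
        dtype={"chrom": str},
    )
    anchors = {
        chrom: (g["bp"].to_numpy(float), g["cm"].to_numpy(float))
        for chrom, g in df.groupby("chrom", sort=False)
    }
    return GeneticMap(anchors)


def write_genetic_map(gmap: GeneticMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# chrom\tbp\tcM\n")
        for chrom in gmap.chroms:
            bp, cm = gmap.anchors(chrom)
            for b, c in zip(bp, cm):
                fh.write(f"{chrom}\t{int(b)}\t{c:.6f}\n")


# ---------------------------------------------------------------------------
# msp-style local-ancestry calls
# ---------------------------------------------------------------------------

_MSP_FIXED = ["chrom", "spos", "epos", "sgpos", "egpos", "n_snps"]


def write_ancestry_calls(
    calls: AncestryCalls, path: str, posterior_path: str | None = None
) -> None:
    """Write msp-style tracts (+ optional posterior companion TSV).

    The msp table has one row per distinct tract span (maximal runs shared
    across haplotypes are not merged: a row is emitted per unique span
    boundary set across all haplotypes, the msp convention). Here we emit
    one row per span in the partition induced by all tract boundaries, with
    one ancestry-code column per haplotype.
    """
    if calls.snps is None:
        raise ValueError("calls carry no SNP metadata; cannot emit bp spans")
    n_snp = calls.n_snps
    cuts = {0, n_snp}
    for t in calls.tracts:
        cuts.add(t.start_snp)
        cuts.add(t.end_snp + 1)
    # spans must not straddle chromosomes
    chroms = [s.chrom for s in calls.snps]
    for j in range(1, n_snp):
        if chroms[j] != chroms[j - 1]:
            cuts.add(j)
    bounds = sorted(cuts)
    code_header = "\t".join(f"hap{h}" for h in range(calls.n_haplotypes))
    with open(path, "w") as fh:
        fh.write(
            "#codes: "
            + " ".join(f"{a}={i}" for i, a in enumerate(calls.ancestries))
            + "\n"
        )
        fh.write("\t".join(_MSP_FIXED) + "\t" + code_header + "\n")
        for s, e in zip(bounds[:-1], bounds[1:]):
            row = calls.codes[:, s]
            fh.write(
                f"{calls.snps[s].chrom}\t{calls.snps[s].pos}\t{calls.snps[e - 1].pos}"
                f"\t{calls.snps[s].cm:.6f}\t{calls.snps[e - 1].cm:.6f}\t{e - s}\t"
                + "\t".join(str(int(c)) for c in row)
                + "\n"
            )
    if posterior_path is not None:
        with open(posterior_path, "w") as fh:
            fh.write("haplotype\tstart_snp\tend_snp\tancestry\tposterior\n")
            for t in calls.tracts:
                fh.write(
                    f"{t.haplotype}\t{t.start_snp}\t{t.end_snp}\t{t.ancestry}"
                    f"\t{t.posterior:.6g}\n"
                )


def read_ancestry_calls(
    path: str,
    snps: list[SnpMeta],
    posterior_path: str | None = None,
    ancestries: tuple[str, ...] = ANCESTRIES,
) -> AncestryCalls:
    """Read msp-style tracts back into :class:`AncestryCalls`.

    Spans must tile the SNP set exactly. Without a posterior file all
    posteriors default to 1.0.
    """
    with open(path) as fh:
        header = fh.readline()
        if header.startswith("#codes:"):
            code_map = {}
            for item in header.split(":", 1)[1].split():
                name, idx = item.split("=")
                code_map[int(idx)] = name
            ancestries = tuple(code_map[i] for i in sorted(code_map))
            fh.readline()  # column header
        raw = pd.read_csv(fh, sep="\t", header=None, dtype={0: str})
    df = raw.iloc[:, :6].copy()
    df.columns = _MSP_FIXED
    codes_block = raw.iloc[:, 6:].to_numpy(dtype=np.int8).T  # hap x span
    n_snp = len(snps)
    pos_index = {(s.chrom, s.pos): j for j, s in enumerate(snps)}
    codes = np.full((codes_block.shape[0], n_snp), -1, dtype=np.int8)
    for r in range(len(df)):
        key_s = (str(df.chrom[r]), int(df.spos[r]))
        key_e = (str(df.chrom[r]), int(df.epos[r]))
        if key_s not in pos_index or key_e not in pos_index:
            raise ValueError(f"span {key_s}-{key_e} does not match the SNP set")
        j0, j1 = pos_index[key_s], pos_index[key_e]
        if (codes[:, j0 : j1 + 1] != -1).any():
            raise ValueError(f"overlapping spans at {key_s}")
        if int(df.n_snps[r]) != j1 - j0 + 1:
            raise ValueError(f"span at {key_s} claims wrong SNP count")
        codes[:, j0 : j1 + 1] = codes_block[:, r][:, None]
    if (codes == -1).any():
        raise ValueError("spans do not tile the SNP set")
    if codes.max() >= len(ancestries):
        raise ValueError("ancestry code outside declared code map")
    calls = AncestryCalls.from_matrix(codes, ancestries, snps=snps)
    if posterior_path is not None and os.path.exists(posterior_path):
        pdf = pd.read_csv(posterior_path, sep="\t")
        tracts = [
            Tract(
                int(r.haplotype), int(r.start_snp), int(r.end_snp),
                str(r.ancestry), float(r.posterior),
            )
            for r in pdf.itertuples()
        ]
        calls = AncestryCalls(codes, tracts, ancestries, snps=snps)
    return calls


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

def read_regions(path: str) -> list[RegionInterval]:
    """Read a BED-like TSV of (chrom, start_bp, end_bp), 1-based inclusive."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end = line.split()[:3]
            out.append(RegionInterval(chrom, int(start), int(end)))
    return out


def write_regions(
    regions,
    path: str,
    extra_cols: list[dict] | None = None,
    header_note: str | None = None,
) -> None:
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        keys = sorted({k for d in (extra_cols or []) for k in d})
        fh.write("# chrom\tstart_bp\tend_bp (1-based, inclusive endpoints)")
        fh.write(("\t" + "\t".join(keys)) if keys else "")
        fh.write("\n")
        for i, r in enumerate(regions):
            fh.write(f"{r.chrom}\t{r.start_bp}\t{r.end_bp}")
            if keys:
                d = extra_cols[i] if extra_cols else {}
                fh.write("\t" + "\t".join(str(d.get(k, "")) for k in keys))
            fh.write("\n")
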