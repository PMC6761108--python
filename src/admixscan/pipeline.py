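"""End-to-end driver: QC -> ancestry scan -> inversion genotyping ->
stratified rescans -> selection statistics -> FCS -> Procrustes.

The configuration (a plain dict, usually loaded from YAML) names either
input files or a simulation block. One global seed drives every stochastic
stage through deterministic per-stage child seeds, so a run is
reproducible bit for bit.
"""

from __future__ import annotations

import os
from dataclasses import replace

import numpy as np
import pandas as pd

from . import io as aio
from .ancestry import (
    ancestry_proportions,
    deviation_scan,
    global_local_concordance,
    individual_mean_ancestry,
    stratified_scan,
    tract_posterior_audit,
    DEVIATION_SD,
)
from .fcs import combine_tracks, label_regions
from .qc import (
    apply_site_filters,
    greedy_relatedness_prune,
    heterozygosity_outliers,
)
from .selstats import STAT_NAMES, interpop_scan, intrapop_scan, pbs_track
from .sim import (
    ChromSpec,
    DeviationSpec,
    InversionSpec,
    SimConfig,
    child_rng,
    genetic_map_for,
    simulate_study,
)
from .structure import (
    classical_mds,
    em_inversion_genotypes,
    ibs_matrix,
    procrustes_protest,
    sample_random_regions,
)
from .types import AncestryCalls, RegionInterval


def _region_from(block: dict) -> RegionInterval:
    return RegionInterval(str(block["chrom"]), int(block["start_bp"]), int(block["end_bp"]))


def sim_config_from_dict(block: dict, seed: int) -> SimConfig:
    kwargs: dict = {"seed": seed}
    for key in (
        "cohort_size", "panel_haplotypes", "generations", "founders",
        "founder_switch_rate", "ambiguous_fraction",
    ):
        if key in block:
            kwargs[key] = block[key]
    if "admixture" in block:
        kwargs["admixture"] = tuple(block["admixture"])
    if "drift" in block:
        kwargs["drift"] = tuple(block["drift"])
    if "chromosomes" in block:
        kwargs["chromosomes"] = tuple(
            ChromSpec(
                str(c["label"]), int(c["length_bp"]),
                float(c["length_cm"]), int(c["n_snps"]),
            )
            for c in block["chromosomes"]
        )
    if "deviation" in block:
        d = block["deviation"]
        kwargs["deviation"] = DeviationSpec(
            _region_from(d), tuple(d["target_props"])
        )
    if "inversion" in block:
        v = block["inversion"]
        kwargs["inversion"] = InversionSpec(
            _region_from(v),
            tuple(v["class_freqs"]),
            float(v.get("divergence", 0.3)),
            float(v.get("within_class_flip", 0.02)),
        )
    return SimConfig(**kwargs)


def _load_inputs(config: dict):
    inp = config["inputs"]
    if "genetic_map" not in inp:
        raise ValueError("config missing genetic map")
    gmap = aio.read_genetic_map(inp["genetic_map"])
    cohort = aio.parse_phased_vcf(inp["vcf"])
    calls = aio.read_ancestry_calls(
        inp["ancestry_calls"], cohort.snps, inp.get("posteriors")
    )
    panels = {}
    for label, path in inp.get("panels", {}).items():
        panels[label] = aio.parse_phased_vcf(path)
    # consistency before any stage runs
    for name, other in [("ancestry calls", calls)] + [
        (f"panel {k}", v) for k, v in panels.items()
    ]:
        if other.n_snps != cohort.n_snps:
            raise ValueError(f"inconsistent SNP sets: cohort vs {name}")
    # stamp genetic positions onto the cohort SNPs
    snps = [
        replace(s, cm=float(gmap.cm_at(s.chrom, s.pos))) for s in cohort.snps
    ]
    cohort.snps = snps
    for p in panels.values():
        p.snps = snps
    calls.snps = snps
    truth = None
    return panels, cohort, calls, truth, gmap


def run_pipeline(config: dict, out_dir: str) -> dict:
    """Run every stage and emit the report bundle under ``out_dir``.

    Returns a dict of in-memory results keyed by stage.
    """
    os.makedirs(out_dir, exist_ok=True)
    seed = int(config.get("seed", 0))
    report: dict = {"seed": seed}

    # ---- inputs ---------------------------------------------------------
    if "simulate" in config:
        sim_cfg = sim_config_from_dict(config["simulate"], seed)
        panels, cohort, calls, truth, gmap = (
            *simulate_study(sim_cfg), genetic_map_for(sim_cfg),
        )
        pop_labels = sim_cfg.pop_labels
    elif "inputs" in config:
        panels, cohort, calls, truth, gmap = _load_inputs(config)
        pop_labels = tuple(calls.ancestries)
    else:
        raise ValueError("config needs a 'simulate' or an 'inputs' block")

    # ---- QC -------------------------------------------------------------
    kept, ledger = apply_site_filters(
        cohort,
        hwe_p=float(config.get("qc", {}).get("hwe_p", 0.01)),
        maf_min=float(config.get("qc", {}).get("maf_min", 0.01)),
    )
    het_flagged, het_mean, het_sd = heterozygosity_outliers(cohort)
    for i in het_flagged:
        ledger.individual_removals.append(
            (cohort.individual_ids[i], "heterozygosity outlier")
        )
    dos = cohort.dosages().astype(float)
    ibs_all = ibs_matrix(dos).values
    # greedy GRM pruning needs a long genome for the 0.125 threshold to
    # exceed estimation noise; it is opt-in (qc.relatedness_threshold),
    # while IBS duplicate removal always runs
    rel_thr = config.get("qc", {}).get("relatedness_threshold")
    if rel_thr is not None:
        p_hat = dos.mean(axis=0) / 2.0
        ok = (p_hat > 0) & (p_hat < 1)
        z = (dos[:, ok] - 2 * p_hat[ok]) / np.sqrt(
            2 * p_hat[ok] * (1 - p_hat[ok])
        )
        grm = z @ z.T / ok.sum()
        _, rel_removed = greedy_relatedness_prune(
            grm, rel_threshold=float(rel_thr), ibs=ibs_all
        )
    else:
        zero = np.zeros_like(ibs_all)
        np.fill_diagonal(zero, 1.0)
        _, rel_removed = greedy_relatedness_prune(zero, ibs=ibs_all)
    for i, reason in rel_removed:
        ledger.individual_removals.append((cohort.individual_ids[i], reason))
    drop = set(het_flagged) | {i for i, _ in rel_removed}
    kept_ind = [i for i in range(cohort.n_individuals) if i not in drop]

    cohort = cohort.subset_individuals(kept_ind).subset_snps(kept)
    hap_rows = np.array([[2 * i, 2 * i + 1] for i in kept_ind]).ravel()
    calls_full = calls  # pre-QC calls keep the original tract posteriors
    calls = AncestryCalls.from_matrix(
        calls.codes[hap_rows][:, kept], calls.ancestries, snps=cohort.snps
    )
    panels = {k: p.subset_snps(kept) for k, p in panels.items()}
    pd.DataFrame(ledger.to_rows(), columns=["category", "count"]).to_csv(
        os.path.join(out_dir, "qc_ledger.tsv"), sep="\t", index=False
    )
    report["qc"] = ledger

    chroms = cohort.chromosomes
    pos = cohort.positions

    # ---- ancestry scan --------------------------------------------------
    track = ancestry_proportions(calls)
    scan = deviation_scan(track, float(config.get("deviation_sd", DEVIATION_SD)))
    props_df = pd.DataFrame(
        {"chrom": chroms, "pos": pos}
        | {a: track.props[i] for i, a in enumerate(track.ancestries)}
    )
    props_df.to_csv(os.path.join(out_dir, "ancestry_props.tsv"), sep="\t", index=False)
    aio.write_regions(
        [iv.region for iv in scan.intervals],
        os.path.join(out_dir, "deviation_calls.tsv"),
        [
            {"ancestry": iv.ancestry, "direction": iv.direction,
             "n_snps": iv.n_snps, "peak_z": f"{iv.peak_z:.3f}"}
            for iv in scan.intervals
        ],
    )
    report["deviation_scan"] = scan

    audits = []
    for iv in scan.intervals:
        n_tr, n_below = tract_posterior_audit(calls_full, iv.region)
        audits.append((iv.region, iv.ancestry, n_tr, n_below))
    report["posterior_audit"] = audits

    local = individual_mean_ancestry(calls)
    if truth is not None:
        glob = individual_mean_ancestry(
            truth.cohort_calls(pop_labels).subset_haplotypes(hap_rows)
        )
    else:
        glob = local
    conc = global_local_concordance(local, glob)
    pd.DataFrame({"ancestry": list(track.ancestries), "pearson_r": conc}).to_csv(
        os.path.join(out_dir, "concordance.tsv"), sep="\t", index=False
    )
    report["concordance"] = conc

    # ---- inversion genotyping -------------------------------------------
    inv_region = None
    if "simulate" in config and sim_cfg.inversion is not None:
        inv_region = sim_cfg.inversion.region
    elif "inversion_region" in config:
        inv_region = _region_from(config["inversion_region"])
    inv = None
    if inv_region is not None:
        idx = cohort.snp_indices(inv_region)
        ibs = ibs_matrix(cohort.dosages()[:, idx].astype(float))
        emb = classical_mds(1.0 - ibs.values, k=2)
        inv = em_inversion_genotypes(emb, axes=1)
        pd.DataFrame(
            {
                "individual": cohort.individual_ids,
                "call": inv.calls,
                "p_NINI": inv.posteriors[:, 0],
                "p_NII": inv.posteriors[:, 1],
                "p_II": inv.posteriors[:, 2],
            }
        ).to_csv(
            os.path.join(out_dir, "inversion_genotypes.tsv"), sep="\t", index=False
        )
    report["inversion"] = inv

    # ---- stratified ancestry rescans ------------------------------------
    strat_scans = {}
    if inv is not None:
        for stratum in ("NI/NI", "I/I"):
            try:
                s = stratified_scan(calls, inv.dosage, stratum, scan.threshold_sd)
            except ValueError:
                continue
            strat_scans[stratum] = s
            tag = stratum.replace("/", "")
            aio.write_regions(
                [iv.region for iv in s.intervals],
                os.path.join(out_dir, f"deviation_calls_{tag}.tsv"),
                [
                    {"ancestry": iv.ancestry, "direction": iv.direction,
                     "n_snps": iv.n_snps, "peak_z": f"{iv.peak_z:.3f}"}
                    for iv in s.intervals
                ],
            )
    report["stratified_scans"] = strat_scans

    # ---- selection statistics + FCS -------------------------------------
    intra = intrapop_scan(cohort, config_label="target")
    target_cache: dict = {}
    per_config = {}
    fcs_results = {}
    labels = list(pop_labels)
    for i, label in enumerate(labels):
        inter = interpop_scan(
            cohort, panels[label], config_label=label, target_cache=target_cache
        )
        outgroup = panels[labels[(i + 1) % len(labels)]]
        track_pbs = pbs_track(cohort, panels[label], outgroup, config_label=label)
        tracks = [
            intra["|iHS|"], intra["|diHH|"],
            inter["|diHH_derived|"], inter["XP-EHH"], track_pbs,
        ]
        per_config[label] = tracks
        p, res = combine_tracks(tracks, chroms, pos)
        fcs_results[label] = res
        df = pd.DataFrame({"chrom": chroms, "pos": pos, "fcs": res.fcs,
                           "outlier": res.outlier})
        for t, name in zip(tracks, STAT_NAMES):
            df[f"std {name}"] = t.standardized
        df.to_csv(
            os.path.join(out_dir, f"fcs_{label}.tsv"), sep="\t", index=False
        )
        pd.DataFrame(
            [
                (b.chrom, b.start_bp, b.end_bp, b.size, b.outlier_prop, b.called)
                for b in res.blocks
            ],
            columns=["chrom", "start_bp", "end_bp", "n_snps", "outlier_prop", "called"],
        ).to_csv(os.path.join(out_dir, f"blocks_{label}.tsv"), sep="\t", index=False)
    report["stat_tracks"] = per_config
    report["fcs"] = fcs_results

    labelled = label_regions(fcs_results)
    aio.write_regions(
        [r for r, _ in labelled],
        os.path.join(out_dir, "regions_labelled.tsv"),
        [{"ancestry_label": lab} for _, lab in labelled],
        header_note=(
            "ancestry labels attribute a block to the reference "
            "configuration(s) whose scan called it (interpretive rule)"
        ),
    )
    report["labelled_regions"] = labelled

    # ---- Procrustes corroboration ---------------------------------------
    proc_rows = []
    if inv_region is not None:
        idx = cohort.snp_indices(inv_region)
        base_emb = classical_mds(
            1.0 - ibs_matrix(cohort.dosages()[:, idx].astype(float)).values, k=2
        )
        n_perm = int(config.get("procrustes_permutations", 10_000))
        n_rand = int(config.get("n_random_regions", 7))
        rand_seed = int(child_rng(seed, "procrustes").integers(2 ** 31))
        length = inv_region.end_bp - inv_region.start_bp
        regions = sample_random_regions(
            cohort.snps, length, n=n_rand, exclude=inv_region, seed=rand_seed
        )
        for k, region in enumerate(regions):
            ridx = cohort.snp_indices(region)
            if ridx.size < 2:
                continue
            emb = classical_mds(
                1.0 - ibs_matrix(cohort.dosages()[:, ridx].astype(float)).values, k=2
            )
            res = procrustes_protest(
                base_emb.coords, emb.coords, n_perm=n_perm,
                seed=int(child_rng(seed, f"protest{k}").integers(2 ** 31)),
            )
            proc_rows.append(
                (region.chrom, region.start_bp, region.end_bp,
                 res.correlation, res.p_value, res.n_permutations)
            )
        pd.DataFrame(
            proc_rows,
            columns=["chrom", "start_bp", "end_bp", "correlation", "p", "n_perm"],
        ).to_csv(os.path.join(out_dir, "procrustes.tsv"), sep="\t", index=False)
    report["procrustes"] = proc_rows
    return report
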