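"""Run every stage of the scan on one synthetic study.

QC -> ancestry deviation scan -> inversion genotyping -> stratified
rescans -> five selection statistics per reference configuration -> FCS
with block calling -> Procrustes corroboration, all driven by one config
dict and one seed; outputs land as TSV tables in ./pipeline_out.
"""

import collections

import admixscan as a

config = {
    "seed": 11,
    "procrustes_permutations": 999,
    "n_random_regions": 3,
    "simulate": {
        "cohort_size": 60,
        "panel_haplotypes": 40,
        "chromosomes": [
            {"label": "1", "length_bp": 12_000_000, "length_cm": 12.0,
             "n_snps": 700},
            {"label": "2", "length_bp": 12_000_000, "length_cm": 12.0,
             "n_snps": 700},
        ],
        "deviation": {"chrom": "1", "start_bp": 4_700_000,
                      "end_bp": 5_300_000, "target_props": [0.1, 0.1, 0.8]},
        "inversion": {"chrom": "2", "start_bp": 5_000_000,
                      "end_bp": 8_000_000, "class_freqs": [0.25, 0.5, 0.05]},
    },
}

report = a.run_pipeline(config, "pipeline_out")

ledger = report["qc"]
print(f"QC: {ledger.remaining}/{ledger.starting_count} SNPs kept; "
      f"{len(ledger.individual_removals)} individuals removed")
for iv in report["deviation_scan"].intervals:
    r = iv.region
    print(f"deviation: chr{r.chrom}:{r.start_bp}-{r.end_bp} {iv.ancestry} "
          f"{iv.direction} (peak |z| {iv.peak_z:.1f})")
inv = report["inversion"]
print("inversion genotypes:", dict(collections.Counter(inv.calls)))
print("labelled selection regions:", report["labelled_regions"] or "none")
print("outputs: see ./pipeline_out/*.tsv")
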