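#!/usr/bin/env python
"""Filtered nucleotide diversity in 10-kb windows and sex-linked ratios.

Reads the cohort VCF, applies the biallelic / hemizygosity / depth
filters, averages per-site pi in 10,000-bp nonoverlapping windows (per-bp
denominator), and compares each sex-linked compartment to the autosome
against the neutral expectations (Y: 25%, X: 75% of autosomal diversity).
"""

import json
from pathlib import Path

import pandas as pd

from regmk.diversity import (
    RegionClass,
    chromosome_pi,
    diversity_ratio,
    filter_genotypes,
    read_vcf_sites,
    windowed_pi,
)

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "sim"

CHROM_LENGTHS = {"chrX": 300_000, "chrY": 300_000, "chrA": 120_000}


def main() -> None:
    sites = read_vcf_sites(
        SIM / "genotypes.vcf",
        {"chrX": RegionClass.X_NONCROSSOVER, "chrY": RegionClass.Y_NONCROSSOVER,
         "chrA": RegionClass.AUTOSOME},
    )
    kept, tallies = filter_genotypes(sites)
    print(f"{len(sites)} sites read, {len(kept)} retained "
          f"(dropped by reason: {dict(tallies)})")

    windows_all = []
    pi = {}
    for chrom, length in CHROM_LENGTHS.items():
        chrom_sites = [s for s in kept if s.chrom == chrom]
        table = windowed_pi(chrom_sites, length, window=10_000, denominator="length")
        table.insert(0, "chrom", chrom)
        windows_all.append(table)
        pi[chrom] = chromosome_pi(table, include_empty=True)
    windows = pd.concat(windows_all, ignore_index=True)
    out = ROOT / "results" / "diversity_windows.tsv"
    windows.to_csv(out, sep="\t", index=False, float_format="%.3e")

    ratio_y, dev_y = diversity_ratio(pi["chrY"], pi["chrA"], "Y")
    ratio_x, dev_x = diversity_ratio(pi["chrX"], pi["chrA"], "X")
    summary = {
        "pi": {k: round(v, 6) for k, v in pi.items()},
        "ratio_Y_over_auto": round(ratio_y, 4),
        "deviation_from_25pct": round(dev_y, 4),
        "ratio_X_over_auto": round(ratio_x, 4),
        "deviation_from_75pct": round(dev_x, 4),
    }
    (ROOT / "results" / "diversity_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n"
    )
    print(f"pi per bp: " + ", ".join(f"{k} {v:.6f}" for k, v in pi.items()))
    print(f"Y/autosome ratio {ratio_y:.3f} (neutral expectation 0.25, deviation {dev_y:+.3f})")
    print(f"X/autosome ratio {ratio_x:.3f} (neutral expectation 0.75, deviation {dev_x:+.3f})")
    print(f"written to {out}")


if __name__ == "__main__":
    main()
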