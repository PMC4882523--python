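#!/usr/bin/env python
"""Quality control on the simulated genotypes.

Applies the three SNP filters (minor allele frequency > 0.01, per-SNP
missing rate < 0.05, autosomes only) and reports how many SNPs each
criterion removed.  Writes the QC report and the filtered PED/MAP under
results/qc.
"""

import argparse
from pathlib import Path

from sweepscan import read_plink, write_plink
from sweepscan.pipeline import run_qc


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    sim = args.results / "sim"
    if not (sim / "manifest.txt").exists():
        raise SystemExit("run analysis/01_simulate.py first (no complete bundle found)")
    g = read_plink(sim / "genotypes.ped", sim / "genotypes.map")
    filtered, report = run_qc(g, args.results / "qc")
    write_plink(filtered, args.results / "qc" / "genotypes_qc.ped",
                args.results / "qc" / "genotypes_qc.map")
    print(f"input SNPs:            {report.n_input}")
    print(f"removed (MAF <= 0.01): {report.removed_maf}")
    print(f"removed (missing):     {report.removed_missing}")
    print(f"removed (chromosome):  {report.removed_chrom}")
    print(f"retained:              {report.n_retained}")


if __name__ == "__main__":
    main()
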