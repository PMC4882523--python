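#!/usr/bin/env python
"""Candidate-SNP association with haematological traits.

For the strongest candidate SNPs: allele-frequency chi-squared contrasts
between the highland and lowland groups; for the top candidate within the
highland group, a general linear model of each trait on genotype with sex as
covariate, adjusted (least-squares) means and Fisher's LSD post-hoc
contrasts; and Welch comparisons of every trait between the groups, overall
and stratified by sex.
"""

import argparse
from pathlib import Path

import pandas as pd

from sweepscan import PopulationMap, read_plink
from sweepscan.pipeline import run_association


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--top", type=int, default=5, help="candidate SNPs to test")
    args = ap.parse_args()

    sim, qc, scan = args.results / "sim", args.results / "qc", args.results / "scan"
    if not (scan / "candidate_snps.tsv").exists():
        raise SystemExit("run analysis/04_selection_scan.py first")
    g = read_plink(qc / "genotypes_qc.ped", qc / "genotypes_qc.map")
    pm = PopulationMap.from_tsv(sim / "popmap.tsv")
    ph = pd.read_csv(sim / "phenotypes.tsv", sep="\t")
    ph.columns = [c.lstrip("#") for c in ph.columns]
    cands = pd.read_csv(scan / "candidate_snps.tsv", sep="\t", comment="#")
    vids = cands.sort_values("theta", ascending=False).vid.head(args.top).tolist()

    res = run_association(g, pm, ph, vids, args.results / "assoc")
    print("allele-frequency chi-squared (G1 vs G2):")
    print(res["chisq"].to_string(index=False))
    if len(res["glm"]):
        print("\nGLM (sex covariate) at the top candidate, highland group:")
        cols = [c for c in res["glm"].columns if not c.startswith("df")]
        print(res["glm"][cols].to_string(index=False))
    print("\nhighland vs lowland trait contrasts (Welch, overall stratum):")
    overall = res["group_compare"].query("stratum == 'overall'")
    print(overall.to_string(index=False))


if __name__ == "__main__":
    main()
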