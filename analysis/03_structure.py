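#!/usr/bin/env python
"""Population structure of the simulated breeds.

LD-prunes the QC-passing SNPs (25-SNP windows, step 5, r^2 <= 0.05),
computes identity-by-state distances and classical MDS, per-breed nucleotide
diversity, the pairwise multi-locus F_ST matrix between breeds and a
neighbor-joining tree from it.  Expects the highland and lowland groups to
separate on MDS component 1 and to fall on distinct branches of the tree.
"""

import argparse
from pathlib import Path

from sweepscan import PopulationMap, read_plink
from sweepscan.pipeline import run_structure


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    qc = args.results / "qc"
    if not (qc / "genotypes_qc.ped").exists():
        raise SystemExit("run analysis/02_qc.py first")
    g = read_plink(qc / "genotypes_qc.ped", qc / "genotypes_qc.map")
    pm = PopulationMap.from_tsv(args.results / "sim" / "popmap.tsv")
    res = run_structure(g, pm, args.results / "structure")

    print(f"LD pruning kept {res['n_pruned']} of {g.n_variants} SNPs")
    mds = res["mds"]
    c1_g1 = mds.C1[mds.group == "G1"]
    c1_g2 = mds.C1[mds.group == "G2"]
    sep = c1_g1.max() < c1_g2.min() or c1_g2.max() < c1_g1.min()
    print(f"MDS component 1 separates G1/G2: {sep}")
    print("per-breed diversity (per-SNP heterozygosity):")
    print(res["diversity"].to_string(index=False))
    print("NJ tree:", res["tree"].newick())


if __name__ == "__main__":
    main()
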