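"""High-level pipeline stages shared by the CLI, the analysis drivers and the
acceptance script.  Each stage is deterministic given its inputs and writes
diff-able TSV artifacts."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, selection, structure
from .genotype_io import (
    GenotypeMatrix,
    HaplotypeSet,
    PopulationMap,
    QcConfig,
    apply_qc,
)
from .selection import CandidateSet, ScanConfig
from .structure import PruneConfig

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


def write_tsv(df: pd.DataFrame, path, title: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#{title}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def run_structure(g: GenotypeMatrix, pm: PopulationMap, out_dir,
                  prune_cfg: PruneConfig | None = None, mds_k: int = 2) -> dict:
    """LD pruning, IBS/MDS, per-breed diversity, pairwise F_ST and NJ tree."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prune_cfg = prune_cfg or PruneConfig()

    kept = structure.ld_prune(g, prune_cfg)
    log.info("LD pruning retained %d of %d SNPs", len(kept), g.n_variants)
    with open(out / "pruned_snps.txt", "w") as fh:
        for i in kept:
            fh.write(g.vids[i] + "\n")
    pruned = g.take_variants(kept)

    ibs = structure.ibs_distance(pruned)
    ibs.to_tsv(out / "ibs_distance.tsv")
    coords = structure.classical_mds(ibs, k=mds_k)
    mds = pd.DataFrame(coords, columns=[f"C{i+1}" for i in range(mds_k)])
    mds.insert(0, "sample", pruned.samples)
    mds.insert(1, "group", [pm.group_of(s) for s in pruned.samples])
    write_tsv(mds, out / "mds_coordinates.tsv", "mds coordinates")

    diversity = structure.nucleotide_diversity(g, pm)
    write_tsv(diversity, out / "nucleotide_diversity.tsv", "per-breed nucleotide diversity")

    fst_breeds = structure.pairwise_fst_matrix(g, pm)
    fst_breeds.to_tsv(out / "pairwise_fst.tsv")
    tree = structure.neighbor_joining(fst_breeds)
    (out / "nj_tree.nwk").write_text(tree.newick() + "\n")

    return {"pruned": pruned, "n_pruned": len(kept), "ibs": ibs, "mds": mds,
            "diversity": diversity, "fst_breeds": fst_breeds, "tree": tree}


def run_scan(g: GenotypeMatrix, pm: PopulationMap, hap_obs: HaplotypeSet,
             hap_ref: HaplotypeSet, genes: pd.DataFrame | None, out_dir,
             cfg: ScanConfig | None = None) -> dict:
    """F_ST + XP-EHH scan, tail thresholds, intersection/rescue candidates
    and gene annotation.  Haplotype sets must cover the scan SNP universe."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = cfg or ScanConfig()

    fst = selection.fst_scan(g, pm)
    # restrict haplotypes to the genotype SNP universe (e.g. after QC)
    hap_vids = {v.vid: i for i, v in enumerate(hap_obs.variants)}
    idx = [hap_vids[v] for v in g.vids if v in hap_vids]
    if len(idx) != g.n_variants:
        raise ValueError("haplotype sets do not cover the scan SNP universe")
    xp = selection.xpehh_scan(hap_obs.take_variants(idx), hap_ref.take_variants(idx), cfg)

    scan = fst.merge(xp[["vid", "ihh_obs", "ihh_ref", "xpehh_raw", "xpehh_std",
                         "xpehh_defined"]], on="vid")
    fst_sel, fst_thr = selection.top_quantile(
        scan.theta.to_numpy(), cfg.fst_quantile, scan.fst_defined.to_numpy())
    xp_sel, xp_thr = selection.top_quantile(
        scan.xpehh_std.to_numpy(), cfg.xpehh_quantile, scan.xpehh_defined.to_numpy())
    cand = selection.build_candidates(fst_sel, xp_sel, scan.xpehh_defined.to_numpy())
    log.info(
        "scan: %d SNPs; F_ST top %.0f%% -> %d SNPs (theta > %.3f); "
        "XP-EHH top %.0f%% -> %d SNPs (std > %.3f); intersect %d, rescue %d",
        len(scan), 100 * cfg.fst_quantile, len(fst_sel), fst_thr,
        100 * cfg.xpehh_quantile, len(xp_sel), xp_thr,
        len(cand.intersect), len(cand.rescue),
    )

    scan["fst_tail"] = False
    scan.loc[fst_sel, "fst_tail"] = True
    scan["xpehh_tail"] = False
    scan.loc[xp_sel, "xpehh_tail"] = True
    scan["candidate"] = ""
    scan.loc[cand.intersect, "candidate"] = "intersect"
    scan.loc[cand.rescue, "candidate"] = "rescue"
    write_tsv(scan, out / "scan_table.tsv", "per-SNP selection scan")

    cand_snps = scan.iloc[cand.union][["chrom", "pos", "vid", "theta", "xpehh_std",
                                       "candidate"]]
    write_tsv(cand_snps, out / "candidate_snps.tsv", "candidate SNPs")

    gene_hits = pd.DataFrame()
    if genes is not None and len(cand.union):
        gene_hits = selection.annotate_genes(
            scan.iloc[cand.union], genes, flank_bp=cfg.gene_flank_bp)
        write_tsv(gene_hits, out / "candidate_genes.tsv", "candidate genes")

    thresholds = pd.DataFrame(
        [
            {"statistic": "fst_theta", "tail_fraction": cfg.fst_quantile,
             "threshold": fst_thr, "n_selected": len(fst_sel)},
            {"statistic": "xpehh_std", "tail_fraction": cfg.xpehh_quantile,
             "threshold": xp_thr, "n_selected": len(xp_sel)},
        ]
    )
    write_tsv(thresholds, out / "thresholds.tsv", "tail thresholds")

    return {"scan": scan, "fst_sel": fst_sel, "fst_thr": fst_thr,
            "xp_sel": xp_sel, "xp_thr": xp_thr, "candidates": cand,
            "genes": gene_hits}


def run_association(g: GenotypeMatrix, pm: PopulationMap, phenotypes: pd.DataFrame,
                    candidate_vids: list[str], out_dir) -> dict:
    """Allele chi-squared per candidate SNP, GLM + LSD for the top candidate,
    and Welch group contrasts per trait."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    from .genotype_io import group_stats

    n1, p1, _ = group_stats(g, pm, "G1")
    n2, p2, _ = group_stats(g, pm, "G2")
    vid_index = {v: i for i, v in enumerate(g.vids)}
    chi_rows = []
    for vid in candidate_vids:
        j = vid_index[vid]
        a1 = round(2 * n1[j] * p1[j])
        a2 = round(2 * n2[j] * p2[j])
        res = association.allele_chisq(
            (2 * n1[j] - a1, a1), (2 * n2[j] - a2, a2))
        chi_rows.append({"vid": vid, "chi2": res.chi2, "p": res.p,
                         "defined": res.defined})
    chisq = pd.DataFrame(chi_rows)
    if len(chisq):
        write_tsv(chisq, out / "allele_chisq.tsv", "allele-frequency chi-squared")

    glm_rows, lsd_frames = [], []
    if candidate_vids:
        # genotype-trait models at the top candidate, highland samples only
        top = candidate_vids[0]
        high = g.take_samples(pm.samples_in_group("G1"))
        calls = association.dosage_to_calls(high, top)
        ph = phenotypes[phenotypes["sample"].isin(high.samples)]
        for trait in association.TRAITS:
            try:
                res = association.glm_association(ph, calls, trait)
            except Exception as exc:  # e.g. a genotype class too small
                log.info("glm for %s on %s skipped: %s", top, trait, exc)
                continue
            glm_rows.append({
                "vid": top, "trait": trait, "F": res.f_stat, "p": res.p_value,
                "df_num": res.df_num, "df_resid": res.df_resid,
                **{f"mean_{k}": v for k, v in res.adjusted_means.items()},
            })
            lsd = association.lsd_posthoc(res)
            lsd.insert(0, "trait", trait)
            lsd.insert(0, "vid", top)
            lsd_frames.append(lsd)
    glm = pd.DataFrame(glm_rows)
    if len(glm):
        write_tsv(glm, out / "glm_association.tsv", "genotype-trait GLM (sex covariate)")
    if lsd_frames:
        write_tsv(pd.concat(lsd_frames, ignore_index=True), out / "lsd_posthoc.tsv",
                  "Fisher LSD pairwise contrasts")

    ph_high = phenotypes[[pm.group_of(s) == "G1" for s in phenotypes["sample"]]]
    ph_low = phenotypes[[pm.group_of(s) == "G2" for s in phenotypes["sample"]]]
    cmp_rows = []
    for trait in association.TRAITS:
        res = association.group_trait_compare(ph_high, ph_low, trait)
        for stratum, vals in res.items():
            cmp_rows.append({"trait": trait, "stratum": stratum, **vals})
    group_cmp = pd.DataFrame(cmp_rows)
    write_tsv(group_cmp, out / "group_trait_compare.tsv",
              "highland vs lowland trait comparison (Welch)")

    return {"chisq": chisq, "glm": glm, "group_compare": group_cmp}


def run_qc(g: GenotypeMatrix, out_dir, cfg: QcConfig | None = None):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    filtered, report = apply_qc(g, cfg or QcConfig())
    report.to_tsv(out / "qc_report.tsv")
    log.info("QC: retained %d of %d SNPs", report.n_retained, report.n_input)
    return filtered, report
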