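"""Synthetic two-group SNP-array data with the structure the scan assumes.

Population allele frequencies follow the Balding-Nichols model: each group's
frequency at a SNP is Beta(p(1-F)/F, (1-p)(1-F)/F) around an ancestral
p ~ Uniform(0.05, 0.95), with F the background differentiation.  Haplotypes
are drawn SNP-wise from the group frequencies through a first-order latent
copying process (adjacent-SNP correlation rho) that creates baseline LD.  A
selective sweep is modelled mechanically: the haplotypes carrying the alt
allele at the core SNP (whose group-1 frequency is overridden to the sweep's
final frequency) all share one donor haplotype across the sweep span, which
guarantees the long-homozygosity signature XP-EHH must detect.

Phenotypes carry an additive genotype effect at the causal SNP (positive on
RBC, negative on MCV and MCH), a group (altitude) shift, a sex effect and
Gaussian noise, all expressed in units of each trait's nominal within-group
standard deviation.

Every generator is a pure function of the config (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    HaplotypeSet,
    PopulationMap,
    VariantRecord,
    write_plink,
    write_vcf,
)

# Nominal haematology for adult sheep: baseline and within-group sd per trait.
TRAIT_BASELINES = {"RBC": 9.5, "HGB": 110.0, "HCT": 0.33, "MCV": 34.0,
                   "MCH": 11.0, "MCHC": 330.0}
TRAIT_UNITS = {"RBC": 1.2, "HGB": 8.0, "HCT": 0.03, "MCV": 2.5,
               "MCH": 0.9, "MCHC": 9.0}
# direction of the per-copy genotype effect (alt allele) per trait
GENO_SIGNS = {"RBC": 1.0, "HGB": 0.0, "HCT": 0.0, "MCV": -1.0, "MCH": -1.0, "MCHC": 0.0}
# direction of the highland-group shift per trait (MCHC deliberately flat)
GROUP_SIGNS = {"RBC": 1.0, "HGB": 1.0, "HCT": 1.0, "MCV": 1.0, "MCH": 1.0, "MCHC": 0.0}


@dataclass(frozen=True)
class SweepSpec:
    chrom: str = "1"
    pos: int = 25_000_000
    freq: float = 0.9
    span_bp: int = 400_000

    def __post_init__(self):
        if not 0.0 < self.freq <= 1.0:
            raise ConfigError(f"sweep frequency must be in (0, 1], got {self.freq}")
        if self.span_bp < 1:
            raise ConfigError("sweep span must be positive")


@dataclass
class SimConfig:
    """Study-scale defaults: two groups of 40 diploids, 10k SNPs on three
    50-Mb chromosomes, background F = 0.08, one sweep to frequency 0.9."""

    n_g1: int = 40
    n_g2: int = 40
    n_snps: int = 10_000
    chrom_lengths: dict = field(default_factory=lambda: {"1": 50_000_000,
                                                         "2": 50_000_000,
                                                         "3": 50_000_000})
    fst_background: float = 0.08
    sweep: SweepSpec | None = field(default_factory=SweepSpec)
    rho: float = 0.3
    missing_rate: float = 0.02
    phenotype_effect: float = 1.0
    group_effect: float = 1.0
    sex_effect: float = 0.5
    noise_sd: float = 1.0
    seed: int = 0
    breeds_g1: tuple = ("TIBQ", "TIBS", "TIBN")
    breeds_g2: tuple = ("HUS", "TON", "LTH", "LOP")

    def __post_init__(self):
        if min(self.n_g1, self.n_g2, self.n_snps) < 1:
            raise ConfigError("sample and SNP counts must be positive")
        if not 0.0 < self.fst_background < 1.0:
            raise ConfigError(f"fst_background must be in (0, 1), got {self.fst_background}")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigError(f"rho must be in [0, 1), got {self.rho}")
        if self.sweep is not None:
            if self.sweep.chrom not in self.chrom_lengths:
                raise ConfigError(f"sweep chromosome {self.sweep.chrom!r} not simulated")
            if self.sweep.span_bp > self.chrom_lengths[self.sweep.chrom]:
                raise ValidationError("sweep span exceeds chromosome length")


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


def simulate_frequencies(cfg: SimConfig) -> pd.DataFrame:
    """SNP map with ancestral and per-group allele frequencies.

    Returns a frame (chrom, pos, vid, p_anc, p_g1, p_g2, sweep_core); the
    sweep core is the SNP nearest the configured sweep position, with its
    group-1 frequency overridden to the sweep's final frequency.
    """
    rng = _rng(cfg, 1)
    chroms = sorted(cfg.chrom_lengths, key=lambda c: (len(c), c))
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    counts = np.maximum(1, np.round(cfg.n_snps * lengths / lengths.sum()).astype(int))
    # adjust rounding drift on the last chromosome
    counts[-1] += cfg.n_snps - counts.sum()

    rows = []
    for c, cnt in zip(chroms, counts):
        length = cfg.chrom_lengths[c]
        # draw unique positions without materializing the whole range
        pool = np.unique(rng.integers(1, length + 1, size=2 * cnt + 16))
        while pool.size < cnt:
            pool = np.unique(np.concatenate(
                [pool, rng.integers(1, length + 1, size=2 * cnt + 16)]))
        pos = np.sort(pool[rng.permutation(pool.size)[:cnt]])
        for p in pos:
            rows.append((c, int(p)))
    df = pd.DataFrame(rows, columns=["chrom", "pos"])
    df["vid"] = [f"snp_{c}_{p}" for c, p in zip(df.chrom, df.pos)]

    m = len(df)
    p_anc = rng.uniform(0.05, 0.95, size=m)
    f = cfg.fst_background
    shape1 = p_anc * (1.0 - f) / f
    shape2 = (1.0 - p_anc) * (1.0 - f) / f
    p_g1 = rng.beta(shape1, shape2)
    p_g2 = rng.beta(shape1, shape2)

    df["p_anc"] = p_anc
    df["p_g1"] = p_g1
    df["p_g2"] = p_g2
    df["sweep_core"] = False
    if cfg.sweep is not None:
        on = df.chrom == cfg.sweep.chrom
        core = (df.pos[on] - cfg.sweep.pos).abs().idxmin()
        df.loc[core, "p_g1"] = cfg.sweep.freq
        df.loc[core, "sweep_core"] = True
    return df


def make_population(cfg: SimConfig) -> tuple[list[str], list[str], PopulationMap]:
    """Sample names and breed/group assignments (breeds split evenly within
    each group, emulating a multi-breed two-group design)."""

    def names_for(n, breeds, group):
        out, assign = [], {}
        base = n // len(breeds)
        extra = n % len(breeds)
        k = 0
        for bi, breed in enumerate(breeds):
            cnt = base + (1 if bi < extra else 0)
            for _ in range(cnt):
                s = f"{breed}_{k:03d}"
                out.append(s)
                assign[s] = (breed, group)
                k += 1
        return out, assign

    g1, a1 = names_for(cfg.n_g1, cfg.breeds_g1, "G1")
    g2, a2 = names_for(cfg.n_g2, cfg.breeds_g2, "G2")
    return g1, g2, PopulationMap({**a1, **a2})


def _draw_group_haplotypes(rng, n_hap, freqs, chrom_codes, rho):
    """Latent-uniform copying: u_j is fresh with prob 1-rho else copied from
    the previous SNP; allele_j = (u_j < p_j).  Chromosome starts are fresh."""
    m = freqs.size
    fresh_vals = rng.random((n_hap, m))
    fresh_mask = rng.random((n_hap, m)) >= rho
    chrom_start = np.r_[True, chrom_codes[1:] != chrom_codes[:-1]]
    fresh_mask[:, chrom_start] = True
    col = np.arange(m)
    last_fresh = np.maximum.accumulate(np.where(fresh_mask, col[None, :], -1), axis=1)
    u = np.take_along_axis(fresh_vals, last_fresh, axis=1)
    return (u < freqs[None, :]).astype(np.uint8)


def simulate_haplotypes(cfg: SimConfig, freqs: pd.DataFrame):
    """Phased haplotypes per group plus the paired genotype matrix.

    Returns (hap_g1, hap_g2, genotypes, popmap).  The sweep forces every
    group-1 haplotype that drew the alt allele at the core to share the first
    such haplotype's alleles across the sweep span; genotypes are formed by
    pairing consecutive haplotypes, with a missingness mask applied to the
    genotype matrix only.
    """
    rng = _rng(cfg, 2)
    chrom_codes = pd.factorize(freqs.chrom)[0]
    g1_names, g2_names, popmap = make_population(cfg)

    h1 = _draw_group_haplotypes(rng, 2 * cfg.n_g1, freqs.p_g1.to_numpy(),
                                chrom_codes, cfg.rho)
    h2 = _draw_group_haplotypes(rng, 2 * cfg.n_g2, freqs.p_g2.to_numpy(),
                                chrom_codes, cfg.rho)

    if cfg.sweep is not None:
        core = int(np.flatnonzero(freqs.sweep_core.to_numpy())[0])
        on_chrom = freqs.chrom.to_numpy() == cfg.sweep.chrom
        half = cfg.sweep.span_bp // 2
        span = on_chrom & (np.abs(freqs.pos.to_numpy() - freqs.pos.iloc[core]) <= half)
        carriers = np.flatnonzero(h1[:, core] == 1)
        if carriers.size:
            donor = h1[carriers[0], span].copy()
            h1[np.ix_(carriers, np.flatnonzero(span))] = donor[None, :]

    variants = [
        VariantRecord(chrom=str(c), pos=int(p), vid=v, ref="A", alt="G")
        for c, p, v in zip(freqs.chrom, freqs.pos, freqs.vid)
    ]
    hap_g1 = HaplotypeSet(samples=g1_names, variants=variants, haplotypes=h1)
    hap_g2 = HaplotypeSet(samples=g2_names, variants=variants, haplotypes=h2)

    dosage = np.vstack([
        (h1[0::2].astype(np.int8) + h1[1::2].astype(np.int8)),
        (h2[0::2].astype(np.int8) + h2[1::2].astype(np.int8)),
    ])
    if cfg.missing_rate > 0:
        mrng = _rng(cfg, 4)
        mask = mrng.random(dosage.shape) < cfg.missing_rate
        dosage = np.where(mask, np.int8(MISSING), dosage)
    genotypes = GenotypeMatrix(samples=g1_names + g2_names, variants=variants,
                               dosage=dosage)
    return hap_g1, hap_g2, genotypes, popmap


def simulate_phenotypes(cfg: SimConfig, causal_dosage, samples, groups=None,
                        sexes=None) -> pd.DataFrame:
    """Phenotype table (sample, sex, six traits) with additive genotype, sex
    and group effects; sexes alternate male/female for balance."""
    rng = _rng(cfg, 3)
    n = len(samples)
    causal = np.asarray(causal_dosage, dtype=float)
    causal = np.where(causal < 0, np.nan, causal)  # missing genotype -> no effect term
    causal = np.nan_to_num(causal, nan=np.nanmean(causal) if np.isfinite(causal).any() else 0.0)
    if sexes is None:
        sexes = ["male" if i % 2 == 0 else "female" for i in range(n)]
    male = np.array([s == "male" for s in sexes], dtype=float)
    high = (
        np.array([g == "G1" for g in groups], dtype=float)
        if groups is not None else np.zeros(n)
    )

    data = {"sample": list(samples), "sex": sexes}
    for trait in TRAIT_BASELINES:
        unit = TRAIT_UNITS[trait]
        vals = (
            TRAIT_BASELINES[trait]
            + GENO_SIGNS[trait] * cfg.phenotype_effect * unit * causal
            + GROUP_SIGNS[trait] * cfg.group_effect * unit * high
            + cfg.sex_effect * unit * male
            + rng.normal(0.0, cfg.noise_sd * unit, size=n)
        )
        data[trait] = vals
    return pd.DataFrame(data)


@dataclass
class SimDataset:
    cfg: SimConfig
    frequencies: pd.DataFrame
    hap_g1: HaplotypeSet
    hap_g2: HaplotypeSet
    genotypes: GenotypeMatrix
    popmap: PopulationMap
    phenotypes: pd.DataFrame
    sweep_core: int | None  # variant index of the forced sweep core


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """One coherent draw of every table the pipeline consumes."""
    freqs = simulate_frequencies(cfg)
    hap_g1, hap_g2, genotypes, popmap = simulate_haplotypes(cfg, freqs)
    core = (
        int(np.flatnonzero(freqs.sweep_core.to_numpy())[0])
        if cfg.sweep is not None else None
    )
    causal = genotypes.dosage[:, core] if core is not None else np.zeros(genotypes.n_samples)
    groups = [popmap.group_of(s) for s in genotypes.samples]
    phenotypes = simulate_phenotypes(cfg, causal, genotypes.samples, groups=groups)
    return SimDataset(cfg=cfg, frequencies=freqs, hap_g1=hap_g1, hap_g2=hap_g2,
                      genotypes=genotypes, popmap=popmap, phenotypes=phenotypes,
                      sweep_core=core)


def _write_gff3(path, cfg: SimConfig, freqs: pd.DataFrame) -> None:
    """Genes of 30 kb tiled every 150 kb per chromosome, plus one gene
    (SWEEPCORE) centred on the sweep core."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(cfg.chrom_lengths, key=lambda c: (len(c), c)):
            length = cfg.chrom_lengths[chrom]
            k = 0
            for start in range(1, length - 30_000, 150_000):
                k += 1
                fh.write(
                    f"{chrom}\tsim\tgene\t{start}\t{start + 29_999}\t.\t+\t.\t"
                    f"ID=gene:{chrom}.{k};Name=G{chrom}_{k:04d}\n"
                )
        if cfg.sweep is not None:
            core_pos = int(freqs.pos[freqs.sweep_core].iloc[0])
            lo = max(1, core_pos - 15_000)
            fh.write(
                f"{cfg.sweep.chrom}\tsim\tgene\t{lo}\t{core_pos + 15_000}\t.\t+\t.\t"
                f"ID=gene:sweep;Name=SWEEPCORE\n"
            )


def write_fixture_bundle(cfg: SimConfig, out_dir) -> dict:
    """Write PED/MAP, phased per-group VCFs, population map, GFF3, phenotypes
    and a manifest (written last, so a manifest marks a complete bundle)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(cfg)

    paths = {
        "ped": out / "genotypes.ped",
        "map": out / "genotypes.map",
        "vcf_g1": out / "haplotypes_g1.vcf",
        "vcf_g2": out / "haplotypes_g2.vcf",
        "popmap": out / "popmap.tsv",
        "gff3": out / "genes.gff3",
        "phenotypes": out / "phenotypes.tsv",
        "manifest": out / "manifest.txt",
    }
    write_plink(ds.genotypes, paths["ped"], paths["map"])
    write_vcf(paths["vcf_g1"], ds.hap_g1.samples, ds.hap_g1.variants,
              haplotypes=ds.hap_g1.haplotypes)
    write_vcf(paths["vcf_g2"], ds.hap_g2.samples, ds.hap_g2.variants,
              haplotypes=ds.hap_g2.haplotypes)
    ds.popmap.to_tsv(paths["popmap"])
    _write_gff3(paths["gff3"], cfg, ds.frequencies)
    with open(paths["phenotypes"], "w") as fh:
        fh.write("#" + "\t".join(ds.phenotypes.columns) + "\n")
        ds.phenotypes.to_csv(fh, sep="\t", header=False, index=False,
                             float_format="%.6f")
    with open(paths["manifest"], "w") as fh:  # manifest last: bundle is complete
        for key, value in asdict(cfg).items():
            fh.write(f"{key}={value!r}\n")
        if ds.sweep_core is not None:
            fh.write(f"sweep_core_vid={ds.genotypes.vids[ds.sweep_core]!r}\n")
    return {k: str(v) for k, v in paths.items()}
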