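"""Genotype containers, PLINK/VCF readers and writers, QC, allele frequencies.

Dosages count copies of the alternate allele and live in int8 arrays with
``MISSING = -1`` marking no-calls.  Coordinates are 1-based inclusive
throughout (PLINK/VCF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError, ValidationError

log = logging.getLogger(__name__)

MISSING = -1


def chrom_sort_key(chrom: str):
    """Order chromosome labels numerically when possible ('2' < '10' < 'X')."""
    try:
        return (0, int(chrom), "")
    except ValueError:
        return (1, 0, chrom)


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic site: chromosome, 1-based position, id and allele pair."""

    chrom: str
    pos: int
    vid: str
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"variant {self.vid}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValidationError(f"variant {self.vid}: ref and alt alleles must differ")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.ref, self.alt)


def _check_sorted(variants) -> None:
    for prev, cur in zip(variants, variants[1:]):
        if prev.chrom == cur.chrom and prev.pos > cur.pos:
            raise ValidationError(
                f"variants not sorted by position within chromosome {cur.chrom} "
                f"({prev.pos} before {cur.pos})"
            )


@dataclass
class GenotypeMatrix:
    """Diploid alt-allele dosages for samples x variants."""

    samples: list[str]
    variants: list[VariantRecord]
    dosage: np.ndarray  # (n_samples, n_variants) int8; -1 = missing

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicated sample IDs")
        bad = (self.dosage < -1) | (self.dosage > 2)
        if bad.any():
            raise ValidationError("dosages must be in {0,1,2} or -1 (missing)")
        _check_sorted(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    @property
    def vids(self) -> list[str]:
        return [v.vid for v in self.variants]

    def take_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[i] for i in idx],
            dosage=self.dosage[:, idx],
        )

    def take_samples(self, names) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in names]
        return GenotypeMatrix(
            samples=list(names), variants=list(self.variants), dosage=self.dosage[idx, :]
        )


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes (2n chromosomes x variants) for one group.

    Haplotype rows are sample-major: sample *i* owns rows ``2i`` and ``2i+1``.
    """

    samples: list[str]
    variants: list[VariantRecord]
    haplotypes: np.ndarray  # (2*n_samples, n_variants) uint8

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape != (2 * len(self.samples), len(self.variants)):
            raise ValidationError(
                f"haplotype shape {self.haplotypes.shape} does not match "
                f"2x{len(self.samples)} x {len(self.variants)}"
            )
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValidationError("haplotype alleles must be 0/1")
        _check_sorted(self.variants)

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    def take_variants(self, idx) -> "HaplotypeSet":
        idx = np.asarray(idx, dtype=int)
        return HaplotypeSet(
            samples=list(self.samples),
            variants=[self.variants[i] for i in idx],
            haplotypes=self.haplotypes[:, idx],
        )


@dataclass
class PopulationMap:
    """Sample -> (breed, group) assignment; groups are the scan contrast."""

    assignments: dict[str, tuple[str, str]]

    def breed_of(self, sample: str) -> str:
        return self.assignments[sample][0]

    def group_of(self, sample: str) -> str:
        return self.assignments[sample][1]

    @property
    def breeds(self) -> list[str]:
        seen = []
        for b, _ in self.assignments.values():
            if b not in seen:
                seen.append(b)
        return seen

    @property
    def groups(self) -> list[str]:
        seen = []
        for _, g in self.assignments.values():
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, (_, g) in self.assignments.items() if g == group]

    def samples_in_breed(self, breed: str) -> list[str]:
        return [s for s, (b, _) in self.assignments.items() if b == breed]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#sample\tbreed\tgroup\n")
            for s, (b, g) in self.assignments.items():
                fh.write(f"{s}\t{b}\t{g}\n")

    @classmethod
    def from_tsv(cls, path) -> "PopulationMap":
        assignments = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ParseError(path, lineno, f"expected 3 columns, got {len(parts)}")
                sample, breed, group = parts
                if sample in assignments:
                    raise ParseError(path, lineno, f"duplicated sample {sample!r}")
                assignments[sample] = (breed, group)
        return cls(assignments)


@dataclass
class QcConfig:
    """QC thresholds: keep SNPs with MAF > maf_min, missing rate < missing_max,
    and chromosome outside *exclude_chroms*."""

    maf_min: float = 0.01
    missing_max: float = 0.05
    exclude_chroms: frozenset = frozenset({"X"})

    def __post_init__(self):
        if not 0.0 <= self.maf_min <= 0.5:
            raise ConfigError(f"maf_min must be in [0, 0.5], got {self.maf_min}")
        if not 0.0 <= self.missing_max <= 1.0:
            raise ConfigError(f"missing_max must be in [0, 1], got {self.missing_max}")
        self.exclude_chroms = frozenset(self.exclude_chroms)


@dataclass
class QcReport:
    """Per-criterion removal counts; each SNP is attributed to the first
    criterion it fails, checked in the order MAF, missingness, chromosome."""

    n_input: int
    removed_maf: int
    removed_missing: int
    removed_chrom: int

    @property
    def n_retained(self) -> int:
        return self.n_input - self.removed_maf - self.removed_missing - self.removed_chrom

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#criterion\tcount\n")
            fh.write(f"input_snps\t{self.n_input}\n")
            fh.write(f"removed_maf\t{self.removed_maf}\n")
            fh.write(f"removed_missing\t{self.removed_missing}\n")
            fh.write(f"removed_chrom\t{self.removed_chrom}\n")
            fh.write(f"retained_snps\t{self.n_retained}\n")


# ---------------------------------------------------------------------------
# PLINK PED/MAP text format
# ---------------------------------------------------------------------------

def _split_sample_key(key: str) -> tuple[str, str]:
    """Invert the FID+IID concatenation used as sample key."""
    if "_" in key:
        fid, iid = key.split("_", 1)
        return fid, iid
    return "0", key


def _join_sample_key(fid: str, iid: str) -> str:
    return iid if fid == "0" else f"{fid}_{iid}"


def read_map(map_path) -> list[tuple[str, str, int]]:
    """Read a PLINK MAP file -> list of (chrom, vid, pos)."""
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ParseError(map_path, lineno, f"expected 4 columns, got {len(parts)}")
            chrom, vid, _cm, pos = parts
            try:
                pos = int(pos)
            except ValueError:
                raise ParseError(map_path, lineno, f"non-integer position {pos!r}") from None
            rows.append((chrom, vid, pos))
    return rows


def read_plink(ped_path, map_path, allele_ref=None) -> GenotypeMatrix:
    """Read whitespace-delimited PLINK PED/MAP into a GenotypeMatrix.

    Without *allele_ref* the dosage counts the globally minor allele
    (frequency ties broken toward the alphabetically later allele); with an
    allele table (list of ``(ref, alt)`` per SNP in MAP order) it counts the
    given alt allele.  PED missing code ``0 0`` maps to the missing sentinel.
    """
    map_rows = read_map(map_path)
    m = len(map_rows)

    samples: list[str] = []
    geno_pairs: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise ParseError(
                    ped_path, lineno,
                    f"expected {6 + 2 * m} fields for {m} SNPs, got {len(parts)}",
                )
            fid, iid = parts[0], parts[1]
            key = _join_sample_key(fid, iid)
            if key in samples:
                raise ParseError(ped_path, lineno, f"duplicated sample ID {key!r}")
            samples.append(key)
            alleles = parts[6:]
            geno_pairs.append(list(zip(alleles[0::2], alleles[1::2])))

    n = len(samples)
    if n == 0:
        raise ParseError(ped_path, 0, "no samples in PED file")

    dosage = np.full((n, m), MISSING, dtype=np.int8)
    variants: list[VariantRecord] = []
    for j, (chrom, vid, pos) in enumerate(map_rows):
        counts: dict[str, int] = {}
        for i in range(n):
            for a in geno_pairs[i][j]:
                if a != "0":
                    counts[a] = counts.get(a, 0) + 1
        observed = sorted(counts)
        if len(observed) > 2:
            raise ParseError(map_path, j + 1, f"SNP {vid} has >2 alleles: {observed}")
        if allele_ref is not None:
            ref, alt = allele_ref[j]
        else:
            if len(observed) == 2:
                # minor allele = less frequent; tie -> alphabetically later
                a1, a2 = observed
                alt = a2 if counts[a2] <= counts[a1] else a1
                ref = a1 if alt == a2 else a2
            elif len(observed) == 1:
                ref, alt = observed[0], "N"
            else:
                ref, alt = "N", "M"  # all missing; placeholder alleles
        variants.append(VariantRecord(chrom=chrom, pos=pos, vid=vid, ref=ref, alt=alt))
        for i in range(n):
            a, b = geno_pairs[i][j]
            if a == "0" or b == "0":
                continue
            for al in (a, b):
                if al not in (ref, alt):
                    raise ParseError(
                        ped_path, i + 1,
                        f"SNP {vid}: allele {al!r} not in expected pair ({ref},{alt})",
                    )
            dosage[i, j] = (a == alt) + (b == alt)

    order = sorted(range(m), key=lambda j: (chrom_sort_key(variants[j].chrom), variants[j].pos))
    if order != list(range(m)):
        variants = [variants[j] for j in order]
        dosage = dosage[:, order]
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def write_plink(g: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PED/MAP; sample keys are split back into FID and IID."""
    with open(map_path, "w") as fh:
        for v in g.variants:
            fh.write(f"{v.chrom}\t{v.vid}\t0\t{v.pos}\n")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(g.samples):
            fid, iid = _split_sample_key(s)
            fields = [fid, iid, "0", "0", "0", "-9"]
            row = g.dosage[i]
            for j, v in enumerate(g.variants):
                d = row[j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [v.ref, v.ref]
                elif d == 1:
                    fields += [v.ref, v.alt]
                else:
                    fields += [v.alt, v.alt]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(vcf_path, require_phased: bool = False):
    """Read a biallelic-SNP VCF.

    Returns a :class:`HaplotypeSet` when *require_phased* is true (every GT
    must use the ``|`` separator), otherwise a :class:`GenotypeMatrix`.
    Multiallelic records are skipped with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gts = rec.genotypes  # per sample: [allele0, allele1, phased]
        if require_phased:
            for i, gt in enumerate(gts):
                if not gt[2]:
                    raise ValidationError(
                        f"unphased genotype for sample {samples[i]} at "
                        f"{rec.CHROM}:{rec.POS} ({rec.ID or '.'}) with require_phased=True"
                    )
        variants.append(
            VariantRecord(
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                vid=rec.ID or f"{rec.CHROM}:{rec.POS}",
                ref=rec.REF,
                alt=rec.ALT[0],
            )
        )
        columns.append([(gt[0], gt[1]) for gt in gts])
    if n_multi:
        log.info("read_vcf(%s): skipped %d multiallelic records", vcf_path, n_multi)

    n, m = len(samples), len(variants)
    if require_phased:
        haps = np.zeros((2 * n, m), dtype=np.uint8)
        for j, col in enumerate(columns):
            for i, (a0, a1) in enumerate(col):
                if a0 < 0 or a1 < 0:
                    raise ValidationError(
                        f"missing allele at phased record {variants[j].vid}; "
                        "phased input must be complete"
                    )
                haps[2 * i, j] = a0
                haps[2 * i + 1, j] = a1
        return HaplotypeSet(samples=samples, variants=variants, haplotypes=haps)

    dosage = np.full((n, m), MISSING, dtype=np.int8)
    for j, col in enumerate(columns):
        for i, (a0, a1) in enumerate(col):
            if a0 >= 0 and a1 >= 0:
                dosage[i, j] = a0 + a1
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def write_vcf(path, samples, variants, *, haplotypes=None, dosage=None) -> None:
    """Write a minimal VCF; phased GTs from *haplotypes* or unphased from *dosage*."""
    if (haplotypes is None) == (dosage is None):
        raise ValidationError("provide exactly one of haplotypes or dosage")
    chroms = []
    for v in variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, v in enumerate(variants):
            if haplotypes is not None:
                gts = [f"{haplotypes[2*i, j]}|{haplotypes[2*i+1, j]}"
                       for i in range(len(samples))]
            else:
                code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
                gts = [code[int(dosage[i, j])] for i in range(len(samples))]
            fh.write(f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# QC and allele frequencies
# ---------------------------------------------------------------------------

def apply_qc(g: GenotypeMatrix, cfg: QcConfig | None = None) -> tuple[GenotypeMatrix, QcReport]:
    """Filter SNPs on MAF, missing rate and excluded chromosomes.

    Undefined MAF (a SNP with no calls at all) is not attributed to the MAF
    criterion; the missingness criterion catches it.
    """
    if cfg is None:
        cfg = QcConfig()
    if g.n_variants == 0:
        raise ValidationError("empty genotype matrix")

    dos = g.dosage
    called = dos != MISSING
    n_called = called.sum(axis=0)
    alt_count = np.where(called, dos, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt_count / np.maximum(2 * n_called, 1), np.nan)
    maf = np.minimum(p, 1.0 - p)
    miss_rate = 1.0 - n_called / g.n_samples
    on_excluded = np.array([v.chrom in cfg.exclude_chroms for v in g.variants])

    fails_maf = ~np.isnan(maf) & (maf <= cfg.maf_min)
    fails_miss = ~fails_maf & (miss_rate >= cfg.missing_max)
    fails_chrom = ~fails_maf & ~fails_miss & on_excluded
    keep = ~(fails_maf | fails_miss | fails_chrom)

    report = QcReport(
        n_input=g.n_variants,
        removed_maf=int(fails_maf.sum()),
        removed_missing=int(fails_miss.sum()),
        removed_chrom=int(fails_chrom.sum()),
    )
    if not keep.any():
        raise ValidationError("QC removed every SNP; check thresholds and input")
    return g.take_variants(np.flatnonzero(keep)), report


def allele_frequencies(g: GenotypeMatrix, pm: PopulationMap, by: str = "group") -> pd.DataFrame:
    """Per-breed or per-group alt-allele frequencies.

    Returns a frame indexed by variant id with MultiIndex columns
    ``(unit, 'freq')`` and ``(unit, 'n')`` where *n* is the count of
    non-missing samples.  A unit with zero calls at a SNP gets NaN, never 0.
    """
    if by not in ("breed", "group"):
        raise ConfigError(f"by must be 'breed' or 'group', got {by!r}")
    for s in g.samples:
        if s not in pm.assignments:
            raise ValidationError(f"sample {s!r} missing from population map")
    units = pm.breeds if by == "breed" else pm.groups
    sample_index = {s: i for i, s in enumerate(g.samples)}

    data = {}
    for unit in units:
        members = pm.samples_in_breed(unit) if by == "breed" else pm.samples_in_group(unit)
        rows = [sample_index[s] for s in members if s in sample_index]
        sub = g.dosage[rows, :]
        called = sub != MISSING
        n_called = called.sum(axis=0)
        alt = np.where(called, sub, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_called > 0, alt / np.maximum(2 * n_called, 1), np.nan)
        data[(unit, "freq")] = freq
        data[(unit, "n")] = n_called
    df = pd.DataFrame(data, index=pd.Index(g.vids, name="vid"))
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return df


def group_stats(g: GenotypeMatrix, pm: PopulationMap, unit: str, by: str = "group"):
    """Per-SNP (n, p, het) for one breed or group: non-missing diploid count,
    alt frequency and observed heterozygote proportion.  NaN where no calls."""
    members = pm.samples_in_breed(unit) if by == "breed" else pm.samples_in_group(unit)
    sample_index = {s: i for i, s in enumerate(g.samples)}
    rows = [sample_index[s] for s in members if s in sample_index]
    sub = g.dosage[rows, :]
    called = sub != MISSING
    n = called.sum(axis=0)
    alt = np.where(called, sub, 0).sum(axis=0)
    het = (sub == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(2 * n, 1), np.nan)
        h = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    return n.astype(float), p, h
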