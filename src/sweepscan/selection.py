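"""Per-SNP selection statistics between two population groups.

Implements the two-population Weir-Cockerham variance-component estimator of
F_ST (components a, b, c; theta = a/(a+b+c)), extended haplotype homozygosity
(EHH) and its integral (iHH) over physical distance, the cross-population
XP-EHH log-ratio with genome-wide standardization, upper-quantile thresholding
with boundary-tie inclusion, the tail-intersection candidate rule with the
"null XP-EHH" rescue, and flank-window gene annotation.

EHH here is the pooled-population homozygosity: the probability that two
randomly chosen haplotypes are identical over the segment from the core SNP
out to a given position (the core allele is part of the compared segment).
A positive XP-EHH indicates unusually long homozygosity — hence selection —
in the observed population; negative values point at the reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .errors import ConfigError, ParseError, ValidationError
from .genotype_io import (
    GenotypeMatrix,
    HaplotypeSet,
    PopulationMap,
    group_stats,
)


@dataclass
class ScanConfig:
    """Scan thresholds and haplotype-extension limits (bp units)."""

    fst_quantile: float = 0.01
    xpehh_quantile: float = 0.05
    ehh_cutoff: float = 0.05
    max_extension_bp: int = 1_000_000
    max_gap_bp: int = 200_000
    gene_flank_bp: int = 25_000

    def __post_init__(self):
        for name in ("fst_quantile", "xpehh_quantile"):
            q = getattr(self, name)
            if not 0.0 < q < 0.5:
                raise ConfigError(f"{name} must be in (0, 0.5), got {q}")
        if not 0.0 < self.ehh_cutoff < 1.0:
            raise ConfigError(f"ehh_cutoff must be in (0, 1), got {self.ehh_cutoff}")


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components (r = 2 populations)
# ---------------------------------------------------------------------------

@dataclass
class FstComponents:
    """Variance components per locus: a (among populations), b (among
    individuals within populations), c (within individuals)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    theta: np.ndarray  # NaN where undefined
    defined: np.ndarray


def wc_components(n1, p1, h1, n2, p2, h2) -> FstComponents:
    """Two-population variance components from per-population diploid sample
    sizes *n*, alt-allele frequencies *p* and observed heterozygote
    proportions *h*.  Accepts scalars or aligned arrays.

    theta is undefined (NaN) when a+b+c = 0 (monomorphic locus) or when either
    population has fewer than two sampled individuals.
    """
    n1 = np.asarray(n1, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    r = 2.0

    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1.0)) * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        usable = (n1 >= 2) & (n2 >= 2) & np.isfinite(denom)
        defined = usable & (denom != 0.0)
        theta = np.where(defined, a / np.where(denom == 0.0, np.nan, denom), np.nan)
    a = np.where(usable, a, np.nan)
    b = np.where(usable, b, np.nan)
    c = np.where(usable, c, np.nan)
    return FstComponents(a=a, b=b, c=c, theta=theta, defined=np.asarray(defined))


def fst_scan(g: GenotypeMatrix, pm: PopulationMap, group_obs: str = "G1",
             group_ref: str = "G2") -> pd.DataFrame:
    """Per-SNP Weir-Cockerham components between the two groups.

    Sample sizes, frequencies and heterozygosities are computed from
    non-missing genotypes only.
    """
    for grp in (group_obs, group_ref):
        if not pm.samples_in_group(grp):
            raise ValidationError(f"group {grp!r} is empty")
    n1, p1, h1 = group_stats(g, pm, group_obs, by="group")
    n2, p2, h2 = group_stats(g, pm, group_ref, by="group")
    comp = wc_components(n1, p1, h1, n2, p2, h2)
    return pd.DataFrame(
        {
            "chrom": g.chroms,
            "pos": g.positions,
            "vid": g.vids,
            "n1": n1, "p1": p1, "h1": h1,
            "n2": n2, "p2": p2, "h2": h2,
            "a": comp.a, "b": comp.b, "c": comp.c,
            "theta": comp.theta,
            "fst_defined": comp.defined,
        }
    )


# ---------------------------------------------------------------------------
# EHH / iHH
# ---------------------------------------------------------------------------

@dataclass
class EhhCurve:
    """EHH decay on one side of a core SNP.

    ``points`` is a list of (distance bp, EHH) starting at the conventional
    (0, 1.0); ``reason`` records why the extension stopped: 'cutoff',
    'max_extension', 'gap' or 'chrom_end'.
    """

    core_index: int
    side: str  # 'left' | 'right'
    points: list = field(default_factory=list)
    reason: str = "chrom_end"

    @property
    def decayed(self) -> bool:
        return self.reason == "cutoff"


def _homozygosity(codes: np.ndarray) -> float:
    n = codes.size
    _, counts = np.unique(codes, return_counts=True)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh(h: HaplotypeSet, core_index: int, side: str, cfg: ScanConfig | None = None) -> EhhCurve:
    """EHH curve outward from *core_index* on one side.

    At each successive SNP, haplotypes are partitioned by identity of the
    extended segment [core..current]; EHH = sum_k C(m_k,2) / C(n,2).
    Truncates when EHH drops below the cutoff, the physical span exceeds
    the extension limit, an inter-SNP gap exceeds the gap limit, or the
    chromosome ends.
    """
    if cfg is None:
        cfg = ScanConfig()
    if side not in ("left", "right"):
        raise ConfigError(f"side must be 'left' or 'right', got {side!r}")
    m = len(h.variants)
    if not 0 <= core_index < m:
        raise ValidationError(f"core_index {core_index} out of range [0, {m})")
    if h.n_hap < 2:
        raise ValidationError("need at least 2 haplotypes")

    step = -1 if side == "left" else 1
    chroms = h.chroms
    pos = h.positions
    core_chrom = chroms[core_index]
    core_pos = pos[core_index]

    codes = h.haplotypes[:, core_index].astype(np.int64)
    curve = EhhCurve(core_index=core_index, side=side, points=[(0.0, 1.0)])
    j = core_index
    while True:
        jn = j + step
        if jn < 0 or jn >= m or chroms[jn] != core_chrom:
            curve.reason = "chrom_end"
            break
        dist = abs(int(pos[jn]) - int(core_pos))
        gap = abs(int(pos[jn]) - int(pos[j]))
        if dist > cfg.max_extension_bp:
            curve.reason = "max_extension"
            break
        if gap > cfg.max_gap_bp:
            curve.reason = "gap"
            break
        codes = codes * 2 + h.haplotypes[:, jn]
        _, codes = np.unique(codes, return_inverse=True)  # keep labels small
        e = _homozygosity(codes)
        curve.points.append((float(dist), e))
        j = jn
        if e < cfg.ehh_cutoff:
            curve.reason = "cutoff"
            break
    return curve


def ihh(left: EhhCurve, right: EhhCurve, cfg: ScanConfig | None = None) -> tuple[float, bool]:
    """Integrated EHH: trapezoidal area of max(EHH - cutoff, 0) over physical
    distance, summed over both sides.

    Returns ``(area, defined)``; *defined* is False when either side was
    truncated before decaying below the cutoff (span, gap or chromosome end),
    which yields the "null XP-EHH" class downstream.
    """
    if cfg is None:
        cfg = ScanConfig()
    if left.core_index != right.core_index:
        raise ValidationError("left and right curves must share the core SNP")
    total = 0.0
    for curve in (left, right):
        pts = curve.points
        for (d0, e0), (d1, e1) in zip(pts, pts[1:]):
            a0 = max(e0 - cfg.ehh_cutoff, 0.0)
            a1 = max(e1 - cfg.ehh_cutoff, 0.0)
            total += 0.5 * (a0 + a1) * (d1 - d0)
    defined = left.decayed and right.decayed
    return total, defined


@njit(cache=False)
def _pop_ihh_kernel(haps, pos, chrom_code, cutoff, max_ext, max_gap):  # pragma: no cover
    """iHH and decay flag for every core SNP of one population (numba)."""
    n, m = haps.shape
    ihh_out = np.zeros(m)
    defined = np.zeros(m, np.bool_)
    codes = np.empty(n, np.int64)
    relab = np.empty(n, np.int64)
    denom = n * (n - 1) / 2.0
    for core in range(m):
        total = 0.0
        ok = True
        for s in range(2):
            step = -1 if s == 0 else 1
            for i in range(n):
                codes[i] = haps[i, core]
            prev_d = 0.0
            prev_e = 1.0
            j = core
            decayed = False
            while True:
                jn = j + step
                if jn < 0 or jn >= m or chrom_code[jn] != chrom_code[core]:
                    break
                dist = abs(pos[jn] - pos[core])
                gap = abs(pos[jn] - pos[j])
                if dist > max_ext or gap > max_gap:
                    break
                for i in range(n):
                    codes[i] = codes[i] * 2 + haps[i, jn]
                order = np.argsort(codes)
                # homozygosity from run lengths of sorted codes
                e = 0.0
                runlen = 1
                for t in range(1, n):
                    if codes[order[t]] == codes[order[t - 1]]:
                        runlen += 1
                    else:
                        e += runlen * (runlen - 1) / 2.0
                        runlen = 1
                e += runlen * (runlen - 1) / 2.0
                e /= denom
                # relabel classes 0..k-1 so codes stay small
                lab = 0
                relab[order[0]] = 0
                for t in range(1, n):
                    if codes[order[t]] != codes[order[t - 1]]:
                        lab += 1
                    relab[order[t]] = lab
                for i in range(n):
                    codes[i] = relab[i]
                a0 = prev_e - cutoff
                if a0 < 0.0:
                    a0 = 0.0
                a1 = e - cutoff
                if a1 < 0.0:
                    a1 = 0.0
                total += 0.5 * (a0 + a1) * (dist - prev_d)
                prev_d = float(dist)
                prev_e = e
                j = jn
                if e < cutoff:
                    decayed = True
                    break
            if not decayed:
                ok = False
        ihh_out[core] = total
        defined[core] = ok
    return ihh_out, defined


def population_ihh(h: HaplotypeSet, cfg: ScanConfig | None = None):
    """Vectorized per-core iHH for one population (numba fast path).

    Equals :func:`ehh` + :func:`ihh` applied core-by-core.
    """
    if cfg is None:
        cfg = ScanConfig()
    chrom_labels, chrom_code = np.unique(h.chroms, return_inverse=True)
    ihh_vals, defined = _pop_ihh_kernel(
        np.ascontiguousarray(h.haplotypes),
        h.positions.astype(np.float64),
        chrom_code.astype(np.int64),
        float(cfg.ehh_cutoff),
        float(cfg.max_extension_bp),
        float(cfg.max_gap_bp),
    )
    return ihh_vals, defined


def xpehh_scan(h_obs: HaplotypeSet, h_ref: HaplotypeSet,
               cfg: ScanConfig | None = None) -> pd.DataFrame:
    """Per-SNP XP-EHH between an observed and a reference population.

    raw = ln(iHH_obs / iHH_ref); std standardizes raw over all defined scores
    genome-wide (mean 0, sd 1).  Scores are undefined when either side of
    either population fails to decay below the cutoff, or either iHH is 0.
    """
    if cfg is None:
        cfg = ScanConfig()
    va = [(v.chrom, v.pos, v.vid) for v in h_obs.variants]
    vb = [(v.chrom, v.pos, v.vid) for v in h_ref.variants]
    if va != vb:
        raise ValidationError("observed and reference haplotype sets must share variants")

    ihh_obs, def_obs = population_ihh(h_obs, cfg)
    ihh_ref, def_ref = population_ihh(h_ref, cfg)
    defined = def_obs & def_ref & (ihh_obs > 0.0) & (ihh_ref > 0.0)
    raw = np.full(len(va), np.nan)
    raw[defined] = np.log(ihh_obs[defined] / ihh_ref[defined])
    std = np.full(len(va), np.nan)
    if defined.sum() >= 2:
        mu = raw[defined].mean()
        sd = raw[defined].std()  # population sd: standardized scores have sd exactly 1
        if sd > 0:
            std[defined] = (raw[defined] - mu) / sd
        else:
            std[defined] = 0.0
    elif defined.sum() == 1:
        std[defined] = 0.0
    return pd.DataFrame(
        {
            "chrom": h_obs.chroms,
            "pos": h_obs.positions,
            "vid": [v.vid for v in h_obs.variants],
            "ihh_obs": ihh_obs,
            "ihh_ref": ihh_ref,
            "xpehh_raw": raw,
            "xpehh_std": std,
            "xpehh_defined": defined,
        }
    )


# ---------------------------------------------------------------------------
# Quantile selection and candidate intersection
# ---------------------------------------------------------------------------

def top_quantile(values, q: float, defined=None) -> tuple[np.ndarray, float]:
    """Indices of the ceil(q*M) largest defined values; boundary ties are all
    included, so the set may exceed ceil(q*M).

    Returns (sorted index array, threshold = smallest selected value).
    """
    if not 0.0 < q < 0.5:
        raise ConfigError(f"tail fraction must be in (0, 0.5), got {q}")
    values = np.asarray(values, dtype=float)
    if defined is None:
        defined = np.isfinite(values)
    else:
        defined = np.asarray(defined, dtype=bool) & np.isfinite(values)
    idx = np.flatnonzero(defined)
    if idx.size == 0:
        raise ValidationError("no defined values to threshold")
    m = idx.size
    k = math.ceil(q * m)
    order = idx[np.argsort(values[idx])[::-1]]
    threshold = float(values[order[k - 1]])
    selected = idx[values[idx] >= threshold]
    return np.sort(selected), threshold


@dataclass
class CandidateSet:
    """SNPs surviving the quantile-intersection rule.

    ``intersect`` = upper F_ST tail AND upper XP-EHH tail;
    ``rescue`` = upper F_ST tail with undefined ("null") XP-EHH.
    """

    intersect: np.ndarray
    rescue: np.ndarray

    @property
    def union(self) -> np.ndarray:
        return np.sort(np.concatenate([self.intersect, self.rescue]))


def build_candidates(fst_sel, xpehh_sel, xpehh_defined) -> CandidateSet:
    fst_sel = set(np.asarray(fst_sel, dtype=int).tolist())
    xpehh_sel = set(np.asarray(xpehh_sel, dtype=int).tolist())
    defined = np.asarray(xpehh_defined, dtype=bool)
    undefined = set(np.flatnonzero(~defined).tolist())
    intersect = np.array(sorted(fst_sel & xpehh_sel), dtype=int)
    rescue = np.array(sorted(fst_sel & undefined), dtype=int)
    return CandidateSet(intersect=intersect, rescue=rescue)


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def read_gff3_genes(path) -> pd.DataFrame:
    """Gene features from a GFF3 file -> frame (chrom, start, end, strand,
    symbol), 1-based inclusive coordinates."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(path, lineno, f"expected 9 columns, got {len(parts)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            try:
                start, end = int(start), int(end)
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if end < start:
                raise ParseError(path, lineno, f"end {end} < start {start}")
            symbol = None
            for kv in attrs.split(";"):
                kv = kv.strip()
                if kv.startswith("Name="):
                    symbol = kv[5:]
                    break
                if kv.startswith("ID=") and symbol is None:
                    symbol = kv[3:]
            if not symbol:
                raise ParseError(path, lineno, "gene feature without Name or ID attribute")
            rows.append((chrom, start, end, strand, symbol))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "symbol"])


def read_bed_genes(path) -> pd.DataFrame:
    """Six-column BED -> same frame as :func:`read_gff3_genes` (converted to
    1-based inclusive)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(path, lineno, f"expected 6 columns, got {len(parts)}")
            chrom, start, end, name, _score, strand = parts[:6]
            try:
                start, end = int(start), int(end)
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            rows.append((chrom, start + 1, end, strand, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "symbol"])


def annotate_genes(snps: pd.DataFrame, genes: pd.DataFrame, flank_bp: int = 25_000) -> pd.DataFrame:
    """Genes with any candidate SNP within [start - flank, end + flank].

    *snps* needs columns chrom, pos, vid.  Genes are deduplicated by symbol
    (supporting SNP lists merged).  Interval arithmetic is 0-based half-open
    internally; inputs and outputs stay 1-based inclusive.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for i, row in genes.iterrows():
        lo = max(1, int(row.start) - flank_bp)
        hi = int(row.end) + flank_bp
        trees.setdefault(str(row.chrom), IntervalTree()).addi(lo - 1, hi, i)

    hits: dict[str, dict] = {}
    for _, snp in snps.iterrows():
        tree = trees.get(str(snp.chrom))
        if tree is None:
            continue
        for iv in tree.at(int(snp.pos) - 1):
            g = genes.iloc[iv.data]
            rec = hits.setdefault(
                g.symbol,
                {"symbol": g.symbol, "chrom": g.chrom, "start": int(g.start),
                 "end": int(g.end), "strand": g.strand, "snps": []},
            )
            rec["start"] = min(rec["start"], int(g.start))
            rec["end"] = max(rec["end"], int(g.end))
            if snp.vid not in rec["snps"]:
                rec["snps"].append(snp.vid)

    out = pd.DataFrame(
        [
            {**rec, "n_snps": len(rec["snps"]), "snps": ",".join(rec["snps"])}
            for rec in hits.values()
        ],
        columns=["symbol", "chrom", "start", "end", "strand", "n_snps", "snps"],
    )
    if len(out):
        out = out.sort_values(
            ["chrom", "start", "symbol"], kind="mergesort"
        ).reset_index(drop=True)
    return out
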