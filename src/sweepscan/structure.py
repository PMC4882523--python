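"""Population structure: LD pruning, IBS distances, classical MDS, per-breed
nucleotide diversity, multi-locus pairwise F_ST and neighbor-joining trees.

The LD pruner follows PLINK ``--indep-pairwise`` semantics: overlapping
sliding windows advanced by a fixed step, dropping members of any retained
pair whose squared dosage correlation exceeds the threshold.  r^2 is the
squared Pearson correlation on mean-imputed dosages, so the operation is
deterministic under missing data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .genotype_io import MISSING, GenotypeMatrix, PopulationMap, group_stats
from .selection import wc_components


@dataclass
class PruneConfig:
    window_snps: int = 25
    step_snps: int = 5
    r2_max: float = 0.05

    def __post_init__(self):
        if self.window_snps < 2:
            raise ConfigError(f"window_snps must be >= 2, got {self.window_snps}")
        if self.step_snps < 1 or self.step_snps > self.window_snps:
            raise ConfigError("step_snps must satisfy 1 <= step_snps <= window_snps")
        if not 0.0 < self.r2_max < 1.0:
            raise ConfigError(f"r2_max must be in (0, 1), got {self.r2_max}")


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {self.d.shape} != ({n},{n})")
        if not np.isfinite(self.d).all():
            raise ValidationError("distance matrix has non-finite entries")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal not zero")
        if (self.d < -1e-12).any():
            raise ValidationError("negative distances")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#unit\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                fh.write(lab + "\t" + "\t".join(f"{x:.10g}" for x in self.d[i]) + "\n")


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _imputed_dosage(g: GenotypeMatrix) -> np.ndarray:
    dos = g.dosage.astype(float)
    miss = g.dosage == MISSING
    with np.errstate(invalid="ignore"):
        means = np.where(
            (~miss).sum(axis=0) > 0,
            np.where(miss, 0, dos).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1),
            0.0,
        )
    dos[miss] = np.broadcast_to(means, dos.shape)[miss]
    return dos


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(g: GenotypeMatrix, cfg: PruneConfig | None = None) -> list[int]:
    """Greedy sliding-window LD pruning; returns sorted retained variant indices.

    Within each window, while any retained pair has r^2 > r2_max, the member
    with more missing calls is dropped (tie: the later position); the window
    then advances by the step.  No surviving within-window pair exceeds the
    threshold.
    """
    if cfg is None:
        cfg = PruneConfig()
    dos = _imputed_dosage(g)
    n_missing = (g.dosage == MISSING).sum(axis=0)
    chroms = g.chroms
    retained = np.ones(g.n_variants, dtype=bool)

    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        n = idx.size
        start = 0
        while start < n:
            window = [int(i) for i in idx[start:start + cfg.window_snps] if retained[i]]
            changed = True
            while changed:
                changed = False
                for ai in range(len(window)):
                    for bi in range(ai + 1, len(window)):
                        i, j = window[ai], window[bi]
                        if _r2(dos[:, i], dos[:, j]) > cfg.r2_max:
                            # drop the member with more missing calls; tie -> later position
                            drop = j if n_missing[j] >= n_missing[i] else i
                            retained[drop] = False
                            window = [k for k in window if k != drop]
                            changed = True
                            break
                    if changed:
                        break
            start += cfg.step_snps
    return np.flatnonzero(retained).tolist()


# ---------------------------------------------------------------------------
# IBS distances and classical MDS
# ---------------------------------------------------------------------------

def ibs_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """1 - mean allele-sharing over jointly non-missing SNPs, per sample pair."""
    if g.n_samples < 2:
        raise ValidationError("need at least 2 samples")
    dos = g.dosage.astype(np.int16)
    called = g.dosage != MISSING
    n = g.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            joint = called[i] & called[j]
            m = int(joint.sum())
            if m == 0:
                raise ValidationError(
                    f"samples {g.samples[i]!r} and {g.samples[j]!r} share no called SNPs"
                )
            shared = 2 - np.abs(dos[i, joint] - dos[j, joint])
            sim = shared.sum() / (2.0 * m)
            d[i, j] = d[j, i] = 1.0 - sim
    return DistanceMatrix(labels=list(g.samples), d=d)


def classical_mds(d: DistanceMatrix, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS: double-center squared distances, eigendecompose,
    scale the top-k nonnegative eigenvectors.

    Axes are ordered by descending eigenvalue; the first nonzero loading of
    each axis is made positive.  If fewer than *k* positive eigenvalues
    exist, remaining columns are zero and a warning is emitted.
    """
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    n = len(d.labels)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d.d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    tol = max(1e-12, 1e-9 * max(abs(evals[0]), 1.0))
    n_pos = int((evals > tol).sum())
    coords = np.zeros((n, k))
    use = min(k, n_pos)
    if use < k:
        warnings.warn(
            f"requested {k} MDS components but only {n_pos} positive eigenvalues; "
            "remaining columns are zero",
            stacklevel=2,
        )
    coords[:, :use] = evecs[:, :use] * np.sqrt(evals[:use])
    for col in range(use):
        nz = np.flatnonzero(np.abs(coords[:, col]) > 1e-12)
        if nz.size and coords[nz[0], col] < 0:
            coords[:, col] = -coords[:, col]
    return coords


# ---------------------------------------------------------------------------
# Nucleotide diversity and pairwise F_ST
# ---------------------------------------------------------------------------

def nucleotide_diversity(g: GenotypeMatrix, pm: PopulationMap,
                         total_sites: int | None = None) -> pd.DataFrame:
    """Per-breed nucleotide diversity pi.

    pi = [sum_sites 2 p(1-p) n/(n-1)] / total_sites, with n the non-missing
    allele count at the site.  *total_sites* is the surveyed sequence length
    behind the SNP set; when unknown it defaults to the SNP count (a per-SNP
    average heterozygosity).  Breeds with <2 samples get NaN.
    """
    if total_sites is None:
        total_sites = g.n_variants
    if total_sites < g.n_variants:
        raise ValidationError(
            f"total_sites ({total_sites}) must be >= number of SNPs ({g.n_variants})"
        )
    rows = []
    for breed in pm.breeds:
        members = [s for s in pm.samples_in_breed(breed) if s in g.samples]
        if len(members) < 2:
            rows.append({"breed": breed, "pi": np.nan, "n_sites": 0})
            continue
        n_dip, p, _ = group_stats(g, pm, breed, by="breed")
        n_alleles = 2.0 * n_dip
        ok = n_alleles >= 2
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = 2.0 * p * (1.0 - p) * n_alleles / (n_alleles - 1.0)
        pi = float(np.nansum(np.where(ok, terms, 0.0)) / total_sites)
        rows.append({"breed": breed, "pi": pi, "n_sites": int(ok.sum())})
    return pd.DataFrame(rows)


def pairwise_fst_matrix(g: GenotypeMatrix, pm: PopulationMap) -> DistanceMatrix:
    """Multi-locus Weir-Cockerham theta for every breed pair:
    theta = sum_loci a / sum_loci (a+b+c), undefined loci skipped, negative
    multi-locus values clipped to 0 for distance use."""
    breeds = pm.breeds
    if len(breeds) < 2:
        raise ValidationError("need at least 2 breeds")
    stats = {b: group_stats(g, pm, b, by="breed") for b in breeds}
    nb = len(breeds)
    d = np.zeros((nb, nb))
    for i in range(nb):
        for j in range(i + 1, nb):
            n1, p1, h1 = stats[breeds[i]]
            n2, p2, h2 = stats[breeds[j]]
            comp = wc_components(n1, p1, h1, n2, p2, h2)
            use = comp.defined
            if not use.any():
                raise ValidationError(
                    f"breeds {breeds[i]!r} and {breeds[j]!r} share no polymorphic loci"
                )
            num = np.nansum(comp.a[use])
            den = np.nansum((comp.a + comp.b + comp.c)[use])
            theta = num / den
            d[i, j] = d[j, i] = max(theta, 0.0)
    return DistanceMatrix(labels=breeds, d=d)


def multilocus_theta(g: GenotypeMatrix, pm: PopulationMap, unit_a: str, unit_b: str,
                     by: str = "group") -> float:
    """Unclipped multi-locus theta between two units (ratio of summed
    components); NaN when no locus is defined."""
    n1, p1, h1 = group_stats(g, pm, unit_a, by=by)
    n2, p2, h2 = group_stats(g, pm, unit_b, by=by)
    comp = wc_components(n1, p1, h1, n2, p2, h2)
    use = comp.defined
    if not use.any():
        return float("nan")
    return float(np.nansum(comp.a[use]) / np.nansum((comp.a + comp.b + comp.c)[use]))


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    label: str
    children: list = field(default_factory=list)  # list of (child, branch length)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class NjTree:
    """Unrooted NJ tree held at an internal trifurcation."""

    root: _Node

    def newick(self) -> str:
        def fmt(node: _Node) -> str:
            if node.is_leaf:
                return node.label
            inner = ",".join(f"{fmt(ch)}:{ln:.10g}" for ch, ln in node.children)
            return f"({inner})"

        return fmt(self.root) + ";"

    def leaf_names(self) -> list[str]:
        out = []

        def walk(node: _Node):
            if node.is_leaf:
                out.append(node.label)
            for ch, _ in node.children:
                walk(ch)

        walk(self.root)
        return out

    def path_lengths(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix through the tree."""
        dists: dict[str, dict[str, float]] = {}

        def leaves_below(node: _Node, acc: float) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.label, acc)]
            out = []
            for ch, ln in node.children:
                out.extend(leaves_below(ch, acc + ln))
            return out

        def walk(node: _Node):
            groups = [leaves_below(ch, ln) for ch, ln in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for la, da in groups[gi]:
                        for lb, db in groups[gj]:
                            dists.setdefault(la, {})[lb] = da + db
                            dists.setdefault(lb, {})[la] = da + db
            for ch, _ in node.children:
                if not ch.is_leaf:
                    walk(ch)

        walk(self.root)
        labels = sorted(self.leaf_names())
        n = len(labels)
        d = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    d[i, j] = dists[a][b]
        return DistanceMatrix(labels=labels, d=d)


def neighbor_joining(dm: DistanceMatrix) -> NjTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken toward the smallest sorted label pair
    (internal nodes inherit the smallest leaf label of their clade).  Negative
    branch lengths are clipped to 0 with the residual moved to the sister
    edge, preserving the joined pair's path length.
    """
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValidationError("neighbor joining needs at least 3 units")
    if not np.isfinite(dm.d).all():
        raise ValidationError("non-finite distances")

    nodes = [_Node(label=lab) for lab in dm.labels]
    labels = list(dm.labels)
    d = dm.d.astype(float).copy()
    active = list(range(n0))

    def join_lengths(dij: float, li: float, lj: float) -> tuple[float, float]:
        # clip negatives to 0 moving the residual to the sister edge; if the
        # pair distance itself is negative both edges collapse to 0
        if li < 0.0:
            li, lj = 0.0, lj + li
        if lj < 0.0:
            li, lj = max(li + lj, 0.0), 0.0
        return li, lj

    while len(active) > 3:
        nn = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (nn - 2) * d[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((labels[i], labels[j])))
                if best is None or q < best[0] - 1e-15 or (
                    abs(q - best[0]) <= 1e-15 and pair_key < best[1]
                ):
                    best = (q, pair_key, i, j)
        _, _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (nn - 2))
        lj = d[i, j] - li
        li, lj = join_lengths(d[i, j], li, lj)
        new = _Node(label=min(labels[i], labels[j]),
                    children=[(nodes[i], li), (nodes[j], lj)])
        # grow matrix with the merged node
        u = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(new)
        labels.append(new.label)
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = _Node(
        label=min(labels[a], labels[b], labels[c]),
        children=[
            (nodes[a], max(la, 0.0)),
            (nodes[b], max(lb, 0.0)),
            (nodes[c], max(lc, 0.0)),
        ],
    )
    return NjTree(root=root)
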