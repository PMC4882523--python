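"""Construction helpers and brute-force oracles shared by the test modules."""

import numpy as np

from sweepscan import (
    GenotypeMatrix,
    HaplotypeSet,
    PopulationMap,
    VariantRecord,
)


def make_variants(n, chrom="1", spacing=1000, start=1000):
    return [
        VariantRecord(chrom=chrom, pos=start + i * spacing, vid=f"v{chrom}_{i}",
                      ref="A", alt="G")
        for i in range(n)
    ]


def make_gm(dosage, chrom="1", positions=None, samples=None, spacing=1000):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if samples is None:
        samples = [f"S{i:03d}" for i in range(n)]
    if positions is None:
        variants = make_variants(m, chrom=chrom, spacing=spacing)
    else:
        variants = [
            VariantRecord(chrom=chrom, pos=int(p), vid=f"v{chrom}_{i}", ref="A", alt="G")
            for i, p in enumerate(positions)
        ]
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def make_haps(haps, positions=None, chrom="1", spacing=1000):
    haps = np.asarray(haps, dtype=np.uint8)
    nh, m = haps.shape
    assert nh % 2 == 0
    samples = [f"S{i:03d}" for i in range(nh // 2)]
    if positions is None:
        variants = make_variants(m, chrom=chrom, spacing=spacing)
    else:
        variants = [
            VariantRecord(chrom=chrom, pos=int(p), vid=f"v{chrom}_{i}", ref="A", alt="G")
            for i, p in enumerate(positions)
        ]
    return HaplotypeSet(samples=samples, variants=variants, haplotypes=haps)


def two_group_popmap(samples, n1, breed1="B1", breed2="B2"):
    return PopulationMap(
        {
            s: ((breed1, "G1") if i < n1 else (breed2, "G2"))
            for i, s in enumerate(samples)
        }
    )


def ehh_pair_oracle(haps, core, j):
    """EHH at SNP j by O(n^2) enumeration of haplotype pairs over the
    segment [core..j] inclusive (the stated probability definition)."""
    haps = np.asarray(haps)
    lo, hi = min(core, j), max(core, j)
    n = haps.shape[0]
    same = 0
    total = 0
    for a in range(n):
        for b in range(a + 1, n):
            total += 1
            if np.array_equal(haps[a, lo:hi + 1], haps[b, lo:hi + 1]):
                same += 1
    return same / total


def wc_scalar_reference(n1, p1, h1, n2, p2, h2):
    """Scalar transcription of the two-population variance-component
    formulas, kept independent of the package implementation."""
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1.0)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    denom = a + b + c
    theta = a / denom if denom != 0 else float("nan")
    return a, b, c, theta


def random_tree_metric(rng, labels):
    """Additive (tree) metric from a random recursively built binary tree."""

    def build(leaves):
        if len(leaves) == 1:
            return {"leaf": leaves[0]}
        k = rng.integers(1, len(leaves))
        order = list(rng.permutation(leaves))
        return {
            "left": build(order[:k]),
            "right": build(order[k:]),
            "bl_left": float(rng.uniform(0.5, 2.0)),
            "bl_right": float(rng.uniform(0.5, 2.0)),
        }

    tree = build(list(labels))
    dists = {}

    def collect(node, acc):
        if "leaf" in node:
            return [(node["leaf"], acc)]
        return collect(node["left"], acc + node["bl_left"]) + collect(
            node["right"], acc + node["bl_right"]
        )

    def walk(node):
        if "leaf" in node:
            return
        left = collect(node["left"], node["bl_left"])
        right = collect(node["right"], node["bl_right"])
        for la, da in left:
            for lb, db in right:
                dists[(la, lb)] = dists[(lb, la)] = da + db
        walk(node["left"])
        walk(node["right"])

    walk(tree)
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                d[i, j] = dists[(a, b)]
    return d
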