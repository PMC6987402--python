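"""Independent reference implementations used only as test oracles.

Everything here is deliberately written as plain scalar/loop code, directly
from the published formulas, sharing no code with the library so that
agreement between the two is evidence of correctness rather than tautology.
"""
from __future__ import annotations

from fractions import Fraction

import numpy as np


def wc_locus_oracle(n_list, p_list, h_list):
    """Weir & Cockerham (1984) variance components for one biallelic locus.

    Scalar transcription of the published a, b, c formulas for populations
    with n_i sampled diploids, alt frequency p_i and heterozygote fraction h_i.
    Returns (a, b, c) or None when fewer than two populations have data or
    nbar <= 1.
    """
    data = [(n, p, h) for n, p, h in zip(n_list, p_list, h_list) if n > 0]
    if len(data) < 2:
        return None
    r = len(data)
    nbar = sum(n for n, _, _ in data) / r
    if nbar <= 1:
        return None
    pbar = sum(n * p for n, p, _ in data) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p, _ in data) / ((r - 1) * nbar)
    hbar = sum(n * h for n, _, h in data) / (r * nbar)
    n_c = (r * nbar - sum(n**2 for n, _, _ in data) / (r * nbar)) / (r - 1)
    if n_c <= 0:
        return None
    a = (nbar / n_c) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def pi_window_oracle(geno_pop: np.ndarray, span: int) -> float:
    """Per-bp window pi as the mean pairwise Hamming distance over all pairs
    of called allele copies, summed over sites; O(m^2) per site."""
    total = 0.0
    for site in geno_pop:
        # expand dosage to allele copies: 0 -> (0,0), 1 -> (1,0), 2 -> (1,1)
        copies = []
        for g in site:
            if g == 0:
                copies += [0, 0]
            elif g == 1:
                copies += [1, 0]
            elif g == 2:
                copies += [1, 1]
        m = len(copies)
        if m < 2:
            continue
        diff = 0
        for i in range(m):
            for j in range(i + 1, m):
                diff += copies[i] != copies[j]
        total += diff / (m * (m - 1) / 2)
    return total / span


def tajimas_d_oracle(alt_copy_counts, total_copy_counts, n: int):
    """Tajima (1989) D from per-site alt copy counts c_k out of m_k copies,
    with nominal sample size n; exact rationals for the constants."""
    S = sum(1 for c, m in zip(alt_copy_counts, total_copy_counts) if 0 < c < m)
    if S < 1 or n < 2:
        return None
    khat = sum(
        Fraction(2 * c * (m - c), m * (m - 1))
        for c, m in zip(alt_copy_counts, total_copy_counts) if m >= 2
    )
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return None
    return float(khat - Fraction(S) / a1) / float(var) ** 0.5


def filter_oracle(geno: np.ndarray, maf_min: float, callrate_min: float):
    """Brute-force retained-variant index list for the MAF/call-rate rule."""
    keep = []
    n_samples = geno.shape[1]
    for i, row in enumerate(geno):
        called = [g for g in row if g >= 0]
        if not called:
            continue
        callrate = len(called) / n_samples
        freq = sum(called) / (2 * len(called))
        maf = min(freq, 1 - freq)
        if callrate >= callrate_min and maf >= maf_min:
            keep.append(i)
    return keep


def dsr_oracle(chroms, starts, ends, fst, ratio, n_snps, fst_q, ratio_q, min_snps):
    """Brute-force joint top-quantile threshold-and-merge region caller."""
    eligible = [
        i for i in range(len(fst))
        if n_snps[i] >= min_snps and np.isfinite(fst[i]) and np.isfinite(ratio[i])
    ]
    fst_thr = np.quantile([fst[i] for i in eligible], fst_q)
    ratio_thr = np.quantile([ratio[i] for i in eligible], ratio_q)
    cand = sorted(
        (i for i in eligible if fst[i] >= fst_thr and ratio[i] >= ratio_thr),
        key=lambda i: (chroms[i], starts[i], ends[i]),
    )
    regions = []
    for i in cand:
        if regions and regions[-1][0] == chroms[i] and starts[i] <= regions[-1][2] + 1:
            regions[-1][2] = max(regions[-1][2], ends[i])
        else:
            regions.append([chroms[i], starts[i], ends[i]])
    return [tuple(r) for r in regions]


def random_additive_distances(rng: np.random.Generator, n_taxa: int):
    """Random additive distance matrix via random sequential joins.

    Returns (names, D, splits): D is exactly additive on a binary tree whose
    nontrivial bipartitions are ``splits``.
    """
    names = [chr(ord("A") + i) for i in range(n_taxa)]
    D = {}

    def get(x, y):
        return 0.0 if x == y else D[frozenset((x, y))]

    def put(x, y, v):
        D[frozenset((x, y))] = v

    # active clusters, each represented by dict leaf -> distance to cluster root
    clusters = [{nm: 0.0} for nm in names]
    splits = set()
    while len(clusters) > 2:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        li, lj = rng.uniform(0.5, 2.0, size=2)
        ci, cj = clusters[i], clusters[j]
        for x, dx in ci.items():
            for y, dy in cj.items():
                put(x, y, dx + li + lj + dy)
        merged = {**{k: v + li for k, v in ci.items()}, **{k: v + lj for k, v in cj.items()}}
        if 2 <= len(merged) <= n_taxa - 2:
            splits.add(frozenset(merged))
        clusters = [clusters[k] for k in range(len(clusters)) if k not in (i, j)] + [merged]
    ca, cb = clusters
    bridge = rng.uniform(0.5, 2.0)
    for x, dx in ca.items():
        for y, dy in cb.items():
            put(x, y, dx + bridge + dy)
    mat = np.array([[get(x, y) for y in names] for x in names])
    # normalise split orientation: side not containing the smallest name
    ref = min(names)
    norm = {frozenset(set(names) - s) if ref in s else s for s in splits}
    return names, mat, norm
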