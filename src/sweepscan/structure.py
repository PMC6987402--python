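"""Individual-level structure analyses.

* identity-by-state (IBS) genetic distance between samples,
* neighbor-joining tree (Saitou–Nei) with SNP-bootstrap bipartition support,
* PCA of Patterson-scaled dosages,
* LD decay from composite (dosage-correlation) r-squared on unphased genotypes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes_io import GenotypeMatrix, PopulationMap

__all__ = [
    "DistanceMatrix", "TreeNode", "ibs_distance", "nj_tree", "bipartitions",
    "bootstrap_support", "PCAResult", "pca", "ld_decay",
]


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def validate(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal is not zero")


def ibs_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """1 - mean allele-sharing over SNPs called in both samples.

    Per-SNP sharing is 1 for identical genotypes, 0.5 when dosages differ by
    one, 0 for opposite homozygotes, i.e. 1 - |g_i - g_j| / 2.
    """
    G = gm.geno
    A = [(G == k).astype(np.float64) for k in (0, 1, 2)]
    C = (G >= 0).astype(np.float64)
    co_called = C.T @ C
    # sum over co-called SNPs of |gi - gj|: IBS1 pairs weight 1, IBS0 weight 2
    ibs1 = A[0].T @ A[1] + A[1].T @ A[0] + A[1].T @ A[2] + A[2].T @ A[1]
    ibs0 = A[0].T @ A[2] + A[2].T @ A[0]
    zero = (co_called == 0) & ~np.eye(gm.n_samples, dtype=bool)
    if zero.any():
        i, j = np.argwhere(zero)[0]
        raise ValueError(
            f"samples {gm.samples[i]!r} and {gm.samples[j]!r} share no called SNPs")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (0.5 * ibs1 + ibs0) / co_called
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against float summation order
    return DistanceMatrix(list(gm.samples), d)


@dataclass
class TreeNode:
    """Node of an unrooted tree (rooted representation at an internal node)."""

    name: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)
    support: float | None = None
    clamped: bool = False

    def leaves(self) -> list["TreeNode"]:
        if not self.children:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def leaf_names(self) -> frozenset:
        return frozenset(l.name for l in self.leaves())

    def to_newick(self, include_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if not node.children:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if include_support and node.support is not None:
                label = f"{node.support:.3g}"
            return f"({inner}){label}:{node.length:.6g}"
        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def _pair_lengths(dij: float, ri: float, rj: float, r: int) -> tuple[float, float]:
    li = 0.5 * dij + (ri - rj) / (2 * (r - 2))
    return li, dij - li


def _clamp(li: float, lj: float) -> tuple[float, float, bool, bool]:
    ci = cj = False
    if li < 0:
        lj += li
        li, ci = 0.0, True
    if lj < 0:
        li += lj
        lj, cj = 0.0, True
        li = max(li, 0.0)
    return li, lj, ci, cj


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor joining with deterministic lexicographic tie-breaking.

    Negative branch lengths are clamped to zero with the deficit moved to the
    sibling branch (flagged via ``clamped``).  Returns the unrooted tree as a
    trifurcation at the final join.
    """
    dm.validate()
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 samples")
    D = dm.values.astype(float).copy()
    nodes = [TreeNode(name=s) for s in dm.ids]
    # deterministic identity of each active node = its smallest leaf name
    reps = [str(s) for s in dm.ids]
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin + 1e-12 * max(1.0, abs(qmin)))
        best = min(
            (tuple(sorted((reps[active[i]], reps[active[j]]))), i, j)
            for i, j in ties if i < j
        )
        i, j = best[1], best[2]
        ai, aj = active[i], active[j]
        li, lj = _pair_lengths(sub[i, j], R[i], R[j], r)
        li, lj, ci, cj = _clamp(li, lj)
        nodes[ai].length, nodes[ai].clamped = li, ci
        nodes[aj].length, nodes[aj].clamped = lj, cj
        parent = TreeNode(children=[nodes[ai], nodes[aj]])
        # reduced distances to the new node
        new_d = 0.5 * (D[ai, :] + D[aj, :] - D[ai, aj])
        D = np.vstack([D, new_d])
        D = np.hstack([D, np.append(new_d, 0.0)[:, None]])
        nodes.append(parent)
        reps.append(min(reps[ai], reps[aj]))
        k = len(nodes) - 1
        active = [x for x in active if x not in (ai, aj)] + [k]

    # final star join of the last three nodes
    order = sorted(range(3), key=lambda t: reps[active[t]])
    x, y, z = (active[t] for t in order)
    dxy, dxz, dyz = D[x, y], D[x, z], D[y, z]
    lx = 0.5 * (dxy + dxz - dyz)
    ly = 0.5 * (dxy + dyz - dxz)
    lz = 0.5 * (dxz + dyz - dxy)
    for node_idx, l in ((x, lx), (y, ly), (z, lz)):
        nodes[node_idx].length = max(l, 0.0)
        nodes[node_idx].clamped = l < 0
    return TreeNode(children=[nodes[x], nodes[y], nodes[z]])


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Internal-edge bipartitions, each normalised as the side NOT containing
    the lexicographically smallest leaf."""
    all_leaves = tree.leaf_names()
    ref = min(all_leaves)
    out: set[frozenset] = set()

    def walk(node: TreeNode) -> None:
        for ch in node.children:
            names = ch.leaf_names()
            if 2 <= len(names) <= len(all_leaves) - 2:
                side = names if ref not in names else all_leaves - names
                out.add(frozenset(side))
            walk(ch)

    walk(tree)
    return out


def bootstrap_support(gm: GenotypeMatrix, n_reps: int = 1000, seed: int = 0) -> TreeNode:
    """Point-estimate NJ tree with SNP-bootstrap bipartition support.

    SNP columns are resampled with replacement ``n_reps`` times; support of
    each internal bipartition of the point tree is the fraction of replicate
    trees containing it.
    """
    tree = nj_tree(ibs_distance(gm))
    if n_reps == 0:
        return tree
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(tree)}
    for _ in range(n_reps):
        idx = rng.integers(0, gm.n_variants, size=gm.n_variants)
        rep_tree = nj_tree(ibs_distance(gm.take_variants(idx)))
        for bp in bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1
    all_leaves = tree.leaf_names()
    ref = min(all_leaves)

    def annotate(node: TreeNode) -> None:
        for ch in node.children:
            names = ch.leaf_names()
            if 2 <= len(names) <= len(all_leaves) - 2:
                side = names if ref not in names else all_leaves - names
                if frozenset(side) in counts:
                    ch.support = counts[frozenset(side)] / n_reps
            annotate(ch)

    annotate(tree)
    return tree


@dataclass
class PCAResult:
    ids: list[str]
    coords: np.ndarray            # samples x components
    explained: np.ndarray         # fraction of variance per component

    def to_frame(self, pm: PopulationMap | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords, index=self.ids,
            columns=[f"PC{i + 1}" for i in range(self.coords.shape[1])],
        )
        if pm is not None:
            df.insert(0, "population", [pm.assignment.get(s, "") for s in self.ids])
        return df


def pca(gm: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """PCA of mean-imputed, Patterson-scaled genotype dosages.

    Each SNP is centred by its mean dosage and scaled by sqrt(p(1-p)) with p
    the panel allele frequency; monomorphic SNPs are dropped.  Coordinates are
    eigenvectors of the sample covariance scaled by the singular values; per
    component, the entry of largest magnitude is made positive.
    """
    G = gm.geno.astype(float)
    G[G < 0] = np.nan
    mean = np.nanmean(G, axis=1)
    p = mean / 2.0
    keep = (p > 0) & (p < 1)
    G, mean, p = G[keep], mean[keep], p[keep]
    X = np.where(np.isnan(G), 0.0, G - mean[:, None]) / np.sqrt(p * (1 - p))[:, None]
    cov = (X.T @ X) / X.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    k = min(n_components, len(evals))
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    for c in range(k):
        if coords[np.argmax(np.abs(coords[:, c])), c] < 0:
            coords[:, c] *= -1
    total = evals.sum()
    explained = evals[:k] / total if total > 0 else np.zeros(k)
    return PCAResult(list(gm.samples), coords, explained)


def ld_decay(gm: GenotypeMatrix, pm: PopulationMap, pop: str,
             max_dist: int = 500_000, n_bins: int = 50) -> pd.DataFrame:
    """Binned mean composite r-squared vs physical distance within a population.

    r is the Pearson correlation of genotype dosages over samples called at
    both SNPs of a pair; all intra-chromosomal pairs within ``max_dist`` are
    used.  SNPs monomorphic among the population's called genotypes are
    skipped.  Returns columns ``bin_mid_bp``, ``mean_r2``, ``n_pairs``.
    """
    cols = pm.member_indices(gm, pop)
    dist_all: list[np.ndarray] = []
    r2_all: list[np.ndarray] = []
    for chrom, sl in gm.chrom_slices().items():
        G = gm.geno[sl][:, cols].astype(float)
        G[G < 0] = np.nan
        with np.errstate(invalid="ignore"):
            poly = np.nanstd(G, axis=1) > 0
        G, pos = G[poly], gm.pos[sl][poly]
        L = len(pos)
        for k in range(1, L):
            d = pos[k:] - pos[:-k]
            mask = d <= max_dist
            if not mask.any():
                break
            x, y = G[:-k][mask], G[k:][mask]
            valid = ~np.isnan(x) & ~np.isnan(y)
            nv = valid.sum(axis=1).astype(float)
            xz = np.where(valid, x, 0.0)
            yz = np.where(valid, y, 0.0)
            sx, sy = xz.sum(1), yz.sum(1)
            sxx, syy = (xz**2).sum(1), (yz**2).sum(1)
            sxy = (xz * yz).sum(1)
            with np.errstate(invalid="ignore", divide="ignore"):
                num = nv * sxy - sx * sy
                den = (nv * sxx - sx**2) * (nv * syy - sy**2)
                r2 = np.where((nv >= 4) & (den > 0), num**2 / np.where(den > 0, den, 1.0), np.nan)
            ok = np.isfinite(r2)
            dist_all.append(d[mask][ok])
            r2_all.append(r2[ok])
    if not dist_all:
        return pd.DataFrame({"bin_mid_bp": [], "mean_r2": [], "n_pairs": []})
    dist = np.concatenate(dist_all)
    r2 = np.concatenate(r2_all)
    edges = np.linspace(0, max_dist, n_bins + 1)
    idx = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=r2, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({
        "bin_mid_bp": (edges[:-1] + edges[1:]) / 2.0,
        "mean_r2": means,
        "n_pairs": counts,
    })
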