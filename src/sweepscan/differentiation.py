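"""Weir–Cockerham Fst: per-locus variance components and ratio-of-sums estimates.

Per locus, with r populations contributing n_i called diploids, alt frequency
p_i and observed-heterozygote fraction h_i:

    nbar = sum(n_i)/r
    pbar = sum(n_i p_i) / (r nbar)
    s2   = sum(n_i (p_i - pbar)^2) / ((r-1) nbar)
    hbar = sum(n_i h_i) / (r nbar)
    n_c  = (r nbar - sum(n_i^2)/(r nbar)) / (r - 1)

    a = (nbar/n_c) [ s2 - (pbar(1-pbar) - ((r-1)/r) s2 - hbar/4) / (nbar-1) ]
    b = (nbar/(nbar-1)) [ pbar(1-pbar) - ((r-1)/r) s2 - ((2 nbar - 1)/(4 nbar)) hbar ]
    c = hbar/2

and the multi-locus estimate is theta = sum(a) / sum(a+b+c) over usable loci
(ratio of sums, never a mean of per-locus ratios).  A locus is unusable when
fewer than two populations have data, when nbar <= 1, or when it is monomorphic
across the populations compared (zero denominator); negative per-locus
components are retained in the sums.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes_io import GenotypeMatrix, PopulationMap

__all__ = [
    "WCComponents", "wc_components", "population_locus_stats",
    "fst_components", "fst_multilocus", "pairwise_fst_matrix", "write_fst_matrix",
]


@dataclass
class WCComponents:
    a: np.ndarray        # among-population component
    b: np.ndarray        # among-individual-within-population component
    c: np.ndarray        # within-individual component
    usable: np.ndarray   # bool; loci entering the ratio of sums

    @property
    def denom(self) -> np.ndarray:
        return self.a + self.b + self.c


def wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> WCComponents:
    """Variance components from per-population locus summaries.

    ``n`` (called diploids), ``p`` (alt frequency) and ``h`` (observed het
    fraction) have shape ``(r,)`` for a single locus or ``(r, L)``; populations
    with ``n == 0`` at a locus are dropped from that locus.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    scalar = n.ndim == 1
    if scalar:
        n, p, h = n[:, None], p[:, None], h[:, None]
    present = n > 0
    p = np.where(present, p, 0.0)
    h = np.where(present, h, 0.0)
    r = present.sum(axis=0).astype(float)
    ntot = n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = ntot / r
        pbar = (n * p).sum(axis=0) / ntot
        hbar = (n * h).sum(axis=0) / ntot
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        n_c = (ntot - (n**2).sum(axis=0) / ntot) / (r - 1)
        inner = pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4
        a = (nbar / n_c) * (s2 - inner / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
    usable = (r >= 2) & (nbar > 1) & (n_c > 0)
    a = np.where(usable, a, 0.0)
    b = np.where(usable, b, 0.0)
    c = np.where(usable, c, 0.0)
    usable = usable & ((a + b + c) != 0.0)
    if scalar:
        return WCComponents(a[0], b[0], c[0], usable[0])
    return WCComponents(a, b, c, usable)


def population_locus_stats(gm: GenotypeMatrix, pm: PopulationMap,
                           pops: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-population (n, p, h) arrays of shape (r, n_variants)."""
    n = np.empty((len(pops), gm.n_variants))
    p = np.empty_like(n)
    h = np.empty_like(n)
    for k, pop in enumerate(pops):
        sub = gm.geno[:, pm.member_indices(gm, pop)]
        called = sub >= 0
        nk = called.sum(axis=1).astype(float)
        alt = np.where(called, sub, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(nk > 0, alt / np.maximum(2 * nk, 1), 0.0)
            h[k] = np.where(nk > 0, (sub == 1).sum(axis=1) / np.maximum(nk, 1), 0.0)
        n[k] = nk
    return n, p, h


def fst_components(gm: GenotypeMatrix, pm: PopulationMap,
                   pop_a: str, pop_b: str) -> WCComponents:
    """Per-locus WC components for a two-group comparison (groups may be pools)."""
    n, p, h = population_locus_stats(gm, pm, [pop_a, pop_b])
    return wc_components(n, p, h)


def fst_multilocus(gm: GenotypeMatrix, pm: PopulationMap, pop_a: str, pop_b: str,
                   loci: np.ndarray | None = None,
                   truncate: bool = False) -> tuple[float, int]:
    """Multi-locus theta-hat between two populations/pools; returns
    ``(theta, n_usable_loci)``.  ``truncate`` clips the final estimate to
    [0, 1] at reporting time only."""
    comp = fst_components(gm, pm, pop_a, pop_b)
    a, d, usable = np.atleast_1d(comp.a), np.atleast_1d(comp.denom), np.atleast_1d(comp.usable)
    if loci is not None:
        mask = np.zeros(len(a), dtype=bool)
        mask[loci] = True
        usable = usable & mask
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError(f"no usable loci for {pop_a} vs {pop_b}")
    theta = float(a[usable].sum() / d[usable].sum())
    if truncate:
        theta = min(1.0, max(0.0, theta))
    return theta, n_usable


def pairwise_fst_matrix(gm: GenotypeMatrix, pm: PopulationMap,
                        populations: list[str] | None = None) -> pd.DataFrame:
    """Symmetric matrix of multi-locus theta-hat, zero diagonal."""
    pops = populations if populations is not None else pm.populations
    mat = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            theta, _ = fst_multilocus(gm, pm, pops[i], pops[j])
            mat[i, j] = mat[j, i] = theta
    return pd.DataFrame(mat, index=pops, columns=pops)


def write_fst_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.4f")
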