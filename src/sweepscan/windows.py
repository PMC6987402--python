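"""Sliding-window engine and windowed statistics: pi, Fst, Tajima's D.

Windows are 1-based inclusive intervals (default 100 kb, stepping 10 kb),
tiled from position 1 of each chromosome; a window is emitted iff its start
lies on the chromosome, with its end clipped to the chromosome length.

Per-site nucleotide diversity uses the pairwise-difference form
2 c (m - c) / (m (m - 1)) with c alt allele copies and m called copies in the
population; window pi is the per-site sum divided by the window span in bp.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes_io import GenotypeMatrix, PopulationMap, ChromTable
from .differentiation import fst_components

__all__ = [
    "Window", "make_windows", "window_snp_counts", "window_pi", "window_fst",
    "tajimas_d", "window_table",
]


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int   # 1-based inclusive
    end: int     # 1-based inclusive
    index: int

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def make_windows(ct: ChromTable, size: int = 100_000, step: int = 10_000) -> list[Window]:
    """Sliding windows over every chromosome in the table."""
    if not ct:
        raise ValueError("empty chromosome table")
    if not (size >= step >= 1):
        raise ValueError("require size >= step >= 1")
    out: list[Window] = []
    idx = 0
    for chrom, length in ct.items():
        start = 1
        while start <= length:
            out.append(Window(chrom, start, min(start + size - 1, length), idx))
            idx += 1
            start += step
    return out


def _window_sums(gm: GenotypeMatrix, windows: list[Window],
                 values: np.ndarray) -> np.ndarray:
    """Sum per-variant ``values`` over each window via per-chromosome prefix sums."""
    sums = np.zeros(len(windows))
    slices = gm.chrom_slices()
    for chrom, sl in slices.items():
        pos = gm.pos[sl]
        csum = np.concatenate([[0.0], np.cumsum(values[sl])])
        wlist = [(k, w) for k, w in enumerate(windows) if w.chrom == chrom]
        if not wlist:
            continue
        starts = np.array([w.start for _, w in wlist])
        ends = np.array([w.end for _, w in wlist])
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        idx = np.array([k for k, _ in wlist])
        sums[idx] = csum[hi] - csum[lo]
    return sums


def _window_slices(gm: GenotypeMatrix, windows: list[Window]) -> list[slice]:
    """Variant index range of each window (global variant coordinates)."""
    out: list[slice] = [slice(0, 0)] * len(windows)
    for chrom, sl in gm.chrom_slices().items():
        pos = gm.pos[sl]
        for k, w in enumerate(windows):
            if w.chrom != chrom:
                continue
            lo = int(np.searchsorted(pos, w.start, side="left"))
            hi = int(np.searchsorted(pos, w.end, side="right"))
            out[k] = slice(sl.start + lo, sl.start + hi)
    return out


def window_snp_counts(gm: GenotypeMatrix, windows: list[Window]) -> np.ndarray:
    return _window_sums(gm, windows, np.ones(gm.n_variants)).astype(int)


def _site_pi_terms(gm: GenotypeMatrix, pm: PopulationMap, pop: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (pairwise-diff term, called allele copies) for a population."""
    sub = gm.geno[:, pm.member_indices(gm, pop)]
    called = sub >= 0
    c = np.where(called, sub, 0).sum(axis=1).astype(float)
    m = 2.0 * called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(m >= 2, 2.0 * c * (m - c) / (m * (m - 1)), 0.0)
    return t, m


def window_pi(gm: GenotypeMatrix, pm: PopulationMap, pop: str,
              windows: list[Window]) -> np.ndarray:
    """Per-bp nucleotide diversity per window (0 for SNP-free windows)."""
    t, _ = _site_pi_terms(gm, pm, pop)
    spans = np.array([w.span for w in windows], dtype=float)
    return _window_sums(gm, windows, t) / spans


def window_fst(gm: GenotypeMatrix, pm: PopulationMap, pop_a: str, pop_b: str,
               windows: list[Window]) -> np.ndarray:
    """Ratio-of-sums Weir–Cockerham theta per window; NaN where no usable loci."""
    comp = fst_components(gm, pm, pop_a, pop_b)
    a = np.where(comp.usable, comp.a, 0.0)
    d = np.where(comp.usable, comp.denom, 0.0)
    a_sum = _window_sums(gm, windows, a)
    d_sum = _window_sums(gm, windows, d)
    n_use = _window_sums(gm, windows, comp.usable.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where((n_use > 0) & (d_sum != 0), a_sum / np.where(d_sum != 0, d_sum, 1.0), np.nan)
    return theta


def _tajima_constants(n: np.ndarray) -> tuple[np.ndarray, ...]:
    """Tajima's normalisation constants for (possibly vectorised) sample size n."""
    n = np.asarray(n, dtype=float)
    nmax = int(n.max()) if n.size else 1
    inv = np.concatenate([[0.0], 1.0 / np.arange(1, max(nmax, 2))])
    a1_tab = np.cumsum(inv)
    a2_tab = np.cumsum(inv**2)
    ni = n.astype(int)
    a1 = a1_tab[np.clip(ni - 1, 0, len(a1_tab) - 1)]
    a2 = a2_tab[np.clip(ni - 1, 0, len(a2_tab) - 1)]
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(gm: GenotypeMatrix, pm: PopulationMap, pop: str,
              windows: list[Window], min_s: int = 3) -> np.ndarray:
    """Tajima's D per window for one population; NaN where undefined.

    The nominal sample size n is the modal called allele-copy count across the
    window's sites (sites keep their own copy number inside the pairwise term),
    so scattered missingness does not force per-site recomputation of the
    normalising constants.  Requires at least ``min_s`` segregating sites and
    n >= 4 copies.
    """
    t, m = _site_pi_terms(gm, pm, pop)
    sub = gm.geno[:, pm.member_indices(gm, pop)]
    called = sub >= 0
    c = np.where(called, sub, 0).sum(axis=1).astype(float)
    seg = (c > 0) & (c < m)
    slices = _window_slices(gm, windows)
    D = np.full(len(windows), np.nan)
    S_arr = np.zeros(len(windows), dtype=int)
    n_arr = np.zeros(len(windows))
    k_arr = np.zeros(len(windows))
    for k, sl in enumerate(slices):
        m_w = m[sl]
        m_w = m_w[m_w > 0]
        if m_w.size == 0:
            continue
        vals, counts = np.unique(m_w, return_counts=True)
        n_arr[k] = vals[np.argmax(counts)]   # ties: smallest modal value
        S_arr[k] = int(seg[sl].sum())
        k_arr[k] = t[sl].sum()
    ok = (S_arr >= max(min_s, 1)) & (n_arr >= 4)
    if ok.any():
        n = n_arr[ok]
        S = S_arr[ok].astype(float)
        a1, e1, e2 = _tajima_constants(n)
        with np.errstate(invalid="ignore", divide="ignore"):
            var = e1 * S + e2 * S * (S - 1)
            d = np.where(var > 0, (k_arr[ok] - S / a1) / np.sqrt(np.where(var > 0, var, 1.0)), np.nan)
        D[ok] = d
    return D


def window_table(gm: GenotypeMatrix, pm: PopulationMap, windows: list[Window],
                 pi_pops: list[str] = (), fst_pairs: list[tuple[str, str]] = (),
                 d_pops: list[str] = ()) -> pd.DataFrame:
    """Tidy per-window statistics table with one column per requested statistic."""
    df = pd.DataFrame({
        "chrom": [w.chrom for w in windows],
        "start": [w.start for w in windows],
        "end": [w.end for w in windows],
        "n_snps": window_snp_counts(gm, windows),
    })
    for pop in pi_pops:
        df[f"pi_{pop}"] = window_pi(gm, pm, pop, windows)
    for pa, pb in fst_pairs:
        df[f"fst_{pa}_{pb}"] = window_fst(gm, pm, pa, pb, windows)
    for pop in d_pops:
        df[f"tajima_d_{pop}"] = tajimas_d(gm, pm, pop, windows)
    return df
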