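"""Per-population genetic-diversity statistics: Ho, He, Nei, PIC, MAF.

Definitions (per variant, averaged unweighted over variants):

* Ho  — fraction of heterozygous genotypes among called genotypes.
* He  — 2*p*(1-p) with p the population alt-allele frequency.
* Nei — unbiased gene diversity (2n/(2n-1)) * (1 - p^2 - q^2), n = called
        diploids at the variant.
* PIC — biallelic polymorphism information content,
        1 - (p^2 + q^2) - 2 p^2 q^2 (Botstein's measure).
* MAF — min(p, 1-p).

Variants monomorphic within a population contribute 0; variants with no called
genotype in the population are skipped (complete-case within population).
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes_io import GenotypeMatrix, PopulationMap, allele_freq

__all__ = [
    "observed_het", "expected_het", "nei_diversity", "pic", "mean_maf",
    "diversity_table", "write_diversity_table",
]


def _pop_geno(gm: GenotypeMatrix, pm: PopulationMap, pop: str) -> np.ndarray:
    cols = pm.member_indices(gm, pop)
    if len(cols) == 0:
        raise ValueError(f"population {pop!r} has no samples")
    return gm.geno[:, cols]


def observed_het(gm: GenotypeMatrix, pm: PopulationMap, pop: str) -> float:
    sub = _pop_geno(gm, pm, pop)
    called = sub >= 0
    n = called.sum(axis=1)
    het = (sub == 1).sum(axis=1)
    ok = n > 0
    if not ok.any():
        raise ValueError(f"no called genotypes in population {pop!r}")
    return float(np.mean(het[ok] / n[ok]))


def _freqs(gm: GenotypeMatrix, pm: PopulationMap, pop: str) -> tuple[np.ndarray, np.ndarray]:
    freq, copies = allele_freq(gm, pm, pop)
    ok = copies > 0
    if not ok.any():
        raise ValueError(f"no called genotypes in population {pop!r}")
    return freq[ok], copies[ok]


def expected_het(gm: GenotypeMatrix, pm: PopulationMap, pop: str) -> float:
    p, _ = _freqs(gm, pm, pop)
    return float(np.mean(2 * p * (1 - p)))


def nei_diversity(gm: GenotypeMatrix, pm: PopulationMap, pop: str) -> float:
    if len(pm.samples_of(pop)) == 1:
        warnings.warn(
            f"population {pop!r} has a single sample; Nei unbiased correction "
            "factor degenerates to 2", stacklevel=2)
    p, copies = _freqs(gm, pm, pop)
    single = copies < 2
    if single.any():
        warnings.warn(
            f"{int(single.sum())} variants with a single allele copy in {pop!r}; "
            "unbiased correction degenerate there", stacklevel=2)
        p, copies = p[~single], copies[~single]
    corr = copies / (copies - 1)
    return float(np.mean(corr * (1 - p**2 - (1 - p) ** 2)))


def pic(gm: GenotypeMatrix, pm: PopulationMap, pop: str) -> float:
    p, _ = _freqs(gm, pm, pop)
    q = 1 - p
    return float(np.mean(1 - (p**2 + q**2) - 2 * p**2 * q**2))


def mean_maf(gm: GenotypeMatrix, pm: PopulationMap, pop: str) -> float:
    p, _ = _freqs(gm, pm, pop)
    return float(np.mean(np.minimum(p, 1 - p)))


def diversity_table(gm: GenotypeMatrix, pm: PopulationMap,
                    populations: list[str] | None = None) -> pd.DataFrame:
    """One row per population with columns Ho, He, Nei, PIC, MAF."""
    pops = populations if populations is not None else pm.populations
    rows = []
    for pop in pops:
        rows.append({
            "population": pop,
            "Ho": observed_het(gm, pm, pop),
            "He": expected_het(gm, pm, pop),
            "Nei": nei_diversity(gm, pm, pop),
            "PIC": pic(gm, pm, pop),
            "MAF": mean_maf(gm, pm, pop),
        })
    return pd.DataFrame(rows).set_index("population")


def write_diversity_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", float_format="%.4f")
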