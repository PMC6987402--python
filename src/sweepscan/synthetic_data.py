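"""Structured-population genotype simulator with known truth.

The model is Balding–Nichols: each SNP has an ancestral alt frequency p drawn
from a truncated Beta; each population i with drift parameter F_i draws its own
frequency p_i ~ Beta(p(1-F_i)/F_i, (1-p)(1-F_i)/F_i), so the expected
Weir–Cockerham Fst between two populations with equal F is F.  Linkage
disequilibrium is induced by sampling each individual's two chromosome copies
as mosaics of K founder haplotypes, with a per-bp founder-switch rate; selective
sweeps are injected by overriding the target population's frequency with a
near-fixation value inside chosen intervals.  Everything is reproducible from
a single integer seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .genotypes_io import MISSING, ChromTable, GenotypeMatrix, PopulationMap

_BASES = np.array(["A", "C", "G", "T"], dtype=object)


@dataclass(frozen=True)
class SweepSpec:
    """A selective sweep: within [start, end] (1-based inclusive) on ``chrom``,
    the ``pop`` population's allele frequency is overridden with ``freq``."""

    chrom: str
    start: int
    end: int
    pop: str
    freq: float = 0.98


@dataclass
class SimConfig:
    """Simulation parameters; defaults emulate a desk-scale livestock panel
    (10 populations of 8 diploids, 3 x 10 Mb chromosomes, ~30k SNPs)."""

    pop_names: list[str] = field(default_factory=lambda: list_default_pops())
    samples_per_pop: dict[str, int] | int = 8
    pop_F: dict[str, float] | float = 0.2
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}
    )
    snp_density: float = 1e-3
    beta_shape: tuple[float, float] = (1.0, 1.0)
    freq_bounds: tuple[float, float] = (0.05, 0.95)
    founder_haplotypes: int | None = 30
    switch_rate: float = 1e-5
    missing_rate: float = 0.1
    sweep_specs: list[SweepSpec] = field(default_factory=list)
    seed: int = 0

    def n_samples(self, pop: str) -> int:
        if isinstance(self.samples_per_pop, dict):
            return self.samples_per_pop[pop]
        return int(self.samples_per_pop)

    def F(self, pop: str) -> float:
        if isinstance(self.pop_F, dict):
            return self.pop_F[pop]
        return float(self.pop_F)

    def validate(self) -> None:
        for rate, name in ((self.missing_rate, "missing_rate"),):
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        for p in self.pop_names:
            if not 0 <= self.F(p) < 1:
                raise ValueError(f"pop_F[{p}] must be in [0,1)")
        for sw in self.sweep_specs:
            if sw.pop not in self.pop_names:
                raise ValueError(f"sweep targets unknown population {sw.pop!r}")
            L = self.chrom_lengths.get(sw.chrom)
            if L is None or not (1 <= sw.start <= sw.end <= L):
                raise ValueError(f"sweep interval {sw} outside chromosome bounds")
            if not 0 < sw.freq < 1:
                raise ValueError("sweep freq must be in (0,1)")


def list_default_pops() -> list[str]:
    # three commercial breeds (pooled as DLY downstream) + seven indigenous
    return ["DD", "LL", "YY", "DPL", "LW", "HG", "WL", "YTL", "YTW", "LC"]


def default_config(seed: int, with_sweeps: bool = True, target: str = "DPL") -> SimConfig:
    """The package's reference synthetic genome: F=0.2 background and, when
    requested, five 200-kb sweeps in the target population."""
    sweeps = []
    if with_sweeps:
        sweeps = [
            SweepSpec("chr1", 2_000_001, 2_200_000, target),
            SweepSpec("chr1", 6_500_001, 6_700_000, target),
            SweepSpec("chr2", 3_000_001, 3_200_000, target),
            SweepSpec("chr2", 8_100_001, 8_300_000, target),
            SweepSpec("chr3", 5_000_001, 5_200_000, target),
        ]
    return SimConfig(sweep_specs=sweeps, seed=seed)


@dataclass
class SimTruth:
    """Ground truth emitted alongside the genotypes."""

    anc_freq: np.ndarray                  # per-SNP ancestral frequency
    pop_freq: dict[str, np.ndarray]       # per-population realized frequency
    sweeps: list[SweepSpec]
    config: SimConfig


def _truncated_beta(rng: np.random.Generator, a: float, b: float,
                    lo: float, hi: float, size: int) -> np.ndarray:
    dist = stats.beta(a, b)
    clo, chi = dist.cdf(lo), dist.cdf(hi)
    return dist.ppf(clo + rng.random(size) * (chi - clo))


def _mosaic_copies(rng: np.random.Generator, founders: np.ndarray,
                   positions: np.ndarray, switch_rate: float, n_copies: int) -> np.ndarray:
    """Sample ``n_copies`` haplotypes as founder mosaics along ``positions``."""
    K, S = founders.shape
    q = np.empty(S)
    q[0] = 1.0  # always draw a founder at the first site
    q[1:] = 1.0 - np.exp(-switch_rate * np.diff(positions))
    switch = rng.random((n_copies, S)) < q
    draws = rng.integers(0, K, size=(n_copies, S))
    cols = np.arange(S)
    last = np.maximum.accumulate(np.where(switch, cols, -1), axis=1)
    fid = np.take_along_axis(draws, last, axis=1)
    return founders[fid, cols]


def simulate(cfg: SimConfig) -> tuple[GenotypeMatrix, PopulationMap, ChromTable, SimTruth]:
    """Generate a genotype panel under ``cfg``; fully deterministic given the seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    a, b = cfg.beta_shape
    lo, hi = cfg.freq_bounds

    chroms, positions_all = [], []
    anc_all: list[np.ndarray] = []
    pop_freq_blocks: dict[str, list[np.ndarray]] = {p: [] for p in cfg.pop_names}
    geno_blocks: list[np.ndarray] = []

    for chrom, L in cfg.chrom_lengths.items():
        n_raw = rng.poisson(L * cfg.snp_density)
        positions = np.unique(rng.integers(1, L + 1, size=n_raw)) if n_raw else np.array([], dtype=np.int64)
        S = len(positions)
        if S == 0:
            continue
        p_anc = _truncated_beta(rng, a, b, lo, hi, S)
        chrom_geno = []
        for pop in cfg.pop_names:
            F = cfg.F(pop)
            if F < 1e-12:
                p_i = p_anc.copy()
            else:
                scale = (1.0 - F) / F
                p_i = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)
            for sw in cfg.sweep_specs:
                if sw.chrom == chrom and sw.pop == pop:
                    mask = (positions >= sw.start) & (positions <= sw.end)
                    p_i[mask] = sw.freq
            n_i = cfg.n_samples(pop)
            if cfg.founder_haplotypes is None:
                copies = rng.random((2 * n_i, S)) < p_i
            else:
                founders = rng.random((cfg.founder_haplotypes, S)) < p_i
                copies = _mosaic_copies(rng, founders, positions, cfg.switch_rate, 2 * n_i)
            g = (copies[0::2].astype(np.int8) + copies[1::2].astype(np.int8))
            chrom_geno.append(g.T)  # -> variants x samples
            pop_freq_blocks[pop].append(p_i)
        chroms.extend([chrom] * S)
        positions_all.append(positions)
        anc_all.append(p_anc)
        geno_blocks.append(np.concatenate(chrom_geno, axis=1))

    if not geno_blocks:
        raise ValueError("snp_density too low: zero SNPs simulated")

    geno = np.concatenate(geno_blocks, axis=0)
    if cfg.missing_rate > 0:
        geno[rng.random(geno.shape) < cfg.missing_rate] = MISSING

    n_var = geno.shape[0]
    ref_idx = rng.integers(0, 4, size=n_var)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_var)) % 4

    sample_ids, assignment = [], {}
    for pop in cfg.pop_names:
        for i in range(cfg.n_samples(pop)):
            sid = f"{pop}_{i + 1:02d}"
            sample_ids.append(sid)
            assignment[sid] = pop

    gm = GenotypeMatrix(
        np.array(chroms, dtype=object), np.concatenate(positions_all),
        _BASES[ref_idx], _BASES[alt_idx], geno, sample_ids,
    )
    pm = PopulationMap(assignment)
    ct = ChromTable(cfg.chrom_lengths)
    truth = SimTruth(
        anc_freq=np.concatenate(anc_all),
        pop_freq={p: np.concatenate(v) for p, v in pop_freq_blocks.items()},
        sweeps=list(cfg.sweep_specs),
        config=cfg,
    )
    gm.validate()
    pm.validate(gm)
    return gm, pm, ct, truth


def write_truth_bed(truth: SimTruth, path: str | Path) -> None:
    """Write sweep intervals as BED (0-based half-open), target pop in column 4."""
    rows = sorted(truth.sweeps, key=lambda s: (s.chrom, s.start))
    with open(path, "w") as fh:
        for s in rows:
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.pop}\n")


def config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["sweep_specs"] = [asdict(s) for s in cfg.sweep_specs]
    return d
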