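"""Genotype data model, VCF I/O, population maps and SNP filtering.

The central container is :class:`GenotypeMatrix`: a variants x samples table
of alt-allele dosages (0, 1, 2) with ``-1`` marking missing genotypes.  Only
biallelic SNPs are represented; multiallelic records are rejected or skipped
at read time.  Coordinates are 1-based throughout (VCF convention); the BED
writers convert to 0-based half-open at the last moment.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

MISSING: int = -1
_BASES = ("A", "C", "G", "T")


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for a panel of diploid samples.

    Attributes
    ----------
    chrom, pos : arrays, one entry per variant; ``pos`` is 1-based and must be
        strictly increasing within each chromosome.
    ref, alt : single-base allele strings per variant.
    geno : ``(n_variants, n_samples)`` int8 array of alt-allele counts, with
        :data:`MISSING` (-1) for uncalled genotypes.
    samples : ordered, unique sample identifiers.
    meta : free-form provenance (e.g. counts of skipped records).
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    geno: np.ndarray
    samples: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        self.samples = list(self.samples)

    @property
    def n_variants(self) -> int:
        return self.geno.shape[0]

    @property
    def n_samples(self) -> int:
        return self.geno.shape[1]

    def validate(self) -> None:
        """Raise ``ValueError`` if any container invariant is violated."""
        if self.geno.shape != (len(self.pos), len(self.samples)):
            raise ValueError("geno shape does not match positions/samples")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        bad = ~np.isin(self.geno, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype values outside {0,1,2,MISSING}")
        for c in dict.fromkeys(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    def called(self) -> np.ndarray:
        """Boolean mask of called genotypes, same shape as ``geno``."""
        return self.geno >= 0

    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[n] for n in names], dtype=np.intp)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"sample {e.args[0]!r} not in genotype matrix") from None

    def take_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.chrom[idx], self.pos[idx], self.ref[idx], self.alt[idx],
            self.geno[idx], list(self.samples), dict(self.meta),
        )

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous variant slice per chromosome, in order of appearance."""
        out: dict[str, slice] = {}
        start = 0
        for i in range(1, self.n_variants + 1):
            if i == self.n_variants or self.chrom[i] != self.chrom[start]:
                out[str(self.chrom[start])] = slice(start, i)
                start = i
        return out


@dataclass
class PopulationMap:
    """Sample -> population assignment, with optional pooled groups.

    A *pool* (e.g. ``DLY = {DD, LL, YY}``) behaves like a population whose
    samples are the union of its member populations' samples.
    """

    assignment: dict[str, str]
    pools: dict[str, set[str]] = field(default_factory=dict)

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.assignment.values()))

    def samples_of(self, label: str) -> list[str]:
        if label in self.pools:
            members = self.pools[label]
            return [s for s, p in self.assignment.items() if p in members]
        if label not in self.assignment.values():
            raise KeyError(f"unknown population or pool label {label!r}")
        return [s for s, p in self.assignment.items() if p == label]

    def member_indices(self, gm: GenotypeMatrix, label: str) -> np.ndarray:
        return gm.sample_indices(self.samples_of(label))

    def validate(self, gm: GenotypeMatrix) -> None:
        known = set(gm.samples)
        missing = [s for s in self.assignment if s not in known]
        if missing:
            raise ValueError(f"mapped samples absent from matrix: {missing[:5]}")
        pops = set(self.assignment.values())
        for pool, members in self.pools.items():
            bad = members - pops
            if bad:
                raise ValueError(f"pool {pool!r} references unknown populations {sorted(bad)}")
        if not pops:
            raise ValueError("population map is empty")

    @classmethod
    def from_tsv(cls, path: str | Path, pools: Mapping[str, Iterable[str]] | None = None) -> "PopulationMap":
        assignment: dict[str, str] = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 'sample<TAB>population'")
            if parts[0] in assignment:
                raise ValueError(f"{path}:{ln}: duplicate sample {parts[0]!r}")
            assignment[parts[0]] = parts[1]
        return cls(assignment, {k: set(v) for k, v in (pools or {}).items()})

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text("".join(f"{s}\t{p}\n" for s, p in self.assignment.items()))


class ChromTable(dict):
    """Chromosome label -> length (bp)."""

    def validate(self, gm: GenotypeMatrix | None = None) -> None:
        for c, length in self.items():
            if length <= 0:
                raise ValueError(f"non-positive length for {c}")
        if gm is not None:
            absent = set(map(str, gm.chrom)) - set(self)
            if absent:
                raise ValueError(f"variant chromosomes missing from table: {sorted(absent)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChromTable":
        out = cls()
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 'chrom<TAB>length'")
            out[parts[0]] = int(parts[1])
        return out

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text("".join(f"{c}\t{l}\n" for c, l in self.items()))


def read_vcf(path: str | Path, on_multiallelic: str = "error") -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Half-missing genotypes (``./1``) and any non-diploid anomaly are coded
    :data:`MISSING`.  ``on_multiallelic`` is ``"error"`` (default) or
    ``"skip"``; skipped record counts land in ``meta``.
    """
    from cyvcf2 import VCF

    if on_multiallelic not in ("error", "skip"):
        raise ValueError("on_multiallelic must be 'error' or 'skip'")
    try:
        vcf = VCF(str(path), gts012=True, strict_gt=True)
    except Exception as e:
        raise ValueError(f"failed to open VCF {path}: {e}") from e
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError(f"duplicate sample IDs in {path}")
    chrom, pos, ref, alt, rows = [], [], [], [], []
    n_multi = n_nonsnp = 0
    for v in vcf:
        if len(v.ALT) != 1:
            if on_multiallelic == "error":
                raise ValueError(
                    f"multiallelic record at {v.CHROM}:{v.POS} in {path}; "
                    "split or normalise upstream, or pass on_multiallelic='skip'"
                )
            n_multi += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_nonsnp += 1
            continue
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        rows.append(g)
    geno = np.array(rows, dtype=np.int8) if rows else np.empty((0, len(samples)), np.int8)
    gm = GenotypeMatrix(
        np.array(chrom, dtype=object), np.array(pos, dtype=np.int64),
        np.array(ref, dtype=object), np.array(alt, dtype=object),
        geno, samples,
        meta={"skipped_multiallelic": n_multi, "skipped_non_snp": n_nonsnp, "source": str(path)},
    )
    gm.validate()
    return gm


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path, chrom_table: ChromTable | None = None) -> None:
    """Write a minimal VCFv4.2 (GT only) that round-trips through :func:`read_vcf`."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if chrom_table:
            for c, length in chrom_table.items():
                fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples) + "\n")
        for i in range(gm.n_variants):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in gm.geno[i])
            fh.write(f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t{gm.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n")


def filter_variants(gm: GenotypeMatrix, maf_min: float = 0.05, callrate_min: float = 0.5) -> GenotypeMatrix:
    """Apply the panel-wide SNP quality filter.

    A variant is retained when its genotype call rate across *all* samples
    ("integrity") is at least ``callrate_min`` and its minor-allele frequency
    over called allele copies is at least ``maf_min``.  Defaults are the
    conventional 0.05 / 0.5 thresholds.  Variant order is preserved and the
    operation is idempotent.
    """
    if gm.n_samples == 0:
        raise ValueError("cannot filter a matrix with zero samples")
    if not (0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0 <= callrate_min <= 1):
        raise ValueError("callrate_min must be in [0, 1]")
    called = gm.called()
    n_called = called.sum(axis=1)
    callrate = n_called / gm.n_samples
    alt_copies = np.where(called, gm.geno, 0).sum(axis=1)
    copies = 2 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(copies > 0, alt_copies / np.maximum(copies, 1), np.nan)
    maf = np.minimum(freq, 1 - freq)
    keep = (callrate >= callrate_min) & (copies > 0) & (maf >= maf_min)
    out = gm.take_variants(np.flatnonzero(keep))
    out.meta["n_filtered_out"] = int((~keep).sum())
    if out.n_variants == 0:
        warnings.warn("all variants removed by filtering", stacklevel=2)
    return out


def allele_freq(gm: GenotypeMatrix, pm: PopulationMap, pop: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant alt-allele frequency within a population or pool.

    Returns ``(freq, copies)`` where ``copies`` is the number of called allele
    copies; ``freq`` is NaN where no genotype was called.
    """
    cols = pm.member_indices(gm, pop)
    sub = gm.geno[:, cols]
    called = sub >= 0
    alt = np.where(called, sub, 0).sum(axis=1)
    copies = 2 * called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(copies > 0, alt / np.maximum(copies, 1), np.nan)
    return freq, copies
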