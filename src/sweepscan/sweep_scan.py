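"""Differentially-selected-region (DSR) calling and gene annotation.

A window is a DSR candidate when it lies in the top tail of BOTH the
reference/target pi log-ratio and the pairwise Fst distributions (default:
top 5% of each, empirical quantiles with linear interpolation).  Overlapping
or bookended candidate windows on the same chromosome are merged into regions,
which are then annotated with every gene overlapping them by at least 1 bp.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SweepRegion", "pi_log_ratio", "call_dsrs", "annotate_regions",
    "write_regions", "read_regions_tsv",
]


@dataclass
class SweepRegion:
    chrom: str
    start: int           # 1-based inclusive merged extent
    end: int
    n_windows: int
    peak_fst: float
    peak_ratio: float
    genes: list[str] = field(default_factory=list)


def pi_log_ratio(pi_ref: np.ndarray, pi_target: np.ndarray,
                 floor: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Natural-log ratio ln(pi_ref / pi_target) per window.

    Zero (or sub-floor) pi values are floored at one tenth of the smallest
    nonzero pi observed on either side before taking the log, so near-fixed
    sweeps keep a finite, rank-preserving ratio; those windows are flagged.
    Returns ``(ratio, flagged)``.
    """
    pi_ref = np.asarray(pi_ref, dtype=float)
    pi_target = np.asarray(pi_target, dtype=float)
    if pi_ref.shape != pi_target.shape:
        raise ValueError("pi arrays are not aligned")
    if floor is None:
        pooled = np.concatenate([pi_ref, pi_target])
        nonzero = pooled[pooled > 0]
        floor = (nonzero.min() / 10.0) if nonzero.size else 1.0
    flagged = (pi_ref < floor) | (pi_target < floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log(np.maximum(pi_ref, floor) / np.maximum(pi_target, floor))
    return ratio, flagged


def call_dsrs(windows_df: pd.DataFrame, fst_col: str = "fst", ratio_col: str = "pi_log_ratio",
              fst_quantile: float = 0.95, ratio_quantile: float = 0.95,
              min_snps: int = 10, flag_col: str | None = "flagged") -> list[SweepRegion]:
    """Joint top-quantile calling followed by merge of overlapping/bookended windows.

    Eligible windows have at least ``min_snps`` SNPs and finite statistics;
    quantile thresholds are computed over eligible, unflagged windows
    (empirical, linear/type-7 interpolation) and applied to all eligible
    windows.  Requires at least 20 eligible windows.
    """
    if not (0 < fst_quantile < 1 and 0 < ratio_quantile < 1):
        raise ValueError("quantiles must be in (0, 1)")
    df = windows_df.reset_index(drop=True)
    eligible = (
        (df["n_snps"] >= min_snps)
        & np.isfinite(df[fst_col])
        & np.isfinite(df[ratio_col])
    )
    if int(eligible.sum()) < 20:
        raise ValueError(f"only {int(eligible.sum())} eligible windows; quantiles are meaningless")
    for_quant = eligible.copy()
    if flag_col is not None and flag_col in df:
        for_quant &= ~df[flag_col].astype(bool)
    if not for_quant.any():
        for_quant = eligible
    fst_thr = float(np.quantile(df.loc[for_quant, fst_col], fst_quantile))
    ratio_thr = float(np.quantile(df.loc[for_quant, ratio_col], ratio_quantile))
    cand = df[eligible & (df[fst_col] >= fst_thr) & (df[ratio_col] >= ratio_thr)]
    cand = cand.sort_values(["chrom", "start", "end"], kind="mergesort")

    regions: list[SweepRegion] = []
    for _, row in cand.iterrows():
        if regions and regions[-1].chrom == row["chrom"] and row["start"] <= regions[-1].end + 1:
            reg = regions[-1]
            reg.end = max(reg.end, int(row["end"]))
            reg.n_windows += 1
            reg.peak_fst = max(reg.peak_fst, float(row[fst_col]))
            reg.peak_ratio = max(reg.peak_ratio, float(row[ratio_col]))
        else:
            regions.append(SweepRegion(
                str(row["chrom"]), int(row["start"]), int(row["end"]),
                1, float(row[fst_col]), float(row[ratio_col]),
            ))
    return regions


def _load_genes(gff3_path: str | Path) -> dict[str, list[tuple[int, int, str]]]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as e:
        raise ValueError(f"failed to parse GFF3 {gff3_path}: {e}") from e
    if db.count_features_of_type() == 0:
        raise ValueError(f"failed to parse GFF3 {gff3_path}: no features found")
    for f in db.all_features():
        if f.start is None or f.end is None:
            raise ValueError(
                f"failed to parse GFF3 {gff3_path}: feature without coordinates "
                f"({f.seqid!r})")
    genes: dict[str, list[tuple[int, int, str]]] = {}
    for g in db.features_of_type("gene"):
        name = (g.attributes.get("Name") or g.attributes.get("gene_name") or [g.id])[0]
        genes.setdefault(g.seqid, []).append((g.start, g.end, name))
    for lst in genes.values():
        lst.sort()
    return genes


def annotate_regions(regions: list[SweepRegion], gff3_path: str | Path) -> list[SweepRegion]:
    """Attach genes overlapping each region by >= 1 bp (sorted, deduplicated)."""
    genes = _load_genes(gff3_path)
    n_missing_chrom = 0
    for reg in regions:
        if reg.chrom not in genes:
            n_missing_chrom += 1
            reg.genes = []
            continue
        hits = {name for start, end, name in genes[reg.chrom]
                if start <= reg.end and end >= reg.start}
        reg.genes = sorted(hits)
    if n_missing_chrom:
        warnings.warn(
            f"{n_missing_chrom} regions on chromosomes absent from the GFF3", stacklevel=2)
    return regions


def write_regions(regions: list[SweepRegion], path: str | Path, format: str = "tsv") -> None:
    """Write regions as TSV (1-based ``start-end`` interval style) or BED
    (0-based half-open)."""
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("Chr\tPosition\tN_windows\tPeak_Fst\tPeak_PiLogRatio\tCandidate_genes\n")
            for r in regions:
                fh.write(
                    f"{r.chrom}\t{r.start}-{r.end}\t{r.n_windows}\t"
                    f"{r.peak_fst:.4f}\t{r.peak_ratio:.4f}\t{','.join(r.genes)}\n"
                )
    elif format == "bed":
        with open(path, "w") as fh:
            for r in regions:
                fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{','.join(r.genes)}\n")
    else:
        raise ValueError("format must be 'tsv' or 'bed'")


def read_regions_tsv(path: str | Path) -> list[SweepRegion]:
    regions: list[SweepRegion] = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        chrom, interval, n_win, fst, ratio, genes = line.split("\t")
        start, end = interval.split("-")
        regions.append(SweepRegion(
            chrom, int(start), int(end), int(n_win), float(fst), float(ratio),
            genes.split(",") if genes else [],
        ))
    return regions
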