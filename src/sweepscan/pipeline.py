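"""End-to-end pipeline: filter -> diversity -> Fst -> windows -> DSRs -> structure.

``run_all`` executes every stage into an output directory and writes a
manifest (input checksums + config echo) that fully determines the outputs:
re-running with identical inputs and seed reproduces every statistical output
byte for byte.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .genotypes_io import (
    ChromTable, GenotypeMatrix, PopulationMap, filter_variants, read_vcf,
)
from .diversity import diversity_table, write_diversity_table
from .differentiation import pairwise_fst_matrix, write_fst_matrix
from .windows import make_windows, window_table
from .sweep_scan import pi_log_ratio, call_dsrs, annotate_regions, write_regions
from .structure import bootstrap_support, ibs_distance, ld_decay, nj_tree, pca

logger = logging.getLogger("sweepscan")


@dataclass
class RunConfig:
    vcf: str
    popmap: str
    chrom_table: str
    out_dir: str
    gff3: str | None = None
    pools: dict[str, list[str]] = field(default_factory=dict)
    ref_pool: str | None = None           # reference side of the scan (e.g. DLY)
    targets: list[str] = field(default_factory=list)
    window_size: int = 100_000
    window_step: int = 10_000
    fst_quantile: float = 0.95
    ratio_quantile: float = 0.95
    min_snps: int = 10
    maf_min: float = 0.05
    callrate_min: float = 0.5
    bootstrap_reps: int = 100
    ld_max_dist: int = 500_000
    seed: int = 0

    def validate(self) -> None:
        if self.window_size < self.window_step:
            raise ValueError("window size must be >= step")
        for q in (self.fst_quantile, self.ratio_quantile):
            if not 0 < q < 1:
                raise ValueError("quantiles must be in (0,1)")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_all(cfg: RunConfig) -> Path:
    """Run the full pipeline; returns the output directory.

    Any stage failure aborts with the stage named; partially written outputs
    of the failed stage are removed.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    current_paths: list[Path] = []

    def begin(name: str, *paths: Path) -> None:
        nonlocal stage, current_paths
        stage = name
        current_paths = list(paths)
        logger.info("stage %s", name)

    skipped: list[str] = []
    try:
        begin("load-inputs")
        gm = read_vcf(cfg.vcf)
        pools = {k: set(v) for k, v in cfg.pools.items()}
        pm = PopulationMap.from_tsv(cfg.popmap, pools=pools)
        pm.validate(gm)
        ct = ChromTable.from_tsv(cfg.chrom_table)
        ct.validate(gm)

        begin("filter")
        gm = filter_variants(gm, maf_min=cfg.maf_min, callrate_min=cfg.callrate_min)

        begin("diversity", out / "diversity.tsv")
        write_diversity_table(diversity_table(gm, pm), out / "diversity.tsv")

        begin("fst-matrix", out / "fst_matrix.tsv")
        write_fst_matrix(pairwise_fst_matrix(gm, pm), out / "fst_matrix.tsv")

        windows = make_windows(ct, cfg.window_size, cfg.window_step)
        region_files: list[str] = []
        for target in cfg.targets:
            ref = cfg.ref_pool
            if ref is None:
                raise ValueError("targets given but no ref_pool configured")
            begin(f"windows-{target}", out / f"windows_{target}.tsv")
            wt = window_table(
                gm, pm, windows,
                pi_pops=[ref, target], fst_pairs=[(ref, target)], d_pops=[ref, target],
            )
            ratio, flagged = pi_log_ratio(wt[f"pi_{ref}"].to_numpy(), wt[f"pi_{target}"].to_numpy())
            wt["pi_log_ratio"] = ratio
            wt["flagged"] = flagged
            wt.to_csv(out / f"windows_{target}.tsv", sep="\t", index=False, float_format="%.6g")

            begin(f"dsr-{target}", out / f"dsrs_{target}.tsv", out / f"dsrs_{target}.bed")
            regions = call_dsrs(
                wt, fst_col=f"fst_{ref}_{target}", ratio_col="pi_log_ratio",
                fst_quantile=cfg.fst_quantile, ratio_quantile=cfg.ratio_quantile,
                min_snps=cfg.min_snps,
            )
            if cfg.gff3 and Path(cfg.gff3).exists():
                regions = annotate_regions(regions, cfg.gff3)
            elif cfg.gff3:
                skipped.append(f"annotation-{target}: GFF3 {cfg.gff3} not found")
                logger.warning("GFF3 %s not found; annotation skipped", cfg.gff3)
            else:
                skipped.append(f"annotation-{target}: no GFF3 configured")
            write_regions(regions, out / f"dsrs_{target}.tsv", "tsv")
            write_regions(regions, out / f"dsrs_{target}.bed", "bed")
            region_files.extend([f"dsrs_{target}.tsv", f"dsrs_{target}.bed"])

        begin("tree", out / "tree.nwk")
        if cfg.bootstrap_reps > 0:
            tree = bootstrap_support(gm, n_reps=cfg.bootstrap_reps, seed=cfg.seed)
        else:
            tree = nj_tree(ibs_distance(gm))
        tree.write(out / "tree.nwk")

        begin("pca", out / "pca.tsv")
        res = pca(gm)
        df = res.to_frame(pm)
        for i, v in enumerate(res.explained):
            df.attrs[f"varexp_PC{i + 1}"] = v
        with open(out / "pca.tsv", "w") as fh:
            fh.write("# explained: " + " ".join(f"PC{i + 1}={v:.4f}" for i, v in enumerate(res.explained)) + "\n")
            df.to_csv(fh, sep="\t", float_format="%.6g")

        begin("ld")
        for pop in pm.populations:
            ld = ld_decay(gm, pm, pop, max_dist=cfg.ld_max_dist)
            ld.to_csv(out / f"ld_{pop}.tsv", sep="\t", index=False, float_format="%.6g")

        begin("manifest", out / "manifest.json")
        manifest = {
            "sweepscan_version": __version__,
            "config": asdict(cfg),
            "inputs": {
                "vcf": _sha256(cfg.vcf),
                "popmap": _sha256(cfg.popmap),
                "chrom_table": _sha256(cfg.chrom_table),
                "gff3": _sha256(cfg.gff3) if cfg.gff3 and Path(cfg.gff3).exists() else None,
            },
            "skipped_stages": skipped,
            "n_variants_after_filter": int(gm.n_variants),
            "outputs": sorted(p.name for p in out.iterdir() if p.suffix in (".tsv", ".bed", ".nwk")),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as e:
        for p in current_paths:
            if p.exists():
                p.unlink()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    return out
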