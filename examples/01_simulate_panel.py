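"""Generate the default synthetic panel and write its standard input files.

The default configuration emulates a livestock SNP panel: 10 populations of 8
diploids (three "commercial" breeds DD/LL/YY plus seven "indigenous" ones),
3 chromosomes of 10 Mb at ~1 SNP/kb, Balding–Nichols differentiation F = 0.2,
10% missing genotypes, and five 200-kb selective sweeps injected into DPL.
"""
from pathlib import Path

import sweepscan as ss

out = Path("example_output/sim")
out.mkdir(parents=True, exist_ok=True)

cfg = ss.default_config(seed=42)
gm, pm, ct, truth = ss.simulate(cfg)

ss.write_vcf(gm, out / "panel.vcf", ct)
pm.to_tsv(out / "popmap.tsv")
ct.to_tsv(out / "chroms.tsv")
ss.write_truth_bed(truth, out / "truth_sweeps.bed")

print(f"simulated {gm.n_variants} biallelic SNPs x {gm.n_samples} samples")
print(f"populations: {', '.join(pm.populations)}")
print(f"missing genotype fraction: {(gm.geno < 0).mean():.3f}")
print("injected sweeps (chrom, 1-based interval, target population):")
for s in truth.sweeps:
    print(f"  {s.chrom}:{s.start}-{s.end} -> {s.pop} (sweep allele freq {s.freq})")
print(f"files written to {out}/")
# The VCF + popmap + chromosome table are the inputs every other example and
# the CLI consume; the truth BED records where sweeps were planted so scan
# output can be scored against it.
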