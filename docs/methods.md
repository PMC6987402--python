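# Methods

This note documents the statistical model behind each component, the defaults
and why they were chosen, and what the synthetic data generator does and does
not emulate.

## Genotype model and filtering

Genotypes are alt-allele dosages in {0, 1, 2} with −1 for missing, one row
per biallelic SNP, positions 1-based (VCF convention). Half-calls (`./1`) and
non-diploid anomalies are conservatively coded missing at read time.
Multiallelic records are rejected by default or skipped with a count — they
are assumed to have been split or dropped upstream.

The quality filter retains a SNP when its panel-wide call rate (often called
*integrity* in reduced-representation sequencing pipelines) is ≥ 0.5 and its
minor-allele frequency over called allele copies is ≥ 0.05. Both thresholds
follow common practice for SLAF/GBS-style SNP panels. MAF is computed over
the whole panel jointly, not per population, so a single filtered SNP set
underlies every downstream statistic; the filter is idempotent and
order-preserving. BED output converts to 0-based half-open coordinates only
at the writers.

## Diversity statistics

All five per-population statistics are unweighted averages over variants,
complete-case within the population at each variant, with monomorphic
variants included (contributing 0) because the panel's SNP set is fixed after
filtering:

- H_o: fraction of heterozygous genotypes among called genotypes;
- H_e: 2p̂(1−p̂) with p̂ the population alt frequency;
- Nei diversity: the small-sample unbiased form (2n/(2n−1))(1 − p̂² − q̂²)
  with n the called diploid count at that variant, hence H_e ≤ Nei always;
- PIC (biallelic): 1 − (p̂² + q̂²) − 2p̂²q̂², bounded above by H_e;
- MAF: min(p̂, 1−p̂).

H_e and Nei are deliberately kept as the uncorrected and corrected estimator
pair; that ordering (H_e < Nei, PIC < H_e) is an invariant of the test suite.
A single-sample population makes the Nei correction factor degenerate (exactly
2) and triggers a warning rather than an error.

## Weir–Cockerham F_ST

Per locus, with r populations contributing n_i called diploids, alt frequency
p_i, and observed heterozygote fraction h_i:

    n̄ = Σn_i / r,  p̄ = Σn_i p_i / (r n̄),  h̄ = Σn_i h_i / (r n̄)
    s² = Σn_i (p_i − p̄)² / ((r−1) n̄)
    n_c = (r n̄ − Σn_i² / (r n̄)) / (r−1)

    a = (n̄/n_c) [ s² − (p̄(1−p̄) − ((r−1)/r)s² − h̄/4) / (n̄−1) ]
    b = (n̄/(n̄−1)) [ p̄(1−p̄) − ((r−1)/r)s² − ((2n̄−1)/(4n̄)) h̄ ]
    c = h̄/2

Multi-locus and windowed estimates combine as the **ratio of sums**
θ̂ = Σa / Σ(a+b+c) — never a mean of per-locus ratios, which is biased by
low-information loci. Negative per-locus components are retained in the sums;
truncation of the final estimate to [0, 1] is available at reporting time
only. A locus is excluded when fewer than two populations have data, when
n̄ ≤ 1, or when it is monomorphic across the compared groups (zero
denominator). Pooled gene pools (e.g. DLY) are treated as a single population
over the union of their samples. The implementation is validated against an
independently coded scalar transcription of the same published formulas to
1e-10, and against the closed-form θ̂ = 1 for fixed divergence.

## Windows, π, Tajima's D

Windows are 1-based inclusive, tiled from position 1 of each chromosome
(default 100 kb, 10 kb step); a window is emitted iff its start lies on the
chromosome, with the end clipped to the chromosome length. Tiling from
position 1 rather than the first SNP keeps window boundaries independent of
the realized SNP set.

Per-site diversity uses the unbiased pairwise-difference term
2c(m−c)/(m(m−1)) (c alt copies out of m called copies in the population);
window π divides the per-site sum by the window **span in bp**, not the SNP
count, so π log-ratios across populations share a common denominator and
empty windows have π = 0.

Tajima's D follows the standard normalization: D = (k̂ − S/a₁) / √(e₁S +
e₂S(S−1)) with a₁ = Σ_{i<n} 1/i etc. Because missingness makes the number of
called copies vary site to site, the nominal n is the **modal called
allele-copy count** across the window's sites (ties broken toward the smaller
value), while each site keeps its own m inside k̂. D is reported only when
S ≥ 3 segregating sites and n ≥ 4 copies; otherwise the window is flagged
undefined. The n = 4, S = 3 fixture with alt-copy counts {1, 1, 2} — D ≈
+0.1676 by exact rational evaluation — is frozen in the tests.

## DSR calling

For a target population against a pooled reference, the per-window signal
pair is (θ̂, ln(π_ref/π_target)); a positive log-ratio means the target lost
diversity. Windows with fewer than 10 SNPs (configurable) or undefined
statistics are ineligible. Zero-π windows are floored at one tenth of the
smallest nonzero window π before the log — this preserves ranks, avoids
infinities, and keeps fully swept windows callable; floored windows are
flagged and excluded from quantile estimation.

A window is a candidate iff it reaches BOTH the 95% empirical quantile of
F_ST and of the log-ratio (quantiles per comparison, linear/type-7
interpolation). Requiring the intersection rather than the union is the
stricter reading of a joint top-5% rule and bounds the candidate fraction at
5%. Overlapping or bookended candidates on one chromosome merge into a
region, which is why called regions (≥ 180 kb typical) exceed a single window.
Gene annotation attaches any GFF3 `gene` feature overlapping a region by
≥ 1 bp. Tajima's D is reported per window for inspection of candidate regions
but does not gate the calls. Fewer than 20 eligible windows is an error —
an empirical 95th percentile is meaningless below that.

## Structure analyses

**Distance.** d_ij = 1 − mean allele sharing over co-called SNPs, with
per-SNP sharing 1, 0.5, 0 for identical / one-shared / opposite-homozygote
dosages (equivalently |g_i−g_j|/2 averaged). A sequence-substitution distance
(e.g. Kimura two-parameter) is not well defined on a biallelic dosage matrix,
so the package uses IBS, the standard choice for SNP panels.

**Neighbor joining.** Standard Saitou–Nei agglomeration on the Q-criterion
with a deterministic tie-break (lexicographically smallest pair of cluster
representatives). Negative branch lengths are clamped to zero with the
deficit moved to the sibling branch, flagged. The final three clusters join
at an unrooted trifurcation via the three-point formulas. On additive
matrices NJ is exact; the suite verifies topology and all path lengths on
random additive trees. Bootstrap support resamples SNP columns with
replacement, rebuilds distance + tree per replicate, and reports the fraction
of replicates containing each internal bipartition of the point tree
(default 1000 replicates; tests and the default pipeline use 100 and 10 for
speed).

**PCA.** Dosages are mean-imputed per SNP, centred, and scaled by
√(p̂(1−p̂)) (Patterson scaling); coordinates are eigenvectors of the
sample-covariance matrix scaled by singular values, with each component's
largest-magnitude entry made positive for a deterministic sign.

**LD decay.** With unphased genotypes, r is the Pearson correlation of dosage
vectors over samples called at both SNPs (composite LD, no phasing or EM);
all intra-chromosomal pairs within the distance cap enter distance bins.
Pairs with fewer than 4 co-called samples or a monomorphic member are
skipped. Binned means carry a finite-sample floor of roughly 1/n, visible in
the null case of independent sites.

## Synthetic data generator

The generator emulates the data regime the statistics assume: ~10 populations
of 5–10 diploids, multi-Mb chromosomes with hundreds of SNPs per Mb,
between-population differentiation in the F_ST ≈ 0.2–0.5 range, per-genotype
missingness, and localized sweep regions. Defaults: 10 populations × 8
diploids, 3 × 10 Mb chromosomes at 1 SNP/kb (~30k SNPs), F = 0.2 for every
population, 10% missingness, and (in the reference configuration) five 200-kb
sweeps in one target population at sweep allele frequency 0.98.

Mechanics, per chromosome: SNP counts are Poisson(L·density); positions
uniform, sorted, deduplicated. Ancestral frequencies are Beta(1, 1) truncated
to [0.05, 0.95] — a flat, bounded spectrum imitating a frequency-ascertained
panel after MAF filtering rather than a neutral site-frequency spectrum. Each
population draws p_i ~ Beta(p(1−F)/F, (1−p)(1−F)/F) (Balding–Nichols), so
the expected Weir–Cockerham F_ST between two equal-F populations is F — this
closed form is what makes parameter recovery testable. Within a sweep
interval the target population's p_i is overridden by the sweep frequency
before haplotypes are drawn, producing exactly the scanned signals: low π,
high F_ST, negative Tajima's D.

LD comes from founder mosaics: K founder haplotypes per population (default
30) are drawn per-site Bernoulli(p_i); each individual's two copies follow a
founder index that switches with probability 1 − exp(−switch_rate·gap)
between adjacent SNPs (default 1e-5/bp, ~100 kb tracks). Setting
`founder_haplotypes=None` draws every copy independently — no LD, genotypes
exactly Binomial(2, p_i) — which is the configuration used for estimator
parameter-recovery checks, because a finite founder pool adds drift of order
(1−F)/(2K) on top of F and would bias θ̂ upward relative to the nominal
parameter. Missingness is i.i.d. per genotype. Everything derives from one
integer seed; identical config + seed yields a byte-identical VCF.

What the generator does **not** emulate: demographic history (growth,
migration, admixture), linked selection or realistic sweep trajectories,
genotyping error beyond missingness, ascertainment correlated with
divergence, and reference-bias artifacts. Passing tests therefore demonstrate
estimator correctness and pipeline behaviour under a clean, well-specified
model — not robustness to every pathology of real reduced-representation
data.

## Numerical and design choices

- Quantiles: empirical, linear (type-7) interpolation throughout.
- π log-ratio orientation is reference/target so that sweeps in the target
  give positive values.
- Window coordinates and region intervals are 1-based inclusive internally;
  only BED writers convert.
- Degenerate inputs fail loudly: zero-sample matrices, unknown population
  labels, non-symmetric distance matrices, < 3 taxa for NJ, < 20 eligible
  windows for quantile thresholds, sample pairs with no co-called SNPs.
- The pipeline writes a manifest (input SHA-256 checksums + config echo) and
  is byte-deterministic given inputs and seed; no threading is used anywhere.
- Problem sizes in the tests and acceptance script (20k SNPs for parameter
  recovery, the ~30k-SNP default genome for the scan) are the package's
  reference desk-scale conditions; they run in seconds while leaving
  Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- Only biallelic SNPs; no indels, no phasing, no imputation.
- Windowed Tajima's D with heavy, non-random missingness leans on the modal-n
  approximation; extreme per-sample dropout patterns could shift D slightly.
- Hudson-style and Nei-style F_ST variants, jackknife confidence intervals,
  haplotype-based scan statistics (XP-EHH, iHS) and admixture/migration
  modelling are out of scope.
- The DSR rule is a fixed empirical-quantile intersection; it controls the
  candidate fraction, not a false-discovery rate.
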