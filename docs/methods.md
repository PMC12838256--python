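# Methods

This note records the models, conventions, and design choices behind
`sweepscan`, in the spirit of a statistical-software methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Scope and pipeline order

The package analyses a two-group (case/control) diploid cohort for selective
sweeps. Stages run in a fixed order: site hard filters → genotype-level
masking → biallelic retention → per-site Weir–Cockerham components and π →
sliding-window aggregation → top-1% dual-statistic outlier calling → ±50 kb
gene annotation → gene-set intersection. Upstream read processing
(trimming, alignment, variant calling) is out of scope; the package starts
from a multi-sample VCF.

## Variant filtering

Site-level hard filters use GATK-style expressions with OR semantics — a
site fails if ANY inequality holds. SNP rules: QD < 3.0, FS > 30.0,
SOR > 4.0, MQ < 30.0, MQRankSum < −10.0, QUAL < 50.0,
ReadPosRankSum < −5.0 (INFO key `RPRS`). InDel rules (QD < 3.0, FS > 100.0,
ReadPosRankSum < −10.0) sit behind a variant-type switch, although the scan
itself is SNP-only. All inequalities are strict, so boundary values
(QD = 3.0 etc.) pass. A missing annotation skips that rule for that site
(GATK emits several annotations conditionally); this is logged once per
key, never fatal.

Genotype-level rules: GQ < 20 → missing; DP below 1/3× or above 3× the
individual's own mean whole-genome depth → missing (boundaries pass); for
heterozygotes only, allele-depth balance min(AD)/sum(AD) < 0.2 → missing
(0.2 exactly passes). The per-individual mean depth may be supplied as a
table or computed from the VCF in a first pass.

After masking, a site is retained iff 0 < alternate-allele frequency < 1
over the non-missing calls (allele count > 0 and frequency < 1), dropping
monomorphic, fixed, and all-missing sites. The columnar (matrix) filter
path and the per-record streaming path implement identical semantics; a
test asserts their agreement site by site.

## Estimators

**Weir–Cockerham components.** Per site with r = 2 populations, components
a (between populations), b (between individuals within populations) and
c (within individuals) are computed exactly as in the classic
variance-components formulation (see README for the formulas). Sites with
fewer than two called diploids in either group are undefined and skipped in
aggregation. Negative per-site components are retained in window sums — no
truncation at zero — preserving the estimator's lack of bias. Windowed and
genome-wide estimates are ratios of sums Σa/Σ(a+b+c), the standard
aggregation for windowed Weir–Cockerham scans, stable at low-information
sites; the per-site ratio θ is exposed for diagnostics only.

**Nucleotide diversity.** Per-site π in a population with m = 2·n_called
allele copies is (m/(m−1))·2p(1−p), the unbiased expected heterozygosity,
identical to the mean pairwise difference over all C(m,2) haplotype pairs
(verified against brute-force enumeration). Window π divides the per-site
sum by the full window span in bp, not by SNP count — the dominant
windowed-π convention; this choice is stated here because either
denominator is defensible. Monomorphic sites contribute exactly 0, so the
biallelic filter does not bias window π.

**π-ratio direction.** The ratio is reported as π_control/π_case by
default, so LARGE values flag diversity loss in the case population — the
direction a sweep in cases produces. An `invert_pi_ratio` flag (CLI:
`--invert-pi-ratio`) reports case/control instead; ranking the appropriate
tail yields identical outlier windows.

## Windows

Windows are half-open [start, end) 0-based intervals tiled from 0 with a
100 kb size and 50 kb step by default (sites and genes are 1-based
inclusive; the conversion happens only at window assignment). A final
partial window is emitted, flagged, iff it covers at least one bp beyond
the last full window. With the default 50% overlap each SNP contributes to
up to two windows — inherent to the stride, and deliberate. A window's
FST is NA when it has no informative SNP or Σ(a+b+c) ≤ 0; π-ratio is NA
when π_case = 0.

## Outlier calling and candidates

Thresholds are empirical 99th percentiles (linear-interpolation quantile)
of the non-NA window distributions, separately per statistic; windows with
statistic ≥ threshold are outliers, so ties at the cutoff are all kept —
conservative for candidate discovery. Windows below 100 rankable values
trigger a warning (the tail quantile is then poorly resolved). Windows
extreme in both statistics are the putative sweep signals; the SNPs inside
outlier windows are the "SNPs under selection".

Candidate genes are those whose interval lies within 50,000 bp (inclusive)
of a selected SNP — distance 0 inside the interval, else distance to the
nearer boundary; gene midpoints and strand are ignored. Candidates are
derived per statistic and intersected at the gene level, with the
FST-only / π-only / shared breakdown reported; window-level overlap is
also available. An optional chromosome allow-list restricts the scan (e.g.
autosomes only). Lookup uses an interval tree and is tested against an
all-pairs brute-force scan.

## Robustness procedures

**Down-sampling.** Cases are repeatedly sampled without replacement to
n_target (default 30, matching the control count; default 100 iterations),
the windowed scan is recomputed on the same grid, and concordance with the
full-data scan is summarized as (i) Spearman rank correlation over windows
non-NA in both runs and (ii) top-1% outlier-window overlap, reported both
as Jaccard and as recall of the full-data outlier set, since "overlap"
admits either reading. Constant window statistics make rank correlation
undefined; NA is reported with a warning. Runs are pure functions of the
seed.

**Block jackknife.** The genome is partitioned chromosome-wise into
contiguous 200 kb blocks; delete-one-block estimates θ̂₍₋ⱼ₎ give
SE² = ((B−1)/B)·Σⱼ(θ̂₍₋ⱼ₎ − θ̂₍·₎)² and CI = θ̂ ± 1.96·SE. Because one
block (200 kb) exceeds one window (100 kb), a per-window jackknife is
ill-posed; the jackknife therefore targets genome-wide summaries — the
ratio-of-sums FST, the genome-wide π-ratio (ratio of summed π), or any
user-supplied callable statistic. The built-in statistics use closed-form
block sums; the callable path recomputes per deletion, and both are tested
to agree. For a fixed dataset the jackknife estimates the sampling
variance of the target statistic, so its SE is not expected to shrink as
blocks are made smaller.

## Phenotype comparison

Group summaries use sample SDs (n−1) and the mean difference is
case − control. The default test is Welch's unequal-variance two-sided
t-test with Welch–Satterthwaite df — the defensible default for a 145/30
imbalance — with a pooled-variance mode behind a flag. A
summary-statistics path computes the identical test from printed group
means/SDs/ns. Degenerate inputs follow a stated convention: zero variance
in both groups with equal means gives t = 0, p = 1; with unequal means it
is an error. Note that recomputing the test from the published sheep
cranial summary statistics at n = 145/30 yields p ≈ 0.10 for maxillary
length under either Welch or pooled variants; only the mean differences,
which follow arithmetically from the printed means, are asserted anywhere.

## Over-representation

For each term: upper-tail hypergeometric p = P(X ≥ k) with universe N,
term size K, candidate count n, overlap k; Benjamini–Hochberg adjustment
across tested terms; adjusted p < 0.05 flags significance. Terms with zero
candidate overlap are excluded from the BH family before adjustment (the
usual over-representation convention; this affects adjusted p and is
therefore stated). The universe defaults to all annotated genes. GO/KEGG
database access, DAG propagation, and pathway topology are out of scope —
the term map is user-supplied.

## Synthetic cohort generator

The generator emulates a 145-case / 30-control resequencing cohort on a
reduced genome (default 3 chromosomes × 2 Mb; the chromosome count and
length are configuration, chosen small so the full pipeline runs in
seconds — real autosome counts are a config choice, not a constant).
Sites are placed uniformly at an expected density of 0.002 SNPs/bp
(~12,000 sites at defaults; parameter-recovery runs raise it to 0.01 for
≥ 50,000 sites).

Per SNP, ancestral frequency p ~ Uniform(0.05, 0.95); population
frequencies follow the Balding–Nichols model Beta(p(1−F)/F, (1−p)(1−F)/F)
with F = background_fst (default 0.02) outside sweeps and F = sweep_fst
inside. Balding–Nichols was chosen because F is the expected FST, giving
an analytically known truth for recovery tests. Inside a sweep the case
frequency is additionally moved toward fixation of the locally common
allele so that case expected heterozygosity is multiplied by
case_diversity_factor — a joint frequency-shift + diversity-shrink that
makes BOTH scan statistics fire on the same region, matching the
dual-statistic intersection logic. The default planted sweep
(chr1:900,001–1,100,000, sweep_fst 0.5, diversity factor 0.3) is chosen
for testability: no effect size is available for the real signal, so
these values are not biological estimates.

Genotypes are Binomial(2, p_pop); DP ~ Poisson(mean_depth = 10, matching
the reported average coverage); AD splits DP binomially by dosage; GQ ≥ 30
except for a 2% corrupted fraction (< 20), and site INFO annotations carry
passing values except for a 2% corrupted fraction assigned one failing
rule at random — so every filter has work to do. Monomorphic draws are
retained in the VCF deliberately, to exercise the biallelic rule.
Phenotypes are Normal draws from the published group means/SDs. All
outputs are pure functions of (config, seed); INFO floats are rounded and
passed through float32 so a VCF write → read cycle is bit-exact.

What the generator does **not** emulate: linkage disequilibrium and
recombination (sites are independent), demography beyond the single F
parameter, read-level error profiles, indels, multi-allelic sites, and
genotype-call uncertainty correlated with depth. Passing tests therefore
demonstrate correctness of the estimators and pipeline logic under a
known truth — not calibration of the scan's false-discovery behaviour on
real, linked genomes, where neighbouring windows are correlated and the
top-1% rule is an enrichment heuristic rather than a significance test.

## Numerical and degenerate-input choices

- Estimator NA policy: < 2 called diploids in either group → components
  NA, site skipped; all-NA windows never ranked; all-NA statistic is an
  error ("no rankable windows").
- Window tables serialize floats to 10 significant digits with NA for
  missing; round-trips are tested to that precision.
- Down-sampling with n_target equal to the full case count is an exact
  no-op (rho = overlap = 1), used as a self-test.
- Jackknife requires ≥ 2 non-empty blocks; a between-block-constant
  statistic yields SE = 0 exactly.
- Problem sizes in the test and acceptance runs (3 × 2 Mb genome, ~12k–60k
  sites, 20-seed detection/coverage experiments, 100 down-sampling
  iterations) are the package's default study conditions, sized so a full
  run completes in well under a minute on one core.

## Known limitations

- Only r = 2 populations; no multi-population FST.
- No haplotype statistics (iHS, XP-EHH), Tajima's D, or composite-
  likelihood sweep tests; significance is empirical-quantile only.
- BCF/tabix, multi-allelic normalization and VQSR are unsupported.
- The detection-rate experiments are conditional on the generator's
  no-LD assumption; on real data the effective number of independent
  windows is smaller and thresholds correspondingly noisier.
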