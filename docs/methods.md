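# Methods

This note documents the statistical models and procedures implemented in
`esoxpop`, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical decisions a user
re-running or extending the analyses should know about.

## Genotype model and coordinates

All analyses operate on a dense samples × variants matrix of biallelic-SNP
calls coded hom-ref / het / hom-alt / missing. The analyses are phase-free,
so phased and unphased heterozygotes are identical. Coordinates are 1-based
inclusive (VCF convention) at the interface; window arithmetic is 0-based
half-open internally, and a SNP at position *p* lies in window
[start, end) iff start < p ≤ end.

## Site filtering

Filters are applied in a fixed order: per-genotype depth masking (calls
with depth < 10× become missing) → site quality (QUAL ≥ 20) → call rate →
monomorphic removal. The order matters and is deliberate: masking a
genotype for low depth can push a site under the call-rate threshold or
render it monomorphic, and applying those rules *after* masking is the
conservative reading of depth-based retention. The call rate is computed
over all samples in the file, not per population; the threshold is exposed
because different analysis sets legitimately use different values (a
single-cohort set can demand 100 %, a cross-cohort set 90 %). Every rule
reports its casualty count.

Ti/Tv classifies sites by their ref/alt pair only (A↔G and C↔T are
transitions); it is undefined, and signalled as such, when there are no
transversions. Teleost panels typically sit near 1.1–1.5, well below the
~2 familiar from mammals, so the ratio is a calling-QC indicator rather
than a fixed target.

## Windowed pooled heterozygosity

Windows are genome-anchored: per chromosome they start at offsets
0, s, 2s, … (default size 500 kb, step 250 kb → 50 % overlap) and are
clipped at the chromosome end. For each SNP the major allele is whichever
of ref/alt is more frequent among non-missing calls (each homozygote
contributes two copies, each het one of each); ties break toward ref,
which cannot affect Hp since the formula is symmetric at a tie. Window
sums ΣnMAJ, ΣnMIN give

    Hp = 2 ΣnMAJ ΣnMIN / (ΣnMAJ + ΣnMIN)²  ∈ [0, 0.5].

ZHp standardizes Hp by the mean and *sample* (n−1) standard deviation over
all windows with defined Hp, genome-wide; windows with fewer than
`min_snps_per_window` SNPs (default 10) carry no Hp and are excluded from
the moments — ZHp on near-empty windows is noise, and the floor is
reported in output so the choice is visible. |ZHp| > 3 flags outliers.

## Fst

Per-SNP Fst is the Weir & Cockerham (1984) two-population estimator
computed from genotype counts: with per-group diploid sample sizes n₁, n₂,
alt-allele frequencies p₁, p₂ and observed heterozygote fractions h₁, h₂,
the variance components a (among populations), b (among individuals within
populations) and c (within individuals) give θ̂ = a/(a+b+c). Estimates are
reported as computed — negative values are *not* clipped, and sites with
fewer than two called diploids in either group are skipped and counted.
θ̂ = 1 exactly when the groups are fixed for opposite alleles.

Two genome-scale summaries exist and differ on purpose:

* **mFst** — the arithmetic mean of per-SNP θ̂ inside a window (and
  `overall_fst`, the same mean genome-wide). This matches the windowed-mean
  convention used for scan figures; windows with mFst > 0.9 are flagged as
  near-fixed differentiation.
* **`genome_fst`** — the multi-locus ratio of sums Σa / Σ(a+b+c) (the
  "weighted" Fst of standard toolkits). The mean of per-SNP ratios is
  biased downward (under the simulator at F = 0.25 with 50+50 samples it
  averages ≈ 0.18, while the ratio of sums recovers 0.25), so the ratio of
  sums is the right single number for overall differentiation and is what
  the parameter-recovery tests check.

Hudson's frequency-based estimator is available behind a flag for
sensitivity analysis, never as the default.

## Runs of homozygosity and F_ROH

Detection follows the scanning-window heuristic: windows of `window_snps`
consecutive SNPs slide one SNP at a time; a window is compatible when it
holds ≤ `max_het_per_window` heterozygous and ≤ `max_missing_per_window`
missing calls; each SNP scores the fraction of covering windows that are
compatible and is run-eligible at ≥ `hit_fraction`; maximal eligible
stretches are split at inter-SNP gaps > `max_gap` (500 kb) and reported if
they span ≥ `min_length` (1 Mb) with ≥ `min_snps_per_segment` SNPs.
Segment coordinates are outermost SNP positions, so length is SNP-span.
The stringency grid crosses window sizes {5, 10, 20} with heterozygote
allowances {1, 2, 3}; the (20, 3) cell is the headline setting — looser
cells (e.g. 5 SNPs / 3 hets, which tolerates 60 % heterozygosity per
window) are intentionally included to show how sensitive F_ROH is to the
rule, and total ROH length is monotone in the stringency.

Unstated secondary parameters default to `hit_fraction` = 0.05,
`max_missing_per_window` = 5, `min_snps_per_segment` = 25, no density
filter; all are explicit config recorded in output. An exhaustive
brute-force scanner (same rules, naive loops) is kept in the test suite as
the correctness oracle.

Two behaviors of the heuristic are worth knowing. First, segment
boundaries bleed: windows straddling the edge of a truly homozygous tract
are still compatible, so eligibility extends up to ~`window_snps` SNPs
beyond the tract (≈ 0.1–0.4 Mb at the densities tested). Second, at sparse
densities chance low-heterozygosity stretches can span the 1-Mb minimum:
with independent sites at ~0.28 heterozygosity, eligible runs of ~135
consecutive SNPs occur, which exceed 1 Mb at ≤ ~135 SNPs/Mb. The
planted-tract recovery experiments therefore run at a WGS-like 200 SNPs/Mb
(the regime the 1-Mb rule is designed for), where both effects together
keep the F_ROH error well under 0.01 of the assessed genome. Real genomes
have linkage disequilibrium, which makes long chance runs rarer than in
this worst-case independent-sites background.

F_ROH = (summed length of reported segments) / (genome length assessed).
The denominator is a **required explicit argument**: whether it should be
the assembly length, the covered-genome length, or the SNP-spanned length
is a study-level decision with materially different answers, so the
package never silently picks one.

## Sex-discordant screen

A marker is sex-discordant when, among non-missing calls, one sex is
entirely heterozygous and the other entirely a single shared homozygote.
By default no missing calls are tolerated (`min_call_rate_per_sex` = 1.0),
formalizing the perfect pattern as an exact predicate; the threshold can
be relaxed for sparser data. The screen is symmetric under swapping sex
labels (the pattern label flips, the marker set does not). Between-sex
Fst reuses the windowed machinery with sexes as groups; its overall value
is the per-SNP mean, consistent with the mFst convention.

## Genotype PCA

Genotypes are coded as alt-allele dosage 0/1/2; missing calls are
mean-imputed per site before centering (the standard toolkit behavior);
constant sites are dropped; optional Patterson scaling divides each site
by √(p(1−p)). Coordinates come from an SVD of the centered matrix, and
variance fractions are relative to its total variance, so they are
non-increasing and sum to ≤ 1. Each component's sign is fixed by making
its largest-magnitude coordinate positive, so output is reproducible under
sample reordering. All samples identical (zero total variance) is an
error, by contract.

## Synthetic data

The generator draws, per site, an ancestral frequency p₀ ~ U(0.05, 0.95)
(default range) and per-population frequencies from the Balding–Nichols
Beta(p₀(1−F)/F, (1−p₀)(1−F)/F), whose mean is p₀ and variance
p₀(1−p₀)F — so F is the expected fixation index; F = 0 degenerates to a
shared point mass. Genotypes are per-diploid binomial draws; positions are
uniform without replacement per chromosome. Depth is negative-binomial
(default mean 26×, dispersion 8 — WGS-like; the sparse preset uses 11×),
quality uniform in 30–60, and missingness uniform outside planted
features. Planted features are: ROH tracts (calls forced homozygous for
the population-major allele), a sex locus (all males het, all females
hom-ref — the male-heterogametic single-locus pattern), and exact numbers
of sites failing each retention filter, all recorded in a truth table.
Identical seed + config gives byte-identical VCF output.

Presets encode the two study-shaped conditions: a small dense cohort
(12 diploids, 6 per sex, 2 × 10 Mb chromosomes, 4000 SNPs, F = 0.05
between its two source groups, planted tracts and a 47-marker sex locus)
and a combined design (12 vs 200 samples, sparse SNPs, F = 0.24, 5 %
missingness, 11× depth).

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: linkage disequilibrium and recombination
(sites are independent, so ROH realism comes entirely from planted
tracts), allele-frequency spectra shaped by demography or ascertainment,
sequencing error and genotype-likelihood uncertainty, reference bias from
cross-species alignment, and RAD-locus dropout. Tests on simulated data
validate the estimators against their own model assumptions; they do not
validate the upstream variant calling.

## Numerical choices and degenerate inputs

* ZHp uses the sample (ddof = 1) standard deviation; all-equal window Hp
  raises a normalization error rather than dividing by ~0.
* Summary rounding uses Python's correctly-rounded `round`, not
  numpy's scale-by-100 rounding, which can flip exact ties (e.g. a mean of
  exactly x.xx5).
* Hp major/minor ties break toward ref (deterministic; Hp is unaffected).
* Fst at sites monomorphic in both groups is undefined (NaN), excluded
  from window means and counted.
* Windows exist wherever their start lies inside the chromosome; the
  trailing window is clipped and reported at its true width, as are
  trailing depth-track windows.
* Ti/Tv with zero transversions, empty sample groups, k ≥ n samples in
  PCA, non-positive F_ROH denominators, and out-of-range configuration
  values all raise typed errors instead of returning sentinel numbers.

## Known limitations

* The ROH detector mirrors the scanning-window heuristic, not a
  likelihood/LOD method; exact concordance with any particular external
  tool's output is not guaranteed because several of that family's
  secondary parameters have no published values in the analyses this
  package reproduces — they are explicit config here.
* Two-population Fst only; the Weir–Cockerham components are implemented
  for r = 2.
* The sex screen presumes a diploid XY-like pattern (one sex consistently
  heterozygous); ZW systems are handled by the symmetric pattern label,
  but polygenic or environmental sex determination leaves no signal it
  can find.
* Per-genotype depth is taken from the VCF DP field as given; no
  recalculation from alignments.
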