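# Methods

## Model and procedure

The scan treats per-SNP coded-allele frequencies across a worldwide population panel
as the response and a country-level environmental variable (pathogen diversity,
climate) as the predictor. Because the environment is only defined per country, its
value is broadcast to every population of that country before any correlation is
computed; this deliberately gives every environmental variable the same tie
structure, so comparisons across variables are like-for-like.

**Kendall τ-b.** For each SNP, τ_b = (C − D)/√((n₀ − n₁)(n₀ − n₂)), where C and D are
concordant and discordant pair counts over the n pairwise-complete populations,
n₀ = n(n−1)/2 and n₁, n₂ are tie-pair counts in the frequencies and the environment.
The two-sided p-value comes from the normal approximation of S = C − D with the full
tie-corrected variance

Var(S) = [n(n−1)(2n+5) − Σt(t−1)(2t+5) − Σu(u−1)(2u+5)]/18
       + [Σt(t−1)·Σu(u−1)] / [2n(n−1)]
       + [Σt(t−1)(t−2)·Σu(u−1)(u−2)] / [9n(n−1)(n−2)],

summing over tie groups of sizes t (frequencies) and u (environment). The
approximation is adequate for n > 10, which is why SNPs with fewer than 10 usable
populations are routed to a skip report instead of the results (reason codes:
`too_few_populations`, `constant_frequency`, `constant_environment`, `all_missing`).
A rank correlation is used because environments are ordinal-ish, heavy-tailed and
tied; τ is invariant to monotone transforms of either side. The implementation agrees
with an exhaustive O(n²) pair-classification oracle and with an independent library
implementation to 12 digits (tau and p), which the test suite asserts.

**Partial τ.** τ_xy·z = (τ_xy − τ_xz τ_yz)/√((1 − τ_xz²)(1 − τ_yz²)). Its
significance is assessed by plugging the partial τ into the same tie-corrected normal
approximation derived from the (x, y) tie structure. This is a documented
approximation — the exact null of the partial coefficient under ties is not
tractable in closed form — and partial mode is off by default because the primary
analysis conditions on nothing.

**MAF and the empirical null.** MAF is the fold min(m, 1−m) of the unweighted mean
coded-allele frequency across populations, so it is invariant to allele orientation.
Each SNP's |τ| receives a midrank percentile among all SNPs whose MAF lies within
±`maf_window` (default 0.01): rank = (#less + 0.5·#equal)/(window − 1), self
excluded. Ranks use |τ|, not signed τ, because coded-allele orientation in frequency
matrices is arbitrary; the signed τ is still reported. Windows holding fewer than
`min_window` SNPs (default 50) are widened symmetrically to the nearest-MAF
neighbours and flagged — on dense panels the window dominates; the floor only
matters for small simulated panels and window edges (MAF near 0.5).

**Calling.** `bonferroni_sig` ⇔ p ≤ α/n_tests with n_tests the number of SNPs
actually tested in the analysis set (a restricted gene-list scan divides by its own
count, not the genome-wide one); `rank_sig` ⇔ rank > 0.99; `final_sig` requires both.
Typical α: 0.05 genome-wide, 0.01 for list-restricted analyses.

## Downstream statistics

**SNP→gene assignment.** BED6 gene models are 0-based half-open; SNP positions are
1-based and converted internally. A SNP at 0-based coordinate P−1 belongs to a gene
iff it lies in [start − u, end) on the + strand or [start, end + u) on the − strand,
with u = 500 bp for gene-level tallies and u = 25 kb for network-style mapping;
extended starts clamp at zero. Transcript rows sharing a symbol are collapsed to
their union span (tallies count genes, not transcripts). Assignment with u = 0 is
pure span overlap and is monotone in u (property-tested).

**Gene-resampling enrichment.** For a list intersecting the SNP-covered universe in
m genes, each of R resamples (default 10,000) draws m genes uniformly without
replacement and counts distinct significant SNPs mapping to them. The default
empirical p is the add-one form (1 + b)/(1 + R), which cannot be zero; the plug-in
b/R is also reported since published values are usually that form. Uniform gene
sampling ignores per-gene SNP density and is anti-conservative for SNP-dense lists;
an optional coverage-matched sampler (each listed gene matched to a universe gene of
similar SNP coverage) is provided, but uniform remains the default because it is the
statistic's standard definition.

**Genic-location test.** For each significant SNP, k (default 10) control SNPs are
drawn without replacement from non-significant SNPs within the same MAF window, and
the 2×2 genic/non-genic × significant/control table is tested by Pearson χ² with
1 df, no continuity correction (counts are large in intended use; the choice is
recorded in the output so it is auditable). The control construction is a design
choice — "MAF-matched control set" admits several readings — and the sampler's seed
is recorded.

**Interaction arithmetic.** Expected interacting genes in a set of n genes is
n·K/N for a background of K interacting among N SNP-covered genes; the observed count
is tested by a 1-df goodness-of-fit χ² on (interacting, non-interacting) vs
(E, n − E), upper tail. The expected counts for the reference backgrounds reproduce
published values; the χ² p-values are those of this documented construction and make
no claim to match any differently-constructed published p.

**Category over-representation.** Per category, the list count k is tested with the
upper-tail exact binomial against the category's reference fraction, Bonferroni
multiplied by the number of categories actually tested. Categories empty in both
list and reference are skipped with a note.

**Confounder screen.** Significant SNPs are re-correlated (same τ machinery) against
annual Tmin, Tmax and shortwave flux broadcast to populations, with a Bonferroni
denominator equal to the number of SNP × variable tests in the report. Constant
variables are skipped with a note. The screen reports and never filters — matching
how such screens are used (inspection, not exclusion); callers wanting strictness
can drop `ConfounderReport.failing_snps()` themselves.

## Synthetic panels

`simulate_panel` draws, per SNP, an ancestral frequency p₀ ~ U(maf_floor, 1 −
maf_floor), one continent frequency per continent from
Beta(p₀(1−F_c)/F_c, (1−p₀)(1−F_c)/F_c), and one population frequency per population
from the same law around its continent value with F_p. Defaults F_c = 0.09,
F_p = 0.02 follow the classic apportionment of human diversity (≈9% among continental
regions, ≈2% among populations within regions, ≈0.11 total), with the default 52
populations / 21 countries / 7 continents nesting in contiguous, near-equal blocks.
Environments are i.i.d. integers per country in [39, 55] (the observed range of
virus-diversity totals for the reference panel; the integer grid produces ties across
countries as well as the exact ties within countries). Sample sizes are drawn
U{5..46}. Spiked SNPs (a fraction `frac_selected`, only when β ≠ 0) get their
population frequencies shifted by ±β × standardized country environment (random sign
per SNP, since allele orientation is arbitrary) and clamped to [0.01, 0.99]. The
effect enters as a frequency shift, not a forward-time selection coefficient: the
scan detects frequency–environment correlation, not trajectories, and the shift
model is exactly the alternative it is powered against. All outputs are a pure
function of (config, seed).

What the generator does **not** emulate: linkage disequilibrium between SNPs (draws
are independent), array ascertainment bias, population-specific drift intensities,
sample-size-dependent estimation noise in the frequencies, and any spatial
autocorrelation of the environment. Passing tests on these panels therefore
demonstrate the statistical machinery (calibration of the tie-corrected p, the rank
null's behaviour under shared drift, recovery of frequency–environment coupling),
not robustness to LD or ascertainment in real array data.

`simulate_annotation` lays non-overlapping genes over the simulated SNP coordinates
so that a configurable fraction of SNPs is genic, builds one list enriched for genes
holding spiked SNPs plus a same-size random control list, and draws per-gene
interaction flags at the 1916/15280 background rate. `evaluate_recovery` reports
power and false-positive rate of `final_sig` and median ranks by class; power is NaN
when nothing was spiked.

## Numerical and design notes

- Variance guard: if the tie-corrected Var(S) ≤ 0 (essentially everything tied), the
  p-value is reported as 1 rather than dividing by zero.
- p-values are clipped into (0, 1]; ranks live in [0, 1] with midrank ties.
- Window search uses a stable MAF sort plus binary search; widening prefers the
  nearer neighbour and breaks exact-distance ties to the left, deterministically.
- All resampling seeds are explicit arguments recorded in outputs; the pipeline
  derives per-list seeds as seed + list index so adding a list does not reshuffle
  the others.
- TSV floats are written with 12 significant digits; round-trips are exact for
  integers and to 12 digits for reals.
- Problem sizes used by the test suite (20k-SNP panels, 2,000-resample enrichment
  runs, 200-replicate calibrations) are chosen as the smallest sizes at which the
  asymptotics under test are visibly in force on a desktop machine.

## Known limitations

- A single environmental realization can align with the continental drift axis by
  chance; when that happens the raw Bonferroni gate admits many drifted SNPs even on
  a fully neutral panel (the rank gate still holds the top-1% line, by
  construction). This is intrinsic to correlating one country-level variable with
  structured frequencies — it is the very confounding the empirical rank null
  exists to mitigate, and it is why the two-criterion call should be read as
  "outlying among MAF peers", not as a calibrated family-wise error rate.
- The empirical rank is relative: under a genome-wide shift in association strength
  (e.g. polygenic response) ranks remain uniform and absolute signal is invisible.
- The partial-τ p-value is approximate (see above).
- The genic test's control sampler allows a control SNP to serve several significant
  SNPs; with few non-significant MAF peers the 2×2 cells are not independent draws.
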