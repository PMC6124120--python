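# Methods

`segscan` implements the statistical core of a bulked-segregant mapping and
expression study of a de-novo multicellular phenotype in the haploid green
alga *Chlamydomonas reinhardtii*: an exact-binomial log-odds genome scan
over two phenotype-enriched sequencing pools, a fourfold differential-
expression filter, phylostratum (gene-age) assignment from homology hits,
and a shared two-tailed hypergeometric enrichment engine.  A synthetic F2
cross and pooled-sequencing generator with known ground truth makes every
stage testable without the original sequencing data.

## The scan statistic

At a biallelic SNP, the two pools contribute alt/ref read counts
`(k_U, n_U)` and `(k_M, n_M)`.  Under the null hypothesis that the marker
is unlinked to any causal locus, both pools sample the same underlying
allele frequency, estimated by the pooled MLE
`p̂ = (k_U + k_M) / (n_U + n_M)`.  With `K_U ~ Binomial(n_U, p̂)` and
`K_M ~ Binomial(n_M, p̂)` independent, the exact tail probability is

    p = P( |K_U·n_M − K_M·n_U| ≥ |k_U·n_M − k_M·n_U| ),

i.e. the probability of a pool-frequency difference at least as large in
magnitude as observed.  Conditioning on the *observed* pooled frequency —
rather than the Mendelian 1:2 expectation — makes the test robust to
alleles that drifted in frequency through growth-rate advantages while the
pools were propagated: only sampling error or phenotype-linked selection
can separate the two pools.

The comparison is done on cross-multiplied integers, so tie handling at
the observed difference is exact and inclusive (`p > 0` always).  The
implementation is an O(n_U) bounded cumulative-sum evaluation whose result
equals exhaustive enumeration of the (n_U+1)×(n_M+1) outcome grid to
summation round-off; the test suite checks this equivalence exhaustively
for all depths ≤ 30 and on random instances up to depth 300 (tolerance
1e−12), and against Monte-Carlo simulation.

The reported score is `log10((1 − p)/p)`, the log odds against the chance
explanation, with numerator and denominator floored at 1e−300 so the
statistic is finite on (0, 1] and bounded to ±300.  A `−log10(p)` column is
emitted alongside.  Interpretive choices deliberately exposed as options:

* **Sidedness** — two-sided (magnitude tail) by default, since both
  directions of enrichment are biologically meaningful; one-sided via
  `sided="one"`.
* **Null conditioning** — two independent binomials at p̂ by default; a
  Fisher-style hypergeometric null conditioning on the total alt count is
  available (`null="conditional"`) for sensitivity analysis.
* **Log base** — base 10 throughout, for readability of genome-scan scales.
* **Depth filter** — SNPs with depth < 10 in either pool are skipped by
  default (configurable); per-site depth thresholds are otherwise a
  caller-side concern.

Statistics are orientation-invariant (invariant to swapping pools or
complementing alleles — property-tested); the `alt_origin` flag is carried
for interpretation only.

Candidate regions merge above-threshold SNPs within `max_gap` bp (default
500 kb) on a chromosome, report the peak SNP (ties broken leftmost), and
rank by peak log odds.  Region output is BED (0-based half-open); all
internal coordinates are 1-based inclusive.

### Known calibration property

The binomial null accounts for read-sampling noise only.  In a real or
simulated cross the two pools are finite samples of the F2 population, so
their true allele frequencies differ slightly even at unlinked markers;
with two ~2500-member pools sequenced at ~150×, this inflates the realized
type-I rate from the nominal 0.05 to roughly 0.055–0.06.  The effect grows
as pools shrink (composition variance ∝ 1/pool size) and vanishes as pools
grow.  Users mapping with small pools should treat borderline scores
accordingly; the acceptance suite verifies the rate stays within three
binomial standard errors of nominal under the default study-scale
conditions.

## The synthetic cross generator

The generator emulates the study design: two haploid parents (multicellular
isolate × unicellular wild type), F1 progeny intercrossed at random to
produce an F2 pool, phenotype-based separation into two pools, and pooled
sequencing.  Defaults are chosen to mirror the study's stated conditions
where given, and conventional values elsewhere:

| parameter | default | rationale |
|---|---|---|
| chromosomes | 17 × 1 Morgan, 1 Mb | chromosome count of *C. reinhardtii*; map/physical lengths are simulator conventions |
| markers | 20 per chromosome, evenly spaced | desk-scale marker density |
| `pool_depth` (λ_U, λ_M) | (155, 128) | the study's reported pool coverages |
| `misclassification_rate` ε | 0.05 | plausible residual impurity after iterated settling selection |
| `seq_error_rate` e | 0.001 | post-trimming per-read error scale |
| `n_f2` / `n_f1` | 2000 / 200 | pool sizes are not reported by the study; surfaced as parameters, not constants |

Model choices:

* **Meiosis** — crossover count per chromosome Poisson with mean equal to
  the genetic length in Morgans, positions uniform on the genetic map, no
  interference (Haldane model).  This gives the closed-form recombination
  fraction `r(d) = (1 − e^(−2d))/2` against which the simulator is tested,
  both for single-meiosis switch rates and for F2 two-locus haplotype
  frequencies.
* **Pool selection** — the study's four rounds of growth plus differential
  centrifugation are collapsed into a single per-individual
  misclassification probability ε: the scan only sees final pool
  composition, so ε is the sufficient knob for enrichment imperfection.
  Null (no-causal-locus) simulations use ε = 0.5, i.e. fully random
  sorting, which is the phenotype-uninformative limit and yields two
  comparably sized pools like the real experiment.
* **Growth advantage** — optionally, carriers of the derived allele at a
  designated locus contribute reads with a configurable weight, emulating
  expansion during pool propagation (the scenario that motivates testing
  against the observed pooled frequency).  Off by default.
* **Sequencing** — depth per SNP Poisson(λ), independent across SNPs and
  pools; each read observes a uniformly random pool member's allele,
  flipped with probability e.  Because members are redrawn per read, the
  alt count is exactly `Binomial(depth, f(1−e) + (1−f)e)` with `f` the
  pool allele frequency, and is sampled in that closed form.  No
  overdispersion is modelled; real pooled libraries show modest extra-
  Poisson variance that this generator does not reproduce.

What passing tests therefore do and do not show: recovery and calibration
results demonstrate the statistic's behaviour under clean Poisson-depth,
independent-error sequencing of an idealised cross (no interference, no
segregation distortion, no mapping artefacts, uniform marker informativeness).
They do not certify performance on real pools with alignment bias,
overdispersed coverage, or allele-specific error.

Acceptance-scale runs use n_f2 = 5000 and 17 × 20 markers, with 20-seed
null panels and 50-replicate recovery panels — sizes chosen so the whole
statistical battery runs comfortably on a laptop.

## Expression filtering

Replicate QC computes Pearson r over genes for each within-condition
replicate pair (the study reported r > 0.98, and R² > 0.96, in all pairwise
comparisons); pairs below a configurable floor (default 0.98) are flagged
but not fatal, and both r and r² are emitted.  Constant replicate vectors
have no defined correlation and are reported missing.

A gene is differentially expressed at a time point when
`|log2((mean_evolved + c) / (mean_ancestor + c))| ≥ log2(fold)`, inclusive,
with fold = 4 (log₂ ≥ 2) by default.  "Average difference" is read as the
ratio of across-replicate mean FPKMs, matching condition-level FPKM
semantics of the usual quantification tools.  The pseudocount c ≥ 0
(default 0.1 FPKM) keeps zero-expression ratios finite; with c = 0, zero
means produce signed infinite ratios (always selected) and 0/0 gives NaN
(never selected).  Note that any c > 0 shrinks ratios, so a gene at
exactly fourfold is included only in the pseudocount-free limit; the ratio
is computed as `log2(num/den)` so exactly representable ratios sit exactly
on the boundary.  An optional per-gene/time significance mask lets users
intersect the fold filter with an upstream statistical DE call, which this
package deliberately does not re-implement.  The per-time-point sets carry
over/under signs; their union implements "at one or more time points".

## Phylostrata and enrichment

A gene's phylostratum is the most inclusive stratum among its qualifying
homology hits (oldest detectable homology); the default ladder is
Chlamydomonas < volvocine (*Chlamydomonas* + *Gonium* + *Volvox*) <
Chlamydomonadales < Chlorophyceae < Chlorophyta < Viridiplantae <
Eukaryota < cellular organisms.  Hits qualify when E < 0.001 — a strict
inequality, so a hit at exactly 0.001 is excluded.  Genes with no
surviving non-self hits are lineage-specific (least stratum); the identity
self-hit is excluded by query ≠ subject id, while other same-species hits
count as least-stratum evidence.  Taxon → stratum resolution uses a frozen
two-column table rather than live taxonomy lookups, for offline
reproducibility; unmapped taxa are skipped with a warning (or raise, by
option).  Assignment is monotone: adding a hit can only move a gene to a
more inclusive stratum, tightening the threshold only to a less inclusive
one — both property-tested.

Enrichment of a gene set against categories (strata or GO terms) uses the
two-tailed hypergeometric test in the minimum-likelihood convention: the
sum of all feasible overlap probabilities no greater than the observed
outcome's, with a 1e−7 relative tolerance guarding floating ties, and the
total normalised so that degenerate draws give exactly 1.  A
double-the-smaller-tail variant is available.  P values are Bonferroni-
corrected with family size m = categories tested per run (configurable);
the replication-mode significance level is α = 0.0025, adopted as printed
(its mapping to a 1% false-discovery rate depends on unstated quantities
and is not re-derived).  The representation score mirrors the scan:
`sign(k/n − K/N) × log10((1 − p)/p)`; a descriptive log odds-ratio of
frequencies is available as an alternative column.

## Numerical notes and degenerate inputs

* All probability masses come from scipy (`binom`, `hypergeom`); the
  package's statistics are built on cumulative sums of those masses, so
  oracle-equivalence tolerances (1e−12 / 1e−10) reflect summation order
  only.
* Zero depth in either pool is undefined for the scan statistic; such
  SNPs are skipped with a logged count (default depth filter 10).
* `log_odds` domain is (0, 1]; the ±300 clamp keeps downstream sorting
  and plotting finite.
* Determinism: every stochastic component consumes a
  `numpy.random.Generator` seeded from the run configuration; fixed seeds
  give byte-identical artifact directories (manifests contain no
  timestamps).

## Limitations

* The scan is strictly per-SNP: no smoothing, sliding-window or
  interval-estimation statistics, and no variant-effect annotation (a
  non-synonymous mask can be supplied externally).
* The DE arm consumes FPKM tables as given: no normalisation,
  quantification or dispersion-based testing.
* Phylostratum assignment is only as good as the supplied hit table and
  taxon map; database-version-dependent genome-wide counts are out of
  scope.
* The generator's idealisations are listed above; none of the acceptance
  results should be read as error rates for real sequencing data.
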