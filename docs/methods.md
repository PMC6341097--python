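# Methods

## Study design the package implements

The workflow mirrors a two-stage familial rare-variant study. In the
discovery stage, multiplex families (ascertained for an affected
first-cousin pair, often with additional affected siblings) are
exome-sequenced and each family's variants are filtered down to a small
set of *variants of interest* (VOIs). In the replication stage, a panel
of candidate genes is resequenced in a large unrelated case-control
cohort and tested for rare-variant burden; a transmission-disequilibrium
test in the families provides an orthogonal within-family check, and
gene-set overrepresentation analysis asks whether the VOI genes cluster
in broad biological processes.

## VOI prioritization

A VOI must pass three independent predicates, applied as a monotone
pipeline (each stage only removes variants, and the result is invariant
to the order of application):

* **functional class** — one of nonsynonymous, splice, stop-gain,
  stop-loss. The class is taken from the annotation input; by the usual
  annotation convention, intronic variants within ±2 bp of an exon
  boundary count as splice (`FilterConfig.splice_window` documents the
  expectation; the package does not re-derive classes from gene models).
* **frequency** — in `private` mode the variant must be absent from
  dbSNP, 1000 Genomes European and ESP European-American. The
  database-presence flags are tri-state; unknown flags count as absent
  under the default `treat_absent` policy (an explicit `fail_variant`
  policy is available for stricter audits). In `rare` mode the reference
  allele frequency must be strictly below `rare_af_threshold` (default
  0.01); a missing frequency means the allele was never observed in the
  panel and counts as rare.
* **segregation** — every affected family member must carry at least one
  alternate allele (carrier status, not necessarily heterozygous). A
  missing genotype in an affected member rejects the variant under the
  default policy: family genotypes are sparse and a false VOI from
  dropout is costlier than a missed one. Unaffected relatives are never
  genotype-checked — reduced penetrance is expected in complex disease.

Deleteriousness scores (SIFT, PolyPhen-2, GERP, CADD phred) are carried
through to the VOI report but never used as filters; they inform manual
gene selection downstream, which is outside the package's scope.

## Gene-based burden association

Qualifying variants (rare and protein-altering) are collapsed per gene
into one carrier indicator per individual: a person with two qualifying
variants counts once. Carrier-based counting is the default;
allele-based counting (two alleles per diploid individual) is available
via `count_mode="allele"`. Missing genotypes count as non-carrier here —
the opposite of the VOI policy, and deliberate: in a sequenced
case-control panel missingness is sporadic and symmetric, so treating it
as non-carrier is unbiased, whereas inflating family segregation from
missing data is not.

The test is the one-sided Fisher exact test in the fixed direction
"greater burden in cases": p = P(X ≥ a) for the case-carrier cell under
fixed margins. The reverse tail exists in the API but is never the
default.

Two odds-ratio conventions are implemented because they answer subtly
different questions and diverge on sparse tables:

* **conditional** (default): the conditional MLE under the Fisher
  noncentral hypergeometric model — the root of E[X | ψ] = a, found by
  Brent's method on log ψ with an expanding bracket — with the exact
  conditional 95% CI obtained by inverting the noncentral upper/lower
  tails at 0.025 each. Boundary cells give one-sided infinite or zero
  bounds; a table with no carriers at all has an undefined estimate
  (NaN) and CI (0, ∞).
* **wald**: the sample cross-product ratio with the Woolf log-scale
  interval; zero cells fall back to the Haldane–Anscombe 0.5 correction
  for the interval. Published epidemiological tables most often follow
  this convention, so it is what to use when checking results against
  literature values.

For the bundled worked example (18/1004 case carriers vs 2/1127 control
carriers) the two give 10.26 (CI 2.45–91.4, conditional) and 10.27 (CI
2.38–44.4, Wald) — same estimate to two figures, very different upper
bounds, which is exactly why both are exposed.

`compare_to_reference_af` reconstructs an external reference panel from
a published allele frequency and allele number (round(af × n_alleles)
alternate alleles) and applies the same machinery on allele counts; the
allele number must be supplied by the caller since frequencies alone do
not determine the table.

Bonferroni-adjusted p-values over the scanned panel are attached by
`run_burden_scan` as a clearly-labelled extension; the per-gene p-values
are the primary output.

## Transmission disequilibrium (sibling-based)

Classical trio TDT scores transmissions from heterozygous parents; here
parental genotypes and phase are not required. Instead, for each proband
carrying a qualifying variant, each *affected sibling* contributes one
event per (sibling, variant) pair: transmitted if the sibling carries
the variant, untransmitted otherwise. For a rare variant this is the
Mendelian 50:50 coin flip. Siblings with missing genotypes contribute no
event. With one qualifying variant per family — the typical situation —
pair-wise counting equals per-sibling counting.

The statistic is χ² = (max(|T−U|−1, 0))² / (T+U), referred to χ²(1); the
continuity correction truncates at zero so |T−U| ≤ 1 gives χ² = 0. The
correction makes the test conservative (simulated null rejection ≈ 2–4%
at α = 0.05 for 10–100 events), so an exact two-sided binomial p at
p = 0.5 is always reported alongside for small counts. As a reference
point, T = 27 vs U = 10 gives χ² = 256/37 = 6.92, p(χ²) = 0.0085,
exact binomial p = 0.0076.

## Overrepresentation analysis

For a universe of N genes, a category with C members in the universe and
an input list contributing k matched genes, the overlap O is tested with
the hypergeometric upper tail P(X ≥ O); E = C·k/N and R = O/E. Gene
symbols are matched upper-cased; input genes outside the universe are
excluded from k. Categories are size-filtered to [500, 1500] genes by
default: a phenotype driven by hundreds of genes is best interrogated at
the level of broad processes, and tiny categories produce unstable
ratios. Benjamini–Hochberg FDR (step-up, via statsmodels) is computed
across all tested sets; stratifying by ontology branch is left to the
caller by running branches separately.

The default universe is the union of all genes in the GMT collection.
Every p-value depends on this choice, which is why cross-tool
comparisons of ORA p-values are unreliable unless the reference set is
identical; the enrichment *ratio* R is far more portable.

## Synthetic data

The generator produces the three study arms with recorded ground truth:

* **families** — three-generation pedigrees (shared grandparental
  couple, two sibling parents with married-in spouses, affected cousins
  ± affected siblings). Founder alleles are dropped by Mendelian
  transmission (each meiosis passes either parental allele with
  probability 1/2, independent across meioses). The marked-allele
  co-inheritance probability for first cousins is 1/16 analytically, and
  the vectorized gene-dropper reproduces it by Monte Carlo. Each family
  receives one planted qualifying VOI inserted along a shared founder
  path (so segregation is Mendelian-consistent), plus decoy variants
  that must *not* survive filtering: a private synonymous segregating
  variant, a database-known protein-altering segregating variant, and a
  private protein-altering variant carried by a single affected member.
* **cohort** — defaults of 1004 cases and 1127 controls over a 13-gene
  panel. Carrier status in the planted gene is Bernoulli per individual
  at rates 18/1004 (cases) and 2/1127 (controls); every carrier is
  heterozygous for exactly one of eight planted variants (chosen
  uniformly), matching the observation that rare-variant signals are
  carried as heterozygous singletons plus one recurrent variant.
  Background genes carry eight rare variants each (panel frequency
  0.002, heterozygote probability 2·af under approximate
  Hardy–Weinberg), identically distributed in both arms. The
  case-control simulation is deliberately marginal (no pedigree
  structure): the burden stage uses one unrelated case per family, so
  pedigree realism lives in the family generator. Linkage
  disequilibrium, haplotype structure and genotyping error are *not*
  modelled; passing tests demonstrate correctness of the counting and
  testing machinery under the stated sampling model, not robustness to
  real-data artefacts.
* **transmissions** — n Bernoulli(τ) draws (defaults n = 37, τ = 0.5
  under the null).

A single global seed is split into named per-stage streams
(`rng_streams`) via `numpy` seed sequences, so stages can be re-run
independently and all outputs are bit-reproducible.

## Numerical and test-scale choices

* Fisher tails come from `scipy.stats.hypergeom`; the test suite checks
  them against brute-force rational enumeration (exact fractions) on all
  tables with group sizes ≤ 8, at 1e−12.
* The conditional-MLE solver works on log ψ with `brentq` (xtol 1e−12)
  and an exponentially expanding bracket; frozen reference values from
  an independent implementation agree to ≲1e−3 (that implementation's
  own optimizer tolerance dominates the difference).
* Null calibration runs use 1000 cohort replicates (13 genes each) for
  the burden type-I error and 2000 replicates of 37 events for the TDT,
  with two Monte-Carlo standard errors of slack on the nominal 5%;
  the cousin co-inheritance check uses 100 000 gene drops against three
  standard errors around 1/16. These sizes keep the full suite within a
  few minutes while leaving the Monte-Carlo error well below the margins
  being tested.
* Pipeline TSVs print floats at six significant digits; ties in result
  orderings are broken by gene/set identifier so outputs are total-ordered
  and diffable.

## Known limitations

* The VOI stage trusts the upstream functional classification and does
  not left-normalize indels; inputs must share the annotation's
  (chrom, pos, ref, alt) convention.
* chrX genotypes are taken at face value (a warning is emitted); no
  hemizygous handling.
* No covariate adjustment or population-stratification correction in
  the burden test; the design assumes ancestry-matched cases and
  controls.
* ORA p-values are universe-dependent (see above) and no
  topology-aware GO pruning is attempted.
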