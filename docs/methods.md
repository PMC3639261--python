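# Methods

This note documents the statistical models implemented in `gwasprio`, the
choices made where the methodology was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Gene-body mapping and candidate ranking

A gene region is the span from the start of the first exon to the end of
the last exon, held internally as a 1-based interval inclusive at both
ends; BED input is converted at the I/O boundary (start = chromStart + 1,
end = chromEnd) and nowhere else. A SNP belongs to a gene iff it lies on
the same chromosome with `start ≤ pos ≤ end`; a SNP inside two overlapping
genes counts for both. Containment and flanked-window membership are
inclusive at both boundaries — the natural convention for 1-based inclusive
intervals, and the one adopted here since coordinate conventions at the
boundary are otherwise underdetermined.

Per gene, the best SNP is the one with the smallest additive-model P; ties
are broken by lexicographically smallest SNP id, and ranking ties between
genes by gene id, so that reports are deterministic and invariant under
permutation of input order. Genes with no SNP coverage are retained and
reported as `n/a` — they matter for the enrichment denominator (below).
Duplicate SNP ids are a hard load error rather than last-wins, because a
silent overwrite would corrupt best-SNP-per-gene results downstream.

## Sub-threshold set enrichment

The set-level question is whether genes whose best SNP passes a moderate
cutoff (default `P < 0.005`, far from genome-wide significance)
over-concentrate in the candidate set. The 2×2 table is set membership ×
passing/not-passing over the user-supplied gene universe, tested with a
two-sided Fisher exact test. By default genes with zero SNP coverage stay
in the denominators (`include_uncovered=True`): they were candidates that
could not pass, and on the packaged 71-gene catalog this convention gives
7/71 ≈ 10% rather than 7/62 ≈ 11%; the alternative is exposed as a flag.
The background universe is supplied by the caller (catalog minus set); no
attempt is made to hard-code a genome-wide background.

The Fisher P is the conventional exact-test definition: the sum of
hypergeometric point probabilities, over all tables with the observed
margins, not exceeding the observed table's probability, computed by direct
enumeration over the feasible range of cell *a* with a relative tie
tolerance of 1e-7 (floating-point equality of point probabilities is not
reliable). Degenerate margins return P = 1 with a warning. A permutation
null (`permutation_set_null`) provides an independent empirical check; the
overlap of a uniformly drawn set is sampled directly from its exact
hypergeometric law, which is distribution-identical to label shuffling and
much faster.

## Co-localization

A gene co-localizes with an association catalog if any catalog SNP lies
within a fixed flank (default 100 kb) of the gene body. The 2×2 table is
set membership × near-SNP over the universe, Fisher-tested as above. Set
members missing from the universe are dropped with a warning rather than
failing the run, since catalogs and set lists routinely drift out of sync.

## Replication statistics

All replication-stage statistics are computed from genotype count tables
(hom-major / het / hom-minor per group) — the unit of data exchange when
individual-level genotypes are unavailable.

- **Trend test.** The Cochran–Armitage statistic with scores (0, 1, 2),
  uncorrected (no continuity correction). Without covariates this is
  exactly the score test of per-allele logistic regression, which the test
  suite verifies against statsmodels. Monomorphic tables return P = 1 with
  a warning rather than raising, so batch report generation can continue.
- **Allelic OR.** From the 2×2 allele-count table (2N alleles per group);
  Wald CI on the log scale (the simplest interval consistent with an
  unqualified "95% CI"); Haldane–Anscombe +0.5 on all four cells only when
  some cell is zero, always flagged in the output. A table monomorphic
  across both groups has no defined OR and raises.
- **Hardy–Weinberg.** Asymptotic: 1-df χ² against n·(p², 2pq, q²) at the
  sample allele frequency. Exact: the conditional distribution of the
  heterozygote count given the allele counts, with the two-sided P summing
  conditional probabilities ≤ the observed one (same tie tolerance as
  Fisher). The exact method is preferred in reports; the χ² version is kept
  for continuity with older analyses. Both agree to < 0.01 on well-filled
  tables (all genotype classes > 500), which the suite checks.
- **Bonferroni.** `min(1, m·p)`; the replication report defaults m to the
  number of loci in the table.
- **Treatment-corrected BP.** For analyses of continuous blood pressure in
  treated subjects the conventional fixed offsets +15/+10 mmHg
  (systolic/diastolic) are provided as a pure function; the caller is
  responsible for applying it once.

The minor allele is taken from the table's printed labels when reading
files; generated tables label the population-minor allele as minor.

## Power

Control minor-allele frequency p₀; under per-allele odds ratio OR the case
frequency is p₁ = OR·p₀/(1 + p₀(OR − 1)). Power of the allelic z-test over
2n alleles per group uses the unpooled SE under the alternative and both
rejection tails:

    power = Φ(d/SE − z₁₋α/₂) + Φ(−d/SE − z₁₋α/₂),  d = |p₁ − p₀|

The far tail is numerically negligible for any real effect but makes power
exactly continuous at the null (power → α as OR → 1), and OR = 1 returns α
directly. The 2N-allele formulation (rather than the genotype-trend
variance) is the simplest model consistent with quoting per-allele odds
ratios; against simulated cohorts analysed with the trend test it agrees
within Monte-Carlo error across a MAF × OR grid (checked at 10,000
replicates per cell). At the replication design (5205 cases / 5320
controls, α = 0.05 two-sided) a MAF near 0.11 yields power ≈ (20, 60, 90)%
at OR 1.05/1.10/1.15.

## Synthetic data

**Cohorts.** Controls are drawn multinomially from Hardy–Weinberg
proportions at the population MAF — the population ≈ control approximation
appropriate when the control group is population-based and the trait is
common enough that controls include affected subjects. Case genotype
probabilities are proportional to HWE proportion × OR^(minor-allele
count), normalized; this is the exact genotype distribution implied by a
per-allele odds model on a HWE population, without simulating prevalence.

**Landscapes.** Genes are placed uniformly without overlap (round-robin
across chromosomes, ≥1 bp gaps; infeasible packings raise). Null SNP
P-values are i.i.d. Uniform(0, 1); each enriched set gene instead carries
one SNP with P ~ Beta(a, 1), a < 1 (default a = 0.05), the standard
one-parameter alternative for enriched P-values — no effect-size
distribution is implied by the workflow itself, so the shape parameter is
exposed in the config. A configurable fraction of genes is forced to have
no SNP coverage, sampled at the same rate inside and outside the candidate
set so a set-restricted report shows a predictable number of `n/a` rows
(default conditions mirror the worked example's 9-of-71); all remaining
genes are guaranteed at least one SNP. Default scale is 20,000 SNPs and
800 genes (71 in the set) over four 25-Mb chromosomes — large enough that
per-gene SNP counts and the enrichment null behave like a dense scan,
small enough that thousands of replicate landscapes are cheap. Under the
null the per-gene best P follows the Beta(1, k) minimum-of-uniforms law
(KS-checked), and the set-level test rejects at ≈ 5% at α = 0.05.

**Catalogs.** Co-localization inputs place a chosen number of hits within
the flank of random set genes and the rest in gene-free background, with
log-uniform P-values in [1e-12, 1e-5].

What the generators do **not** emulate: linkage disequilibrium (every SNP
is independent, so there is no clumping structure and "best SNP per gene"
never reflects correlated neighbours), allele-frequency spectra (MAF is a
single parameter, not a distribution), covariates and population
stratification, and genotyping error. Tests passing on this synthetic
structure therefore validate the bookkeeping, the exact distributions and
the calibration of the tests under independence — not robustness to LD or
confounding in real cohorts.

## Numerical choices

- Tie tolerances for exact-test point-probability comparisons: relative
  1e-7.
- P-value report formatting: two significant figures, upper-case
  scientific (`1.8E-03`), `n/a` for undefined; chosen so reports diff
  cleanly against the published tables' dialect.
- Seeds are mandatory for every generator; identical config + seed gives
  byte-identical output files. Pipeline runs write outputs atomically
  (temp + rename) and record input checksums in a manifest.

## Known limitations

- No covariate-adjusted models: the trend test and crude OR reproduce the
  unadjusted analysis only.
- No LD-aware proxy lookup or clumping; the unit of prioritization is the
  single best SNP per gene body.
- The exact HWE test enumerates the full conditional support; for samples
  of millions of alleles this is O(n) per test, fine at cohort scale.
- Orthology mapping between species is treated as upstream data
  preparation: gene ids in the set file must match the catalog.
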