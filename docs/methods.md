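# Methods

This document records the statistical models, parameter defaults, numerical
choices and known limitations of the `trioexome` package.

## Trio phasing

At a biallelic site, the parental origin of each child allele is assigned
by enumerating the ordered transmissions `(paternal, maternal)` drawn from
the parents' allele sets that reproduce the child genotype:

* no consistent transmission → Mendelian violation (flagged, unphased);
* exactly one → the site is phased;
* more than one → ambiguous. For diploid biallelic genotypes this is
  exactly the triple-heterozygote configuration (child and both parents
  0/1), plus any site with a missing parent.

Phasing is purely rule-based; no population LD or read-backed phasing is
attempted.

## Recessive candidate classification

**Homozygous recessive** requires, at an autosomal site passing the filter
policy: child 1/1, both parents 0/1. A 1/1 child with a non-carrier parent
is a Mendelian violation, not a candidate.

**Compound heterozygous** requires two policy-passing heterozygous variants
in the same gene with opposite parental origins. An ambiguous-phase variant
may pair only with a variant of *definite* opposite origin; such pairs are
emitted with `phase_assumed=True` as a lower-confidence tier. Two ambiguous
variants never pair. Output ordering is deterministic (paternal variant
first, genes and positions sorted) and independent of input order.

**Filter policy defaults** (`FilterPolicy`): population MAF < 1 % (the
maximum over the two annotation panels; a variant never reported in either
panel is treated as rare), protein-altering consequence (missense,
nonsense, splice-site, initiator-codon), and when `require_damaging` is
set, SIFT < 0.05 or PolyPhen-2 ≥ 0.85 with loss-of-function classes
exempt. Every emitted call carries the list of filter rules it passed.

## De novo calling

The caller computes the joint posterior over the 27 trio genotype
configurations `(g_father, g_mother, g_child)`:

* parental genotypes carry a Hardy–Weinberg prior at the site's annotated
  population MAF; sites with no reported frequency use `default_maf = 1e-4`
  so novel alleles still receive a proper (skeptical) prior;
* transmission allows a per-allele germline mutation with probability
  `mu = 1e-8`: a gamete from genotype g carries the alt allele with
  probability `[mu, 0.5, 1 - mu][g]`;
* read evidence enters through each member's Phred-scaled genotype
  likelihoods (`PL`); a missing PL in any member is a no-call.

The de novo posterior is the mass on configurations where the child
carries an allele absent from both parents (parents 0/0 with child
carrying alt, or parents 1/1 with child carrying ref). The default calling
threshold is 0.5. The posterior is monotone decreasing in the site MAF:
common alleles are explained as inherited-but-miscalled long before rare
ones.

### Measuring recall under read noise

At 30× mean depth a true de novo het child occasionally draws few alt
reads; the likelihood advantage of the het call then fails to overcome the
~2·mu prior penalty, giving a per-event miss probability of roughly 1 %.
Recall is therefore measured **aggregated over eight independently seeded
44-trio cohorts** (~140–150 events): a single cohort carries only ~17
events, so one miss already yields 0.94 and cannot resolve a 0.95
threshold. Observed aggregate recall: 0.98.

## Poisson model of per-trio de novo counts

Per-trio coding de novo counts are fit by maximum likelihood (λ̂ = sample
mean). Goodness of fit is a chi-square on the binned counts {0, 1, ≥2}
against Poisson(λ̂) masses, with **1 degree of freedom** (3 bins − 1 −
1 estimated parameter). Counts in this regime rarely exceed 2, so the
three bins avoid near-empty expected cells. Calibration was verified by
simulation: on Poisson(0.4) null cohorts of 44 trios the test rejects at
rate 0.051 at α = 0.05 (10,000 replicates).

### De novo count dispersion

The packaged reference cohort's per-trio coding de novo counts
(32 trios with 0, 7 with 1, 5 with 2; λ̂ = 0.386) **reject** this test:
statistic 4.30, p = 0.038. The excess sits entirely in the two-event bin
(5 observed vs 2.55 expected) — a mild overdispersion. A parametric
bootstrap of the same statistic agrees (p ≈ 0.035), while the classical
Poisson dispersion (variance/mean) test does not reject (p ≈ 0.14), so the
qualitative conclusion depends on which fit statistic is prescribed. The
package reports the exact binned chi-square faithfully; the corresponding
acceptance clause is deliberately left failing rather than substituting
the weaker test.

## Site quality control

Filters run in a fixed order and each exclusion is logged with the rule
name, statistic and p-value:

1. call rate ≥ 0.95;
2. minor allele frequency ≥ threshold (this rule is **skipped** in the
   candidate pipeline, which must keep rare variants; it belongs to the
   array-style QC track used for ROH);
3. exact Hardy–Weinberg test p ≥ 1e-4, computed on **founders only** when a
   pedigree is supplied (children of the same parents are not independent
   draws from the population);
4. case/control differential missingness, two-sided Fisher exact, p ≥ 0.01.

The HWE test is the exact conditional (Levene–Haldane) test: the two-sided
p-value sums the probabilities of all heterozygote counts no more likely
than the observed one, computed in log-space with a `1 + 1e-12` tolerance
on the inclusion comparison. It matches full integer enumeration to
1e-10 relative error for every configuration up to 50 samples.

Diagnostics: Ts/Tv ratio (undefined when no transversions; indels logged
and skipped) and replacement:silent ratio (replacement = missense +
nonsense + splice + initiator-codon; undefined when no synonymous calls).

## Runs of homozygosity

* **LD pruning**: greedy left-to-right; a SNP is dropped when its squared
  genotype correlation with any kept SNP within a 50-SNP window exceeds
  0.9. Monomorphic SNPs (undefined r²) are kept and logged.
* **Detection**: sliding windows of 50 SNPs are flagged homozygous when
  they contain ≤ 1 heterozygous and ≤ 5 missing calls; maximal stretches of
  markers covered by at least one flagged window become segments, kept at
  ≥ 2 Mb and ≥ 100 SNPs. Boundary resolution is one window: planted 5 Mb
  tracts are recovered with edge error below 50 SNP spacings; 1.5 Mb
  tracts are never reported.
* **Burden/association**: per-sample statistics (segment count, total
  length, genes spanned) are compared case vs control by one-sided mean
  difference under label permutation; per-locus coverage on the atomic
  intervals induced by segment breakpoints is corrected genome-wide by the
  permutation max-statistic. Empirical p-values are `(b + 1)/(n_perm + 1)`,
  never zero, and **super-uniform** under the null — validity tests
  therefore only bound `P(p ≤ α)` from above.

## Cohort statistics

* **Summary t-tests** use the pooled-variance Student form on published
  `(n, mean, SD)` summaries, df = n₁ + n₂ − 2. The packaged parental-age
  comparisons reproduce from printed summaries only under pooling (fathers
  p = 0.059, mothers p = 0.042, onset p < 1e-17).
* **EASE score**: hypergeometric upper tail with one hit removed from the
  gene list — `P(X ≥ k − 1)` for `X ~ Hypergeom(M, n, N)`; a list with ≤ 1
  hit can never be significant. Categories are significant at EASE p <
  0.05 and Benjamini–Hochberg q < 0.1.
* **Burden tabulation** works from per-patient event counts; compound-het
  counts are *gene pairs* (two variants each), and percentages are of the
  cohort size, rounded to integers.

## Synthetic cohort generator

The generator (`trioexome.simulate`) emulates the study regime:

* background site frequencies from a U-shaped spectrum: 70 % common
  Uniform(0.05, 0.5) and 30 % rare exponential tail capped at 0.005 — the
  cap keeps chance rare-recessive genotype collisions negligible, so
  recall/precision against truth are meaningful;
* founders at Hardy–Weinberg, children by fair-coin transmission;
* per-child coding de novo counts Poisson(17/44 by default), placed at
  otherwise-monomorphic sites and annotated as novel;
* planted compound-het (two sites per gene, one allele per parent) and
  homozygous-recessive (child 1/1, parents 0/1) configurations annotated
  rare and damaging;
* optional ROH tracts realized as identity-by-descent (parental alleles
  forced to match the transmitted haplotype) so Mendelian consistency is
  preserved exactly;
* genotype likelihoods from a binomial read model: depth ~
  Poisson(depth_mean), alt reads ~ Binomial(depth, [0.01, 0.5, 0.99]),
  PLs normalized and capped at 255, GQ = second-smallest PL.
  `depth_mean=None` emits sharp (noise-free) likelihoods.
* annotation MAFs are rounded to 6 significant digits at creation: htslib
  stores INFO floats in single precision, and 6-digit values survive a VCF
  write/read round trip exactly.

What it does **not** emulate: LD between background sites, indels, X/Y
inheritance, sequencing batch effects, population stratification, or
variable per-site capture efficiency.

Everything derives deterministically from the config seed through
independent per-stage substreams, so changing, say, the read-noise stream
does not perturb the genotypes.

## Numerical and engineering choices

* Exact tests (HWE, Fisher) are computed in log-space with `lgamma`; test
  oracles re-derive them with exact integer arithmetic.
* Pipeline outputs are deterministic and stamped with a 16-hex config hash
  covering the analytic parameters (file paths excluded), so identical
  analyses are byte-identical.
* Packaged fixture tables are guarded by SHA-256 checksums; corruption
  raises `FixtureIntegrityError`.
* Multiallelic VCF records are decomposed into one biallelic record per
  ALT; sample alleles matching another ALT are re-coded as REF and PL
  triples are projected onto the (0/0, 0/k, k/k) axis.

## Limitations

* Phasing is single-site transmission logic only; comp-het pairs with both
  variants triple-het remain undetectable by design (reported tiers make
  this explicit).
* The de novo prior treats sites independently; no per-gene mutability or
  CpG context.
* ROH detection assumes a reasonably dense, mostly-common marker set;
  exome capture gaps are not modeled.
* The X chromosome is excluded from recessive classification
  (autosomes only).
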