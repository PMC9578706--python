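# Methods

This note records the statistical models implemented in `evosuppress`, the
assumptions behind them, the defaults and why, and what the synthetic-data
generators do and do not emulate.

## Tetrad segregation and the suppression test

A diploid heterozygous at a deleterious locus (genotype `DEL/del`) and at a
candidate suppressor locus (`SUP/sup`) is sporulated. A spore forms a large
colony when it carries the wild-type deleterious allele or a rescuing
suppressor allele. With a single segregating locus (no suppressor) every
tetrad is 2:2 large:small and 50% of spores are large. With two unlinked
loci the tetrad types PD:NPD:TT occur 1:1:4; mapping spore genotypes to
colony sizes turns these into large:small patterns 2:2, 3:1, 4:0 in a
1:4:1 ratio, with an expected 3/4 of spores large
(1/6·1/2 + 4/6·3/4 + 1/6·1). `tetrads.enumerate_two_locus_patterns`
re-derives the 1:4:1 ratio by brute-force enumeration of the six
equally likely assortments of suppressor alleles against the deleterious
locus; the test suite asserts the closed form against this enumeration
rather than trusting a constant.

**Error model.** Real dissections contain patterns impossible under one
hypothesis (dead spores, gene conversion). Under each hypothesis, every
pattern with probability zero receives a probability ε and the remaining
mass is scaled onto the possible patterns (for non-suppression:
p(2:2)=1−2ε, p(3:1)=p(4:0)=ε; suppression has no impossible pattern among
the three and is unchanged). This is the minimal perturbation that makes
both likelihoods proper; ε defaults to 0.01 and applies symmetrically.
The inference is insensitive to ε over a wide range: with ten tetrads the
log-likelihood ratio moves by tens of units between hypotheses while ε
shifts it by at most a few.

**Likelihood ratio.** For observed pattern counts n_p,

    LLR = Σ_p n_p · log( p(p | suppression, ε) / p(p | non-suppression, ε) ),

positive favoring suppression. The multinomial coefficient cancels. The
LLR is additive over disjoint tetrad sets. Log base defaults to 10 and is
configurable; the default decision threshold τ = 2 in base 10 corresponds
to 100:1 odds. With ε = 0 an observed 3:1 or 4:0 tetrad makes the
non-suppression likelihood zero; the LLR is then reported as a signed
infinity with a warning instead of raising.

The worked ten-tetrad dissection (one 4:0, nine 3:1; 31/40 = 77.5% large
spores, displayed 78%) gives LLR ≈ +17.6 at the defaults (base 10,
ε = 0.01) and ≈ +40.6 in natural log. A published analysis of the same
dissection reports 27.6, which this model reproduces exactly with base-10
logs and ε = 10⁻³; both parameters are exposed so either convention is
expressible. Under every convention the verdict at τ = 2 is identical.

**Dominance.** A second dissection uses a strain with an integrated extra
wild-type copy of the suppressor gene, so that every spore carries a
wild-type copy next to whatever suppressor allele it inherited. A dominant
suppressor rescues in both designs (both LLRs > τ); a recessive suppressor
only in the standard design; neither LLR above τ means non-suppressor.
Tetrads with dead or unscoreable spores (`n_other`) are excluded from the
likelihood by default.

## LOF / non-LOF spectrum classifier

Hypotheses: selection acts by eliminating a gene's function (LOF — any
disruptive mutation is adaptive, so spectra mix missense with
frameshift/nonsense) or by altering it (non-LOF — truncations are not
recovered, spectra are nearly all missense). The model is a two-class
naive Bayes on the spectrum (n_missense, n_truncating):

* priors: fraction of training genes per class (10 LOF and 6 non-LOF
  training genes give 0.625 / 0.375);
* class conditionals: mutation counts pooled across each class's training
  genes and normalized, with an optional pseudocount per class (default 0,
  matching unsmoothed pooling; 0.5 recommended when a pool lacks a class
  entirely — fitting raises on a degenerate conditional rather than
  silently producing ±∞ log-likelihoods);
* log-likelihood of an observed spectrum omits the binomial coefficient
  (identical under both hypotheses, cancels from the posterior);
* posterior computed in log space for stability at extreme spectra.

The posterior is calibrated by construction when the data are generated
from the model; the suite checks this by simulation (10⁴ draws) and checks
the monotonicity property that more missense mutations raise, and more
truncating mutations lower, the non-LOF posterior whenever
p(missense|non-LOF) > p(missense|LOF). The classifier ignores gene length
and codon composition: it conditions only on the effect-class split, which
is the contrast the two hypotheses actually disagree about.

## Recurrence and gene-set enrichment

With N nonsynonymous mutations spread over a universe of G genes
(default 5906, the yeast gene count used genome-wide), the neutral count
in a gene set of size m is X ~ Binomial(N, m/G). Enrichment and depletion
are the exact tails P(X ≥ k) and P(X ≤ k); per-gene recurrence uses
m = 1, or a length-proportional weight when gene lengths are supplied.
Tails are computed exactly (regularized incomplete beta via scipy, which
the tests verify against direct term-by-term summation up to N = 500).
The trials are mutation events: each clone's mutation counts once, and an
option collapses identical variants (same position and allele) across
clones of one population for the "unique mutations" convention. Multiple
testing correction (Benjamini–Hochberg) is available but off by default,
since the genome-wide binomial test is typically reported raw in this
assay. Aggregating experiments sums per-gene counts first and then tests
the pooled table; the two orders commute exactly and a test asserts it.

## Variant ingestion and ploidy

Input is either a plain mutation-table TSV or a VCF with SnpEff-style
`ANN` annotations (one record per alternate allele; allele fraction from
allelic depths `AD` when present, else the `AF` INFO field, else 1.0).
Annotation terms map onto a closed effect vocabulary {missense, nonsense,
frameshift, synonymous, noncoding, other}; unknown terms become "other"
with a logged warning, and compound `A&B` annotations resolve to their
first recognised term. "Nonsynonymous" = missense + nonsense + frameshift.

A clone is called diploid when at least `min_het` (default 2) of its
mutations have allele fractions inside an open heterozygosity window
(default (0.4, 0.6)). The window width is a declared choice: a
heterozygous variant sits at exactly 0.5 only in expectation, and
finite-depth allelic counts scatter around it; the window and threshold
are both parameters. The call is monotone — adding a heterozygous record
can never flip diploid back to haploid.

Group burden is the per-clone nonsynonymous count summarized per genotype
group as mean ± t-based 95% CI (half-width t(0.975, n−1)·sd/√n); a group
with one clone reports an undefined CI rather than a fabricated one.

## Competitive fitness

The query strain is co-cultured with a fluorescent reference; both are
counted by flow cytometry every ~10 generations (10 generations per daily
growth cycle). Under constant selection ln(query/reference) is linear in
generation with slope s, the per-generation selection coefficient, so s is
estimated by OLS of the log count ratio on generation, reported in percent
per generation; deleterious strains are negative. The slope is
intercept-free, so the estimate is invariant to the initial mixing ratio
(1:1 or 50:1 — the latter is what a strongly deleterious query needs to
stay countable for a few timepoints). Timepoints where either count is
zero carry no finite log ratio and are dropped with a warning — truncation,
not pseudocounting, because a zero count at late generations reflects
genuine exclusion of the lineage rather than sampling noise to smooth
over. Replicates are summarized as mean ± t-based 95% CI across replicate
slopes (between-replicate variation dominates within-regression error in
this assay design). Group comparisons use one-way ANOVA with Tukey's HSD.

## Enzyme kinetics and the statistics layer

Michaelis–Menten fits v = Vmax·S/(Km+S) use nonlinear least squares
(Levenberg–Marquardt from a data-driven start, falling back to a bounded
trust-region solver if LM leaves the positive quadrant), with 95% CIs from
asymptotic standard errors scaled by t(0.975, n−2). Rates are specific
activities in µmol·min⁻¹·mg⁻¹; substrate in mM. kcat/Km is only computed
when the caller supplies mg-per-mol for the enzyme (63 kDa monomer →
63·10⁶ mg/mol); the unit conversion is explicit, never inferred. Activator
dose-response uses the same hyperbola with EC50 in place of Km and rejects
monotone-decreasing data (a decreasing response is not activation). CI
coverage of the MM fit is simulation-calibrated in the suite (500
simulated assays at 2%-of-Vmax noise, coverage within Monte-Carlo error
of 95%).

The substrate-competition check compares rate ratios against a matched
control grid per competitor concentration and flags competitive inhibition
only for ratios below one that decrease monotonically with competitor.
Forward/reverse reaction ratios are per-replicate ratios summarized as
mean ± sample sd, excluding zero-denominator replicates with a warning.

Welch's t uses the unequal-variance statistic with Welch–Satterthwaite
degrees of freedom; the Mann–Whitney statistic follows the first-sample
U convention (W = #{x_i > y_j} + half-ties) with an exact p-value via
full enumeration when min(n, m) ≤ 8 without ties, else the
continuity-corrected normal approximation. Quadratic regression
(y = b0 + b1·x + b2·x²) reports R², adjusted R², and the
overall-regression F on (2, n−3) df — the generic tool for hump-shaped
fitness-versus-activity relationships; any transformation of the response
axis is the caller's concern. Standard-curve quantification fits a linear
calibration, averages technical replicates before inversion, and flags
unknowns outside the standards' signal range as extrapolated.

## Synthetic data

Generators emulate the statistical structure each analysis assumes, with
known ground truth:

* **Mutation tables** — per-clone mutation counts Poisson with a
  group-specific mean (the count distribution is an assumption, flagged
  and configurable by editing the generated table; nothing downstream
  depends on Poissonness except the burden-recovery checks); gene
  assignment multinomial over a 5906-gene universe with optional relative
  enrichment weights; effect classes from a configurable
  (missense, truncating) split; a configurable fraction of clones
  (default 131/188 ≈ 0.70, the observed autodiploid fraction) emit all
  mutations at allele fraction 0.5, the rest at 1.0. Chromosome and
  position are synthetic placeholders.
* **Tetrads** — multinomial pattern counts under either hypothesis at any ε.
* **Spectra** — binomial missense/truncating splits at given class
  conditionals (defaults 0.5/0.5 for LOF, 0.95/0.05 for non-LOF).
* **Flow counts** — binomial sampling of `depth` cells per timepoint
  around the exponential ratio trajectory with a fixed s; default scenario
  s = −0.2586 per generation, sampling every 10 generations to 50.
* **Kinetics** — Michaelis–Menten rates with additive Gaussian noise
  truncated at zero (activities are nonnegative).

Reproducibility: one master seed; each generator draws from an independent
substream `SeedSequence([seed, STREAM_ID])` with fixed per-generator
stream ids, so outputs are identical across runs and platforms and
generators do not perturb each other.

What the generators do **not** emulate: clonal interference or any
population-genetic dynamics (lineages are independent), linkage between
mutations, sequencing error or coverage variation, gene-length variation
in mutational target size, frequency-dependent fitness, or enzyme assay
artifacts (substrate impurities, coupled-enzyme lags). Passing the
recovery tests therefore shows the estimators are correct under their own
assumptions, not that those assumptions hold in any particular real
dataset.

## Problem sizes in the test suite

Monte-Carlo checks use sizes chosen to keep sampling error well below the
asserted tolerances while running in seconds: 10⁴ draws for tetrad power
and classifier calibration, 10⁴ genes for type-I control of the recurrence
test, 500 simulated assays for MM CI coverage, 100 seeds for the fitness
bias check at counting depth 10⁶, and 10⁴ clones for burden recovery. All
are fixed-seed.
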