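# evosuppress

Statistical analyses for evolve-and-resequence suppressor studies in
yeast, built around the workflow used to dissect compensatory evolution in
a disease-model background (e.g. hypomorphic *SEC53*, the yeast homolog of
human *PMM2*, whose deficiency causes the most common congenital disorder
of glycosylation). Populations founded from a deleterious ancestor are
evolved for hundreds of generations, clones are sequenced, and candidate
suppressors are validated genetically and biochemically. This package
implements the statistics layer of that workflow as a tested, reusable
library plus a CLI:

* **variants** — ingest annotated calls (TSV or SnpEff-annotated VCF),
  classify effects, call spontaneous autodiploids from allele fractions
  (≥2 mutations at allele fraction ≈ 0.5), summarize per-group
  nonsynonymous burden with t-based 95% CIs.
* **recurrence** — exact binomial tests for genes mutated more often than
  chance and for enrichment/depletion of curated gene sets: with N
  mutations over G = 5906 genes, a set of m genes has neutral count
  X ~ Binomial(N, m/G); p_enrich = P(X ≥ k), p_deplete = P(X ≤ k).
* **lofbayes** — a Bayesian classifier deciding from a gene's mutational
  spectrum (n_missense, n_truncating) whether selection acted on loss of
  function or on alteration of function; priors from labeled training
  genes, pooled class conditionals, log-space posterior.
* **tetrads** — expected segregation patterns for suppression crosses
  (1:4:1 of 2:2/3:1/4:0 large:small for two unlinked loci, 75% large
  spores; all-2:2 and 50% without suppression), a log-likelihood
  suppression test with an explicit error term ε, and dominance
  classification from the integrated-extra-copy design.
* **fitness** — per-generation selection coefficients as the OLS slope of
  ln(query/reference) flow-cytometry counts against generation, replicate
  pooling, one-way ANOVA with Tukey HSD.
* **kinetics** — Michaelis–Menten and EC50 fits with asymptotic CIs,
  substrate-competition checks, forward/reverse ratios, Welch's t,
  Mann–Whitney (first-sample U convention), quadratic regression with the
  ANOVA F test, and standard-curve quantification.
* **synthdata** — seeded generators producing inputs with known ground
  truth for every stage (Poisson mutation burdens, multinomial tetrad
  patterns, binomial competition counts, noisy Michaelis–Menten curves).

See `docs/methods.md` for the models, defaults, and assumptions.

## Worked example

Score two tetrad dissections — a candidate suppressor cross (one 4:0 and
nine 3:1 tetrads) and a cross with an integrated extra wild-type copy
where all ten tetrads came out 2:2:

```sh
$ cat tetrads.tsv
strain	n22	n31	n40
sec53-V238M_pgm1-T521K	0	9	1
sec53-V238M_pgm1-null_integrated	10	0	0

$ evosuppress tetrads tetrads.tsv --outdir out
sec53-V238M_pgm1-T521K: percent_large=77.5 llr=17.64 -> suppression
sec53-V238M_pgm1-null_integrated: percent_large=50.0 llr=-7.69 -> non-suppression
```

77.5% of the first cross's 40 spores formed large colonies — close to the
75% expected when a dominant suppressor segregates, far from the 50% of a
non-suppressing cross — and the base-10 log-likelihood ratio of +17.6
(ε = 0.01) favors suppression by over 10¹⁷:1; the second cross is the
recessive-suppressor signature (suppression in the standard cross, none
once every spore carries a wild-type copy). From Python, a gene-set
enrichment test of 8 hits in a 24-gene set among 524 mutations:

```pycon
>>> from evosuppress import recurrence
>>> r = recurrence.geneset_test(N=524, k=8, m=24, G=5906)
>>> print(f"p_enrich = {r.p_enrich:.2e}")
p_enrich = 1.57e-03
```

about 2.1 set hits were expected by chance (524 × 24/5906), so 8 is a
significant enrichment. An end-to-end run on synthetic data:
`evosuppress all --seed 7 --outdir run/`.

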