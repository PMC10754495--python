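# Methods

This note documents the models, the defaults and their rationale, the
synthetic study conditions, and the known limitations of the analyses in
`ednaident`.

## Matching model

A soil haplotype is an ordered run of alleles from one phase set of the
sample's phased VCF. Matching against the panel uses one of two semantics:

* **consistency** (default): individual *i* matches haplotype *h* iff at
  every site of *h* the called allele is carried by *i*'s diploid genotype
  (alt requires ≥ 1 alt copy, ref requires ≤ 1 alt copy). This is
  equivalent to: some assignment of one allele per site, each drawn from
  the genotype, reproduces *h* (the test suite checks this equivalence
  against brute-force enumeration). It is the right default because cohort
  callsets from short-read pipelines are typically unphased.
* **phased**: some single phased chromosome of *i* carries exactly *h*'s
  alleles, with all sites in one phase set of *i*. If *h* spans two of
  *i*'s phase sets the cross-block phase is unknown and the indicator is
  *missing* (not 0) — the information to refute a match is absent.

In both modes a missing genotype (or phase) at any site of *h* makes the
indicator missing. The two consumers of the match matrix treat missingness
differently, deliberately:

* **agreement scores** drop missing indicators from numerator and
  denominator — the score is a percentage of *confirmable* overlaps;
* the **mixture** and **contributor** likelihoods use the mean-imputed
  matrix (each missing entry replaced by its row mean over observed
  individuals), so a fully populated real-valued matrix feeds the
  probabilistic models. Rows with no observed entry are removed.

Haplotypes require ≥ 2 sites by default (`min_sites`): a single-site
"haplotype" is only a genotype observation. Identical observations within a
sample are deduplicated, since read-depth multiplicity is not modeled.
Unphased heterozygous calls are excluded from haplotype construction;
homozygous calls are phase-constant and may join an enclosing block.

## Mixture model

Retained haplotypes are treated as exchangeable draws from a mixture over
panel individuals (each individual a reference collection of size one):

    pi ~ Dirichlet(alpha, ..., alpha),  alpha = 1 (uniform prior)
    z_j | pi ~ Categorical(pi)
    likelihood of haplotype j under individual i: L_ji = M_imputed_ji + eps

A two-block Gibbs sampler alternates `z | pi` (categorical, proportional to
`pi_i L_ji`) and `pi | z` (Dirichlet(alpha + counts)), initialized at
uniform `pi`. Defaults: 2000 sweeps, burn-in 100, no thinning (J and I are
small; the full retained trace is kept). Reported proportions are
retained-trace means; the per-haplotype assignment matrix records the
retained frequency of each `z_j`; the per-individual "posterior mean of
assignment" is the column mean of that matrix.

The likelihood floor `eps = 1e-6` replaces pseudo-count allele priors: it
prevents absorbing states (a haplotype with all-zero likelihood) while
leaving rankings unchanged — the suite demonstrates rank-insensitivity
across `eps` in [1e-8, 1e-4]. `eps = 0` is allowed and used in the
conjugacy test, where assignments are deterministic and the posterior is
the closed-form Dirichlet.

Shrinkage matters for interpretation: with a uniform prior the posterior
mean of a proportion is at most `(1 + n_i) / (I + J)`, where `n_i` is the
number of haplotypes assigned to individual *i*. With J observations spread
over a large panel, even a dominant contributor's posterior mean is pulled
well below its true weight; mixing proportions should be read as a ranking
and a rough composition, not unbiased weight estimates. This ceiling also
dictated the study conditions for the recovery study below.

## Contributor likelihood

For candidate set C, each haplotype contributes
`p_h(C) = (sum of imputed match values over C) / |C|` — the *fraction of
the candidate set* carrying the haplotype — and the likelihood of C is the
product over haplotypes, accumulated in log space (the suite checks
agreement with the linear product to 1e-12 relative error above 1e-300).
The "fraction of C" reading is the only one that makes the maximum
well-defined: normalizing by the whole panel instead would make every
likelihood independent of C. Zero likelihoods are reported as exact zeros
together with the count of unexplained haplotypes, for diagnosis.

The best set of each size n = 1..n_max (default 6) is found by exhaustive
enumeration while `C(I, n)` is within a 10^6 budget, otherwise by greedy
forward beam search (width 50), flagged approximate. Ties break to the
lexicographically smallest identifier set, deterministically. The estimate
n-hat is the smallest n attaining the overall maximum; a likelihood still
strictly increasing at n_max is reported as the open bound ">= n_max".

## Synthetic study conditions

The generator emulates the features the analyses depend on and nothing
more. Founder haplotype alleles are independent Bernoulli draws with
per-site alt frequencies uniform on [0.05, 0.5]; variants sit on one contig
at 100 bp spacing in phase blocks of `block_length` consecutive sites;
pedigree children inherit one whole block haplotype per parent (Mendelian
by block, no recombination within blocks); genotype missingness is applied
per entry after the truth is stored. Soil observations draw a contributor
by weight, a chromosome copy uniformly and a block uniformly *without
replacement* (a diploid VCF carries at most two haplotypes per block, and
duplicates are removed anyway), truncate the block to a shifted-Poisson
site count (min 2, mean 4), flip each allele with probability `site_error`,
and are emitted as homozygous phased blocks under fresh phase-set ids.
Alien observations substitute uniformly random alleles.

Not modeled, hence not demonstrated by passing tests: linkage
disequilibrium beyond shared descent, realistic site-frequency spectra,
asymmetric (deamination-type) damage, read-depth multiplicity, and
population structure. Chance matching is therefore governed only by allele
frequencies and haplotype length: with ~4-site haplotypes an unrelated
individual is genotype-consistent with a given haplotype with probability
~0.4 — far higher than for long, LD-structured real haplotypes — which
makes these conditions conservative for discrimination but lenient for
error removal (see limitations).

Replicated recovery studies (each replicate re-simulates panel and sample
with a fresh seed):

* **single** (I=50, V=1000, 5-site blocks, 5% missingness, J=25, 2% error):
  the true contributor is the unique top agreement score in ~100% of
  replicates.
* **pair** (10-individual panel, equal weights, J=30, 2% error): the
  contributor MLE recovers n=2 with the true pair in roughly half to
  two-thirds of replicates; see limitations.
* **mixture** (5-candidate panel, weights 0.7/0.3, J=40, ~10-site
  haplotypes, no error): both posterior means fall within ±0.15 of truth in
  ~90% of replicates. The small panel and long haplotypes are deliberate:
  the shrinkage ceiling above is `(1 + 0.7·40)/(5 + 40) = 0.645` for the
  major contributor, so a larger panel could not reach 0.55 even with
  perfect assignment, and shorter haplotypes dilute assignments through
  chance matches.
* **relative confusion** (parent-offspring pair in the panel, soil from the
  parent): the offspring scores ~72% against ~48% for unrelated
  individuals, reproducing the known risk of close relatives ranking as
  second-best hits.

Problem sizes were chosen so each study completes in seconds while leaving
binomial noise on 50-100 replicates around a few percent.

## Numerical and degenerate-input choices

* Strict inequalities in the panel filter (missingness < 0.20, MAF > 0.01);
  an empty result warns rather than raises. The filter is idempotent.
* Multiallelic records are rejected unless `split_multiallelic` is set
  (the matching key is a single ref/alt pair); indels are ordinary alleles
  under exact string equality; gVCF non-variant blocks are skipped.
* Categorical row sampling uses cumulative sums with a single uniform per
  row; a one-individual panel short-circuits to the exact degenerate
  simplex [1.0].
* All randomness flows through `numpy.random.default_rng`; the pipeline
  fans a single run seed out to per-stage seeds by CRC32 of the stage name,
  so stages are independently reproducible and identical configs produce
  byte-identical outputs.
* Agreement ranking ties break by identifier order; mixture summaries flag
  ties explicitly.

## Known limitations

* **Error haplotypes inflate n-hat.** A per-site flip at a site where the
  source is homozygous breaks the source match (~5% of 4-site haplotypes at
  2% site error). Under these synthetic conditions such a haplotype is
  usually still genotype-consistent with some unrelated individual, so it
  survives the population-match filter and *annihilates* the product
  likelihood of every candidate set lacking that individual — pushing n-hat
  from 2 to 3 in roughly a third of pair replicates. This is a property of
  the zero-annihilating product likelihood itself; real panels with long,
  frequency-structured haplotypes shed error haplotypes at the exact-match
  filter instead. A likelihood with per-haplotype error tolerance would
  remove the failure mode but is a different model.
* Mixing proportions are shrunk toward uniform (see ceiling above) and are
  not comparable across panels of different size.
* Consistency matching cannot distinguish an individual carrying a
  haplotype from one merely genotype-compatible with it; with short
  haplotypes this inflates agreement scores of non-contributors (unrelated
  mean ~48% under the synthetic conditions).
* The pipeline trusts upstream phasing; switch errors inside a phase set
  translate directly into false haplotypes.
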