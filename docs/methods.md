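# Methods

## The model

We consider a binary trait expressed only by breeding females of a
ZW-sexed species, observed on a completely known pedigree descending from
a single founding pair. A single biallelic locus (`a`, `A`) governs the
trait under one of 64 fully specified inheritance models: the cross of

- 4 × 4 parentally ordered founder genotypes (`aa`, `aA`, `Aa`, `AA` for
  each founder; first letter maternal),
- mode of expression: dominant (affected iff carrying ≥ 1 copy of `A`) or
  recessive (affected iff carrying no `A`),
- location: autosome or Z chromosome.

Penetrance is full and phenocopies are excluded: a female's phenotype is
a deterministic function of her genotype, males never express the trait.
On the Z, females are hemizygous (the W carries no copy of the locus), so
the two homozygous female founder labels collapse to the corresponding
single-allele state while the two heterozygous labels have no realisable
hemizygous counterpart; those 16 models are retained in the enumeration
with zero prior mass, keeping the 64-model bookkeeping intact. Ordered
genotypes make `aA` and `Aa` distinct states, but no observable quantity
depends on the within-founder allele order: every likelihood is invariant
under mirroring `aA ↔ Aa` in the founder labels (enforced by a property
test), so mirror pairs are reported as an equivalence class when models
are compared.

W-linkage is handled outside the model space: a single
affected-mother/unaffected-daughter pair excludes strict W inheritance
(`w_linkage_check` lists all such pairs), which is why the space spans
autosome and Z only.

## Likelihood by sequential Monte Carlo

The likelihood of the observed phenotypes under model *M* is the sum over
all joint genotype configurations of their Mendelian prior probability
times the 0/1 compatibility indicator. The SMC estimator targets this sum
over a nested sequence of sub-pedigrees built breadth-first from the
founding pair (each level adds every individual whose parents are both
already included; lexicographic order within a level makes runs
bit-reproducible; the likelihood itself is invariant to the expansion
order).

Each particle holds a joint genotype configuration. Founder genotypes are
fixed by the model; each new individual's genotype is proposed from the
Mendelian transmission distribution given the particle's parental
genotypes (autosome: one maternal and one paternal allele uniformly; Z
son: the mother's single Z allele plus a uniform paternal draw; Z
daughter: a uniform paternal draw, hemizygous). After each *observed*
individual is proposed, incompatible particles are killed, the survival
fraction is recorded, and survivors are bootstrap-resampled back to the
full particle count. The product of survival fractions is an unbiased
estimator of the likelihood with or without resampling (`resample=never`
reduces to rejection sampling and is retained for unbiasedness tests and
for drawing independent posterior configurations on small problems).

Filtering at one observed individual at a time, rather than one
breadth-first level at a time, matters: a cohort of 40 observed females
processed as a single filtering event has a survival probability around
2⁻⁴⁰, which no feasible particle count survives, while the per-individual
conditional fractions stay well away from zero. Resampling is what makes
likelihoods of order e⁻⁴⁰ (typical here) reachable at all.

Numerical/accounting choices:

- **Default particle count** 2,000,000 for headline runs; experiments and
  tests use 10⁴–10⁵, which the oracle-agreement tests show is ample at
  their problem sizes.
- **Monte-Carlo standard error** of the log-likelihood by the
  product-of-ratios delta approximation, `sqrt(Σ (1−p_k)/(p_k N))` over
  filtering events (for `resample=never`, from the final acceptance
  fraction), cross-checked against replicate spread in the tests.
- **Zero vs depletion.** A zero survival fraction yields log-likelihood
  −∞ with the failing event index. At particle counts below 10⁴ one
  confirmation rerun at 10× particles precedes any zero report; during
  the 64-model sweep, zeros on pedigrees small enough for enumeration are
  confirmed exactly, and a contradiction triggers one 10× rerun. A
  founder-phenotype contradiction is deterministic and never rerun.
- **RNG.** One counter-based (Philox) generator keyed by the run seed;
  derived streams (per model, per permutation) come from spawned
  `SeedSequence`s. Identical inputs give bit-identical output.

`exact_likelihood` enumerates all joint configurations (state space 4 per
diploid, 2 per hemizygous individual) vectorized over a mixed-radix code
table, capped by default at 12 non-founders; it is the oracle against
which the SMC is validated, and `exact_posterior` the oracle for the
trajectory summaries. The test suite additionally carries an independent
pure-Python recursion that rebuilds transmission probabilities from first
principles, so table construction and vectorized enumeration are checked
against something that shares neither code path.

## Model selection

All models have zero free parameters, so AIC = −2 log L + 2k with shared
k; we set k = 0 and report AIC ≡ −2 log L — rankings by likelihood, AIC
and posterior coincide. Posterior model probabilities assume the uniform
1/64 prior; normalization shifts by the best log-likelihood (log-sum-exp)
because the likelihoods involved are of order e⁻⁴⁰. Relative likelihood
is `exp((AIC_best − AIC_i)/2)`.

## Allele-count trajectories

Each retained compatible configuration implies, for every calendar year,
a count of `A` copies among individuals present that year. An individual
is present in every year of `[first_year, last_year]` (the census rule;
recruits count from their hatch year) and contributes 2 alleles on an
autosome, while at a Z-linked locus males contribute 2 and females 1.
Summaries are the posterior mean and pointwise equal-tailed 50%/95%
quantile bands per year — pointwise, not simultaneous, bands; integer
quantiles are widened by at most one count where needed to contain a
fractional mean, keeping point estimate and interval consistent.

Resampling makes late-stage particles share ancestors, collapsing
early-year marginals toward few ancestral configurations. The trajectory
front-end therefore first attempts a `resample=never` pass (surviving
particles are independent posterior draws); when fewer than 500 particles
survive — the norm at realistic likelihoods — it falls back to the full
resampled particle histories and the early-year bands inherit some
degeneracy (visible as zero-width early bands).

## Permutation test

Under the non-genetic null each mature female ("mature" operationalized
as: phenotype observed in the data) expresses the trait as an i.i.d.
Bernoulli draw; the affected count is minimally sufficient, so
conditional on it all label permutations among the observed females are
equally likely. The statistic is the SMC log-likelihood under a chosen
model (the posterior-best model in practice); observed and permuted
statistics are computed at the same particle count with independent
derived streams, so their Monte-Carlo noise is exchangeable and the test
remains exact. The p-value is the plain proportion of permutations with
statistic ≥ observed (ties count as extreme); the add-one estimate
`(1+b)/(1+m)` is reported alongside, labelled. A permuted −∞ counts as
not-as-extreme. Both observed and permuted statistics get the same
one-shot 10× rerun before a zero is accepted, preserving exchangeability.
If the observed statistic is −∞ even then, the ordering is degenerate and
an error advises choosing a different statistic model — which is also why
calibration experiments mask the founding female: her genotype is fixed
by the statistic model, so a randomized label on her tests nothing but
that fixed genotype. Per-permutation particle counts default to 10⁴
(rank comparisons need far less precision than headline likelihoods);
10,000 permutations by default, configurable.

## Synthetic data generator

The forward simulator emulates the statistical structure the analysis
assumes: descent of an entire population from one founding pair, yearly
cohorts over about a decade, multi-generation inbreeding loops
(father–daughter and grandfather–granddaughter matings arise naturally
because mate choice is a weighted draw over all mature males, with
relatives admitted at weight `inbreeding_weight`, default 1.0 — no
avoidance, which is what a one-pair bottleneck enforces anyway), and
phenotype observation restricted to females that breed.

Per year, each mature female breeds with probability 0.9, takes a mate,
and produces Poisson(2.4)-distributed eggs of which each recruit with
probability 0.72; established birds survive the year with probability
0.85. These defaults were chosen once to give a plausible passerine life
history whose ten-year growth from a single pair lands near the scale of
the motivating study (final-year breeding females in the thirties), and
they stay fixed. Under `management='reposition'` the trait has no
demographic effect, so the trait allele drifts as a neutral martingale
(verified by a symmetry test over 1,000 replicates); under
`management='none'` an affected female's expected clutch is multiplied by
`fitness_factor` (default 1.12/2.02 ≈ 0.55, the observed ratio of
affected to unaffected incubated clutch sizes), acting on fecundity
rather than survival.

`make_robin_like_fixture()` pins one seed (chosen during development so
the final year holds 30–40 observed females with roughly half affected)
under the autosomal dominant `aa × Aa` truth; it is synthetic data
emulating the study's structure, not a transcription of any real
pedigree.

What the simulator does **not** emulate: age-structured fecundity and
senescence, pair fidelity across years, island subdivision, environmental
covariates, observation error in phenotype scoring, or incomplete
parentage records. Tests passing on simulated studies therefore establish
correctness of the inference machinery under the stated model, not
robustness to those real-data complications.

## Scale of the built-in experiments

The test suite validates the estimator against exhaustive enumeration on
200 random pedigrees of ≤ 10 non-founders at 10⁴ particles; calibrates
the permutation test on 200 null phenotype sets (500 permutations × 10⁴
particles each) on a fixed 26-individual pedigree; and measures model
recovery on 100 informative ten-year replicate studies (≥ 20 observed
females, ≥ 3 affected) at 2 × 10⁴ particles, where the generating model's
mirror-equivalence class ranks first in 67% of replicates — the misses
are replicates genuinely better fitted by a competing model at that study
size (likelihood gaps of several log units), an identifiability limit of
single-bottleneck data rather than estimator noise. These problem sizes
are the package's chosen experiment scale; all are configurable upward.

## Known limitations

- The model space assumes exactly one founding pair; pedigrees with
  immigrants or extra founders are rejected by design.
- Full penetrance means a single misrecorded phenotype can zero out the
  true model's likelihood; there is no phenocopy or error rate.
- The SMC proposal is the Mendelian prior; no importance-sampling
  proposals or peeling (Elston–Stewart) backends are provided.
- Likelihood-equivalence of ordered-heterozygote mirror founders means
  "the" best model is only identified up to that two-member class.
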