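# Methods

## The growth model

A CHIP clone is treated as a population of mutant hematopoietic cells whose
share of blood grows (or shrinks) deterministically and exponentially
between two draws. For a heterozygous autosomal driver mutation the VAF is
half the mutant cell fraction, so the model is written directly on VAF:

    VAF₂ = VAF₁ · (1 + CF)^T,        CF = (VAF₂ / VAF₁)^(1/T) − 1

where T is elapsed time in years and CF ("clonal fitness") is the annual
proportional growth rate: CF = 0.08 means the clone's VAF grows 8% per
year. CF is bounded below by −1 and has no upper bound. The model carries
the usual caveats: it ignores saturation (a clone approaching 100% of
hematopoiesis cannot keep growing exponentially), stochastic drift in the
stem-cell pool, and any interaction between co-resident clones. With only
two timepoints none of those are identifiable anyway; CF is exactly the
two-point summary.

`compute_growth_rate` evaluates CF in log space, `expm1(log(v₂/v₁)/T)`,
which is stable across the full usable range (a detection-floor 0.001
growing to 0.5 within a year is a ratio of 500). `project_vaf` is its
exact inverse except when the projection exceeds 1, where it clamps with a
warning; the round trip is otherwise accurate to ≲10⁻¹⁴ and is enforced at
10⁻¹⁰ in the tests.

## Calling and filtering

VAF is always recomputed as alt reads / total depth from the per-sample
AD and DP fields, never taken from caller AF tags, so calls from different
callers are comparable. Multi-allelic records are decomposed per alt
allele, each keeping the site DP as its depth.

A call is retained iff depth ≥ 100, alt reads ≥ 3, VAF ≥ 0.02, and the
site falls inside the panel (boundary values pass; "below threshold" is
what gets removed). Panel intervals are BED (0-based half-open), VCF
positions are 1-based, and the conversion lives in one function
(`vcf_pos_to_bed`). The shipped default panel covers the 22 driver genes
of the assay across ≈43 kb; its coordinates are package-supplied interval
definitions, and any BED with `contig start end gene [capture_mode]`
columns can replace it.

## Pairing timepoints: rescue and imputation

Mutation identity across draws is an exact (contig, pos, ref, alt) match —
no fuzzy matching of nearby indels, a documented limitation for unstable
indel representations. For a mutation passing filters at ≥ 1 timepoint,
the other timepoint's VAF comes from, in order:

1. its own filter-passing call;
2. any raw call at the same key with ≥ 3 alt reads, even below 2% VAF
   ("rescue") — at ~2000× depth a 0.5% clone still yields ~10 supporting
   reads, which is real evidence, and the assay resolves VAFs down to
   roughly 0.3%;
3. the imputation floor 0.001, representing a clone below the detection
   limit.

The floor makes growth rates for appearing/disappearing clones finite but
conservative: a clone observed only at draw 2 gets the fastest CF
consistent with having been undetectable at draw 1. Individuals flagged
with a disqualifying blood-cancer diagnosis are dropped before pairing
(the flag is an input, not inferred). Elapsed time prefers draw dates
(days/365.25) over age differences, which are usually coarser.

## Trajectory classes and two-clone architecture

Stagnant clones are the bottom `stagnant_fraction` (default 0.10) of the
cohort by |CF|, using the nearest-rank ceiling: exactly ⌈0.10·n⌉ clones,
ties broken by (individual, mutation key) so input order never matters.
The quantile is taken over the full cohort jointly, and the implied |CF|
cutoff is reported rather than fixed — it is a cohort-specific number, not
a constant of nature. Remaining clones are labelled by the sign of CF.

Within each class, CF values are z-scored with the sample SD (n−1);
classes of size 1 or zero spread get z = 0 so gap comparisons stay
defined. For an individual with exactly two clones: different classes ⇒
distinct clones; same class and |Δz| < 0.6 ⇒ sub-clone; |Δz| ≥ 0.6 ⇒
distinct. Two conventions here were genuinely open and are package
decisions: (a) a stagnant + non-stagnant pair counts as "different
directions" (distinct), because z-scores are only comparable within a
class; (b) individuals with ≥ 3 mutations receive trajectories but no
architecture call — the pairwise heuristic does not generalize. The
heuristic itself is a coarse proxy for phylogeny: similar growth does not
prove nesting, and the simulation-based recoverability test reports its
accuracy under favorable (strongly separated) conditions as an upper
bound, not a guarantee.

## Cohort statistics

Per-gene summaries are arithmetic means of clone-level CF; genes with
< 10 clones are reported but flagged as under-powered and excluded from
ranking. The single-mutation sensitivity analysis repeats the summary on
individuals with exactly one retained mutation, guarding against
multi-clone individuals dragging gene means.

The co-occurrence test treats each two-mutation individual as one
unordered gene pair. Under the null the two genes are independent draws
from the marginal driver-gene prevalence p, so E{g,h} = n·2·p_g·p_h
(g ≠ h) and E{g,g} = n·p_g², a proper multinomial over unordered pairs
(same-gene pairs are legal cells). χ² = Σ(O−E)²/E over cells with E > 0.
Two p-values are offered: the asymptotic χ² with (cells − 1) degrees of
freedom — prevalences are treated as known, not estimated from the pairs —
and a permutation p that resamples pairs from the prevalence distribution.
At realistic cohort sizes most expected cells are ≪ 5, where the
asymptotic reference is unreliable; the permutation p is the honest
default and the analytic value is reported for comparison.

Covariate associations fit, one covariate at a time, least squares of
clone-level CF on the covariate plus driver-gene fixed effects.
Categorical covariates enter as dummies and are summarized by a joint
Wald test. Because covariates are individual-level and nested sub-clones
have correlated growth, rows are not independent when individuals
contribute several clones; standard errors are therefore cluster-robust by
individual (with the t reference), which keeps the type-I error at the
nominal level in the null-calibration study. A `fastest_only` flag
collapses to one row per individual (the fastest clone) as a documented
alternative. Covariates with zero variance are skipped; covariates that
are an exact function of the gene labels are flagged `collinear` rather
than silently dropped. Raw p-values are reported; no multiplicity
correction is applied.

## The synthetic cohort generator

The generator produces the statistical structure the analysis assumes,
with full ground truth:

* **Mutation counts** per individual: 1/2/3+ with probabilities
  0.66/0.26/0.08.
* **Genes** drawn from a skewed prevalence (DNMT3A 0.50, TET2 0.17,
  JAK2 0.09, PPM1D 0.07, ASXL1 0.06, …), matching the field's observation
  that most CHIP lives in DNMT3A/TET2.
* **Growth**: per-clone CF ~ Normal(gene mean, gene SD) truncated > −1.
  Default means follow the gene ordering the analysis is meant to resolve
  (JAK2 1.09/yr fast, DNMT3A 0.08/yr slow, ASXL1 0.05 with a heavy
  reduction tail); the between-clone SDs are simulation settings chosen
  for testability — within-gene variance is not an empirically derived
  quantity here, and all of it is user-configurable.
* **Baseline clone size**: VAF₁ log-uniform on [0.02, 0.30]; elapsed time
  uniform over 1–12.5 years (drawn in integer days so draw dates and
  elapsed years agree exactly); age at first draw Normal(65, 15) clipped
  to [18, 95].
* **Feasibility caps**: distinct clones of one individual are rescaled so
  their total cell fraction stays < 1 at both draws; a nested sub-clone's
  cell fraction is capped at its parent's at both draws, and its CF is
  the parent's plus a small Normal(0, 0.05) increment (sub-clones ride
  inside the parent clone, so their trajectories track). Two-mutation
  individuals are nested with probability 0.54.
* **Reads**: depth ~ Poisson(mean 1725 by default; 2000 in the validation
  studies), alt ~ Binomial(depth, true VAF). Poisson depth exercises the
  depth filter; it also makes the marginal alt count exactly
  Poisson(depth·VAF), which the detection-limit analytics use.

Because of truncation and the feasibility caps, the *realized* growth rate
of a clone (recomputed from its true VAFs) can differ from the drawn
parameter — fast clones get compressed at the full-fraction ceiling. All
recovery checks therefore compare pipeline estimates against realized
ground truth (the `truth.tsv` table), which is the quantity the estimator
can in principle recover; comparing against the configured gene means
would conflate estimator error with the generator's own nonlinearity. For
the same reason the injected-covariate-effect study measures recovery of
the realized slope.

What the generator does **not** emulate — and hence what green tests do
not demonstrate about real data: sequencing artifacts and mapping error
(alt reads are exactly binomial), germline contamination, clonal
interference or drift (growth is deterministic), indel representation
ambiguity, age-dependent mutation acquisition, and any correlation between
covariates and true fitness beyond what is explicitly injected.

Fixtures are emitted as one multi-sample VCF 4.2 (samples `<IND>_T1/_T2`,
GT:DP:AD populated for carriers, missing otherwise) plus metadata and
ground-truth TSVs; identical config + seed gives byte-identical files.

## Validation study sizes

The packaged validation studies are sized to run comfortably on one CPU:
growth-model round trip at 10⁴ random triples (tolerance 10⁻¹⁰);
classifier and filter fidelity against brute-force rule restatements at
10³ random cohorts and 10⁴ random calls; parameter recovery on one
500-individual cohort at 2000× (acceptance bound: every well-powered
gene's mean CF within 3 SE of realized truth); detection-limit Monte
Carlo at 10⁵ draws against the exact binomial/Poisson tails; and null
calibration of the covariate model over 200 cohorts of 60 individuals
(type-I error within the binomial 95% interval around 0.05).

## Known limitations

* Two timepoints identify a single exponential rate; acceleration,
  saturation and non-monotone trajectories are invisible.
* The 0.001 imputation floor makes appearing/disappearing clones'
  rates sensitive to that constant near the detection limit.
* The sub-clone/distinct heuristic is not a phylogenetic reconstruction;
  its accuracy is bounded by how well growth similarity proxies nesting.
* Exact-key mutation matching may split indels represented differently
  across draws.
* The stagnant class is a cohort-relative quantile: the same clone can be
  stagnant in one cohort and expanding in another.
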