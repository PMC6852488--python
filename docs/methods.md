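# Methods

This note documents the models and procedures implemented in `seedweb`,
the assumptions behind them, and the numerical and design choices that a
re-implementer would need to know.

## From rearing records to a quantitative web

A *sample* is one collection event: seeds/fruits of one plant species on
one day at one site. Emergences are tied to samples; dissection of every
seed at the end of rearing yields a per-sample count of seeds with
evidence of attack. Three per-plant responses are derived: incidence
(any seed predator reared), richness (number of seed-predator species
reared) and predation rate (predated / dissected seeds). Both mature and
immature material counts toward seed totals, matching a design in which
many predators attack pre-dispersal seeds.

Detection is effort-limited, so species with ≥ 200 seeds collected are
flagged *well-sampled* and analyses sensitive to effort are restricted
to them. `detection_curve` makes the underlying claim checkable: a
logistic regression of incidence on log10(seeds) should show a positive
slope overall and no detectable slope within the well-sampled subset.

Link weights are seeds killed per m² of seed rain:

    alpha_ik = density_i * attacked_ik / sampled_i

with `density_i` from the trap network (seeds observed / trap area) and
`attacked_ik` the number of sampled seeds of plant *i* attributed to
predator *k*.

**Attribution rule.** The per-association quantity actually estimable
from rearing is insects emerged per attacked seed. When one plant hosts
several predator species, the dissection counts do not say which
predator attacked which seed. Predated seeds are therefore apportioned
among a plant's predators in proportion to reared-individual counts
(at a provisional brood size of one insect per seed), and the
emergence-per-attacked-seed ratio is then re-estimated per association.
Single-predator plants are exact; multi-predator plants inherit a shared
ratio. When insects emerged but dissection scored no seed as predated
(the dissection protocol is deliberately conservative), the ratio falls
back to 1.0 and the attacked-seed count is imputed as the individual
count, flagged in the output. The synthetic generator enforces at most
one predator species per seed, which makes this attribution rule exact
on synthetic data — deliberately, so that attribution error becomes
measurable the moment the gregarious-brood option is switched on.

**Exclusions.** Plants never seen in the traps have no density and are
excluded; Hymenoptera are always excluded (per-seed emergence counts are
not reliable for them); plants flagged as multi-seeded-fruit systems
(one larva destroys an unknown number of tiny seeds) and plants lacking
seeds-per-fruit metadata are excluded. Every removal is logged with a
reason so the exclusion accounting of any run is reproducible from its
log. The flag for multi-seeded-fruit systems is an explicit metadata
column, not inferred from the data, because the condition is a
natural-history fact about taxa, not a statistical property.

Canonical ordering of the web (rows and columns by descending marginal
totals, ties alphabetical) makes outputs order-independent and
deterministic.

## Specialisation indices

d′ and H2′ standardise Kullback–Leibler/Shannon statistics between the
minimum and maximum attainable under fixed marginal totals. For consumer
*k* with column proportions p′ and availability q (row totals over the
grand total), d = Σ p′ ln(p′/q); H2 is the entropy of the whole table.
Both null models are defined on integer event counts, so real-valued
webs are first scaled to an integer grand total (by default the number
of reared individuals behind the web; 10 000 when nothing better is
known) with largest-remainder rounding that preserves the grand total
and keeps every observed link positive.

The extrema are computed **exactly** when the table is small enough:
for H2 a dynamic programme over rows with the remaining column totals as
state (the entropy objective is cell-separable, so partial sums
compose), for d a bounded enumeration of capped integer allocations.
The exact path covers every table whose DP state space fits a fixed
budget (~2·10⁶ states) — far beyond the 4×4 regime where the behaviour
is pinned against an independent exhaustive-enumeration oracle in the
tests. Larger tables fall back to the conventional heuristics: greedy
largest-marginal pairing for minimum entropy, proportional fill with
largest-remainder rounding for maximum entropy, and rarest-first greedy
filling (capped by row totals) for d_max. Ties break by canonical
species order; 0·ln 0 ≡ 0 throughout; results are clamped to [0, 1].
Degenerate cases: a single-cell web, or marginals admitting only one
table, return H2′ = 1 by convention; a consumer whose extrema coincide
returns d′ = 0 (no room to deviate).

One behaviour worth knowing: a monophage on an *abundant* host scores
d′ < 1, because the standardisation maximum reallocates its
interactions to the rarest hosts. Median d′ therefore stays below 1
even in a fully monophagous community — this is the index working as
designed, not an artefact.

Chao1 treats each distinct plant×predator association as a "species"
with abundance equal to reared individuals (abundance-based
frequencies; an incidence-based variant using the number of samples is
available). The bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) is the
default so the estimate stays finite with no doubletons; the classic
F1²/(2F2) form is an option. Coverage = S_obs / S_est.

The Coleoptera-vs-Lepidoptera d′ comparison uses the two-sided
Mann–Whitney/Wilcoxon rank-sum test; because the statistic's value
depends on which sample is "first", both conventions (W_first,
W_second = n₁n₂ − W_first) are reported.

## Potential for apparent competition

d_ij = Σ_k (α_ik/Σ_l α_il)(α_jk/Σ_m α_mk) is the probability that a
randomly chosen predator attacking plant *i* developed on plant *j*:
the first factor is predator *k*'s share of *i*'s predator load, the
second is host *j*'s share of *k*'s production. Rows sum to one by
construction, the matrix is invariant to rescaling all weights, and it
is asymmetric — ordered pairs are the unit everywhere (141 plants give
141·140 = 19 740 ordered pairs). Exceedance uses strict inequality
(d_ij > 0.1), diagonal entries are excluded from all summaries, and the
Spearman correlation with patristic distance drops PAC = 0 pairs. Its
p-value uses the standard t approximation and treats pairs as
independent; the pairwise non-independence of distance data is
unmodelled, exactly as in the analysis tradition this follows.

## Phylogenetic signal

**Fritz–Purvis D.** The observed statistic d_obs is the sum of
sister-clade differences with node values formed by successive
equal-weight averaging from the tips down (polytomies are resolved
arbitrarily with zero-length edges first). D scales d_obs between the
mean of tip-label shuffles (D = 1) and the mean under a Brownian
threshold model (D = 0): unit-rate Brownian motion simulated on the
tree, thresholded so the number of 1-tips matches the observed
prevalence. P(D < 1) is the fraction of shuffles with d ≤ d_obs;
P(D > 0) the fraction of Brownian sets with d ≥ d_obs. Defaults:
1000 permutations of each null.

**Blomberg's K.** With C the Brownian covariance of the (pruned) tree,
the phylogenetic mean is â = (1ᵀC⁻¹x)/(1ᵀC⁻¹1) and

    K = (MSE0/MSE) / [(tr C − n/(1ᵀC⁻¹1)) / (n − 1)],

MSE0 the ordinary mean squared deviation from â and
MSE = (x−â)ᵀC⁻¹(x−â)/(n−1). K = 1 in expectation under Brownian
evolution; the implementation reproduces picante's `Kcalc` to seven
decimals on fixed fixtures. The p-value is the fraction of tip-shuffled
arrangements (observed included) with MSE ≤ observed, 999 shuffles by
default. A singular C (zero-length cherries) gets one 10⁻⁸ diagonal
regularisation attempt before erroring.

**Grafting.** Species missing from the tree but with a congener present
are attached at the midpoint of the edge subtending the genus MRCA (a
single congener's terminal edge is bisected), with pendant length
chosen so the new tip's depth equals the congeners' mean depth —
ultrametric trees stay ultrametric and all pre-existing pairwise
distances are untouched. Species with no congener are dropped from
signal analyses with a logged count.

Both statistics are vectorised over an array encoding of the tree
(postorder child indices), making the 200-replicate calibration suites
run in seconds.

## Trait models

The forest is a bootstrap ensemble of depth-unconstrained randomised
decision trees (feature subsets of ⌈√p⌉ for classification, ⌈p/3⌉ for
regression, minimum leaf 5, 500 trees), evaluated strictly out-of-bag:
each species is predicted only by trees that did not see it, by
averaged class probabilities (classification) or averaged predictions
(regression). Missing trait values are median/mode-imputed with a
missingness-indicator column per incomplete trait, so "unmeasured" is
itself available to split on. Importance of a trait is the mean change
in OOB accuracy (or OOB squared error) when its values are permuted;
indicator-column importances are folded into their base trait. The
conditional-inference machinery of the party tradition
(permutation-test split selection, unbiased under mixed measurement
scales) is intentionally not re-implemented; the contract here is a
standard randomised-tree ensemble, which is sufficient for the
question the statistics answer — whether traits carry predictive signal
at all.

κ = (Accuracy − Baseline)/(1 − Baseline) with Baseline the
majority-class proportion (no-information rate) by default; the classic
marginal-product Cohen baseline is an option. A point worth recording:
on pure-noise data the majority baseline makes κ slightly *negative* in
expectation (≈ −0.1 at n = 200) because bagged trees' OOB accuracy dips
below the no-information rate — a property shared by standard
random-forest implementations, verified against scikit-learn's
`oob_score_`. The marginal baseline centres exactly on zero under
independence, and the calibration tests pin both behaviours.
Pseudo-R² = 1 − SS_res/SS_tot on OOB predictions; it is negative when
the model predicts worse than the mean, which is the expected outcome
on trait tables carrying no signal.

The main analysis runs on well-sampled species only; a parallel run
uses all species with total seed count appended as a predictor, as a
check that any apparent trait effect is not an artefact of effort.

## The synthetic-community generator

The generator draws, in order: a Yule (pure-birth) phylogeny scaled to
unit depth, with genera induced by cutting the tree at depth 0.8;
lognormal seed densities (log-mean 1.0, log-sd 1.5, seeds/m²) — rank
order of density also drives sampling effort and trap detection, so
"rare" is a single coherent notion; 13 plant traits with Brownian
structure on the tree plus noise (two categorical ones by threshold),
~15% missing cells; predators with host-range size 1 with probability
s = 0.75, otherwise zero-truncated geometric (p = 0.5) capped at 7 —
mean latent diet richness ≈ 1.25; extra hosts congeneric with
probability c = 0.375, uniform otherwise; per-link per-seed attack
probabilities Beta(1, 9) (mean 0.1, a realistic seed-predation scale).

Sampling: each species targets 200 seeds split into ~25-seed samples;
the rarest quarter (by density rank) has effort scaled down to as
little as 5%, so rare species are genuinely under-sampled and rare
interactions are censored. Each seed is attacked independently by each
linked predator; simultaneous strikes are resolved uniformly so at most
one predator develops per seed (the ground-truth kill probabilities
account for this competition exactly, by subset enumeration per plant).
Emergences are attacked seeds × brood size thinned by rearing success
(both default 1); dissection scores attacked seeds as predated with
probability 1 (a conservative-scoring option lowers it). Traps:
negative-binomial counts with mean density × 100 m²; the rarest 25% of
species are truncated to zero (reared but never trapped), ~6% lack
seeds-per-fruit metadata and ~4.5% are flagged as multi-seeded-fruit
systems, exercising all three exclusion rules downstream.

Defaults are the study-design scale: 478 plants, 369 predators with
orders drawn 60/30/10% Coleoptera/Lepidoptera/Hymenoptera. Under these
defaults the assembled web sits reliably in the regime the method was
built to detect: H2′ > 0.9, over 60% monophagy among predators with
≥ 10 individuals, and PAC exceedance well under 1% of ordered pairs.

**What the generator does not emulate** — and hence what passing tests
do not demonstrate about field data: no spatial structure (seed shadows,
trap placement), no fruiting phenology (temporal traits are static
covariates), no misidentification or morphospecies lumping, trait
effects on attack default to zero, and the one-predator-per-seed rule
is exact rather than approximate. Chao1 coverage on synthetic defaults
(~0.95) is accordingly higher than typical field values: the simulated
sampling is cleaner than reality.

## Reproducibility and problem sizes

Every stochastic routine takes a seed; the pipeline derives per-stage
seeds by hashing (top-level seed, stage name), so stages are
reproducible in isolation. Reports are byte-identical across repeated
runs. Test-suite simulation sizes are chosen to make distributional
assertions stable at small cost: signal calibration uses 200 replicate
64-tip trees with 150–200 permutations per statistic; the end-to-end
regime check runs 50 full-scale replicates; enumeration oracles cover
webs up to 4×4 with marginals ≤ 6, where exhaustive search is exact and
fast. The acceptance script runs one full-scale pipeline (≈ 1 minute on
one core).

## Known limitations

- The multi-predator attribution rule is proportional, not
  identifiability-correct; with gregarious broods it biases
  emergence-per-attacked-seed ratios (measurably, via the generator's
  brood-size option).
- Heuristic entropy extrema on large webs are not guaranteed optimal;
  d′/H2′ on large webs inherit the same approximation the published
  index implementations use.
- PAC quantifies *potential*, not realised, apparent competition; no
  dynamics are modelled.
- The trait ensemble is not split-selection-unbiased under mixed
  measurement scales; importance comparisons between continuous and
  many-level categorical traits should be read cautiously.
- Spearman p-values for PAC-vs-distance treat plant pairs as
  independent observations.
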