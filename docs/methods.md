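# Methods

This note documents the models implemented in `linkqa`, the defaults and
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the design decisions taken where the methodology
leaves room.

## Linkage model

### Comparison

Each configured identifier is compared per candidate pair to one of three
levels: **agree**, **disagree**, or **missing** (either side absent).
String identifiers may use a Jaro–Winkler comparator (standard definition:
matching window `max(|s1|,|s2|)/2 − 1`, transposition count halved, prefix
bonus up to 4 characters at scale 0.1), binarized at a per-comparator
cut-off (default 0.88, which accepts e.g. SMITH/SMYTH at 0.8933). Graded,
multi-level agreement weights are deliberately out of scope: binarization
keeps the m/u model two-parameter per identifier and the weights
interpretable.

Candidate pairs come from **blocking**: the union of pairs agreeing on at
least one blocking key, deduplicated. Records missing a blocking key value
cannot agree on it. With no keys the full cross product is generated (with
a warning); this is intended only for small gold-standard evaluations.

### Deterministic cascades

A rule cascade is an ordered list of steps, each a set of identifiers that
must all agree. A pair links at the first satisfied step and carries that
step index as its **match rank** (1 = most stringent), mirroring stepwise
algorithms used for national hospital data (unique number first, then
combinations of date of birth, sex and postcode). Pair outputs always
retain the rank or weight and the agreement-pattern string (e.g. `AA?D`),
because downstream audits need them.

### Fellegi–Sunter weights and EM

The probabilistic model is a two-class latent mixture over agreement
patterns under **conditional independence** of identifiers given true match
status — the standard assumption, violated in practice by correlated
identifiers (household members share surname *and* postcode); this is a
documented limitation, and one reason the synthetic generator plants
exactly that correlation.

Weights use **base-2 logarithms** (any base works; 2 is conventional and
makes a weight of 15 an odds ratio of 2^15). A missing comparison
contributes **zero** weight — the neutral choice; alternatives (imputing
agreement probabilities for missingness patterns) are out of scope.

EM estimation: the E-step computes each pair's match responsibility; the
M-step re-estimates per-identifier `m`, `u` over non-missing comparisons
and the mixture proportion π. Defaults: initialization `m = 0.9`,
`u` = empirical agreement rate (capped at 0.85), `π = 10/√n_pairs`;
tolerance 1e-6 on the largest parameter change; at most 500 iterations;
non-convergence is flagged in diagnostics, not fatal. Parameters are
clamped to [1e-6, 1−1e-6], and any identifier that converges to `u ≥ m`
(possible when blocking forces near-universal agreement) is clamped to
`u = m − 1e-6` with a warning, so weights never invert sign. If label
switching occurs the classes are swapped so the high-agreement class is
the match class. The observed-data log-likelihood is recorded per
iteration; monotonicity is a tested invariant.

Estimating the model on *blocked* candidate pairs means `u` is estimated
relative to the blocked non-match population, not the full cross product —
appropriate for classifying those same candidates, but not a
population-level collision rate.

### Classification and resolution

Two thresholds classify weights: `w ≥ upper` → link, `w < lower` →
non-link, otherwise **possible** (retained for review or imputation;
`lower = upper` gives a binary rule). The default single threshold is the
weight at which the posterior match probability under the fitted model is
0.5, i.e. `log2(1/prior_odds)`.

One-to-one resolution is **greedy** by descending weight with a
deterministic tie-break (lexicographic row keys); displaced candidates are
demoted to possible, never silently dropped. Greedy rather than optimal
assignment is a deliberate choice: transparent, deterministic, and within a
factor of two of the optimum in total weight (in tests it is compared
against exhaustive enumeration on small instances). Multiplicity violations
(links beyond the structure's maximum) are counted before resolution —
under 1:1 or many:1 matching each such excess link implies at least one
false match.

## Linkage structures

Analyses declare one of three set relationships between cohort and linked
file, because the meaning of an unlinked record depends on it:

- **Master** (cohort linked to a disease/death register): unlinked means
  *negative class*. Missed matches are false negatives.
- **Nested** (every cohort record should have a match, e.g. birth
  registrations): unlinked means *missing data*.
- **Intersection** (unknown subset should link): unlinked means *excluded
  from the analysis sample*; a missed-match count is not interpretable and
  is suppressed in reports.

This declaration drives which error-estimation methods apply and, most
consequentially, the no-match branch of prior-informed imputation (below).

## Error estimation

The pair universe for gold-standard evaluation defaults to the **full cross
product** of the gold subset's records, not the blocked candidate set —
otherwise missed matches excluded by blocking would be invisible. Truth
must cover the whole universe; partial truth raises rather than silently
ignoring pairs. One accounting subtlety is inherited from the standard 2×2:
each pair is classified exactly once, so a false match does not additionally
count the implied missed match of the correct partner; reports note this.

All proportions carry **Clopper–Pearson exact** 95% intervals — audit
contexts favour conservative coverage over shorter Wald/Wilson intervals.
Zero denominators yield explicitly undefined metrics, never silent NaN.

Implausibility triage (events after death, sex-specific procedure codes,
excess multiplicity) yields a **minimum** false-match count — the union of
rule-flagged pairs and excess links — which is a lower bound by
construction; more false matches may exist unflagged. Standardized
differences in linked-vs-unlinked comparisons use the difference in means
over the pooled SD (pooled proportion variance for binary indicators) with
the conventional 0.1 annotation, descriptive only. Identifier validity is
checked by per-field validators supplied in config; a modulus-11 NHS-number
check digit validator is built in. The external-marginals comparison
requires the user to supply reference marginals (nothing is downloaded) and
is labelled descriptive: a chi-square-style divergence with per-category
contributions.

## Quantitative bias analysis

Classification sensitivity and specificity are estimated from **positive
and negative control subsets** (records known to have / not to have a true
match). PPV and NPV are deliberately not computable from these objects:
control subsets are not representative samples, so the 2×2 rows cannot be
summed.

Proportions are corrected by the **Rogan–Gladen estimator**
`p_true = (p_obs + Sp − 1)/(Se + Sp − 1)`, the exact inverse of the forward
misclassification model `p_obs = Se·p_true + (1−Sp)(1−p_true)`, defined
when Se + Sp > 1 (an uninformative classifier raises). Corrections outside
[0,1] are truncated **and flagged** — silent clipping would hide exactly
the extreme scenarios QBA exists to surface. Intervals propagate the
binomial uncertainty of (p_obs, Se, Sp), treated as independent, by the
delta method; components without counts contribute no variance. A risk
ratio is corrected group by group; shared (nondifferential) accuracy
attenuates the observed RR towards 1 — algebraically,
`(a·p1 + b)/(a·p0 + b) < p1/p0` whenever `b = 1−Sp > 0` — and the
correction removes the attenuation exactly. Subgroup-specific accuracies,
when available, generally give a different (better) correction.

Scenario sweeps operate on **aggregate tables**: at each grid point,
`n_missed` truly-positive records are added back and
`n_false × (1 − p_false_comparable)` misclassifying false matches removed
(`p_false_comparable` is the proportion of false matches landing on records
that happen to share the analysis-variable value, which cause no
misclassification). Errors are allocated between groups at every corner
allocation; because the estimand is monotone in each group's corrected
count, corners attain the extremes, so this equals exhaustive reallocation
(verified against enumeration in tests). Impossible cell counts are skipped
with a warning. Record-level sweeps and probabilistic (Monte-Carlo) bias
analysis with priors over (Se, Sp) are out of scope.

## Imputation of link-derived variables

Records are partitioned by certainty: exactly one candidate at or above the
upper threshold → **certain link**; no candidate above the lower threshold
→ **certain non-link**; anything else — including two candidates both above
the upper threshold — is **uncertain**, retaining all candidates above the
lower threshold (ambiguity overrides the threshold).

The **match prior** gives candidate *j* unnormalized mass
`prior_odds × 2^(w_j)` and the no-match branch mass 1, normalized to sum to
one. This is the canonical Bayes reading of a base-2 log-likelihood-ratio
weight: posterior odds = prior odds × likelihood ratio. The methodology
literature describes the prior only as "a direct function of the match
weights" without fixing the function; this choice is therefore a documented
interpretation, as is the relative mass of the no-match branch.
`prior_odds` defaults to 1 in the worked structure and should in practice
be set to (expected matches)/(candidate pairs) from the linkage run.
Normalization is done in log2 space so extreme weights cannot overflow.

The imputation model is a logistic (binary) or linear (continuous)
regression of the link-derived variable on user-named covariates, fitted on
the certain records: certain links contribute their resolved value, and
certain non-links contribute the negative class under a Master structure
(unlinked = disease-free) or are themselves imputed under a Nested
structure (unlinked = missing). Intersection structures are rejected:
their non-links define exclusion, not a value. Proper MI draws model
parameters from the asymptotic normal posterior per imputation (and the
residual variance from its scaled inverse-chi-square for linear models); a
perfectly separated or degenerate logistic fit falls back to an
intercept-only model with a warning. Prior-informed imputation currently
supports binary variables; the posterior over {candidate values} ∪
{no match} multiplies prior mass by the model likelihood of each value
given the covariates, with the no-match branch contributing the negative
class (Master) or the model predictive (Nested).

Reproducibility: default `M = 20` imputations; the RNG uses substreams
indexed by (seed, record) so results are bit-reproducible under fixed
(seed, M) and independent of unrelated records.

**Rubin's rules**: pooled estimate Q̄ = mean of per-imputation estimates;
within-variance W̄ = mean of per-imputation variances; between-variance B =
sample variance of estimates; total T = W̄ + (1 + 1/M)·B; degrees of
freedom (M−1)(1 + W̄/((1+1/M)B))², infinite when B = 0.

## Synthetic-data generator

The generator emulates the error mechanisms that drive linkage error in
administrative data:

- **Population structure**: households (shared surname and postcode; sizes
  from a configurable distribution, default P(1,2,3,4) = .30/.35/.20/.15)
  and twin pairs (Binomial(n, twin_rate) of them; shared surname, date of
  birth, sex and postcode, differing only in forename) — the canonical
  sources of false matches. Surnames and forenames come from fixed built-in
  lexicons (222 surnames, 104 forenames) with Zipf (1/rank) frequencies so
  that name collisions occur at realistic rates and u-probabilities are
  non-trivial. Each person carries a valid modulus-11 10-digit unique
  number, a date of birth uniform over 1940–2005, sex, a household
  "AANN NAA"-shaped postcode token, a subgroup label and a binary outcome
  with per-subgroup probability.
- **Corruption**: per field, a single categorical draw selects one of
  missing / typo (single-character substitution, insertion or deletion:
  edit distance exactly 1) / transposition (dates only: day↔month swap when
  both ≤ 12 and distinct, else a one-day shift — the "31 December 1999 vs
  1 January 2000" class of error) / update (a genuine change over time:
  the postcode redraw models a house move) / intact. One draw per field
  makes each marginal rate exactly nominal and guarantees at most one
  event per field. Fields are processed in schema order from one explicit
  RNG stream, so derivations are bit-reproducible.
- **Observation**: each person is captured with probability `coverage` and
  emits 1 + Geometric(duplication_rate) records (registry duplication).
- **Differential quality**: a per-subgroup multiplier scales all corruption
  rates (rates are renormalized with a warning if the multiplied sum
  exceeds 1). This is the simplest mechanism that produces a non-random
  distribution of linkage errors across subgroups.
- **Control subsets**: positive controls are cohort records whose person
  has a register record by construction; negative controls are those whose
  person is absent from the register.

What it does **not** emulate: real name/address corpora and their phonetic
error structure, temporal event streams (at most one update per field),
correlated missingness across fields, aliases and nicknames, and
multi-person identifier recycling. Passing tests on this generator
therefore demonstrate correctness of the machinery and the direction and
rough magnitude of the statistical effects, not performance on any real
national dataset.

Default corruption rates in the convenience constructor (typo 2%,
missingness 5%, postcode update 10%) are fixtures chosen as plausible for
administrative data; the methodology literature reports no canonical
values.

## Validation studies and problem sizes

`linkqa.studies` packages the validation experiments run by the test suite
and `scripts/acceptance.py`:

- EM recovery: 50,000 pairs from (m = 0.95, u = 0.10, π = 0.01) with five
  identifiers sharing one (m, u); the recovered common parameter is the
  mean of per-identifier estimates (≈500 expected matches give a
  per-identifier SE of ~0.01, so individual estimates scatter accordingly
  while the common-parameter estimate is accurate to well under 0.02).
- Gold-standard linkage: 5,000 persons, two files at the default corruption
  rates, EM-weighted linkage, 500-person gold subsets, 20 seeds; subset
  interval coverage of the truth-based full-universe sensitivity and
  specificity.
- Risk-ratio attenuation: 200 replicates of two-group binomial draws
  (n = 10,000/group, true RR 4.0) pushed through the forward
  misclassification model at (Se 0.884, Sp 0.997); attenuation holds in
  every replicate by the algebraic argument above, and the corrected RR is
  unbiased.
- Differential imputation: 800-person nested cohorts, minority subgroup
  with 3× corruption and a 4× outcome rate, fixed weight model, M = 10,
  50 replicates; prior-informed pooling versus certain-links-only
  prevalence.
- The five-record worked structure (two certain links, one certain
  non-link, candidates with weights 15 and 2) at M = 10,000 against the
  closed-form posterior.

These sizes keep the full suite at about two minutes on one core while
leaving each Monte-Carlo margin several standard errors wide.

## Known limitations

- Conditional independence in the FS model; no multi-level agreement.
- Greedy (not optimal) one-to-one assignment.
- `u` estimated on blocked candidates, not the full cross product.
- Prior-informed imputation: binary variables only; single link-derived
  variable; no congeniality diagnostics; the no-match mass convention is an
  interpretation (documented above).
- Manual-review workflows are supported only to the point of exporting
  flag-sorted candidate lists; the human judgement itself is out of scope,
  as are machine-learning classifiers and privacy-preserving (hashed)
  linkage.
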