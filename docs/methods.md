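# Methods

## Scope and data model

`groomstats` analyzes dyadic social behavior of a closed group of adult
females observed by continuous focal sampling (timed directed events:
approach, displacement, groom, aggression) and instantaneous scan sampling
(focal's spatial state with one partner: contact, proximity,
co-provisioning). All inputs and outputs are plain CSV/JSON; seasons are
opaque labels; within-session times are seconds from session start, which
keeps the 20-second grooming-termination rule exact.

## Dominance statistics

Displacements are tallied into a wins matrix per season. The dyadic
dominance index corrected for chance is

    D_ij = P_ij − (P_ij − 1/2) / (n_ij + 1),    P_ij = wins_ij / n_ij,

which shrinks sparsely observed dyads toward 1/2. Unobserved dyads are
assigned `D_ij = 1/2` ("no information"): this keeps David's scores defined
when some relationships are unknown, as they usually are in field matrices.
David's scores use the standard weighted form `DS = w + w2 − l − l2` and
`NDS = (DS + N(N−1)/2)/N`, a cardinal value in `[0, N−1]` with mean
`(N−1)/2`. Downstream, *rank distance* between two individuals is the
absolute NDS difference (cardinal), not the difference of ordinal positions.

**Steepness** is the absolute OLS slope of NDS against positions `1..N`
after a descending sort. Its randomization test keeps each dyad's
interaction count and redraws wins as `Binomial(n_ij, 1/2)`; the one-tailed
p-value is the fraction of null matrices at least as steep as observed.

**Linearity**: Landau's `h = 12/(N³−N) · Σ(V_i − (N−1)/2)²` with `V_i` the
number of group-mates individual *i* dominates; "dominates" is a strict win
majority. Reported `h` gives undecided dyads (ties and unknowns) half
credit. The improved index `h′` is the Monte-Carlo mean of `h` over fair
random resolutions of undecided dyads; its p-value compares `h′` against
fully random dominance structures. With `n_randomizations=0` both tests are
skipped (p-values `None`) and `h′` uses the closed-form expectation
`h + 6(u+t)/(N³−N)` — each undecided dyad contributes variance 1/4 to two
`V_i` terms. Defaults are 10,000 randomizations and right-tailed p-values;
identical seeds give identical p-values.

The directional consistency index is `Σ(H−L)/Σ(H+L)` over dyads with at
least one interaction.

## Affiliation measures

Grooming segments of one directed pair in one session are merged into
*acts* when the pause between them is under 20 s; a pause of 20 s or more
terminates the act. Act duration sums active segments only (pauses are not
grooming). Directed grooming rate (acts/h) and time (min/h) divide by the
**sum of both individuals' focal hours** in that season: an A→B interaction
is observable whenever either member is the focal animal. The reverse
applies to aggression: the (A, B) row of the model table carries the rate
of aggression **B→A** — what the groomer receives from the groomee.

Scan states convert to time as count × scan interval, summing both focal
perspectives of a dyad (our documented choice; with equal focal effort this
doubles counts symmetrically and cancels out of the friendship index).
Co-provisioning is a percentage of all scans in which either member was
focal — a sampling-level reading of "percent of time", flagged as an
interpretation. The friendship index of A toward B divides A's contact time
with B by A's mean contact time with all other females, zero-contact
partners included in the mean; rows with no contact at all get zeros and a
warning. Contact is the default basis (it is the most intimate spatial
measure and the least confounded with grooming itself); proximity,
approach and grooming bases are selectable, and Spearman correlations
between the four are available.

## Dyadic mixed model

The model table has one row per ordered pair per season. The response —
grooming rate or grooming time — is log-transformed with offset
`log(x + c)`; by default `c` is half the smallest positive observed value
of that response and is always recorded in the fit. Nine fixed effects
enter: age difference; kinship (reference *kin*, so the reported
coefficient is for non-kin); rank distance; relative rank of the groomer
(reference *dominant*); friendship; grooming received (the raw
reverse-direction measure, per the reciprocity hypothesis); co-provisioning
percentage; aggression received; season (reference season 1). Groomer and
groomee identities are crossed random intercepts, encoded as two variance
components over a single grouping constant and fitted by REML through
statsmodels' MixedLM. Constant predictor columns (e.g. the season dummy on
single-season data, or kinship in a subset containing no kin) are dropped
with a note; collinearity among non-constant terms raises an error naming
the aliased terms.

Confidence intervals are Wald, `b ± 1.96·SE` exactly — closed-form and
library-independent. Profile or bootstrap intervals are typically slightly
wider; we do not attempt to match them. Whole-model significance is a
likelihood-ratio test against the intercept-plus-random-effects null; both
models are refitted by ML for that comparison because REML likelihoods are
not comparable across fixed-effect structures. A term is flagged
significant when its CI excludes zero. Effect sizes translate to percent
changes as `(exp(b·δ) − 1)·100` (δ = 1 for most predictors, 0.1 for the
received-grooming and received-aggression rates, whose natural increments
are small).

`fit_lmm(random_effects=False)` pins both variance components at 1e-10 (an
exact zero makes the solver's covariance factorization singular); in this
degenerate limit the estimator coincides with OLS to ~1e-9, which the test
suite verifies against an independent OLS fit.

The rank-distance split partitions rows at the pooled two-season mean rank
distance: strictly above → high subset, at or below → low subset; each
subset is refitted with the same specification. Per-season thresholds are
available via the library by passing a subset table.

## Synthetic data generator

The generator emulates a troop of 17 adult females in 6 matrilines
(4+3+3+3+2+2), observed for 15.5 focal hours per female per season in
30-minute sessions with 2-minute scans, over two seasons — with the focal
budget met exactly (31 sessions tile 15.5 h). Within each matriline the
oldest female is the mother of the rest, so every within-matriline pair is
maternal kin. The latent rank order lists matrilines in blocks, the
nepotistic pattern of real macaque hierarchies; a consequence worth knowing
is that kin are close in rank, so the high-rank-distance subset can contain
no kin dyads at all (the kinship term is then dropped).

Dyadic affinity is symmetric log-normal with a kin boost
(`log a = 1·kin + N(0, 0.8²)` symmetrized); the latent friendship index is
its row normalization. Directed grooming A→B is a homogeneous Poisson
process whose log-rate is

    β0 + β_kin·kin + β_sub·1[A subordinate] + β_friend·F(A,B)
       + d(A,B) + actor(A) + receiver(B),

with `d` symmetric across the two directions — reciprocity arises through
this shared dyadic effect rather than an explicit lagged dependence,
because the analysis model treats reciprocity only as a covariate. Events
are generated during the focal time of either dyad member, so a dyad's
exposure equals the sum of both members' focal hours, matching the
denominator used downstream. Acts of the same directed pair within one
session are placed in disjoint sub-slots at least 21 s apart, so the 20 s
rule never merges distinct simulated acts. Displacements occur per dyad at
0.12/dyad-hour and run down the latent hierarchy with probability 0.98;
aggression and approaches scale with the friendship index; scans put the
focal in a social state 30% of the time, split contact/proximity/
co-provisioning 0.5/0.4/0.1, with the partner drawn proportionally to
affinity and at most one partner-state per scan (contact is defined to
exclude other concurrent behaviors).

Defaults were calibrated to published troop-level magnitudes *before* any
recovery test was run: mean directed grooming rate ≈ 0.17 acts per combined
hour (β0 = −2.66 after accounting for the mean fixed effects and the
log-normal variance inflation), bout mean 4.6 min (≈ 0.8 grooming minutes
per hour), displacement density ≈ 3.7 interactions per dyad-season, random
effect SDs 0.3/0.3/0.2 (dyad/actor/receiver). One RNG stream per behavior
module, seeded from the master seed by fixed offsets, keeps existing draws
stable when behaviors are added; identical configurations and seeds give
byte-identical logs.

### What the generator does and does not emulate

It reproduces the observation design, event-rate magnitudes, kin structure
and a near-linear hierarchy. It does **not** emulate within-day temporal
structure (event times are uniform within sessions — no downstream
statistic uses within-session timing except the 20 s rule), male behavior,
seasonality of rates beyond the season label, observation heterogeneity
across dyads (displacement exposure is homogeneous, so simulated matrices
have fewer unknown dyads and higher h′ than typical field matrices), or
zero-inflation beyond what the Poisson process produces. Passing tests
therefore demonstrate the correctness of the statistical machinery under a
known homogeneous sampling design, not the field realism of any particular
coefficient value.

### Known limitation: attenuation of the friendship coefficient

The pipeline measures friendship from contact scans. At the emulated design
each female contributes ~465 scans per season, of which ~15% are contact,
spread over 16 partners — about 29 contact scans per dyad-season after
symmetrization. The measured index then correlates ~0.93 with the latent
one, and the resulting errors-in-variables attenuation (amplified by
covariates that proxy the same latent affinity: kinship and grooming
received) biases the fitted friendship coefficient downward by roughly a
third (e.g. ≈ 0.23–0.29 for a generating value of 0.4). Signs are recovered
essentially always, but 95% CIs for the friendship coefficient rarely cover
the latent value; coverage for the relative-rank coefficient, whose
predictor is measured almost without error, is nominal. No realistic scan
density under a 2-minute protocol removes this: it is a property of the
design being emulated, not of the estimator.

## Numerical conventions

- Randomization tests: right-tailed, default 10,000 replicates, explicit
  seeds; fewer than 100 replicates warns, negative counts error, zero
  skips.
- Rank ties: broken lexicographically by id and flagged.
- Unknown dyads: `D_ij = 1/2`; excluded from DCI; randomized in `h′`.
- Problem sizes in the test suite are scaled to the emulated study
  (17 females, 2 seasons) for end-to-end checks and smaller groups
  (6–10 females) for unit-level checks.
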