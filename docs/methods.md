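# Methods

## Data model

The unit of observation is a *visit*: patient id, professional id (may
be missing), calendar date, municipality code, occupation title and
group, service-type code and group, ICD-10 and ICPC-2 diagnosis codes,
a home-care flag and the patient's age in years at the visit.  Tables
are delimited text (UTF-8, comma, ISO-8601 dates by default; dialect
configurable).  Rows violating the field grammars — unparseable date,
malformed code (ICD-10 must match `^[A-Z][0-9]{2}`, ICPC-2
`^[A-Z][0-9]{2}$`), empty or duplicate identifiers — go to a rejects
sidecar with their line numbers rather than being silently dropped, so
record counts reconcile across processing phases.

## Cohort selection

A visit is MH/SU-related if any of three criteria holds (a disjunction):

1. an ICD-10 F-chapter code outside the exclusion ranges — default
   F00–F03 (dementia), F70–F79 (intellectual disability), F80–F83
   (specific developmental/speech disorders), F84+ retained;
2. an ICPC-2 P-chapter code outside the exclusion set — default P24,
   P70, P85;
3. a mental-health/substance-use service-type code.

The exclusions are named diagnostic categories; the code ranges
realising them are configuration, since category boundaries are not
universal.  "Adult" is age ≥ 18 at the visit by default (a strict >18
switch exists).  Age is taken as provided per visit; birth-date
arithmetic is out of scope.

The cascade applies, in a fixed and reported order: S1 study window,
S2 adult age, S3 MH/SU patient selection (a qualifying patient keeps
*all* their service visits; visit-level selection is a config switch),
S4 home-care visits out, S5 uninformative ("other/unspecified") and
occupational-health service codes out, S6 visits without a professional
id or occupation group out, S7 single-visit patients out, S8
single-professional patients out.  Because S4–S6 can strip a patient of
their only qualifying visit or reduce them to a single visit, S3/S7/S8
are iterated to a fixed point (extra passes appear as report rows).
This makes the cascade idempotent — re-filtering its own output is a
no-op — which a single left-to-right pass would not guarantee.  The
stage order itself is a frozen convention; the counts it yields are
what the audit table reports.

Each professional is then assigned exactly one municipality, occupation
group and 3-level service group (outpatient / MH-SU / other) by the
majority of their visits, each attribute independently.  Ties go to the
value of the professional's chronologically first visit among the tied
values, then lexicographically — any deterministic rule would do; this
one is stable under row permutation.

## Networks

The bipartite graph has one tie per observed (patient, professional)
pair, weighted by visit count.  The unipartite projection connects two
professionals iff they share ≥ 1 patient, weighted by the number of
distinct shared patients; isolated professionals remain as nodes.  No
transitive closure occurs: the adjacency equals the off-diagonal
support of B·Bᵀ, which the tests verify against an explicit
incidence-matrix product.

Municipality sub-networks are built from the visits *located in* that
municipality, not from the post-assignment unique attributes, so a
professional practising in two municipalities appears in both
sub-networks; the stricter reading (both of a shared patient's visits
inside the municipality) is used for sub-network edges.  The
sensitivity variant keeps, per patient, only visits within `window_days`
(default 90 ≙ "3 months") of that patient's first visit; the
uninformative-patient filters must be re-applied before projection, and
the drivers do so.

Metrics: mean degree 2E/N; density 2E/(N(N−1)); mean distance = mean
geodesic edge count over pairs in the same component (cross-component
pairs excluded; geodesic length, not intermediary count, since observed
values ≈ 2 at densities ≈ 0.5 are only consistent with path length);
transitivity = 3·triangles / connected triples.  Undefined metrics
(empty node set, no connected pair, no triple) raise a signal and are
recorded as missing, never zero.  Shortest paths use a compiled BFS;
the test oracles re-derive them with pure-Python BFS and O(N³) triple
enumeration.

## ERGM estimation

With edges, nodefactor and nodematch terms only, the ERGM
P(Y=y) ∝ exp(θᵀg(y)) factorises over dyads: the tie probability of a
dyad is logistic(θᵀx) with x its change-statistic vector (edges → 1;
nodefactor at level ℓ → number of endpoints at ℓ, reference level
omitted, K−1 columns per K-level attribute; nodematch → endpoint
agreement indicator).  MPLE therefore coincides with exact ML and no
MCMC is involved; the fit is deterministic.

The design aggregates the N(N−1)/2 dyads by distinct change-statistic
pattern (at most a few hundred patterns even at N≈1600, making the fit
O(patterns) per iteration).  Estimation is Newton/IRLS on the grouped
Bernoulli log-likelihood with deviance-based step halving, stopping at
relative log-likelihood change < 1e-10 or 50 iterations.  Wald standard
errors come from the inverse observed information; odds ratios are
exp(θ) with 95% CIs exp(θ ± 1.96·se) (CI level fixed to match the
reporting convention).  Degenerate inputs: an empty or complete network
is rejected; a rank-deficient design raises an error naming the
collinear terms (checked on the k×k Gram matrix so deficiency is caught
even with fewer patterns than columns); coefficients diverging beyond
|θ| > 15 are flagged as separation and reported as ±∞ sentinels with a
warning.

BIC = −2·loglik + k·ln(D) with D the dyad count — the pseudo-likelihood
sample size.  This convention reproduces the published null-model BIC
exactly from N and E alone, which supports it as the convention of the
original toolchain; across-model BIC *ordering* is the quantity treated
as reproducible on synthetic data.  The cumulative sequence is: model 1
edges; model 2 + municipality nodefactor/nodematch; model 3 +
occupation; model 4 + service type.  Reference levels default to the
largest category of each attribute (the dominant municipality,
physicians, outpatient services in both the emulated and synthetic
settings) and are user-settable.

## Synthetic data

Two generators, deliberately independent so parameter recovery is not
circular:

**Register simulator.**  Defaults emulate the study conditions: 7
municipalities with patient weights 576/1114/1241/570/253/6977/155 and
professional weights 103/220/180/66/40/1162/32 (one dominant centre),
1566 professionals, 8500 patients, occupation mix 25.8% physicians /
61.9% nurses / 12.3% other, service mix 58.6% outpatient / 5.3% MH-SU /
36.1% other.  Visit counts per patient are zero-truncated negative
binomial (mean 16, shape 0.8 — heavy-tailed; the register's true
distribution is unpublished, so only its mean and skew are emulated).
Each visit picks a professional with revisit persistence 0.65 (a new
draw favours the patient's home municipality with probability 0.9), and
MH/SU patients (85%) are steered to MH/SU-service professionals with
probability 0.12 and receive qualifying F-/P-codes with per-visit
probabilities 0.35/0.15 (at least one qualifying visit is guaranteed).
Within-pool choice is weighted 1.6/1.0/0.75 by occupation so physicians
act as hubs.  The persistence, preference, affinity and hub weights
were set once so that the emergent network reproduces the published
network's qualitative structure — order-of-magnitude edge count at the
published N, strong municipality homophily, physician hub effect,
positive MH/SU service main effect — not its exact cell values, which
are not a generator target.  Configurable fractions of rows exercise
every filter stage: 2% minor patients, 1% missing professional ids, 1%
home care, 1% uninformative service codes, 0.5% occupational health,
0.2% out-of-window dates; the injected counts are echoed in the ground
truth for reconciliation.  All rows are grammar-valid; parser rejects
are exercised by hand-written fixtures instead.  What the simulator
does *not* emulate: seasonality and weekday structure, referral chains,
professional turnover, multi-title professionals' visit-level title
changes, and any real-register marginal beyond the above — so passing
end-to-end tests demonstrates pipeline correctness under realistic
scale and structure, not epidemiological fidelity.

**Dyadic ERGM sampler.**  Draws each dyad independently with
probability logistic(θᵀx) — exact for dyad-independent models; −∞
coefficients are honoured as hard zeros.  Used for the recovery study
(N=300, 200 replicates, θ = (−2.0 edges, −0.3 nodefactor, 0.5
nodematch)): bias ≲ 0.002, coverage 0.95–0.96.

All randomness flows through one `numpy.random.Generator` seeded from
the mandatory config seed; replicate seeds are drawn below 2³¹.

## Problem sizes in tests and drivers

The acceptance-style tests run the full default register (~148k visits,
1566 professionals) once through the complete chain, the recovery study
at N=300 × 200 replicates, and the homophily-monotonicity comparison
(same-municipality preference 0.95 vs 0.5) on 20 paired seeds at a
reduced register scale (2000 patients, 250 professionals, mean 6
visits) — sizes chosen as the smallest at which the respective effects
are unambiguous.

## Known limitations

- The pipeline is in-memory and targets registers up to a few hundred
  thousand visits and a few thousand professionals; dyad enumeration is
  O(N²) in memory before aggregation.
- Only dyad-independent ERGM terms are supported (no triangles, GWESP,
  degree terms, MCMC-ML, valued ties) — by design, since the analysis
  this pipeline reproduces uses none.
- Centrality measures and graph drawing are out of scope.
- The occupation-title → group mapping is data (a lookup), not a
  classifier; free-text titles must be pre-coded.
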