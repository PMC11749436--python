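# psnet — patient-sharing networks from primary-care visit registers

`psnet` reconstructs, as a tested and reusable pipeline, a register-based
analysis of collaboration among primary-care professionals who treat
patients with mental-health or substance-use (MH/SU) problems.  Starting
from visit-level records (one row per patient–professional contact), it

1. **selects the cohort**: adult patients with at least one MH/SU visit,
   identified by ICD-10 F-codes (excluding dementia, intellectual
   disability and specific developmental/speech disorders), ICPC-2
   P-codes (excluding the analogous categories), or an MH/SU service-type
   code; then removes home-care visits, uninformative and
   occupational-health service codes, visits without an identifiable
   professional, and patients whose visits cannot inform patient sharing
   (a single visit, or every visit to one professional) — with a
   per-stage audit of visit/patient/professional counts;
2. **builds the network**: the bipartite patient–professional graph is
   projected to a unipartite *patient-sharing network* in which two
   professionals are adjacent iff at least one patient visited both
   (edge weight = number of distinct shared patients).  Equivalently,
   the adjacency is the off-diagonal support of B·Bᵀ for the incidence
   matrix B;
3. **describes each municipality's sub-network**: edges, mean degree
   2E/N, density 2E/(N(N−1)), mean geodesic distance, global
   transitivity 3·triangles/triples;
4. **models tie formation** with dyad-independent exponential random
   graph models, P(Y=y) ∝ exp(θᵀg(y)), using `edges`, `nodefactor`
   (main effect of municipality / occupation group / service type,
   reference level omitted) and `nodematch` (homophily) statistics.
   Because all terms are dyad-independent, the model factorises over
   the N(N−1)/2 dyads and maximum pseudo-likelihood — grouped logistic
   regression of tie indicators on change statistics — *is* the exact
   maximum likelihood.  Models are compared by BIC with the dyad count
   as sample size.

Because the source register is not public, the package ships a
mechanistic register simulator (municipality sizes, occupation and
service mixes, heavy-tailed visit counts, within-municipality care
preference, revisit persistence) and an exact dyadic ERGM sampler, both
fully seeded, so every stage is testable against known ground truth.

Audience: health-services researchers and methodologists working with
administrative visit data who want an auditable, deterministic
patient-sharing/ERGM pipeline in Python.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
synthetic register (about two minutes in total); the same steps are
available as a CLI (`psnet all --seed 1 --out-dir run`) and as library
calls.  With the default configuration and seed 1:

```text
$ python analysis/01_simulate_register.py --seed 1
simulated 148369 visits for 8500 patients and 1566 professionals (seed 1)

$ python analysis/02_filter_cohort.py
stage  description                                visits  patients professionals
S0     input                                      148369      8500          1566
S1     within study window                        148055      8499          1566
S2     adult patients                             145746      8344          1566
S3     patients with a MH/SU visit                132798      7371          1566
...
S8+1   fixed-point pass 1                         124996      6104          1566

$ python analysis/03_build_networks.py
full network: 1566 professionals, 198893 edges, density 0.162,
mean distance 1.84, transitivity 0.34
90-day window variant: 1563 professionals, 24858 edges (12% of full)

$ python analysis/05_fit_ergms.py   # abbreviated
                        model_1              model_4
edges                   0.19 (0.19 to 0.19)  0.01 (0.01 to 0.01)
nodematch.municipality                       32.98 (32.34 to 33.63)
nodefactor.occupation_group.physician        1.73 (1.71 to 1.74)
BIC                     1086889.04           831139.69
best model by BIC: model 4
```

Reading the output: the per-stage table audits every exclusion (counts
can only decrease; the fixed-point pass re-checks patients whose
qualifying or companion visits were removed mid-cascade).  In the ERGM
table, an odds ratio above 1 means the term makes a tie between two
professionals more likely: here ties concentrate strongly within
municipalities (nodematch OR ≈ 33 under a 0.9 same-municipality visit
preference), physicians are better connected than nurses (nodefactor
physician OR 1.73 with nurses as implicit baseline), and BIC improves at
every step of the cumulative model sequence.  `analysis/06_parameter_
recovery.py` checks the estimator against the exact dyadic sampler:
at N=300 with 200 replicates the maximum absolute bias is 0.0016 and
95%-CI coverage is 0.95–0.96 per term.  Summary tables land in
`results/`.

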