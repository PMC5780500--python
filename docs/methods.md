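# Methods

## Colonisation model

The model is a deterministic, discrete-time (annual), female-only,
age-structured recursion for a nesting area that starts empty at year 0.
Sporadic colonisers contribute a constant stream of clutches (`Pr` per
year, one clutch per coloniser per event, no `Cy` factor); females hatched
locally imprint on the new beach, recruit `Ma` years later with
hatch-to-maturity survival `Sm`, and then breed every year for `Tr + 1`
seasons (their recruitment year plus `Tr` more) with annual adult survival
`Sa`.  The nesting population `N(t)` is the survival-discounted sum of the
last `Tr + 1` recruitment cohorts.  Within a year the update order is
R → N → Fp → F, so recruits breed in their recruitment year.  All state is
zero before year 0.

Assumptions worth making explicit: reproductive parameters are
density-independent (an optional hard ceiling on `N` is provided as a
crude stand-in, motivated by observed rookery sizes of roughly 20–687
females); years and cohorts are continuous-valued (fractional females), so
the model describes expectations, not demographic stochasticity; a seeded
stochastic mode (Poisson clutch counts, binomial survival) is available as
an extension for sensitivity analysis.  Without a ceiling the recursion is
linear, so every trajectory scales exactly with `Pr` and long-run growth
approaches the dominant eigenvalue of the associated linear recurrence
(the test suite checks this against a companion-matrix power iteration,
and checks the recursion itself against an independent cohort-bookkeeping
oracle and against the `Cy = 0` closed form
`N∞ = Sm·Fc·(1 − Sa^(Tr+1))/(1 − Sa)`).

### Parameters and defaults

| symbol | meaning | default | unit |
|---|---|---|---|
| Pr | propagule pressure (sporadic clutches arriving) | scenario | clutches/yr |
| En | eggs per nest | 112 | eggs |
| Cy | clutches per resident female per year | 3 | clutches |
| Sm | survival hatch → maturity | 0.005 | proportion |
| Ma | age at maturity | 24 | yr |
| Sa | annual adult survival | 0.809 | proportion |
| Tr | reproductive period | 29 | yr |
| Of, Es | % female, emergence success | from grid | proportion |

`Ma = 24` is the Mediterranean-origin maturation value (Atlantic-origin
animals mature around 29; the parameter is configurable).  `Tr = 29` is
the midpoint of the published 23–35-year range.  Percentages (`Sm = 0.5%`,
`Sa = 80.9%`, `Of`, `Es`) are converted to proportions once at ingestion
and all internal computation uses proportions; percentages appear only at
file/CLI boundaries.

The temperature grid (28, 29.1, 29.3, 29.5, 31, 33 °C) is interpolated
piecewise-linearly — the published scenarios evaluate only the six nodes,
so interpolation is a convenience that is exact at the nodes.  Below the
coldest row `Of` is forced to 0 (no females below the pivotal
temperature; the grid's 28 °C row and the ~28.3 °C pivotal statement
differ slightly, so the grid governs node values and the clamp governs
everything colder).  Queries above 33 °C clamp to the hottest row with a
warning.  Scenario horizons of 1,000 years and an establishment threshold
of 20 females are the package's standard reporting choices.

## Parentage reconstruction

`detect_multiple_paternity` applies the parental-allele-count rule: with
an unknown mother, more than four distinct alleles at a locus across the
clutch cannot come from two parents; with a known mother, more than two
distinct non-maternal alleles exceed one father.

`min_fathers` performs an exhaustive search.  Maternal candidates at each
locus are all allele pairs (homozygotes included) over the alleles
observed in the clutch that share at least one allele with every typed
offspring; a mother carrying an allele never observed in any offspring is
constraint-equivalent to a homozygote for her observed allele, so this
enumeration covers all equivalence classes.  For each multilocus maternal
candidate, every offspring's feasible paternal-allele set per locus is
derived, and offspring are partitioned among `k = 1, 2, …` fathers
(canonical ordering: an offspring may open father *g* only after *g − 1*
exists).  A group is feasible at a locus when some single allele pair hits
every member's paternal set; feasibility is maintained incrementally as
the intersection of feasible father pairs, so dead branches are pruned
immediately.  The smallest feasible `k` is returned with every optimal
(mother, partition) solution; the count is a lower bound on the true sire
number by construction.  Reported father genotypes are representative —
the lexicographically smallest compatible pair per locus — rather than an
enumeration of all completions, which is unbounded under rare-allele
completion.  When allele frequencies are supplied, solutions are ranked by
the summed log Hardy–Weinberg probability of the parental genotypes.

Numerical guardrails: loci typed in fewer than 50% of offspring are
excluded (logged); missing loci are handled pairwise; the search is capped
by `max_fathers` (default 4), a node budget (default 500,000; exceeding it
returns a result flagged non-exhaustive) and a solution cap (default
1,000).  Genotyping error and mutation are not modelled.  Clutches with
fewer than three offspring are analysed but flagged low-power.

## Relatedness

The pairwise estimator is Lynch & Ritland (1999), computed per locus from
reference allele frequencies, combined across loci with the estimator's
sampling-variance weights, and averaged over the two reciprocal
reference/proband orderings.  Values are reported on the *doubled* scale
used by GenAlEx-style software, spanning −1..1, on which unrelated pairs
centre on 0 and full sibs on 0.5 (Monte-Carlo checks in the test suite:
full-sib mean 0.5 ± 0.05, unrelated |mean| < 0.05 over 400–500 simulated
pairs); the half-scale raw value is stored alongside.  Estimates outside
[−1, 1] (possible for the estimator at rare-allele configurations) are
clamped with a log entry.  Reference loci that are monomorphic, or where
the reference individual is homozygous for a (near-)fixed allele, carry no
information and are skipped.  By default frequencies are pooled from all
analysed samples; any external frequency table can be supplied instead.

## Origin assignment

The supervised two-population assignment is a closed-form no-admixture
model: per population, the genotype log-likelihood is the sum over typed
loci of log Hardy–Weinberg genotype probabilities (p² homozygote, 2pq
heterozygote) under that population's allele frequencies; the posterior
combines the two likelihoods with a prior (default 0.5).  Frequencies are
Laplace-smoothed (pseudocount 1 per allele over the dataset-wide allele
set per locus) and leave-one-out is applied when the query belongs to the
baseline.  This is the deterministic analogue of supervised two-cluster
MCMC assignment with prior population labels; it was chosen over an MCMC
implementation because the use case is exactly two labelled source
populations, for which the closed form is standard, fully reproducible
and fast.  It is a documented methodological simplification: per-nest
probabilities produced by external MCMC software on the real baseline are
not expected to be reproduced numerically.

A call is *reliable* only when the larger posterior strictly exceeds 0.8
(a posterior of exactly 0.8 is Unknown).  Clutch-level categories follow
the reliability rule: a reliable mean offspring posterior names the
origin; otherwise parentage solutions are partitioned by the maternal
origin call, and a partition whose fathers reliably assign to the other
basin yields Mixed (parents of different origin); anything else is
Unknown.  Up to 100 candidate parents are assigned per clutch by default.

Haplotype matching is exact: equality, or query-substring-of-reference
(reported with a short-fragment flag, since a ~380 bp fragment cannot
separate long-haplotype variants), on either strand; a query contained in
several references is ambiguous and all candidates are listed.  No
edit-distance search is attempted.  The packaged FASTA contains *synthetic
stand-in* sequences for the six named haplotypes — the real control-region
sequences live in public accessions recorded in the sidecar table — so
sequence-level tests use constructed fixtures, and only the
name/origin-class metadata is meaningful.

## Synthetic data

`simulate_baseline` draws, per locus, ancestral frequencies from a
symmetric Dirichlet(1) and population frequencies from the
Balding–Nichols distribution (Dirichlet with parameters `p(1 − F)/F`),
then samples individuals in Hardy–Weinberg proportions within population.
Defaults mirror the reference baseline: 112 Mediterranean + 56 Atlantic
individuals, 7 loci, 8 alleles per locus (a stated assumption —
microsatellite allele counts of the real markers are not published — and
configurable), target F_ST 0.029.  The multi-allele Weir–Cockerham θ
estimator (variance components combined ratio-of-sums over alleles and
loci) verifies the calibration: the multilocus estimate averages within
0.01 of the target over 24 seeds, and a hand-computed two-population toy
table is frozen in the tests.  `simulate_clutch` performs Mendelian
segregation with a recorded sire per offspring; `simulate_nest_dataset`
writes a complete bundle whose clutch sizes, father counts and origins
mirror the observed 18-clutch record (121 samples, including one sampled
nesting female).

What the generator does *not* emulate: mutation and genotyping error,
linkage between loci, null alleles, allele-size homoplasy, within-
population structure or inbreeding, and realistic microsatellite frequency
spectra (Dirichlet-flat ancestral spectra are more even than typical
microsatellites).  Passing tests therefore demonstrate correctness of the
algorithms under the stated statistical model, not robustness to those
real-data complications; the missing-data injection path (configurable
rate) exercises pairwise-deletion handling only.

## Problem sizes and determinism

Standard analyses run in seconds: 1,000-year horizons for trajectories and
sweeps, 24-seed calibration batches, 400–500-pair Monte-Carlo relatedness
checks, father-count recovery over 60–90 simulated clutches of 12
offspring.  Every stochastic routine takes an explicit seed or
`numpy.random.Generator`; identical seeds give byte-identical outputs, and
derived seeds are kept below 2³¹.

## Known limitations

* The colonisation model has no spatial structure, no environmental
  stochasticity, no genetic feedback on demography, and treats `Of`/`Es`
  as fixed per scenario rather than varying among years.
* `min_fathers` assumes a single mother per clutch and error-free
  genotypes; a clutch that violates single-mother Mendelian consistency is
  reported as such rather than resolved.
* The assignment model ignores admixed ancestry: an F1 hybrid tends to
  receive an intermediate, unreliable posterior rather than an admixture
  proportion — at the default F_ST ≈ 0.029 a substantial unassignable
  fraction is expected and observed.
* Fig-style sweep outputs are qualitative reproductions: exact published
  plotting choices (maturation/reproductive-period point values within
  their ranges, horizon) are not stated, so curves are compared by shape
  and ordering, never read off numerically.
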