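# Methods

## Cohort definition

The analysis unit is one **baseline record per inpatient**: the earliest
admission of each patient (date ties broken by the lexicographically
smallest record id, for determinism). Diagnosis codes of any precision
are truncated to their 3-character ICD-10 category; several codes
collapsing to one category count once, because the disease category per
inpatient is the unit of analysis. Codes outside Chapters 1–14 are
removed; a record whose codes all fall in Chapters 15–22 (obstetric,
perinatal, congenital, symptom, injury, external-cause, contact,
special-purpose) is excluded. The record-level filter order is:
normalize → chapter-scope filter → baseline selection → age filter
(40–59 inclusive) → stratification. Selecting the baseline after the
chapter filter means a patient whose first-ever admission carried only
out-of-scope codes is represented by their first in-scope admission; the
alternative (baseline first, then exclusion) would drop such patients
entirely. Both readings are defensible; the implemented order keeps more
patients and is applied uniformly. Age bands (40–44, 45–49, 50–54,
55–59) are inclusive on both ends and partition the cohort exactly.

The chapter map is hard-coded from the standard ICD-10 letter/number
ranges (A00–B99 → 1, C00–D48 → 2, D50–D89 → 3, E00–E90 → 4, F → 5,
G → 6, H00–H59 → 7, H60–H95 → 8, I → 9, J → 10, K00–K93 → 11, L → 12,
M → 13, N → 14, O → 15, P → 16, Q → 17, R → 18, S/T → 19, V–Y → 20,
Z → 21, U → 22). Strings in classification gaps (e.g. D49) are treated
as unparseable and tallied, not guessed.

## Association estimation

For a disease pair the logistic regression of one indicator on the other
has closed-form maximum-likelihood solution: the coefficient is
log(a·d/(b·c)) and its Wald standard error sqrt(1/a+1/b+1/c+1/d). The
implementation computes these directly (a stratum scores tens of
thousands of pairs; fitting an iterative model per pair buys nothing),
and the test suite verifies agreement with an explicit statsmodels
logistic fit to 1e-6 relative on the odds ratio. p-values are two-sided
Wald tests; the Wald choice (over likelihood-ratio) is the conventional
logistic-output p-value. No covariates enter the model: stratification
by sex and age band is the confounding control. No continuity
correction is applied — a pair with a zero off-diagonal cell has a
non-finite odds ratio and can never become an edge, and a pair with
a = 0 has OR = 0 and fails the OR > 1 criterion anyway.

**Candidate universe and Bonferroni N.** Candidates are all unordered
pairs of diseases observed in the stratum with a finite odds ratio. N
counts candidates with OR > 1, *per stratum*: every network carries its
own N (reported in its provenance block), since each stratum is its own
family of hypotheses. All three criteria use strict inequalities
(OR > 1, p < 0.05/N, prevalence > 1/10 000); the prevalence denominator
is the stratum's inpatient count.

**Known limitation — sparse cells.** For pairs whose expected
co-occurrence count is small (roughly a ≲ 20) the Wald p-value is
anti-conservative: a pair with a = 8 expected 1.4 can show Wald
p ≈ 6e-7 where the exact tail probability is ≈ 1e-4. The prevalence
floor removes the rarest patterns but not this whole regime, so in
cohorts with many very rare diseases the realized family-wise error can
exceed the nominal Bonferroni level. An exact or mid-p test would fix
this at the cost of departing from standard logistic output; the package
keeps the conventional Wald test and documents the caveat.

## Network levels and hubs

Pattern identity is the unordered code pair only — the set algebra of
sex-specific (difference) and sex-overlapped (intersection) networks
ignores the per-sex statistics, which are retained side-by-side for
inspection. Derived networks keep only nodes incident to surviving
edges, so "k patterns across m diseases" reads directly off the object;
complete networks keep every observed disease including isolated ones.
The decomposition identity |complete| = |specific| + |overlapped| holds
by construction and is asserted on every pipeline run.

Hubs are the top-10 nodes by degree among nodes with degree > 0. No tie
rule is standard for the cut, so the package fixes one: descending
degree, then descending maximal clique centrality, then ascending code.
k = 10 is the default and configurable.

All seven node metrics are computed on the unweighted simple graph
(odds ratios serve as display attributes only). Conventions for
disconnected graphs, fixed for determinism: closeness is the
within-component value scaled by (component size − 1)/(n − 1);
betweenness is the raw (unnormalized) count of shortest-path fractions,
so only connected pairs contribute and a path's midpoint scores 1.0;
eigenvector centrality is the principal eigenvector of the largest
component's adjacency matrix (dense symmetric eigendecomposition),
zeros elsewhere, normalized to maximum 1; PageRank uses damping 0.85
over the whole graph and sums to 1. Maximal clique centrality of node v
is Σ over maximal cliques C containing v of (|C|−1)!; an isolated node's
singleton clique gives MCC = 1, though degree-0 nodes never become hubs.
Degree, closeness, betweenness, clustering and MCC are validated against
brute-force oracles (BFS path counting, exhaustive subset enumeration)
on random graphs of ≤ 12 nodes.

## Chapter attribution

A cross-chapter pattern's frequency is credited to **both** endpoint
chapters in full; a within-chapter pattern is credited once. This makes
"chapter-k-associated patterns" mean every pattern with a chapter-k
endpoint, at the price that chapter percentages (taken against the
network's total pattern frequency) can sum past 100% — they are reported
as-is. A half-credit mode (cross-chapter edges split 50/50) is available
behind a switch. Chapter ranks break percentage ties by ascending
chapter number; in age-band trajectories a chapter absent from a band is
recorded as missing, never as the bottom rank.

## Synthetic cohorts

The generator exists because the real inpatient data underlying this
kind of analysis are access-controlled. Per stratum it samples each
planted pair exactly from the 2×2 joint with the pair's marginals and
target odds ratio — the Plackett construction: p11 solves
ψ(p_x−p11)(p_y−p11) = p11(1−p_x−p_y+p11), taking the root in the
Fréchet interval, so the cells' cross-product ratio equals ψ
identically. Planted pairs are disease-disjoint (this is what makes the
exact joint sampling possible); all other diseases are independent
Bernoulli draws, so every non-planted pair is a true null. Records that
come out empty are redrawn, since ingest rejects empty code sets; the
redraw count is recorded in the ground-truth manifest because the
conditioning biases marginals slightly upward (negligible below ~1%
empty-row probability, which all shipped configurations satisfy). Ages
are uniform within the band and admission dates constant — baseline
selection is exercised by dedicated multi-admission fixtures, not the
generator.

Three shipped configurations define the study conditions:

* **study_config** — eight sex × age strata with record counts
  proportional to a middle-aged Chinese inpatient cohort (default scale
  0.1 ≈ 18 400 records), 260 diseases across Chapters 1–14 with
  log-uniform marginals 0.002–0.03, and 18 planted pairs (8 shared, 5
  male-only, 5 female-only; odds ratios 2–8) whose diseases get
  marginals 0.03–0.10.
* **recovery_config** — one 50 000-record stratum, 30 planted pairs with
  odds ratios cycling 2/4/8, 200 background diseases; *all* marginals
  drawn in 0.03–0.10 so every pair sits in the regime where the Wald
  test is well calibrated (see the sparse-cell caveat above).
* **decomposition_config** — one male and one female stratum of 25 000
  records, 8 shared + 5 male-only + 5 female-only pairs with odds
  ratios 4 and 8: strong, structural effects, because the question is
  which derived network a pattern lands in, not dose-response.

What the generator does **not** emulate: the disjoint-pair design caps
node degree, so synthetic networks have no genuine hub structure (real
cohorts have diseases like hypertension touching dozens of partners);
disease counts per record are near-Poisson, giving a much higher
multimorbidity fraction (~90%+) than real admission data, where single-
diagnosis records dominate; and there is no confounding structure, so
the unadjusted odds ratio is the estimand by construction. Passing
recovery tests therefore demonstrates correctness of the estimation and
selection machinery under the generative model, not robustness to the
messiness of real claims data.

## Validation benchmarks and problem sizes

The seeded benchmarks run the full generate → ingest → build path. The
recovery benchmark (20 runs at n = 50 000) checks per run that ≥ 90% of
planted OR ≥ 4 pairs are recovered and that the largest absolute log-OR
error over recovered pairs stays ≤ 0.25 (≈ 2σ of the sampling error at
the smallest planted marginals), and across runs that at most one false
background edge appears in ≥ 19 of 20 runs. The decomposition benchmark
checks that every male-only planted pair lands in the male-specific
network and none in the overlapped network, and every shared pair in the
overlapped network. Problem sizes (50 000 / 25 000 records, 230–260
diseases, 20 seeds) are chosen so the whole suite completes in a few
minutes on one core while keeping binomial sampling error well inside
the asserted tolerances; the pairwise tabulation is a single boolean
matrix cross-product, so larger cohorts scale linearly in records.
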