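# Methods

## Qualitative-network semantics

A qualitative network (QN) is a finite discrete dynamical system.  Each
variable holds an integer level in a bounded range — throughout the
packaged model {0, 1, 2}, read as inactive / healthy-intermediate /
overactive — and owns a target function over the levels of its regulators.
Updates are **synchronous** and **unit-step**: at each tick every unclamped
variable moves one level toward its evaluated target (staying put if it is
already there), and all variables read the same input state.  Clamped
variables are frozen; a mutation is a clamp (loss of function at the
range minimum, constitutive activation at the maximum).

Numerical conventions, fixed because they change attractors:

* target functions evaluate in exact rational arithmetic; fractional
  values (the n-ary `avg` can produce them) are rounded **half-up**,
  `floor(x + 1/2)`, then clipped to the variable's range;
* a variable without an explicit target uses
  `avg(activator levels) − avg(inhibitor levels)`, with an empty set
  contributing 0.  Note the consequence: a variable with only inhibitors
  can never exceed 0 at a fixpoint — a pair of mutual inhibitors with
  default targets has the single fixpoint (0, 0), not a toggle (memory in
  these networks requires explicit positive feedback, which is the point);
* cycles are stored starting from their lexicographically smallest state,
  so attractor equality is well defined;
* asynchronous update schemes and continuous/ODE refinements are out of
  scope by design.

Simulation from a given state must revisit a state within (state-space
size + 1) steps, which is the default step bound.  Global fixpoint
enumeration is available two ways: brute force over the state space
(guarded by a configurable bound, default 10^7), and a
constraint-propagation solver that iteratively prunes each variable's
domain (a level survives only if some in-domain assignment of its
regulators maps to it) and splits the smallest open domain, verifying
candidate solutions exactly.  The two strategies provably enumerate the
same set and are cross-checked on random networks in the test-suite.

## The MPN network

The packaged model (`data/mpn_model.json`, 19 variables, 28 signed edges)
is the single source of truth; `build_mpn_network()` loads it and
self-validates against the packaged specification table
(`data/table1.tsv`).  The wild-type state is all-ones — the model assumes
intermediate activity for every component, including HOXA9, in health.

The switch core is `T_HOXA9 = clip(STAT5 + TET2 + HOXA9 − 2)`, the
minimal function with the required memory: with STAT5 tracking JAK2, the
four genotype outcomes are healthy (1) in the wild type, 0 after TET2
loss, 2 after JAK2 activation, and in the double mutant whichever extreme
the *first* mutation selected.  Because the target degenerates to
`T_HOXA9 = HOXA9` whenever STAT5 + TET2 = 2, raw fixpoint enumeration of
the wild type (and of the double mutant) contains a line of fixpoints
with HOXA9 ∈ {0, 1, 2}.  These are not hidden: enumeration reports them.
Disease states are instead defined by **sequential-acquisition
reachability** — stabilise the wild type from all-ones, clamp the first
mutation, re-stabilise from where the system was, clamp the second, and
so on.  This is both the biologically meaningful notion (a clone acquires
mutations one at a time from its current state) and what makes order
matter.

Target functions for the remaining nodes are constrained by the
specification table and the qualitative statements the model encodes
(RUNX1 tracks the HOXA9 memory; RUNX1 drives the SPI1/GATA1 pair, which
jointly inhibit MYB; erythroid output follows KLF1/GATA1 with a
JAK2/STAT5 drive; GMP expansion is released by NOTCH suppression through
MAPK→ITCH and by TET2 loss; stem-cell self-renewal is held down by TET2;
MEP expansion follows STAT5; GMP differentiation needs both SPI1 and a
JAK2-dependent input).  Within those constraints the functions were
chosen as the simplest algebraic forms that satisfy all 30 specification
cells *and* stabilise to fixpoints in every genotype column — the wiring
of the SPI1/GATA1 pair is deliberately saturating
(`SPI1 = min(RUNX1, 2 − GATA1)`,
`GATA1 = clip(RUNX1 + min(RUNX1, STAT5) − SPI1)`) because a naive
symmetric mutual inhibition oscillates under synchronous update.
The documented RUNX1–MYB relation is implemented as indirect inhibition
through SPI1 and GATA1 (both direct MYB inhibitors); a direct
RUNX1→MYB activation reading also circulates but is inconsistent with
the CMP-expansion bifurcation the model must reproduce, so the indirect
route is packaged.  JAK2's effect on HOXA9 is modelled as activation;
mouse microarray data exist in which the direction appears reversed, and
the model deliberately follows the human-derived phosphorylation
evidence.

### Self-loop ablations

`ablate_self_loop` removes the HOXA9→HOXA9 edge and substitutes one of
three targets, each encoding a hypothesis about what the loop was doing:

| mode | HOXA9 target | double-mutant outcome |
| --- | --- | --- |
| `remove` | `clip(2·JAK2 + TET2 − 2)` | stable overexpression (HOXA9 = 2), JAK2 dominates |
| `basal_dependent` | `0` | null activity, stable |
| `compensated` | `clip(JAK2 + TET2 − 1)` | healthy level (HOXA9 = 1) |

All three abolish the mutation-order bifurcation (a single reachable
HOXA9 outcome).  In the compensated variant the SPI1/GATA1 pair at
intermediate RUNX1 input additionally admits a synchronous 2-cycle
(SPI1/GATA1 flipping 0↔1 and 1↔2 in antiphase).  That cycle is **not**
reached from the wild type by either mutation order — both orders
stabilise — so `find_compensated_instability` locates it by scanning all
SPI1 × GATA1 initial levels around the reachable double-mutant state.

## Stratification pipeline

Inputs are a genes × samples matrix of log2(TPM+1) values and a clinical
table (time in days, event 1 = death / 0 = censored).

* **Low-expression filter.** A gene is dropped when more than 50 samples
  (or, in fractional mode, more than a given fraction) have TPM < 1; the
  boundary is strict (exactly 50 low samples keeps the gene).
* **Multimodality test.** The excess mass of k intervals at level λ is
  E(λ, k) = max over k disjoint intervals of Σ(empirical mass − λ·length);
  the statistic is Δ₂ = max_λ [E(λ, 2) − E(λ, 1)].  For fixed λ the
  interval optimisation is exact (prefix/suffix scans over the sorted
  sample, endpoints at data points).  The λ-maximisation uses a
  deterministic geometric grid (128 points between the slopes at which the
  whole range, respectively the tightest pair, stops paying) with two
  local refinement passes, augmented by all pairwise slopes for n ≤ 64;
  the observed statistic and every bootstrap statistic use the same rule,
  so the calibration below is unaffected by the grid approximation.  The
  null distribution is a smoothed bootstrap from the **critical-bandwidth**
  Gaussian KDE — the smallest bandwidth at which the sample's density
  estimate is unimodal (found by bisection over a 512-point density grid)
  — with Silverman's variance rescaling; p = (1 + #{Δ₂* ≥ Δ₂})/(B + 1).
  The test is somewhat conservative at these sample sizes (empirical
  type-I ≈ 0.05 or below at nominal 0.05, checked over 200 simulations of
  n = 111 in the acceptance suite).  `method="silverman"` bootstraps the
  critical bandwidth itself instead and serves as an independent, simpler
  cross-check; the exhaustive interval-pair oracle used to validate the
  statistic lives in the test-suite.  Zero-expression samples are removed
  before testing (a detection zero is a point mass, not a mode).
* **Cohort split.** Zero-expression samples are excluded; values in
  (0, 1] form the low cohort, values in [4, 5.5] the high cohort,
  everything else is excluded.  The half-open low interval makes the
  zero-exclusion rule and the printed bounds consistent.  Both the raw
  low-interval occupancy (zeros included) and the analysed cohort size
  are reported, because both readings of "low peak size" occur in
  practice.  Conclusions are robust to moving the high-interval lower
  bound across {3.5, 4.0, 4.5}; exact membership is stable only across
  the empty inter-peak gap (e.g. 4.0 → 3.5), since a bound raised into
  the high peak's own support necessarily reassigns the samples it
  crosses.
* **Survival.** Kaplan–Meier product-limit curves (ties grouped); the
  standard observed-minus-expected log-rank chi-square with 1 df; and a
  hazard ratio for low vs high expression.  The default hazard-ratio
  estimator maximises the one-covariate Breslow partial likelihood by
  Newton iteration on the per-event-time risk-set table — for a binary
  grouping this is the exact proportional-hazards estimate, with Wald
  interval exp(log HR ± z/√information).  The classical
  (O_A/E_A)/(O_B/E_B) summary is available as `method="oe"`; it is kept
  because it is common and cheap, but it is not the default because its
  magnitude shrinks noticeably toward 1 when the true ratio is far from
  1 and follow-up is long (≈0.35 where the partial likelihood recovers a
  true 0.29 in the simulation below).
* **Gene ranking.** Genes are ranked by |mean(low) − mean(high)| (or by
  fold change of means with a pseudocount of 1), top 30, ties broken by
  gene id.  No per-gene hypothesis testing or multiple-testing correction
  is attached to the ranking — it is a ranking, not a test.

## Synthetic-data generator

`generate_bimodal_cohort` emulates the cohort structure the pipeline
assumes, not RNA-seq reads: the marker gene is drawn from two
truncated-at-zero normal peaks — defaults 31 low-cohort samples at
mean 0.5 and 80 high-cohort samples at mean 4.75 log2(TPM+1), sds
(0.25, 0.3) chosen so the conventional peak intervals (0.005–1 and
4–5.5) span roughly ±2–2.5 sd — with 9/40 of the low cohort set to
exactly zero (detection nulls).  Background genes are unimodal noise
(gene-specific means uniform in [2, 6], unit-sd noise, clipped at 0).
Survival times are exponential — the simplest model consistent with a
single hazard-ratio summary; a Weibull shape parameter is exposed but
defaults to 1 — with baseline hazard 1/365 per day for the high cohort
and baseline × 0.29 for the low cohort.  Censoring is independent of the
event process: censoring times are uniform on (0, τ], with τ solved
(closed form for shape 1, quadrature otherwise) so the expected censored
fraction equals `censor_rate` (default 0.2).  Everything is determined by
the config seed.

What passing on this generator does and does not show: the peaks are
cleanly separated normals with an empty inter-peak gap, survival is
exactly proportional-hazards, and censoring is exactly independent — so
the tests demonstrate correctness of the machinery and calibration of the
statistics under the assumed structure, not robustness to skewed peaks,
overlapping modes, batch effects, or informative censoring found in real
cohorts.  Background genes are independent of cohort, so the gene-ranking
step on synthetic data has a flat truth (its correctness is checked
against a brute-force oracle instead).

`generate_random_qn` draws each possible directed edge (self-edges
included) independently with the configured density and a random sign,
leaving default target functions; `acyclic=True` restricts edges to a
topological order, producing feed-forward networks with no feedback and
hence no mutation-order memory — the negative control for the
bifurcation analysis.

## Problem sizes and determinism

The packaged analyses are small and exact: every model-level check runs
in well under a second.  The stochastic checks use fixed problem sizes
chosen to keep the full suite fast while leaving Monte-Carlo error well
inside the asserted margins: 100 random networks for the
enumeration cross-check, 200 unimodal cohorts of n = 111 (100 bootstrap
draws each) for type-I calibration, 1000 subjects per cohort for
hazard-ratio recovery, and 10^4 label permutations for the log-rank
oracle.  All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); re-running any command with the same seed
reproduces byte-identical outputs.

## Known limitations

* Synchronous determinism is an idealisation; attractors can differ under
  asynchronous schedules, which are not implemented.
* The network's target functions are a reconstruction constrained by the
  phenotype specification and the qualitative statements above, not a
  unique solution; alternative functions satisfying the same constraints
  exist.
* The hazard-ratio interval is a Wald interval; for very small cohorts a
  profile or exact interval would be preferable.
* The excess-mass λ-maximisation is grid-refined, not breakpoint-exact;
  agreement with the exhaustive oracle is verified on small samples, and
  calibration is unaffected at any size (observed and null statistics
  share the rule).
* The generator draws background genes independently of cohort and of
  each other; correlated co-expression structure is not simulated.
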