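# Methods

## Setting and targets

`clustmsm` performs nonparametric, population-averaged inference for a
finite-state multistate process X(t), t ∈ [0, τ], observed on *n*
clusters of subjects (hospitals in a multicenter trial, families,
repeated units within a patient).  Observations are right-censored and
possibly left-truncated; within a cluster they may be dependent in an
arbitrary way, and the cluster size M_i may itself be associated with
the members' event processes (informative cluster size, ICS).  The
cluster-level summed counting and at-risk processes are assumed i.i.d.
across clusters, and censoring/truncation are independent of the
process and of cluster size.

Two populations define the estimands.  Over the *all cluster members*
(ACM) population every subject counts once, so large clusters dominate:
the occupation probability is P_j(t) = E{M I(X(t)=j)} / E{M}.  Over the
*typical cluster member* (TCM) population every cluster counts once:
P'_j(t) = E{I(X(t)=j)} for one randomly drawn member per cluster.  With
noninformative or constant cluster size the two coincide; under ICS
they differ, and the difference is itself of scientific interest.
Analogous pairs exist for the transition probabilities P_hj(s, t) and
the cumulative transition intensities A_hj.

## Estimation

Estimation is pure plug-in.  The cluster-weighted Nelson–Aalen jumps

    dÂ_hj(u) = Σ_i w_i dN_{i·,hj}(u) / Σ_i w_i Y_{i·,h}(u),

with w_i = 1 (ACM) or 1/M_i (TCM), feed the product integral
P̂(s, t) = ∏_{s<u≤t} (I + dÂ(u)), the working-independence
Aalen–Johansen estimator (inverse-size-weighted for TCM).  Occupation
probabilities combine rows of P̂(0, ·) with estimated initial-state
weights; under left truncation the weights are corrected by π̂, the
estimated probability of being under observation at time 0, and the
transition part is computed from the subset of subjects under
observation at 0, which keeps the estimator consistent even for
non-Markov processes.  For transition probabilities from s > 0 with a
non-Markov process, the landmark device is used: only subjects in state
h and under observation just after s enter the estimation.  The point
estimators are valid without any model for the within-cluster
dependence; only the variance changes.

Conventions: episodes are intervals (entry, exit]; Y(t) counts subjects
in a state *just before* t, so a censoring tied with another subject's
transition leaves the censored subject in that risk set.  Jump times
with a zero weighted at-risk sum contribute no intensity jump (0/0 := 0)
and the product integral carries P̂ forward flat; beyond the last event
the step functions are extended by right-continuity.  All estimates live
on the pooled grid of observed transition times and are evaluated
elsewhere by last-value carry-forward.

## Inference

Two asymptotically equivalent routes are implemented and validated
against each other.

*Influence functions (fast route).*  The per-cluster influence
functions of P̂_hj(s, ·) are the ratio linearisation of the weighted
Nelson–Aalen increments pushed through the Duhamel expansion of the
product integral; they are accumulated in one forward sweep over the
jump grid.  Occupation-probability influence functions add, by the
delta method, the residuals of the initial at-risk counts, of π̂ and
(ACM) of the total size Σ M_i; in the no-truncation single-initial-state
case they reduce exactly to the transition influence functions.
Empirical second moments give pointwise variances; perturbing the
influence sums with i.i.d. standard normal multipliers (wild bootstrap)
simulates the limiting Gaussian process for bands and tests.

*Cluster bootstrap (reference route).*  Whole clusters are resampled
with replacement and the full estimator recomputed.  This is valid
under arbitrary within-cluster dependence and ICS and requires no
analytic derivation, so it serves as the reference: the package's test
suite checks that influence-function variances and multiplier critical
values agree with their bootstrap counterparts within Monte Carlo
error.  Internally the bootstrap is vectorised by carrying multinomial
resample multiplicities through the cluster-level aggregation, which is
algebraically identical to rebuilding the resampled episode table.

*Intervals and bands.*  Pointwise 1−α intervals are transformed Wald
intervals, by default on the g(x) = log(−log x) scale so limits stay in
(0, 1).  Simultaneous bands over [t1, t2] use the critical value ĉ_α,
the empirical ⌈(1−α)D⌉ order statistic (a conservative tie-break) of
sup_t |q̂(t) g′(P̂(t)) Z(t)| with Z either multiplier or centred
bootstrap realisations scaled by √n, and the weight
q̂(t) = {1 + v̂(t)}⁻¹ built from the influence-function variance v̂.
Bands are unstable near the edges of the observation window, so the
domain defaults to the 10th–90th percentile range of the observed
transition times feeding the target (5/95 is a reasonable alternative);
grid times where the estimate sits at 0 or 1 are flagged and excluded.
Defaults: α = 0.05, 1000 draws.

*Two-sample tests.*  For groups 1 and 2 observed within the same
clusters (each cluster must contain both), the statistic is
K = sup_t |Ŵ(t) Δ̂(t)| with Δ̂ the difference of group-specific
estimates.  Two weight families are provided: the indicator weight,
I[∏_l Ȳ_{1,l} Ȳ_{2,l} > 0] over the transient states l traversable
during the target transition, and the default product weight
∏_l Ȳ_{1,l} Ȳ_{2,l} / Σ_l (Ȳ_{1,l}+Ȳ_{2,l}), which downweights times
with sparse risk sets.  P-values come from multiplier realisations of
the differenced influence processes or from cluster-bootstrap
realisations √n·sup|Ŵ(Δ̂* − Δ̂)|, with Ŵ frozen at its data value
across resamples (its variability does not enter the limiting null
distribution); the p-value uses the add-one rule
(1 + #{draws ≥ observed}) / (1 + D) with ≥ as the conservative
tie-break.

*ICS diagnostic.*  Because ACM and TCM targets coincide under
noninformative cluster size, the statistic sup_t |Ŵ(t){P̂_j(t) −
P̂'_j(t)}| with a cluster-bootstrap (or multiplier) null of the centred
difference is a diagnostic for informativeness.  The joint dependence
between the two estimates is handled implicitly by resampling them
together.  The exact published form of this diagnostic is not available
in the main text of the source literature; the implementation here is a
reconstruction and is labelled as such.  It is undefined for constant
cluster sizes.

*Naive comparator.*  The "naive" analysis is the same point estimator
with the classical i.i.d. Aalen–Johansen (Greenwood-type) variance that
treats subjects as independent.  It is computed by a covariance
recursion on the *aggregated* processes that accumulates the
multinomial innovation variance of the Nelson–Aalen increments and
drops between-time cross terms (martingale orthogonality); in the
two-state survival case this is exactly Greenwood's formula, and the
test suite checks it against the subject-level influence-function
variance.  It exists to quantify what ignoring the clustering costs;
it is not a recommended analysis.

## Synthetic data generator

The generator emulates a two-arm multicenter study with a non-Markov
irreversible illness-death process (1 = healthy, 2 = ill, 3 = dead).
Defaults, which are also the conditions of the package's acceptance
experiments:

| parameter | default | meaning |
|---|---|---|
| n_clusters | 80 | number of clusters (20/40/80 are the studied sizes) |
| size_range | (10, 30) | M_i ~ discrete uniform; (5, 15) is the other studied case |
| frailty | Gamma(1, 1) | cluster-level multiplicative frailty v_i |
| slope_12, slope_13, slope_23 | 0.25, 0.25, 0.5 | baseline intensity slopes per unit time |
| ics_bump | 0.25 | added to slope_12 when M_i ≤ E(M): informative cluster size |
| arm_effect | 0 (0.5 under H1) | added to arm 2's slope_12 |
| censoring | U(0, 3) | independent right censoring |
| truncation | none / Beta(1,2) / 0 w.p. 2/3 else Beta(1,2) | left truncation scenarios |

Conditionally on (v_i, m_i) each subject follows constant hazards
slope·v_i, so sojourns are exponential with competing-risks destination
draws; marginally over the frailty the process is non-Markov and
within-cluster dependent.  Two-arm allocation alternates assignment
within each cluster after a random offset, guaranteeing both arms in
every cluster of size ≥ 2.  Under the censoring-only scenario the
generator reproduces the reference outcome mix (≈57.5% censored while
healthy, ≈24.4% observed illness, ≈18.1% direct deaths; ≈46% of ill
subjects later observed to die).

Because the frailty is Gamma(1, 1) (Laplace transform (1+s)⁻¹), the
population-averaged occupation and transition probabilities have closed
forms: the conditional constant-hazard illness-death solution is
integrated analytically over the frailty and mixed over cluster sizes
with weights p(m)·m/E(M) (ACM) or p(m) (TCM).  These closed forms are
verified against brute-force Monte Carlo in the tests and serve as the
ground truth for all coverage and rejection-rate experiments.  Gamma is
the only supported frailty family precisely because this exact truth
would otherwise be lost.

What the generator does *not* emulate: covariate-dependent censoring or
truncation, recovery transitions, between-cluster dependence,
non-exponential conditional sojourns, and cluster-size distributions
beyond the discrete uniform.  Passing experiments therefore demonstrate
correctness of the estimators and calibration of the inference under
frailty-type dependence with ICS — not robustness to, e.g., informative
censoring, which is outside the model.

Evaluation times are population percentiles of the follow-up duration
(entry to exit from observation), computed once from a large reference
cohort (10⁶ subjects by default) with a fixed internal seed, so the
evaluation time is a deterministic function of the configuration and is
common across replicates.  The under-observation fraction reported for
the truncation scenario is the landmark-eligible share at s = 0.5 among
subjects ever at risk in state 1 — the pool a landmark analysis at
(h=1, s=0.5) draws on; a denominator over all simulated subjects is
also available.

## Experiment scales

The packaged experiments use 500–1000 Monte Carlo replicates (the
pointwise runs, cheap per replicate, use 1000), 200 bootstrap resamples
for pointwise standard errors and 500 draws for bands and test
p-values, with n = 80 clusters of 10–30 subjects; these sizes give
binomial Monte Carlo error around one percentage point on a 95%
coverage estimate while keeping a full run in the minutes range on one
core.  The runners accept larger values for higher precision.

## Numerical and design choices

- Weighted ratios with zero denominators contribute nothing rather than
  NaN; a jump matrix row that would leave [0, 1] raises an error.
- With constant cluster size the TCM weights cancel algebraically; the
  implementation then uses unit weights so ACM and TCM results are
  identical to the bit, not merely to rounding.
- TCM weighting after landmarking uses the *original* cluster sizes
  M_i (they define the population), not the landmark subset sizes;
  clusters emptied by landmarking are dropped and n is the number of
  retained clusters.  Both are genuinely open conventions; the
  alternative is one flag away in the code.
- Group-specific TCM estimates in the two-sample test weight by the
  group-specific cluster sizes M_pi, matching the group-wise definition
  of the weighted risk paths.
- Band coverage in the experiments is checked by containment of the
  true curve at every grid time of the restricted domain (the band is a
  step function; the smooth truth is compared at the step points).
- Bootstrap resamples that are degenerate for a target (e.g. nobody
  under observation at time zero) are redrawn, with a hard cap, rather
  than silently imputed.
- All randomness flows through `numpy.random.Generator` seeds; every
  stochastic operation is reproducible from (seed, n_draws).

## Known limitations

- Inference is large-sample in the number of clusters; below ~30
  clusters coverage erodes by a few points (visible in the experiment
  runners at n = 20).
- The influence-function formulas are a reconstruction of the standard
  clustered Nelson–Aalen + Duhamel construction; they are validated
  against the cluster bootstrap (the fully specified reference path)
  rather than against a published closed form, and may differ from the
  latter in finite-sample constants.
- Interval-censored observation schemes, covariate-dependent censoring,
  semiparametric regression on the probabilities, and non-i.i.d.
  clusters are out of scope.
- The two-sample test supports exactly two groups present in every
  cluster.
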