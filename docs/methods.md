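# Methods

## Model

`progdbn` models disease progression as a discrete two-slice dynamic
Bayesian network over an unrolled node set: static covariates (sex, age at
onset, onset site, onset delta, Riluzole, placebo/treatment), every dynamic
variable at slice *t−1* and at slice *t*, the cumulative time since symptom
onset (TSO) and a binary survival indicator. The key assumptions are

* **stationarity** — one transition distribution is shared across all slice
  pairs, so every consecutive visit pair of every patient contributes one
  training instance;
* **first-order Markov dynamics** — slice *t* depends on slice *t−1*, the
  statics and TSO, plus acyclic intra-slice edges;
* **absorbing, per-slice death** — survival is encoded as a binary death
  indicator sampled once per slice from its conditional table; once it
  fires, the trajectory ends. This honors both the layered treatment of
  survival as a top-layer node and the simulator's stop-on-death rule.
  Because death is sampled *before* the contemporaneous slice, its parents
  are restricted to statics, slice *t−1* and TSO;
* **irreversible MITOS** — the four loss-of-autonomy flags never decrease,
  enforced during preprocessing (running maximum) and clamped during
  simulation.

### Layered edge mask

Edges are admissible only from lower to higher strata: layer 1 (sex, age at
onset) → layers 2, 3, slice *t*, survival; layer 2 (onset site/delta) →
layer 3, slice *t*, survival; layer 3 (Riluzole, treatment) → slice *t*,
survival; slice *t−1* → slice *t*, survival; TSO → slice *t*, survival;
slice *t* ↔ slice *t* (acyclic). Slice *t−1* nodes and TSO are evidence and
never receive edges.

## Structure learning

**Conditional independence.** The G² likelihood-ratio statistic with
`(Rx−1)(Ry−1)·ΠRs` degrees of freedom, significance level 0.05, maximum
conditioning-set size 3, and the usual reliability heuristic: a test whose
average cell count falls below 5 is skipped and read as independence.
Tests run on available cases (records complete for the variables involved).
One situation needs care: terminal death instances have every slice-*t*
value structurally missing, so conditioning on a slice-*t* variable removes
all death events from the available cases and the indicator degenerates to
a constant. A test in which either tested variable shows no variation is
*uninformative* — it returns a NaN p-value and is never counted as evidence
of independence. Without this guard the skeleton silently loses every edge
into the survival node.

**MMPC.** Per target, a forward phase admits the candidate with the
strongest minimum association (smallest maximum p-value over conditioning
subsets of the current candidate set), rejecting candidates once some
subset renders them independent; a backward phase prunes the survivors; an
edge is kept only when each endpoint selects the other. Pairs forbidden by
the mask in both orientations are never tested.

**Hill climbing.** Greedy BIC search (natural log; empty cells contribute
zero to the likelihood; family scores memoized) over add/delete/reverse
moves, restricted to MMPC adjacencies in mask-allowed orientations, with
acyclicity enforced and deterministic lexicographic tie-breaking on
(child, parent, move type). The iteration cap (default 15) budgets up to
one accepted move per node per iteration, so the default still assembles
networks with dozens to hundreds of edges. BIC cannot distinguish
structures within a likelihood-equivalence class, and a purely greedy
search can converge to the wrong orientation of a collider; at a local
optimum the search therefore walks chains (depth ≤ 3) of exactly
score-neutral reversals and commits a chain only when it ends at a position
with a strictly improving move. Ledger BICs are consequently
non-decreasing, and strictly increasing except at those neutral reversals.
On exhaustive enumeration over random 3-/4-node problems this search
attains the global optimum in ≳90% of instances and stays within 1% of the
optimal score otherwise (measured in the test suite).

**Parameters.** Maximum-a-posteriori tables under a symmetric
Dirichlet(α) prior, `(n_k + α − 1)/(n + R(α − 1))`, with α = 2 (add-one
smoothing) by default, so no simulated transition ever has probability
zero. α → 1 recovers maximum likelihood. Parent-configuration rows are
indexed by the mixed-radix encoding of parent codes in declared parent
order, most-significant first; a guard rejects families with more than 10⁶
parent configurations.

The observation count M in the BIC penalty is the total number of
transition instances; family likelihoods use available cases.

## Preprocessing

* Variables missing for **more than** 50% of subjects (absent at every
  visit, for dynamic variables) are dropped; exactly 50% is retained.
* Quantization is half-open binning `[low, high)` with the top bin closed:
  a value equal to a cut point falls in the upper bin, matching the reading
  of the age bins `<51, [51, 61), ≥61`.
* Tertile cuts (age at onset, onset delta, inter-visit time, TSO) are the
  order statistics at ranks ⌊n/3⌋ and ⌊2n/3⌋ of the sorted training
  values — an exact sort-and-split that gives equal masses whenever n is
  divisible by 3 — and are always frozen from the training part to avoid
  leakage into validation or simulation.
* ALSFRS-R → MITOS conversion is a configurable rule table (data, not
  code): a domain is lost when any of its defining items falls at/below its
  cut — movement: item 8 (walking) ≤ 1 or item 6 (dressing/hygiene) ≤ 1;
  communication: item 1 (speech) ≤ 1 or item 4 (handwriting) ≤ 1;
  swallowing: item 3 ≤ 1; breathing: item 10 (dyspnea) ≤ 1 or item 12
  (respiratory insufficiency) ≤ 2. A missing defining item leaves the flag
  missing unless another defining item already proves the loss.
* Irreversibility: the running maximum over observed flags; a missing entry
  is filled only when forced (the running maximum is already 1, or the next
  observed value equals the current maximum 0) — impairment onset is never
  moved earlier than observed.
* TSO(visit) = onset delta + day offset; patients without a known onset
  time are excluded. The raw value is carried alongside its code so the
  simulator can advance real time.
* The train/validation split (default 25% validation) is stratified by the
  death indicator via a seeded stratified shuffle; a cohort without any
  death-status variation falls back to a plain random split with a warning.
* The inter-visit interval can be tertile-quantized like the other timing
  variables, but it is not part of the default network roster: the
  simulator advances time on a fixed slice grid, where the interval is a
  constant and would carry no signal.

## Simulation

Default configuration: 30 time slices of 30 days, 400 replicates per
patient. From each patient's first visit, every slice advances TSO by the
slice duration (re-quantized with the training tertile cuts), samples the
death indicator (absorbing; event times are assigned to the slice end,
the conservative discrete-hazard convention), then samples slice-*t*
variables in topological order of the intra-slice edges, clamping MITOS
monotone. Replicates are vectorized; months are 30-day months, so with
default settings slice index = month. Missing baseline entries are sampled
from the model — statics from their (conditional) tables root-down,
dynamic variables from their slice-*t* table marginalized uniformly over
parent configurations — and logged. Stratification clones the base
population, overrides static (or baseline) variables per arm, and reuses
identical random streams across arms so arm contrasts carry reduced
Monte-Carlo variance (identical outcomes when the intervened variable has
no directed path to the outcome).

Against exact joint propagation on small all-binary models, empirical slice
marginals from 10⁴ replicates agree within total-variation distance 0.02
over ten slices (tested).

## Assessment

Outcomes are death plus the four MITOS domains, evaluated at months 12, 24,
36 and 42 by default. Status at a horizon uses the standard fixed-horizon
binary reduction: events by the horizon are positives, patients observed
beyond it are negatives, and patients censored before it are excluded from
both the real event percentage and the AU-ROC labels. Simulation error is
the absolute difference, in percentage points, between the real and the
simulated event percentage over the same patient basis; a horizon with no
observable patient is reported as undefined, never as zero. Risk is the
fraction of a patient's replicates with the event by the horizon; AU-ROC
uses the Mann–Whitney convention (ties one half) and is undefined when a
class is empty. Cross-validation refits the network per fold (default
k = 10, death-stratified, seeded), simulates the held-out fold from its
first visits, and aggregates AU-ROCs as mean ± sample (n−1) SD over the
folds in which they are defined, with the contributing fold count reported.

## Synthetic cohorts

The generator emulates the *structure* of pooled ALS trial data: six static
covariates across layers 1–3; seven labs/vitals on three-level clinical
scales; four monotone MITOS domains emitted as consistent ALSFRS-R item
scores; an irregular visit grid with 44 ± 20-day gaps (minimum 7); a
per-patient administrative observation window of 549 ± 244 days (minimum
90); entry-level missingness (5% MCAR) plus whole-variable dropout per
subject (5%), giving block missingness; and an absorbing death hazard.
Continuous values are emitted uniformly within per-code intervals that
leave a margin around each quantization cut, so re-quantization recovers
the generating codes exactly under the generating cuts.

The `als_like` preset is designed as a high-discrimination regime, the
operating point the method is meant for: patients enter across the whole
spectrum of disease stages (e.g. 20% with baseline breathing impairment,
30% with FVC below 50% predicted), dynamic states are persistent, and the
death hazard is steeply multiplicative in breathing impairment, FVC,
treatment and age (per-transition hazards spanning roughly 0.0004 to the
clipped maximum of 0.95). Under these defaults ~35–40% of patients die
within their observation window — consistent with a mean 3–5-year survival
for a mid-disease trial population — and the generating model itself ranks
12-month death risk with AU-ROC ≈ 0.85, so a well-recovered network can
reach ≥ 0.8. The `small8` preset keeps eight variables with strong effects
for fast exact-oracle tests.

What the generator does **not** emulate: realistic lab-value distributions
beyond bin-level fidelity, informative (state-dependent) missingness or
visit scheduling, measurement error that crosses quantization cuts,
inter-trial heterogeneity, or deaths reported after the visit window.
Passing recovery tests therefore demonstrates the correctness of the
algorithms under their own assumptions — not clinical validity on real
registry data.

## Numerical choices and conventions

* Missing codes are −1 throughout; G² tests and family counts use
  available cases; uninformative tests (no variation in a tested variable)
  return NaN p-values and never count as evidence of independence.
* Score improvements must exceed 1e-9 to be accepted; CPT rows sum to 1
  within 1e-9; ties in the search break lexicographically.
* Per-patient random streams derive from `(seed, patient index)` seed
  sequences, so results are independent of patient-iteration order and
  identical streams can be shared across stratification arms.
* Terminal death instances take TSO at the last visit.
* Degenerate inputs: empty cohorts, all-variables-dropped, zero-death
  cohorts, unseen parent configurations (uniform prior rows), horizons
  beyond the simulated span, and single-class AU-ROC labels all have
  explicit, tested behaviors (error, warning or NaN as documented).

## Known limitations

* **Timescale mismatch.** Transitions are learned per consecutive visit
  pair (≈44-day mean gap, whatever its actual length) but simulated on a
  fixed 30-day grid, so simulated cumulative event curves run slightly fast
  relative to generated cohorts. This biases the simulation-error metric
  against real-time cohorts while leaving risk *ranking* (AU-ROC)
  essentially untouched; self-consistency checks therefore compare the
  simulator against populations drawn from the fitted model on the same
  grid. A gap-matched `slice_duration` is one configuration change away.
* Hazards are per transition, not per day: a long inter-visit gap carries
  the same death risk as a short one during learning.
* The BIC observation count M is global, while family likelihoods use
  available cases; with heavy missingness the complexity penalty is
  slightly conservative for sparsely observed families.
* Mode-one interpolation of missing MITOS entries is deliberately
  minimal — flags stay missing unless the fill is forced by
  irreversibility.
* Structure learning returns a DAG, not an equivalence class; reported
  edges within a likelihood-equivalence class carry no causal orientation
  guarantee beyond the layer mask.

## Problem sizes

The test suite and acceptance script size their experiments to run on one
CPU in minutes: structure recovery uses 10 × 2000-patient cohorts of the
small preset; parameter recovery 500/2000/5000 patients; the end-to-end
discrimination check a 3000-patient ALS-like cohort with 5-fold
cross-validation at 100 replicates per patient; the exhaustive-enumeration
comparison 50 random 3-/4-node problems at n = 2000; the self-consistency
check 250 starting patients × 20 reference draws against 400 simulated
replicates. These sizes are the package's validation conditions; all are
configurable upward.
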