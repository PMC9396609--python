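# Methods

## The model

A progressive condition is represented as a finite Markov chain over
severity states ordered least to most severe.  Two structural
assumptions define the class of models handled:

* **Monotone progression.**  Between ordinary states a patient never
  improves: the raw transition matrix is upper-triangular.  Recovery
  happens only through the *reset* state — by default the most severe
  state — which returns to the least severe state with probability 1
  (modelling a definitive intervention such as a pacemaker).  Validation
  treats any other below-diagonal mass as a hard error.
* **Independent misdiagnosis.**  The diagnosis/treatment process and
  the progression process are independent, so the chain a cohort
  actually follows weights each raw transition `raw[i, j]` by the
  probability `acc[i, j]` that a patient in state `i` is treated as
  state `j`, renormalising each row:

  `x[i, j] = acc[i, j]·raw[i, j] / Σ_j acc[i, j]·raw[i, j]`.

  The reset row is set to the unit vector on state 1 unconditionally:
  the product form is 0/0 there whenever the reset state is never
  treated as state 1, yet the reset convention fixes the answer.  A
  zero denominator on any other row is raised as a degenerate-row
  error naming the state — it means the state admits no
  treatment/transition combination with positive probability.

  Renormalisation makes each effective row invariant to positive
  rescaling of the raw row.  This is deliberate: elicited transition
  rows are aggregated expert means and need not sum exactly to 1 (the
  packaged example's Moderate row sums to 0.957).  Raw row sums within
  1 ± 0.05 are therefore accepted with a warning; the 0.05 slack is a
  package choice, configurable per call.

## Stationary analysis and the deterministic cost

`θ*` solves `θᵀX = θᵀ`, `Σθ = 1`.  The solver replaces one redundant
balance equation with the normalisation row and solves the dense
system (a condition number above 1e12 triggers a warning); the balance
residual must come out below 1e-9.  Uniqueness requires exactly one
closed recurrent class — checked via strongly connected components of
the positive-transition graph — and a violation raises a non-ergodic
error naming the classes.  Transient states are allowed and receive
probability 0.  Power iteration, implemented independently in the test
suite, is the cross-checking oracle, and a seeded Monte-Carlo
trajectory simulator provides an empirical check (occupancy within
three standard errors at 10^6 simulated transitions).

One textbook-style identity sometimes quoted for reset chains,
`θ*(state 1) = θ*(reset state)`, is *not* imposed: it conflicts with
the general balance equations (state 1 also retains its own mass), so
balance plus normalisation govern.

The deterministic-policy cost is `E_det = Σ_m c(m) θ*(m)` — linear and
monotone in each state cost.

## The randomized-policy LP

Variables are the admissible (decision, state) pairs only, ordered by
(state, decision).  Cost coefficients are `c(k, m)`: a per-pair
override when configured, else the state cost.  Pair costs are the
general model because realistic schedules are decision-indexed — e.g.
a watch-and-wait decision on a minor condition carries only an
administrative charge (about $50 in the packaged example) rather than
the state's treatment cost.

Constraints are one normalisation equality, one balance equality per
state (so M + 1 equality rows; one is linearly redundant but is kept —
HiGHS tolerates it and the row count then matches the conventional
M + 2 functional-constraint tally when the redundant row is counted),
and `0 ≤ y ≤ 1` bounds reported as two "soft" constraints per
variable.  Decision-dependent transition matrices `P_k` are accepted
as explicit input; the default shares the effective matrix across
decisions, under which (with state-only costs) the objective provably
equals `E_det` — a property the tests assert.

Solving uses `scipy.optimize.linprog` (HiGHS).  Because degenerate
optima are common (any mixture of optimal pure policies is optimal), a
second restricted solve over the optimal face minimises a fixed
geometric weighting of the variables, giving a reproducible,
mixture-free representative basis across runs and formulations.

`D(k, m) = y(k, m)/Σ_k y(k, m)` recovers the conditional policy;
states with zero steady-state mass get explicit `None` markers rather
than 0/0.  The pure-policy enumeration oracle builds, for every
assignment of an admissible decision per state, the induced chain and
its stationary cost, guarded to 10,000 assignments; LP/enumeration
agreement on random small instances is an acceptance-level property.

## Sensitivity analysis

One steady-state probability at a time is scaled over a factor grid
(default 0.90–1.10 in steps of 0.01 — 21 points echoing a ±10%
design), two designated states are held fixed, and an *absorber* state
takes up the change so the vector stays a distribution.  Which states
are held and which absorbs depends on the varied state, on whether the
factor is below or above 1, and on the condition — `higher` routes the
mass shift so the cost is bounded from above, `lower` from below.  The
two condition tables are exact mirror images across the 100% point;
they are encoded as data and caller-overridable, because verbal
descriptions of such designs are notoriously ambiguous (the package
resolves each row by the rule *absorber = the state named neither as
varied nor as held*).  Factors that overdraw the absorber are recorded
as infeasible grid points, not fatal errors.  At the packaged example's
published steady state the expected cost rises in θ(Severe), falls in
θ(Minor), and is most sensitive to θ(Major) — its ±10% swing moves
roughly $840 per patient, versus about $42 for θ(Severe) — because
sensitivity scales with θ(m) itself, and θ(Major) dominates.

## Synthetic clinician cohorts

The generator emulates a panel of clinicians reporting diagnosis
frequencies on the severity scale:

* **Report noise** is compositional: each report is a Dirichlet draw
  centred on the target means with concentration `dispersion`.  The
  default means are the published cohort means (0.54366667, 0.31075,
  0.117333, remainder 0.02825033 for Severe).  The default
  concentration of 10,000 (per-state s.d. ≈ 0.005 for the Minor state)
  is chosen so that a ~100-report cohort lies within the ±2% band that
  practitioners describe as realistic panel agreement; it is a single
  realism choice, not a fitted quantity.
* **Contamination**: exactly `round(n · contamination)` reports
  (default 13/115) get a random adjacent frequency pair swapped,
  reproducing the ordering-violating outlier pattern used to screen
  real panels.
* **Matrix estimates** (optional): per-report accuracy and transition
  matrices are row-wise Dirichlet draws around supplied means,
  preserving structural zeros and elicited row totals.

What the generator does **not** emulate: between-clinician systematic
bias (site or cohort effects), correlation between a clinician's
frequency and matrix errors, non-compositional reporting artifacts
(rounding to round percentages), and panel dynamics of iterated
elicitation rounds.  Passing tests therefore demonstrate that the
pipeline recovers parameters from *well-behaved* panels and flags the
modelled outlier pattern — not robustness to every failure mode of
real expert data.

### Test battery

* **Outlier screen**: a report is flagged iff its frequencies are not
  strictly decreasing with severity — threshold-free by design, since
  the ordering inversion is the one documented exclusion pattern.
* **Normality**: Shapiro–Wilk per state at α = 0.05; constant samples
  are reported as undefined rather than raising.
* **Homogeneity**: with one frequency per clinician per state, a
  clinician-factor ANOVA is not computable as such; the package splits
  the cohort into consecutive blocks (default 2) and runs a one-factor
  ANOVA per state — exchangeable blocks make this fail to reject for
  homogeneous cohorts — combined with a band check that every report
  lies within ±0.02 of the grand mean.  The 2% band is absolute by
  default (a relative variant is a flag) because the customary "within
  2%" phrasing does not specify the arithmetic.
* **Ordering**: all C(M,2) = 6 pairwise *paired* two-tailed t-tests
  (paired, because panel reports of two states by the same clinician
  are dependent — the output includes the Pearson correlation), with
  one-/two-tailed p-values, 5% critical values and the sample-mean
  ordering verdict.  The battery reports the raw tests and the
  ordering verdict side by side without claiming the t-tests *confirm*
  the ordering — failing to reject equality and affirming an ordering
  are different inferential acts, and conflating them (equivalence vs
  difference testing) is a known tension in elicitation practice.
* **Aggregation**: unweighted elementwise means over retained reports;
  matrix rows are renormalised only on explicit request, with a log
  note.

## Numerical choices and problem sizes

* Probability tolerances: accuracy rows 1e-6; effective/stationary
  quantities 1e-9; LP equalities 1e-8.
* Display rounding in reports: 3 decimals for probabilities, 2 for
  costs; computations stay in double precision throughout.
* Reference cross-checks in the test suite use the packaged cardiac
  example (4 states, 5 decisions, 11 admissible pairs), 100 random
  LP-vs-enumeration instances of up to 4 states × 3 decisions, and
  Monte-Carlo runs of 10^6 transitions — desk-scale sizes chosen so
  the whole suite runs in seconds while exercising every code path.
* The published case-study steady state (0.171, 0.158, 0.650, 0.021)
  is *not* the stationary vector of the published effective matrix
  (that is ≈ (0.187, 0.154, 0.639, 0.021)); likewise the published
  optimal occupancy implies decision-dependent transitions that were
  never published.  The package therefore treats those published
  vectors as fixed reference inputs where downstream values are
  evaluated at them, and relies on internal consistency properties
  (solver vs oracle, LP vs enumeration) everywhere else.

## Limitations

* Time-homogeneous chains only; no discounting and no finite-horizon
  (transient) cost analysis.
* No recovery transitions besides the reset convention.
* Per-decision transition matrices must be supplied externally if the
  dynamics are decision-dependent; the package does not elicit them.
* The built-in sensitivity redistribution tables cover the canonical
  4-state scale; other sizes need caller-supplied schemes.
* Costs are direct treatment costs, unit-agnostic; indirect costs
  (wages, administration) are out of scope.
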