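# Methods

## Model

`psadapt` simulates metastatic castrate-resistant prostate cancer (mCRPC)
under abiraterone as a three-species Lotka-Volterra competition system. The
state is the vector of cell counts x = (x_T+, x_TP, x_T−) for
testosterone-dependent (T+), testosterone-producing (TP) and
testosterone-independent (T−) cells. Each type grows logistically with
cross-type competition:

    dx_i/dt = r_i x_i (1 − Σ_j a_ij x_j / K_i),      i ∈ {T+, TP, T−}

with unit intra-type coefficients (a_ii = 1) and inter-type coefficients
a_ij ∈ (0, 1].

Abiraterone blocks the CYP17A pathway by which TP cells synthesize
testosterone. The drug is modelled as a change of carrying capacities, not
of growth rates:

* K_TP = 10 000 cells off treatment, collapsing to K_TP = 100 while the
  drug is on;
* K_T+ = μ·x_TP — T+ cells live off the testosterone the TP cells produce,
  so their capacity is proportional to the TP density, with μ = 1.5 off
  treatment and μ = 0.5 on treatment;
* K_T− = 10 000 cells always (T− cells are testosterone-independent and
  ignore the drug).

Growth rates are fixed at r = (0.0027726, 0.0034657, 0.0066542) per day,
derived from measured doubling times of representative cell lines (LNCaP,
H295R, PC-3). All times in the package are in days under this convention
(ln 2 / r_T+ ≈ 250-day doubling for T+).

Serum PSA is a weighted read-out of the composition rather than of total
burden:

    PSA(t) = α x_T+(t) + β x_TP(t) + (1 − α − β) x_T−(t),

with 0 ≤ α ≤ 1, 0 ≤ β ≤ 1 − α, so the weights form a convex combination and
PSA always lies between the smallest and largest population. The feasible
(α, β) set is the lower-triangular unit simplex; the corners are the
"single-producer" limits.

## Treatment protocols

Two controllers are compared, both starting with the drug on at t = 0 and
taking PSA(0) as the baseline:

* **MTD** — continuous maximum tolerable dose; the drug never goes off.
* **AT** — adaptive therapy: withdraw the drug when PSA falls to half of
  baseline, re-administer when it recovers to baseline. This is a hysteresis
  state machine; switches trigger on directional zero-crossings (downwards
  through ½·baseline while on, upwards through baseline while off), located
  by the ODE solver's event root-finder. Ties at t = 0 do not fire. The
  threshold fractions (0.5, 1.0) are configurable, but the defaults are the
  protocol under study.

A run counts as adaptive therapy only if the drug is actually withdrawn at
least once before competitive release; otherwise the trajectory is identical
to MTD and the run is reported "AT not applicable" (N/A). With α = β = 0 and
no initial T− cells the baseline PSA is zero and the thresholds are
undefined; such runs are likewise reported as not applicable rather than as
errors.

Outcome is measured by the **time to competitive release (TCR)**: the first
time the resistant type reaches the combined sensitive burden,
x_T−(t) ≥ x_T+(t) + x_TP(t). Treatment keeps cycling after release (the
controller only sees PSA, not the composition); AT-applicability, however,
only inspects withdrawals strictly before release.

## Patient categories and the untreated equilibrium

Patients differ in their competition matrix. The six inter-type coefficients
take values in {0.4, 0.5, 0.6, 0.7, 0.8, 0.9}; the clinically meaningful
summary is the frequency f of T− at the stable untreated equilibrium:

* **best responder** — f < 10⁻⁶ (T− competitively excluded),
* **responder** — 10⁻⁶ ≤ f < 0.20,
* **non-responder** — f ≥ 0.20.

The 10⁻⁶ cutoff operationalizes "T− absent" as a numerically robust zero
test; the 0.20 boundary is inclusive for non-responders.

Because K_T+ = μ·x_TP is linear in the state, the equilibrium conditions
(for each type, either x_i = 0 or Σ_j a_ij x_j = K_i) form linear systems.
`untreated_equilibrium` enumerates the seven non-empty supports in order of
decreasing size, solves each linear system, keeps candidates with all
components ≥ −10⁻⁹ (clamped to zero), and returns the first whose full 3×3
Jacobian has no eigenvalue with positive real part — so ties resolve
deterministically toward the largest support. The equilibrium is linear in
the carrying-capacity scale, hence the classification is scale-free; tests
confirm the solve against long-time integration of the ODE.

The three representative presets carry the published competition matrices
and start therapy at the printed initial cell counts, which sit at one tenth
of the untreated equilibrium computed with K = 10 000 (equivalently, the
equilibrium at K = 1000). The responder row is a known, slight exception:
the printed values (560.36, 747.59, 47.10) differ from the exact equilibrium
of the responder matrix (560.75, 747.66, 46.73) by up to 0.4 cells. The
presets use the printed values verbatim; the cohort generator uses the exact
equilibrium. The discrepancy is far too small to affect any reported TCR at
the tolerances used.

## Numerical integration

The hybrid system (smooth ODE + protocol switching) is integrated piecewise:
each smooth segment runs until the horizon or the next switching event, the
carrying-capacity regime flips at the event state, and integration restarts
there. No smoothing is applied across the discontinuity.

Numerical choices, all configurable:

* **Floored carrying capacity.** K_T+ = μ·x_TP vanishes as x_TP → 0; every
  K is floored at 10⁻⁹ cells inside the vector field. With x_T+ > 0 and K at
  the floor the per-capita rate is hugely negative — rapid T+ decline, the
  correct biological reading (T+ cells starve without testosterone) — while
  the field stays finite and continuous. Populations are never forcibly
  zeroed: sub-cell counts (the best-responder preset starts with
  x_T− ≈ 2·10⁻¹⁰) are a sanctioned regime of this continuous model.
* **Solver.** LSODA with rtol = 10⁻⁸, atol = 10⁻¹²; atol must sit far below
  the smallest meaningful population (~10⁻¹⁰ cells), and trajectories span
  ~14 orders of magnitude. In the floored regime after competitive release
  (populations at ~10⁻¹² cells) LSODA can abort; the engine then retries the
  segment with Radau at identical tolerances. Tests verify every reported
  TCR moves by < 0.1% when both tolerances tighten a hundredfold.
* **Events.** Switch thresholds and the release condition
  x_T− − (x_T+ + x_TP) = 0 are solver-located roots (directional crossings),
  so TCR precision is limited by rtol, not by the 1-day output grid.
* **Horizon.** Default 10 000 days — comfortable headroom over the largest
  headline TCR (~5400 days). `run(..., stop_at_tcr=True)` terminates at
  release; the comparison tables and simplex scans use it because every
  table entry (TCR, AT-applicability) depends only on the trajectory up to
  release. Full-horizon runs are the default and are what the trajectory
  plots and PSA series use.
* **Reporting.** TCR is kept at full event precision; published tables print
  integer days, so table reproductions round to nearest. Percentages for
  table reproduction are recomputed from the integer-rounded TCRs (this is
  the convention the published integers follow); the `ComparisonRow` API
  keeps full-precision percentages.

## Synthetic cohort

`generate_cohort` emulates the study's patient-construction scheme rather
than any observed population: competition coefficients drawn independently
and uniformly from the stated six-value set (all 6⁶ combinations
admissible), classification by equilibrium T− frequency, and initial
conditions at `init_fraction` (default 0.1) of the untreated equilibrium.
Draws use `numpy.random.default_rng` seeded explicitly; identical seeds give
identical cohorts.

`synthesize_psa_series` samples the continuous PSA trace on a regular grid
and optionally applies multiplicative lognormal noise with unit mean and a
chosen coefficient of variation — useful for exercising protocol logic
against measurement-like series. The underlying model is deterministic and
noiseless, so noise defaults to off.

What the generator does *not* emulate: inter-patient variation in growth
rates or carrying capacities, measurement schedules of real PSA follow-up,
PSA secretion dynamics (production delay, serum decay), or the relative
prevalence of the matrix cases in any trial population. Passing tests
therefore show internal consistency of the model and protocol logic, not
fidelity to clinical PSA data.

## Problem sizes

The package's standard analyses are desk-scale: headline table
reproductions are ten deterministic runs (~1 s total); the full
(α, β) simplex scan uses a 0.05 lattice (231 points per category, ~15 s for
all three categories with shared MTD runs); sampler calibration uses 10 000
matrix draws.

## Known limitations

* PSA is instantaneous and deterministic: no serum decay, no production
  delay, no measurement noise in the protocol loop.
* Resistance is qualitative (a fixed T− type); no mutation between types,
  no quantitative dose response, and only full-dose on/off protocols.
* The equilibrium solver targets this three-type structure (K_T+ coupled
  linearly to x_TP); it is not a general Lotka-Volterra equilibrium tool.
* TCR is a proxy endpoint; the model makes no claim about time to
  radiographic or PSA progression.
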