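# Methods

## Model and partition

A well-mixed mass-action network with species split into a simulated set
(promoter-state indicators and mRNA) and a non-simulated set (the protein
pool), and reactions split accordingly: **G1** reactions are simulated
event by event and may change any species; **G2** reactions change only
non-simulated species.  Promoter occupancy is encoded one-hot — each
operator state is an indicator species in {0,1}, exactly one active — so
binding and unbinding are ordinary mass-action reactions and stoichiometry
vectors carry the whole model.  All rate constants are per-minute
frequencies; the defaults of the two built-in models are stated in the
README.

The genetic switch's transcription channel is deliberately a single
compound reaction with propensity `r0·S0 + r0·S1 + r·S2`, not three
reactions.  This keeps the hybrid's reaction-probability vector aligned
with the model's six-way reaction grouping (binding ×2, unbinding ×2,
transcription, mRNA decay).  A consequence worth noting: the
copy-number-independent part of the total propensity is
`β1·S1 + β2·S2 + r0·(S0+S1) + r·S2 + (K+k)·m`, i.e. no basal-transcription
contribution from the saturated promoter state.  The deterministic
mean-field equations use `dm/dt = r·S2 + r0 − k·m` (basal term independent
of occupancy) — a deliberate, slightly different convention kept for the
rate-equation layer only; the two differ by `r0 = 0.1` against a total of
~11 when S2 is occupied and the mean-field layer is qualitative.

## Closed-form G2 propagation

At fixed G1 state the G2 sub-system is a linear (immigration /
conversion / death) cascade, so a Poisson or product-Poisson law stays
Poisson with mean vector λ(t) obeying

* switch: `dλ/dt = K·m − q·λ`;
* cascade: `dλ1/dt = K·m − a·λ1`, `dλi/dt = a(λ_{i−1} − λ_i)`,
  `dλd/dt = a·λ_{d−1} − q·λd`.

The no-G1-event survival function is the lattice sum of the unnormalized
distribution `e^{−g(t)} ∏ h_i^{n_i}/n_i!`, giving `Q(τ) = exp(Σh_i(τ) −
g(τ))` with `g(0) = Σλ_i(0)` so that `Q(0) = 1` exactly (g is maintained
relative to its reset value; no additive constants accumulate across
steps).  The h-equations equal the λ-equations except in the terminal
stage, whose decay rate becomes `q̃ = q + Σ_i α_i S_{i−1}` (switch:
`q̃ = q + α1·S0 + α2·S1`); `dg/dt = K̃ − q·h_d` with `K̃` the constant part
of the total (G1+G2) propensity.  Substituting the ansatz into the
survival master equation fixes both effective rates; the package's
truncated-CME oracle verifies them to ~1e−13, and a `literal_printed`
variant of the cascade's `q̃` (without the `+q` term) is available for
comparison — ensemble validation shows it wrong by two orders of magnitude
in z-score.

Closed forms used in the production path:

* switch λ, h: single exponentials; g: the exponential-plus-linear form.
* cascade λ_i (i<d): finite exponential-polynomial sums; λ_d, h_d and
  `∫₀ᵗ h_d` reduce to `I_j(c,t) = ∫₀ᵗ e^{−cs} s^j ds`, evaluated by a
  truncated alternating series for `c·t ≲ j+4` (which also covers the
  `a = q` and `a = q̃` rate collisions as analytic limits) and by upward
  recursion otherwise.  `g` by adaptive quadrature of `h_d` (abs. tol.
  1e−10) is kept as the reference implementation and agrees with the
  analytic reduction to 1e−9.

## The hybrid cycle

1. **Waiting time.** `ln Q(τ) ≈ −b1·τ + b2·τ²/2` with `b1 = c0 + c1·λ_last`
   (the G1 propensity sum at the mean hidden count, `c0 + c1·n` being the
   G1 propensity sum) and `b2 = −c1·ḣ_last(0)`.  The fast path accepts
   `τ0 = ln(1/ξ1)/b1` when the first-order correction ratio
   `|τ1/τ0| = |(b2/b1)L/2 / (b1 − (b2/b1)L)| < ε` (default ε = 0.001,
   configurable); otherwise `Q(τ) = ξ1` is solved exactly: bracket by
   doubling, then safeguarded Newton on the closed-form `ln Q` to relative
   tolerance ~1e−13.  If `Q` never reaches `ξ1` (G1 silent) the realization
   coasts to the final time with λ relaxing analytically.
2. **Reaction identity.** Every G1 propensity at fixed G1 state is either
   constant or linear in the terminal hidden species, so the marginalized
   probabilities are `p = (const/c1)·⟨1/(n+A)⟩` per constant channel and
   `1 − A·⟨1/(n+A)⟩` for the binding channel, with `A = c0/c1`; they sum
   to one identically, even under the approximate inverse moment.  The
   inverse moment `⟨1/(n+a)⟩` is computed either exactly — series summation
   centred on the Poisson mode with term-ratio stopping at ~1e−17, immune
   to `e^{−λ}` underflow at large λ and analytically equal to the
   incomplete-gamma form `e^{−λ}B(a,λ)`, whose negative-argument branch is
   avoided on purpose — or by the three-term moment expansion
   `1/(a+λ) + λ/(a+λ)³ − λ/(a+λ)⁴` (production default), with automatic
   exact fallback when `a < 1` or `λ < 1`.  The expansion's truncation
   error is Θ((3λ²+λ)/(a+λ)⁴) relative: ≲1e−4 only for `(a+λ)⁴ ≳ 3e4·λ²`,
   which holds in the regimes the hybrid visits (the binding offsets `A`
   are ≥100 at the default rates) but not for small `a` with moderate λ.
3. **Reset.** The clock advances by τ, the G1 counts by the stoichiometry,
   and λ(τ) is carried unchanged through the reaction.  The ±1 hidden
   molecule exchanged by binding/unbinding is ignored in this default mode
   (relative error O(1/λ) per event, negligible for α ≪ 1 since binding
   events are rare relative to the pool size).  An exact validation mode
   propagates a truncated probability vector with the oracle and applies
   the literal updates: an up-shift for releases and a mass-conserving
   down-shift with pile-up at zero for removals (`P'(0) = Σ_{j≤w} P(j)`,
   `P'(n) = P(n+w)` for n ≥ 1 — the printed update operator reduces to
   this for w = 1).

## Exact SSA reference

Direct-method Gillespie on the full network: exponential waiting time
`τ = ln(1/r1)/a0`, reaction index = smallest cumulative-sum exceedance of
`r2·a0`.  Compound propensity channels are summed into their reaction
before selection, so the reference and the hybrid share the same reaction
granularity.  One root seed; realization *i* uses an independent child
stream derived by numpy seed-sequence spawning, making ensembles
reproducible and order-independent.  Trajectories store all events for
small runs; ensembles are recorded on a caller-supplied uniform grid by
zero-order hold to bound memory.

Both the SSA and the two hybrid loops have compiled (numba) kernels used
for ensembles; the pure-Python implementations define the semantics and
are held equal to the kernels by driving both with one pre-drawn uniform
stream and asserting identical trajectories.

## Numerical CME oracle

The verification module integrates the G2 master equation on a truncated
lattice (`n_max = mean + 10·sqrt(mean) + 20` initially).  Because the
generator at fixed G1 state is a constant sparse matrix, propagation uses
the Krylov matrix exponential (`expm_multiply`), which is exact to
machine rounding — the 1e−8-level total-variation comparisons against the
closed forms need that headroom, and it is why an implicit ODE integrator
was not used.  Truncation follows the finite-state-projection convention
(out-of-lattice flux is dropped); a breach of either the relative
boundary-mass bound (1e−12) or, for normalized runs, probability
conservation (1e−10) enlarges the lattice and restarts.  The joint-lattice
oracle is exercised for cascades up to d = 3 (the joint state space grows
geometrically); the d = 10 production model is verified component-wise
against the λ ODEs and by full-SSA ensemble comparison.

## Ensemble comparison conventions

Means are compared per species and grid time by
`z = (m_A − m_B)/sqrt(s_A²/N_A + s_B²/N_B)`; standard deviations the same
way with the delta-method standard error from the fourth central moment
(population convention, stated in the summary metadata).  Two calibration
rules, fixed from exact-vs-exact null experiments before the hybrid was
judged:

* For indicator (0/1) columns the std is a function of the occupancy
  fraction and its SE is meaningless near the boundary; std comparisons
  with fewer than 10 occupied or unoccupied runs in either arm are masked.
* A band of ±3 combined standard errors applied to ~150 correlated
  comparisons is breached occasionally by two independent exact-SSA
  ensembles (measured null maxima up to ~4.6 before masking, ~3.5 after).
  The switch validation (21 comparison times × 4 species, 1000 runs per
  arm) is asserted strictly at ±3; the oscillator validation (15 times ×
  6 species, 300 runs per arm) asserts that at least 99% of comparisons
  lie within ±3 and none beyond 4, plus matching oscillation peak count,
  peak times within one comparison step (50 min) and peak amplitudes
  within the 3-SE band.  A genuinely wrong hybrid (e.g. the
  `literal_printed` effective rate) produces |z| > 100 on most of the
  grid, so the allowance costs no practical power.

Histograms of integer counts use unit bins over the observed range;
two-sample χ² with adjacent bins pooled to ≥5 combined counts.

Validation scales: 1000 realizations per arm to t = 500 for the switch
(histograms at t = 150 and 300), 300 per arm to t = 700 for the
oscillator; recording every 5 min, moment comparisons every 25 min
(switch) / 50 min (oscillator) — roughly the systems' autocorrelation
times, so comparisons are not trivially redundant.  All validation seeds
are fixed constants in the test suite.

## Hidden-species recovery

The hidden mean obeys the closed linear system driven by the simulated
mRNA mean (`dn̄/dt = K·m̄ − q·n̄`, or the conversion chain for the
cascade).  `recover_hidden_mean` advances it exactly per grid interval
with an augmented matrix exponential under piecewise-linear `m̄(t)`, so the
map from `m̄` to `n̄` is linear to rounding (superposition is a test).  The
per-realization Poisson mean recorded by the hybrid is an unbiased
conditional-mean estimator of the hidden count, so its ensemble scatter
provides the standard error attached to the recovered curve.

## Synthetic fixtures and what the tests show

Property tests draw randomized-but-valid parameter sets (defaults jittered
log-uniformly within 3×) and hybrid states (random occupancy, mRNA ≤ 6,
Poisson means up to 150 with a deliberate sub-unit share to exercise the
exact-fallback path).  The built-in models *are* the study conditions: the
generator emulates nothing beyond them (no extrinsic noise, no cell
division, no measurement model), so passing tests demonstrate agreement
between the hybrid and the exact simulator of the stated mass-action
models, not fidelity to any experimental data set.

## Known limitations

* Only Poisson-solvable partitions are supported (linear G2 cascades with
  mass-action G1 coupling through the terminal species); there is no
  automatic detection of solvability for user-defined partitions, and no
  SBML import.
* The default reset ignores the ±1 protein of binding/unbinding; for
  binding rate constants approaching 1 the exact mode (switch only, slow)
  should be used to quantify the error.
* The moment-expansion inverse moment degrades for small `a` — the
  automatic fallback guards `a < 1`, but intermediate regimes (`a ~ 1–10`
  with large λ) silently carry relative errors up to ~1e−2; pass
  `inverse_moment="exact"` when that matters.
* Wall-clock advantage over the full SSA grows with the hidden pool size;
  for partitions that place the abundant species in G1 the hybrid has no
  edge.
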