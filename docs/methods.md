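# Methods

## Model

The package analyzes n-species Lotka–Volterra competition with an added
per-capita mortality term,

    dN_i/dt = r_i N_i (1 − Σ_j α_ij N_j) − δ N_i,     α_ii = 1,

where N_i is density normalized to species i's carrying capacity, r_i its
maximum growth rate (h⁻¹), α_ij the dimensionless inhibition of i by j, and
δ a mortality rate applied equally to all species. Mortality is realized in
two modes:

* **continuous death** — δ appears in the ODE;
* **serial dilution** — growth runs with δ = 0 for a cycle of T hours
  (default 24), then all densities are divided by a dilution factor DF.
  Equal per-cycle survival fractions force the correspondence
  δ = ln(DF)/T, which the package uses to put model and experiment on the
  same axis.

For a pair, substituting Ñ_i = N_i/(1 − δ/r_i) turns the mortality model
into a mortality-free LV model with effective coefficients

    α̃_ij = α_ij (1 − δ/r_j)/(1 − δ/r_i),    r̃_i = r_i − δ,

defined for δ < min r_i. Outcomes follow the classical rule: both α̃ < 1 →
stable coexistence; both > 1 → bistability (winner set by the starting
fraction, the unstable interior point is the separatrix); exactly one > 1 →
exclusion of the more-inhibited species. Because α̃_ij α̃_ji is independent
of δ, sweeping mortality moves a pair along a line of slope −1 in
(log α̃_12, log α̃_21) — the 45° trajectory — so a pair whose slow grower
dominates at δ = 0 must traverse coexistence (if α_12 α_21 < 1) or
bistability (if > 1) before the fast grower wins at high mortality. The
two crossing mortalities have the closed form
δ* = r_i r_j (1 − α_ij)/(r_j − α_ij r_i). A per-species mortality vector is
accepted everywhere a uniform δ is; it moves pairs along the same 45° line,
in a direction set by the rate differences.

**Discrete vs. continuous caveat.** The two modes are *not* exactly
conjugate processes; their outcomes coincide away from outcome boundaries.
Two genuine divergences, mapped empirically on 800 random pairs: (i) near
the viability bifurcation δ → r_i the continuous equilibrium 1 − δ/r_i
falls to zero while the discrete within-cycle orbit still saturates near
carrying capacity, which can flip exclusion/bistability calls; (ii) for
bistable pairs at large relative mortality (δ ≳ 0.4·min r) the two
processes' separatrices drift apart. The equivalence tests therefore define
"away from boundaries" as: |log α̃_ij| > 0.1 for both orientations, any
interior-point fraction within [0.10, 0.90], (r_i − δ)·T ≥ 5 for both
species, and δ ≤ 0.35·min r for bistable conditions. Inside that region the
survivor sets agree exactly (0 flips / 800 conditions at the defaults).

## Numerics

* Integrator: LSODA (stiffness-switching), rtol 1e-8, atol 1e-12 —
  exclusions drive densities toward zero and must not oscillate.
* Extinction threshold: normalized density 1e-10 (configurable). Pure LV
  exclusion is only asymptotic; finite populations go extinct, and the
  threshold makes finite-cycle exclusion realizable. Extinction is
  absorbing: a zeroed species never recolonizes.
* Serial runs record post-growth (pre-dilution) states — when an
  experiment plates. Convergence of a default 7-cycle run: composition
  change < 1e-4 (sup norm) over the last 3 cycles. Oracle-style runs stop
  early when the post-growth density vector changes < 1e-9 between cycles.
* Continuous runs checkpoint every 50 h and stop at a sup-norm change
  < 1e-9 or 5000 h.
* α̃ within 1e-9 of 1 is classified "degenerate", never put on an arbitrary
  side; α̃_12 α̃_21 within 1e-9 of 1 raises an explicit degenerate-equilibria
  signal (a continuum of fixed points).

## Outcome inference from colony counts

Endpoint compositions come from final-cycle counts; each fraction carries
the SD of the Beta(a+1, b+1) posterior (a = focal colonies, b = all
others). A species is called extinct in a condition when its endpoint count
is 0 or its fraction is below 0.005 (under one colony at the ~42-colony
platings; configurable). Replicate plates are pooled per starting
composition. Starts agreeing on an interior survivor set are called
coexisting when their endpoint fractions lie within 0.10 of their common
mean; starts reaching different survivor sets are called bistable — unless
the excess species of a non-converged start is still *significantly
declining* (net drop over the second half of the run exceeding
max(0.02, 2× the multinomial SE)), in which case that endpoint is treated
as a slow exclusion still in progress. Divergence only counts as
bistability when it is divergence to stable states; this mirrors reading
trajectory direction off a bifurcation diagram. A mixed
coexistence/exclusion bistability is reported and flagged `non_LV` — it is
not an outcome the LV model allows and is never coerced into one.

## Assembly rules and baselines

A candidate survivor set S is allowed iff every pair inside S coexists and
every species outside S is excluded by some member of S on some branch
(exclusion, or the losing side of a bistable pair). Bistable pairs
generate multiple allowed states; enumeration is exhaustive over 2^n
subsets (n ≤ 5). Predicted compositions: singleton → 1; pair → the
pairwise fractions verbatim; |S| ≥ 3 → the weighted geometric mean
f_i = (Π_j f_ij^{w_j})^{1/Σ w_j} with w_j the geometric mean of j's
pairwise fractions within S, normalized to sum to one. For trios this is
exactly w_2 = √(f_21 f_23); **for quads and larger the geometric-mean
weight is an extrapolation** — the natural generalization of the trio
weights — and is flagged as such here.

Baselines: the carrying-capacity prediction assumes all species always
coexist at fractions proportional to their monoculture endpoint densities;
the random baseline draws uniformly (flat Dirichlet) from the composition
simplex, one draw per case. How "random" should be constructed is
genuinely open; the flat simplex is this package's declared choice.

## Error statistics

Quantitative error = ‖predicted − observed‖₂ / √2, the maximum distance
between compositions (a species predicted extinct in fact dominating), so
errors live in [0, 1]. Scoring a community case: observed starts are
grouped by final survivor set and averaged within group; each group is
compared to the predicted state with the matching survivor set (or the
best-scoring state, flagged, when none matches); a case with multiple
observed states contributes the smaller error. The SEM unit is the case
(biological replicate after start-averaging). Qualitative error is the
fraction of species miscalled present/absent, scored against the
best-matching allowed state. Competitive score = a species' mean endpoint
fraction over its pairs (replicates averaged within pair first); its SE is
the SD of 5000 bootstrap scores resampling replicate-level pair outcomes.
The bootstrap resampling unit is declared here because only n and B are
conventionally reported. The growth-rate/score relationship is summarized
by an OLS slope with its standard error.

## Growth rates from OD curves

The primary estimator assumes exponential growth from the known starting
OD (equalized stock × initial dilution) to a threshold of OD 0.1 and
returns r = ln(0.1/OD₀)/t*, with t* linearly interpolated between the
15-minute samples; lag time is implicitly folded in. The explicit
alternative fits a line to log-OD over the window OD ∈ [0.02, 0.1]
(declared; at least 4 points), giving the exponential rate and a lag from
back-extrapolation to OD₀. Two numerical details matter at realistic
plate-reader noise (~0.002 OD): the window's lower bound sits at 10× the
noise SD so log-residuals stay small and symmetric, and window membership
is decided on a 5-sample moving average — selecting points on raw noisy
readings correlates the noise with inclusion at the window edges and
biases the slope downward by several percent. Even so a single curve
carries ~3–5% slope noise over the short window; accuracy claims hold for
the per-species average across dilutions and replicates, which is how the
estimator is deployed. The "effective rate" multiplies the exponential
rate by (T − λ)/T, the fraction of a dilution cycle spent growing — the
precise form of this correction is this package's declared choice and is
recorded in the method label of every output; it preserves rate ordering
among species with equal lags.

## Synthetic data: what it emulates, and what it does not

`sample_params` draws communities with a tunable growth/competitive-ability
tradeoff: r_i log-uniform on [0.25, 1.0] h⁻¹ (the range of daily-dilution
soil isolates), α_ij = 0.75·exp(γ(r_i − r_j) + ε_ij), ε ~ N(0, 0.35). With
the default γ = 2.5 slower growers carry a strong incoming advantage, so
slow growers dominate most pairs at δ = 0, coexistence windows are more
common than bistable ones (product of a random pair's coefficients is
usually < 1), and outcomes reverse as dilution increases — the regime the
analysis targets. γ = 0 gives tradeoff-free controls. Carrying capacities
are log-uniform on [5e8, 5e9] CFU/ml, lags uniform on [0.5, 4] h.

`simulate_experiment` reproduces the laboratory design: dilution factors
10–10⁶, 24-h cycles, 7 cycles, equal and 90–5–5%-style starts (pairs use
fractions {0.05, 0.5, 0.95}), day-0 inocula prediluted by the condition's
DF capped at 10⁵ (the harshest condition starts one decade denser to avoid
day-0 stochastic extinction), and plating that draws a Poisson(42) colony
total split multinomially across species. Observed fractions weight model
densities by absolute carrying capacity (plating counts cells; normalized
densities are not what a plate sees) — a deliberate model/observation
mismatch probing robustness; a switch (`abundance_weighting=False`)
disables it, since whether real comparisons are abundance-weighted is not
observable from composition data alone.

OD curves are flat at the starting OD for the species' lag, then logistic
to a per-species plateau drawn from [2.5, 3.5], sampled every 15 min for
50 h with additive Gaussian noise (SD 0.002). The plateau range is set by
an analytic constraint: a logistic curve crosses OD 0.1 later than a pure
exponential by ln(P/(P−0.1))/r, biasing the time-to-threshold rate by
ln(P/(P−0.1))/ln(0.1/OD₀); at the densest prescribed start (5.3 e-folds
below threshold) the 1%-recovery property of the estimator requires
P ≳ 2.1, which [2.5, 3.5] satisfies with margin.

**What passing tests do not show about real data:** the generator's noise
is plating noise only (no demographic stochasticity, pipetting error, or
cross-contamination); its interactions are exactly pairwise LV (no
higher-order interactions, pH or secreted-metabolite mechanisms), so
recovery benchmarks certify the inference/prediction machinery, not the LV
model's adequacy for any particular community.

## Benchmark problem sizes and margins

The recovery benchmark runs 20 communities of 3–5 species (seeded),
2 replicates, full 6-DF design; pair-outcome recovery is scored only on
*resolvable* conditions (`condition_is_resolvable`): |log α̃| > 0.15, a
mortality–growth gap |δ − r_i| > 0.08 h⁻¹ (so a dying species actually
crosses the extinction threshold — and a viable one becomes detectable —
within 7 cycles from the day-0 inoculum), and interior-point fractions
within [0.10, 0.90] in both normalized and abundance-weighted units
(outside that band an interior point is invisible to 90–5–5 starts and
~42-colony platings). The oracle-equivalence ensemble uses 220 conditions;
oracle runs start at composition {0.05, 0.5, 0.95} with unit total density
because dilute starts pass through a pure-exponential phase that distorts
fraction-space basins before interactions engage.

## Known limitations

* The assembly weight rule beyond trios is an extrapolation (above).
* Serial-dilution/continuous equivalence is regional, not global (above);
  the package reports both axes so users can see where they are.
* `call_pair_outcome` needs ≥ 2 starting fractions and cannot distinguish
  a separatrix outside the probed starts from plain exclusion — a limit of
  the design, not the code.
* The quantitative rules require coexisting fractions strictly inside
  (0, 1); inferred fractions at the detection limit propagate their bias
  into community predictions.
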