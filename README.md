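# dilucomp

Microbial competition under added mortality: simulation, inference, and
prediction for serial-dilution coculture experiments.

Periodic dilution of a batch coculture discards a fixed fraction of cells
every cycle and therefore acts as a tunable, species-blind death rate
δ = ln(DF)/T (DF the dilution factor, T the cycle length). `dilucomp`
implements the analysis built around that observation, for researchers
studying how community composition shifts along a mortality/dilution
gradient:

* **Dynamics** — the Lotka–Volterra competition model with mortality,
  dN_i/dt = r_i N_i (1 − Σ_j α_ij N_j) − δN_i (α_ii = 1), integrated in
  continuous-death and discrete growth/dilution modes, with fixed-point
  location and stability.
* **Phase analysis** — the re-parameterization into a mortality-free model
  with effective coefficients α̃_ij = α_ij (1 − δ/r_j)/(1 − δ/r_i).
  Outcomes follow the classical rule (both α̃ < 1: coexistence; both > 1:
  bistability; one > 1: exclusion), and because α̃_ij α̃_ji is independent
  of δ, increasing mortality moves every pair along a 45° line through the
  (log α̃_12, log α̃_21) phase plane — always toward the faster grower.
  Closed-form critical mortalities δ* = r_i r_j (1 − α_ij)/(r_j − α_ij r_i)
  bound the intermediate coexistence/bistability window.
* **Outcome inference** — qualitative outcome calls and equilibrium
  fractions from colony-count time series, with beta-posterior error bars
  σ = √[(a+1)(b+1) / ((a+b+2)²(a+b+3))] on compositions.
* **Assembly rules** — survivor-set prediction for 3–5-species communities
  from pairwise outcomes (a species survives iff it coexists pairwise with
  every other survivor; bistable pairs yield alternative states), plus the
  quantitative weighted-geometric-mean composition rule
  f_1 = (f_12^{w_2} f_13^{w_3})^{1/(w_2+w_3)}, w_2 = √(f_21 f_23), and
  carrying-capacity and flat-simplex random baselines.
* **Metrics** — normalized L2 prediction error (max error √2), qualitative
  miscall rates, per-species competitive scores with bootstrap errors, and
  the growth-rate/competitive-score regression whose slope flips sign as
  dilution increases.
* **Growth rates** — time-to-threshold (OD 0.1) and explicit lag/exponential
  estimators for OD600 curves.
* **Synthetic data** — a seeded generator for ground-truth communities with
  a growth/competitive-ability tradeoff and a full simulator of the
  serial-dilution design (6 dilution factors 10–10⁶, 24-h cycles, 7 cycles,
  equal and 90–5–5 starts, ~42-colony multinomial platings), so the entire
  pipeline is testable against known truth.

See `docs/methods.md` for model assumptions, margins, numerical choices,
and known limitations.

## Worked example

Run the demo pipeline (synthesize a 3-species tradeoff community, simulate
the design, infer outcomes, predict, score):

```python
from dilucomp import RunConfig, run_pipeline
run_pipeline(RunConfig(outdir="runs/demo", seed=7, n_species=3))
```

or equivalently `dilucomp run --config config.yaml`. The run directory then
contains, among other artifacts, `error_report.csv`:

```
  prediction_type stratum  mean_error      sem  n
         assembly    trio    0.045815 0.011137 12
carrying-capacity    trio    0.340545 0.035710 12
           random    trio    0.365821 0.057176 12
```

mean normalized prediction errors over 12 community cases (6 dilution
factors × 2 replicates): the assembly rules predict observed community
composition to within ~5% of the maximum error, an order of magnitude
better than assuming monoculture carrying capacities or guessing uniformly
on the simplex. `growth_score_regression.csv` shows the competitive-score
slope against growth rate:

```
 dilution_factor    slope  slope_se
            10.0 -5.47996  1.039960
          1000.0 -5.36749  0.967921
        100000.0  1.14672  1.020060
       1000000.0  7.45389  0.291168
```

negative at low dilution (slow growers are the strong competitors — the
tradeoff), flipping positive once mortality is high enough to favor fast
growth. The community "subway map" (`dilucomp render`, species ordered
fastest → slowest) shows the same story as survivor sets:

```
DF           10       100     1000     10000   100000    1e+06
sp2           ·        ·        ·        ·        ●        ●
sp3           ●        ●        ●        ●        ●        ●
sp1           ●        ●        ●        ●        ●        ·
```

the slowest grower (sp1) is present at low dilution and extinct at DF 10⁶,
while the fastest (sp2) only appears at DF ≥ 10⁵.

## Command line

`dilucomp` exposes thin subcommands over the library: `synth`, `simulate`,
`sweep`, `infer`, `predict`, `score`, `run`, `render`; all accept `--seed`
and write plain CSV/YAML. Exit codes: 0 success, 2 config error, 3 data
error, 4 numerical failure.

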