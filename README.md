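# fermbed

Batch-wise, multi-objective Bayesian experimental design (BED) for optimizing
fermentation media — built around the concrete case of growing tobacco BY-2
suspension cells in stirred-tank batch fermentations, where each experiment
takes a week, only four reactors run in parallel, and replicate runs are
noisy. The package proposes, four media at a time, the compositions most
likely to push out the Pareto front of two maximized objectives: the final
fresh-mass concentration (g/L) and the fresh-mass increase rate (g/(L·h)).

It is written for bioprocess engineers running real campaigns from CSV
experiment sheets, and for method developers who want a self-contained,
dependency-light implementation of noisy multi-objective Bayesian
optimization with an end-to-end testable synthetic oracle.

## The method

The design space is a box `X ⊂ R⁵`: sucrose 20–175 mM, ammonium 5–60 mM,
phosphate 2–15 mM, nitrate 5–150 mM and inoculum fresh mass 5–22 g/L. The
unknown response `f: X → R²` (final FM, FM increase) is observed with noise.
Each objective gets an independent Gaussian-process surrogate with constant
mean, homoscedastic Gaussian noise and an ARD Matérn-5/2 kernel

    k(x, x′) = σ² (1 + √5 r + 5r²/3) exp(−√5 r),
    r² = Σᵢ (xᵢ − x′ᵢ)² / ℓᵢ²,

with hyperparameters (ℓ₁…ℓ₅, σ², σ_n²) re-estimated every iteration by
multi-restart maximization of the log marginal likelihood. The per-dimension
length scales ℓᵢ double as relevance estimates for the five medium
parameters.

Batches of q = 4 experiments are chosen by q-Noisy Expected Hypervolume
Improvement (qNEHVI): the value of a candidate set is the Monte-Carlo
expectation, over joint posterior draws of the latent objectives at all
observed and candidate inputs, of the gain in Pareto hypervolume (area
dominated above the reference point (0 g/L, 0 g/(L·h))) that the candidates
add to the drawn incumbent front. Sampling the incumbent front instead of
trusting the noisy measurements is what makes the criterion robust to
replicate scatter. The inner maximization uses common random numbers, Sobol
multi-start and Nelder-Mead refinement; batch members are selected
sequentially-greedily by default (a literal "top-q local optima" mode is also
provided). A closed-form bi-objective EHVI and an exact 2-D hypervolume sweep
back the Monte-Carlo machinery and its tests.

Because the wet lab is slow, the package ships a synthetic fermentation
oracle: a Monod-type multi-substrate ODE model in which nitrate (required but
inhibitory at high levels) and phosphate set the growth rate, while sucrose
and the ammonium+nitrate nitrogen pool cap the final biomass, with
multiplicative lognormal noise on every daily fresh-mass sample. It exists so
the whole loop — including four-iteration campaigns — runs and is tested
without a bioreactor; see `docs/methods.md` for its equations, calibration
and limits.

## Worked example

A complete campaign round against the bundled oracle:

```bash
fermbed make-historical --out batch0.csv --n 10 --seed 7
printf 'q: 4\noptimization_iterations: 4\nseed: 42\n' > config.yaml
fermbed init --historical batch0.csv --config config.yaml --out campaign/
fermbed propose --campaign campaign/
```

which prints the four proposed media for iteration 1:

```
I1_01: sucrose=175, ammonium=5, phosphate=15, nitrate=116, start_fm=22
I1_02: sucrose=175, ammonium=5, phosphate=2, nitrate=5, start_fm=5
I1_03: sucrose=175, ammonium=5, phosphate=15, nitrate=150, start_fm=5
I1_04: sucrose=43.5, ammonium=25.4, phosphate=12.1, nitrate=125, start_fm=12
```

Already at iteration 1 the acquisition probes the sucrose-rich corner (high
final-yield cap) at several nitrate/inoculum levels while keeping one
moderate composition: maximal spread of plausible front improvements, not a
single guess. "Run" the experiments with the simulator and feed the results
back:

```bash
fermbed simulate --sheet campaign/observations.csv --out results1.csv --seed 101
fermbed ingest --campaign campaign/ --results results1.csv
fermbed report --campaign campaign/
```

```
campaign at iteration 1, 14 completed records
{
  "hypervolume": 521.0791904340141,
  "pareto_size": 1,
  "best_observed_suggestion": "B0_04"
}
```

The hypervolume (g/L × g/(L·h) area above the reference point) is the running
score of the campaign; `report.json` in the campaign directory additionally
holds per-iteration five-number summaries of every parameter and objective
(the convergence picture), the Pareto-front membership, the hypervolume
trail, and box plots of parameters and objectives by iteration. Repeat
`propose → simulate → ingest` until the four-iteration budget is spent, or
let `fermbed run --campaign campaign/` close the loop automatically. For a
real campaign, replace the `simulate` step with your bioreactor runs and fill
the proposed rows of the sheet by hand.

The same workflow is available as a library: `Campaign.init(...)`,
`.propose()`, `.ingest(...)`, `.report()`, with `fermbed.gp`,
`fermbed.pareto`, `fermbed.acquisition` and `fermbed.simulator` usable on
their own.

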