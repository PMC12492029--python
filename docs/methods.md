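# Methods

This note records the models, numerical choices and limits behind fermbed:
what is being optimized, how the surrogates and the acquisition are defined,
what the synthetic fermentation oracle does and does not emulate, and which
design decisions were genuinely open.

## Problem setting

A batch fermentation campaign optimizes five controllable medium/inoculum
parameters (sucrose, ammonium, phosphate, nitrate in mM; starting fresh mass
in g/L) against two maximized objectives measured per run: the final
fresh-mass concentration FM(T) in g/L and the fresh-mass increase
(FM(T) − FM(0))/T in g/(L·h), with T ≈ 7 days. Experiments are expensive
(one week each), parallelism is fixed at q = 4 reactors, and replicate runs
scatter substantially, so the loop must be noise-aware and batch-wise. All
file I/O uses named CSV columns (`sucrose_mM`, …, `final_fm_g_L`,
`fm_increase_g_L_h`, `status`), so column order never silently matters;
out-of-bounds historical records are warned about and retained, never
dropped, because legacy data commonly sits at or beyond the current bounds.

## Surrogates

One GP per objective, independent across objectives. Inputs are affinely
mapped to the unit cube; targets are standardized to zero mean / unit
variance per refit (a zero-variance guard handles constant targets). The
kernel is Matérn-5/2 with one length scale per input dimension (ARD) times a
signal variance, plus homoscedastic observation noise:

- mean: constant, fixed at the standardized-target mean (0). After
  standardization a jointly optimized constant is redundant at these sample
  sizes (N ≈ 10–30), so it is not a free parameter.
- hyperparameter search: log-parameterized L-BFGS-B with analytic gradients
  of the log marginal likelihood, 8 restarts (1 canonical start + 7 scrambled
  Sobol points over the log-bounds), bounds ℓ ∈ [0.05, 10] (normalized
  units), σ² ∈ [0.05, 20], σ_n² ∈ [10⁻⁶, 1]. The 10⁻⁶ noise floor keeps the
  covariance invertible when replicates coincide.
- numerics: Cholesky with a jitter ladder (0, 10⁻⁸, 10⁻⁶, 10⁻⁴, then a hard
  error); posterior variances are clamped at 0 from above −10⁻⁸.
- "noise" means observation noise on the outputs, one learned variance per
  objective. Errors-in-inputs (mispipetted media) is out of scope.

Choosing two independent GPs over a joint multi-output model was an open
decision: nothing in the acquisition requires cross-objective correlation,
and at N ≈ 10–30 a coregionalized model mostly adds variance to the
hyperparameter estimates.

## Pareto bookkeeping

Maximization convention throughout. The 2-D hypervolume is computed exactly
by sorting on the first objective and summing staircase rectangles; points on
or below the reference point contribute zero (half-open dominated region), so
hypervolume improvement is nonnegative by construction. Three or more
objectives are rejected explicitly rather than approximated. The default
reference point is (0 g/L, 0 g/(L·h)) — the objectives' physical minima —
and is configurable.

## Acquisition

qNEHVI, Monte-Carlo form. For a candidate set C the value is

    α(C) = E[ HV(front(F_obs ∪ F_C)) − HV(front(F_obs)) ],

where F_obs, F_C are joint posterior draws of the latent objectives at the
observed inputs and at C. Implementation details that matter:

- Common random numbers: one base-sample set per proposal run. The draws at
  the observed inputs are generated once; candidate draws come from the exact
  Gaussian conditional given those fixed observed draws (Schur complement,
  eigenvalue clipping for singular blocks). Consequences: the inner
  optimization sees a deterministic objective; every per-draw improvement is
  nonnegative; growing a pending batch increases the value draw by draw; and
  a candidate duplicating an observed input has exactly zero conditional
  spread and hence (at the noise floor) zero value.
- Defaults: 512 draws during optimization, 4096 for audited values; 16
  restarts from a scrambled Sobol design refined by bounded Nelder-Mead
  (derivative-free on purpose — the Monte-Carlo objective is cheap and
  gradients would pin the implementation to an autodiff stack).
- Batch construction: sequential-greedy by default — point k+1 maximizes the
  acquisition of the pending k points plus itself. A "top-q" mode (the q best
  distinct local optima of the single-point acquisition) is provided because
  both readings of batch selection exist in practice; greedy conditioning is
  the default as it matches how qNEHVI is defined. Pending duplicates are
  rejected at 10⁻⁶ normalized distance, falling back to the next-best
  restart.
- A closed-form bi-objective EHVI (vertical-strip decomposition; each strip
  contributes E[width]·E[height], two Gaussian excess integrals) serves as
  the exact oracle for the Monte-Carlo path in the tests.

## Campaign mechanics

A campaign directory holds the config snapshot (YAML), the experiment sheet
(CSV), serialized models (JSON), per-iteration proposal sidecars and reports.
Iteration 0 is the historical batch (default expectation: 10 runs);
iterations 1–4 are optimization rounds (the default budget is four, matching
one month of reactor time); later rounds can be ingested as plain
confirmation data with externally chosen media. Termination is by iteration
budget, plus an optional off-by-default stall rule (relative hypervolume gain
below 1% for two consecutive iterations). Failed runs stay in the sheet but
are excluded from fitting. All randomness flows from the campaign seed via
`numpy.random.SeedSequence((seed, iteration, stream))`, which is why a re-run
from the same sheets reproduces proposals bit for bit.

Reporting deliberately mirrors how such campaigns are read: per-iteration
five-number summaries of every parameter and objective (the convergence
picture), the Pareto set (authoritative), the hypervolume trail, and — as a
suggestion only — a single "best observed" record under a stated
scalarization (sum of range-normalized objectives minus 0.1 × mean
normalized nutrient concentration, the penalty encoding a mild preference for
cheaper media).

## Synthetic fermentation oracle

The oracle exists so the loop is testable end to end; it is calibrated to
qualitative behaviour, not to any particular wet-lab trajectory. State
X (fresh mass, g/L) and medium concentrations S (sucrose), N (nitrate),
A (ammonium), P (phosphate):

    μ = μmax · N/(K_N+N) · K_IN/(K_IN+N) · P₀/(K_P+P₀) · A₀/(K_A+A₀) · S/(K_S+S)
    X_cap = X₀ + min(Y_S·S₀, Y_NH4·A₀ + Y_NO3·N₀)
    dX/dt = μ X max(0, 1 − (X/X_cap)^s)
    dS/dt = −(1/Y_S) dX/dt
    dN/dt = −(1/Y_NO3) dX/dt   once growth exceeds the ammonium-funded
                                increment Y_NH4·A₀, else 0
    dA/dt = −k_A A,   dP/dt = −k_P P

Ammonium and phosphate are taken up quickly into implicit internal pools
(hence first-order disappearance from the medium while the growth law sees
their initial concentrations); a full cell-quota model was deliberately
avoided. Nitrate is required yet inhibitory at high concentration, and is
drawn down only after the internal ammonium pool is spent — this ordering is
what makes the ammonium term of the nitrogen cap actually bindable, so
reducing ammonium lowers the final yield. The cap exponent s sharpens the
logistic factor so growth is essentially unperturbed until near the cap;
with a plain logistic (s = 1) a lower cap would depress the 4-day growth rate
long before the yield difference appears, contrary to the intended
sucrose/ammonium behaviour ("cap the yield, spare the rate").

Defaults (all overridable via YAML): μmax = 0.03 h⁻¹ (BY-2 doubling time
≈ 25–30 h), K_N = 5 mM, K_IN = 150 mM, K_P = 2 mM, K_A = 0.25 mM, K_S = 1 mM,
Y_S = 2.0, Y_NH4 = 1.0, Y_NO3 = 3.2 g/(L·mM), k_A = k_P = 0.05 h⁻¹, s = 12,
horizon 168 h, RK4 step 0.5 h (fixed-step for bit-reproducibility; halving
the step moves FM(168) by < 0.03%), daily sampling, lognormal multiplicative
noise with CV = 0.10 on every sampled FM value. The constants were calibrated
once so that a mid-range medium (100/20/5/40 mM, 15 g/L) crosses 100 g/L
between days 3 and 6 and finishes between 100 and 200 g/L, and so that the
contract suite holds: nitrate 10→60 mM raises and 60→150 mM does not raise
the 4-day rate; phosphate 2→10 mM raises it; halving sucrose or cutting
ammonium 40→10 mM moves the 4-day rate by < 5% while lowering the final
yield; zero sucrose or zero ammonium means zero growth; fresh mass is
monotone and cap-bounded. K_P in particular is large enough that phosphate
remains rate-relevant across its whole 2–15 mM design range rather than
saturating at the low end.

What the oracle does not emulate: dry-mass dynamics and the fresh/dry-mass
ratio, semi-continuous feeding, assay noise on nutrient measurements,
day-to-day drift between reactors, or quantitative agreement with any real
BY-2 dataset. Passing the loop tests therefore demonstrates that the
machinery optimizes a plausibly-shaped noisy fermentation response — not
that it would reproduce a specific laboratory outcome.

## Benchmark and test problem sizes

The closed-loop benchmark compares, per seed, a full adaptive campaign
(10 historical + 4×4 adaptive runs) against the same historical data plus 16
scrambled-Sobol media, both scored by observed-front hypervolume over (0, 0).
For these desk-scale runs the acquisition uses 10 restarts, 384 draws and a
120-evaluation refinement budget per restart — enough that the adaptive arm's
advantage is limited by the experimental budget rather than by the inner
optimizer — while the module defaults stay at 16/512/150. Ten paired seeds
are used in the tests and the acceptance script. Monte-Carlo oracles in the
test suite are judged at 3 standard errors per comparison, with two caveats
applied where plain 3σ would be statistically wrong: the maximum of 50
independent deviations is allowed 4σ, and a small absolute floor (10⁻⁴
hypervolume units) covers the regime where the true acquisition value is a
few 10⁻⁶ and no finite draw set lands in the improving region.

## Known limitations

- Box constraints only; no mixtures, integrality or feasibility modelling.
- Two objectives only; the exact hypervolume sweep is 2-D by design.
- Independent-GP surrogates ignore cross-objective correlation (the two
  objectives are in fact strongly correlated in this system; qNEHVI does not
  need the correlation, but a joint model could be more sample-efficient).
- The acquisition optimizer is derivative-free; at much higher dimensions or
  larger q a gradient-based reparameterized sampler would scale better.
- Asynchronous ingestion (acting before a full batch resolves) is not
  supported; partial results park the campaign at the current iteration.
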