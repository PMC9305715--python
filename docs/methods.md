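# Methods

## Model

The unit of analysis is a population of `n` identical sinks drawing sugars
from one source through a shared phloem pathway.  Three relations define the
dynamics:

1. **Flow** `F = k·C·(C − Cf)` with `k = κ·n^α`.  This is a Münch-flow
   approximation in which turgor pressures are taken proportional to sugar
   concentrations, so the pressure-driven mass flow reduces to a conductance
   times a concentration-gradient term.  Xylem water relations, pressure
   dynamics and the distinction between symplastic and apoplastic unloading
   pathways are deliberately outside the model.
2. **Unloading** `U = n·s·Vm·Cf/(Km + Cf)`: Michaelis–Menten kinetics of the
   carriers moving sugar from sink phloem into sink tissue, scaled by total
   sink dry mass `n·s`.
3. **No phloem storage**: `F = U` at every instant.  Substituting gives a
   quadratic in `Cf`,

       A·Cf² + [A·(Km − C) + n·s·Vm]·Cf − A·C·Km = 0,   A = κ·n^α·C,

   whose unique positive root is the sink phloem concentration.  The root
   always satisfies `0 < Cf < C`.

Individual dry mass grows as `ds/dt = (1 − r)·U/n` from `s(t0) = s0`, where
`t0` is the hour at which population size becomes fixed (end of cell
division, anthesis, or thinning, depending on the level) and `r` is the
fraction of unloaded sugar respired.  Fresh masses are `M = s/DMC` and
`TM = n·M`.

Two regimes are density-independent by construction and are used as analytic
oracles in the tests: at `α = 1` all coefficients of the quadratic scale
linearly in `n`, so `Cf` and hence `U/n` and `s(t)` do not depend on `n`;
and when `Km ≪ Cf` the unloading saturates at `U/n = s·Vm`, giving
exponential growth `s(t) = s0·exp((1−r)·Vm·t)` when supply is non-limiting.

## Parameters

| name | meaning | units | default / range used |
|------|---------|-------|----------------------|
| κ    | conductance of a single-individual population | cm⁶ g⁻¹ h⁻¹ | level-dependent, searched 1e-7–1e4 |
| α    | conductance–size exponent | – | searched 1e-4–1 |
| Vm   | maximal unloading rate per unit dry mass | h⁻¹ | searched 1e-5–1e-2 |
| Km   | Michaelis constant of unloading | g cm⁻³ | searched 1e-6–0.1 |
| r    | respired fraction of unloaded sugar | – | 0.16, fixed |
| DMC  | dry matter content of sink tissue | – | measured per dataset, 0.06–0.24 |
| C    | source phloem concentration | g cm⁻³ | 0.1 below plant level |
| b, d | steepness / midpoint of the logistic decline of C with plant density | –, individuals | plant level only |

A single respiration fraction is used; growth and maintenance respiration
are not separated.  `C` is constant in time (no seasonal source dynamics)
and `n` is constant over a simulation (populations fixed after `t0`).  `n`
is accepted as a positive real, since observed population sizes are often
means (e.g. 5.7e6 cells).

## Numerics

- **Quadratic root.**  The positive root of the `Cf` quadratic is computed
  with the q-formula (`q = −(b + sign(b)·√(b²−4ac))/2`, root `c/q` or
  `q/a`).  With demand `n·s·Vm` up to ~15 orders of magnitude away from
  supply `A·C`, the textbook formula subtracts nearly equal numbers and can
  lose all significant digits; the q-formula keeps the relative error at the
  1e-15 level across the whole fitted parameter box (checked against an
  independent bracketing root-finder on `F(Cf) = U(Cf)`).
- **Integration.**  Explicit first-order (forward Euler) at `dt = 1 h`, the
  model's native time step; `dt` is configurable, and halving it changes
  final mass by well under 1% on the reference scenario with the error
  shrinking linearly in `dt`, as expected of a first-order scheme.
- **Overflow guard.**  `n^α` is evaluated in log space for `n > 1e6` so
  cell-level populations lose no precision.
- **Bookkeeping.**  The integrator guarantees, bit-exactly, that
  `s_end − s0` equals the sum over steps of `dt·(1−r)·U/n` accumulated in
  integration order (`GrowthTrajectory.mass_balance_gap() == 0.0`); the
  algebraically rearranged identity `(s_end − s0)·n/(1−r) = Σ U·dt` holds to
  1e-12 relative, the residual being float reassociation only.
- **Degenerate inputs** (non-positive κ, Vm, Km, s0, `n < 1`,
  `duration` not a whole number of steps) raise a typed invalid-parameter
  error; non-finite integration states raise an error carrying the step
  index.  During estimation these become a finite penalty (1e12 g²) so the
  stochastic search continues.

## Density-dependence index

`DD = −[(M(n_min) − M(n_max))/M̄]·[n̄/(n_min − n_max)]` uses only the
endpoint masses; the means `M̄` and `n̄` are therefore taken as endpoint
means, keeping the formula self-contained (grid means over a whole
density grid are available as an option).  "Maturity" is the state at the
final integration step; no maturity-detection rule is applied.
Compensation is classified from the endpoint population masses with a
relative tolerance band (default 0.05, configurable): `under` if `TM`
rises by more than the band, `over` if it falls by more, `exact` otherwise.
The index can be computed either from model-predicted endpoint masses or
directly from observed masses (the `dd` command); both modes are exposed
because either convention is defensible for field data.

DD responds to the physiology as follows, on the reference scenario
(populations of 1–20, 50 days, `C = 0.1`, `s0 = 3 g`, `DMC = 0.16`): it
increases with sink demand `Vm` and decreases with `α` monotonically across
the whole fitted parameter box.  In `κ` and `Km` the response is monotone
only within the supply-limited regime: DD vanishes at *both* conductance
extremes — no supply means no growth and nothing to compete for, while
unlimited supply drives `Cf` toward `C ≫ Km` and unloading saturates — so
DD is unimodal in `κ`, and in demand-saturated corners of the box a larger
`Km` can *raise* DD by re-introducing supply limitation.  This is the
model's own behaviour, not a numerical artefact, and the sensitivity-grid
test records it.

## Estimation

- Objective: sum of squared errors of individual fresh masses (g², natural
  scale, no log transform), at the observation times for seasonal series or
  at the final step for maturity cross-sections.  When population masses are
  present they are included as residuals rescaled to the per-individual
  scale, `(TM_pred − TM_obs)/n`, with weight 1.0 — comparable units, no
  domination by the population column; the weight is configurable and the
  column optional, since whether population totals entered the original
  objectives is not documented.
- Search space: log10 for κ, Vm, Km (each spans ≥ 3 decades across levels),
  linear for α, b and d.  Default boxes are the fitted ranges above; plant
  fits add `b ∈ [0, 1]` and `d` within the observed density range.
- Optimiser: real-coded GA — population 50, 300 generations, binary
  tournament selection, BLX-0.5 blend crossover (probability 0.9), per-gene
  Gaussian mutation (probability 0.05, σ = 0.1 of the search width),
  elitism 2 — all configurable.  Equivalence with the original estimation
  procedure is at the level of "real-coded GA minimising SSE", not
  operator-for-operator, since the original operator settings are not
  reported.  Every run is reproducible from its integer seed; multi-restart
  fits (default 15) derive distinct sub-seeds from one master seed and keep
  all solutions for ensemble analysis, flagging the best by SSE.
- Identifiability: on noiseless cross-sections spanning one decade of `n`
  with bounds a decade around the truth, the best-of-15 fit recovers the
  observed curves to RRMSE < 1e-4 and `α` to within ~0.01.  On
  density-independent data (generated at `α = 1`) the parameters are *not*
  identifiable and the fits fall into the two expected degenerate families —
  `α ≈ 1`, or low demand with `Km` negligible — both reproducing the flat
  density response exactly.

## Synthetic data

The generator emulates the *structure* of the field datasets the analysis
assumes — designs, population-size ranges, scenario constants — because no
original tables are deposited.  Twelve fixtures cover five organisation
levels: three tomato pericarp-cell seasonal series (truss positions;
fruit-load manipulation in two cultivars), two peach mesocarp-cell maturity
cross-sections at contrasting fruit loads, apple and sarsaparilla
seed cross-sections, grape and dogwood cluster cross-sections (the dogwood
truth has `α = 1`), peach and apple fruit-per-plant cross-sections, and a
peach orchard plant-density cross-section with logistic source decline.
Truth parameters were chosen once, inside the per-level fitted ranges, to
give realistic masses and growth multiples (e.g. tomato pericarp cells of
~1e-5 g fresh in fruits of 50–300 g; 2-g grape berries; 30-kg tree yields);
seed- and plant-level truths have high `Vm`/low `Km` (strong sink demand),
cell- and cluster-level truths are closer to saturation, reproducing the
strong-vs-weak density-dependence contrast between those levels.

Observation noise is multiplicative lognormal with unit mean, CV 0.10 by
default — masses are positive and measurement scatter scales with size;
no noise model is documented for the original data, so this is a standard
choice for growth data, and `cv=0` gives exact model output for round-trip
tests.  One master seed drives per-fixture derived seeds.

What the generator does **not** emulate: measurement protocols (cell
dissociation, dissection), the pre-`t0` cell-division phase, seasonal source
dynamics, between-individual heterogeneity within a population, and any
correlation structure in the errors.  Passing tests on these fixtures
therefore demonstrate internal consistency of the pipeline — the estimation
machinery recovers known truths from data with the assumed structure — not
that the model is correct for any particular field dataset.

## Problem sizes

The test suite and the reproduction script run at desk scale: 1000 random
draws for the root-solver check, a 5⁴ sensitivity grid evaluated at the two
endpoint densities only, 15-restart GA fits on six-point cross-sections with
1500–2400 hourly steps per simulation, and the twelve-fixture suite.  The
hourly Euler kernel is numba-compiled, which keeps a full 15-restart fit
under two minutes on one CPU.

## Known limitations

- The model is continuous and deterministic; demographic stochasticity in
  `n` and individual heterogeneity are out of scope.
- DD monotonicity in `κ` and `Km` holds only in the supply-limited regime
  (see above); global claims across all organisation levels at once mix
  regimes.
- `b` and `d` of the logistic source are only weakly identifiable from a
  single density cross-section; fits at plant level should be read as a
  family of compensating solutions.
- The GA is a global heuristic: with wide (non-informative) bounds,
  individual restarts may stall on flat objective regions — hence the
  mandatory multi-restart protocol.
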