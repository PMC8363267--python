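# Methods

## The model

`synerk` simulates a single, well-mixed compartment containing a mass-action
reaction network in which three inputs — free calcium, cAMP and the βγ
subunit of inhibitory G protein (Giβγ) — converge on doubly phosphorylated
ERK (ppERK), the readout used throughout.  Species are declared with total
concentrations in nM; every reaction is an elementary step of order at most
two per side.  Counts and concentrations are linked through the compartment
volume, n = c·N_A·V (1 nM in the default 4 µm³ compartment is ≈2.4
molecules), so spine-sized volumes (0.1–0.8 µm³) are intrinsically noisy
while large volumes recover the deterministic mass-action limit.

The package is built to carry the full published parameterisation of the
five-pathway ERK model as plain tabular text (a species table plus one or
more reaction tables, loaded with `load_network`).  Because those tables are
distributed separately, the repository ships a **reduced fixture network**
(13 species, 18 reactions, `build_fixture_network`) that reproduces the
structural motifs the analyses depend on:

1. **Ultrasensitive kinase switch.**  A CaMKII-like kinase CK is
   phosphorylated by calcium (`ck_act`, 2·10⁻⁴ /nM/s) and by its own active
   form (`ck_auto`, 2.5·10⁻³ /nM/s — positive feedback), and
   dephosphorylated by a small phosphatase pool PP (20 nM) through an
   explicit enzyme–substrate complex (Km ≈ 0.3 nM, Vmax = 4 nM/s).  The
   saturable phosphatase makes the off state stable against basal calcium
   yet allows the feedback to outrun dephosphorylation once a threshold is
   crossed, after which pCK remains high far beyond the stimulus — the
   fixture's analogue of CaMKII ultrasensitivity under PP1 control.  With
   0.5 µM calcium the duration threshold emerges at ≈5.5 s; with 1 s pulses
   the amplitude threshold falls between 1.5 and 2 µM.  `pp_concentration`
   rescales the phosphatase pool (the analogue of varying the PP1:CaMKII
   ratio): more phosphatase raises the threshold and flattens the
   dose–response.
2. **Linear cAMP branch.**  cAMP activates a GEF (Epac-like), the active GEF
   loads a GTPase pool (GtGDP→GtGTP), and GtGTP phosphorylates ERK.  All
   steps are first order in the input, so ppERK AUC is close to proportional
   to cAMP exposure.
3. **Competition for a shared substrate.**  The Giβγ branch and the GEF
   branch (and the switch output) all draw on the *same* GtGDP pool, so
   combined stimulation produces less ppERK than the sum of the single-branch
   responses — the mechanism behind sublinear summation of the cAMP
   pathways.
4. A small graded calcium→GTPase reaction (RasGRF-like, `gt_act_ca`) keeps
   sub-threshold calcium from being silent.

Basal conditions are tuned to the physiological resting points: free
calcium 50 nM (source 25 nM/s against a 0.5 /s clearance lump) and cAMP
30 nM (3 nM/s against 0.1 /s).  The ERK pool is 240 nM with a basal ppERK
near 48 nM after equilibration.

## Propagators

Three interchangeable methods consume the same network and protocol:

* **Exact SSA** (`ssa_exact`) — Gillespie's direct method over directed
  reaction channels (reversible reactions are split).  Propensities use
  count-space combinatorics (n(n−1)/2 for homodimeric channels).
  Conserved totals are integer-exact along every path.
* **Adaptive tau-leaping** (`tau_leap_adaptive`, default) — leap lengths
  bounded so the expected relative propensity change per leap stays below
  `leap_tolerance` (default 0.1), via the standard species-based selection
  (bound ε·xᵢ/gᵢ on both the mean and variance of the per-species change).
  Channels within ten firings of exhausting a reactant are *critical* and
  fire singly; when the admissible leap is shorter than ~10 exact events the
  kernel falls back to exact SSA steps for a window; candidate leaps that
  would drive a population negative are rejected and retried at half the
  leap.  Because updates are integer multiples of the stoichiometry,
  conservation remains exact.
* **ODE oracle** (`ode`) — the mass-action rate equations integrated with
  LSODA at relative tolerance 10⁻⁸ (the network is stiff: binding steps are
  fast against the phosphatase and hydrolysis timescales).  Tiny negative
  excursions from the solver are clipped to zero.

Both stochastic kernels are numba-compiled and bit-reproducible: the seed
fully determines a trajectory.  Output is sampled on a uniform grid
(`output_interval`, default 1 s).

**Stimulus semantics.**  A protocol is a list of clamp windows: during a
window the input species is *held* at the stated free concentration (an
ideal buffered source — reactions read the clamped count but cannot deplete
it), and on release the species relaxes under the network's own clearance.
Holding the level exactly, rather than injecting a flux, reproduces stated
peak concentrations independent of clearance parameters; within a 1 s
100 Hz train the clamp is maintained continuously because the 10 ms
inter-pulse gaps are far below the clearance timescale (τ = 2 s for
calcium).  File-based protocols replay a (time, species, value) series as a
piecewise-constant forcing input.

**Steady state.**  `run_to_steady_state` relaxes the unstimulated network
for 5400 s and compares per-species means over the last two 600 s windows;
the maximum relative change (denominator floored at one molecule, so
structurally empty pools are ignored) must stay below 1%, otherwise the
worst species is reported.  Experiment suites always start from the
equilibrated state and include a 300 s pre-stimulus baseline.

## Analysis stage

* **AUC.**  Kinase activity is quantified as the integral of concentration
  above the trajectory's own pre-stimulus mean (positive part,
  trapezoidal), from stimulation onset to the end of the analysis window.
  The suites close the window 900 s after the last train by default — the
  fixture's ppERK transients complete well within that — with the window
  length a per-plan parameter (`post_window`) for slower parameterisations.
  `time_to_basal` is the first time after the peak at which the signal
  stays within 5% of baseline for 60 s.
* **Dose–response classification.**  Candidate models: line a + bx,
  logarithm a + b·log₁₀x, and Hill max·xⁿ/(xⁿ + hⁿ).  The Hill fit is
  initialised from the data (max = max y, h = first x above half-max,
  n = 2) with a multistart on n ∈ {2, 1, 4}; non-convergent fits are
  flagged and excluded.  Goodness of fit uses adjusted R² and
  AIC = n·ln(RSS/n) + 2k with k counting parameters plus the error
  variance — only AIC *differences* matter, so the convention is fixed and
  documented.  Decision rule: the response is *linear* iff the linear fit's
  adjusted R² ≥ 0.9; otherwise the lowest-AIC converged model decides (log
  and Hill both count as non-linear).
* **Synergy (combination vs summation).**  For each grid point the suites
  run every input alone and all inputs together with shared seeds, and
  compare the combined AUC with the per-trial sum of single-input AUCs by
  two-way ANCOVA: OLS of AUC on the continuous covariate (duration or
  intertrain interval) and a categorical type factor with the summation
  group as reference.  A significant type effect (α = 0.05) below zero is
  sublinear, above zero supralinear, otherwise the pathways add linearly.
* **Temporal sensitivity.**  Over the five intertrain intervals
  (3, 20, 40 s massed; 80, 300 s spaced): mean AUC, sensitivity
  = max − min, and the best interval (ties resolve to the larger
  interval).
* **Robustness.**  Molecule totals are perturbed by ±10%, singly or
  jointly (uniform draws); each row re-equilibrates and reruns the
  five-interval scan deterministically (perturbation effects, not trial
  noise, are the object).  Percent changes are taken against the included
  unperturbed control row.  A 100-tree random-forest regression ranks the
  totals by importance for the temporal sensitivity; importances are
  non-negative and sum to one by construction.

## Synthetic data

Every statistic has a seeded generator with stored ground truth: Hill and
linear dose–response pseudo-AUCs with multiplicative Gaussian noise (trial
spread scales with signal, as stochastic AUCs do), ANCOVA groups with a
planted combination offset, exact interval profiles, and planted
single-feature regression sets for the forest.  `generate_iso_like_inputs`
emits five labelled-synthetic forcing series standing in for the
bath-application experiments (slow 540 s cAMP bath for isoproterenol; a 1 s
high-calcium train; 180 s of moderate calcium for 5 Hz; the two
combinations).  Component traces are jittered once and shared across
conditions, as if produced by one upstream simulation, and the time grid is
refined around the 1 s train so its duration is honoured at any sampling
interval.  Train amplitudes sit below the switch threshold so no single
condition saturates ppERK; the package asserts the *ordering* (combinations
out-activate singles), not absolute levels.

## What the fixture does and does not show

Passing the suite demonstrates that the machinery is correct: exact
conservation, the mass-action limit, faithful protocol timing, and that
every statistic recovers planted ground truth.  The fixture's behaviour
mirrors the full model qualitatively — a linear cAMP arm, an ultrasensitive
calcium arm under phosphatase control, sublinear cAMP-branch summation,
spaced-preferring ppERK for cAMP trains and massed-preferring switch
activation — but its rate constants are the package's own, so quantitative
statements (absolute AUCs, Hill exponents, robustness rankings) apply to
the fixture, not to the published parameterisation.  Loading the published
tables through `load_network` runs the identical pipeline.  The validation
suite refuses the fixture by default for exactly this reason.

## Design choices and limitations

* The package is a library: the importable API plus `examples/` scripts are
  the interface, and experiment suites are plain functions; no shell
  entry point is installed.
* Clamped inputs are hard clamps (the τ→0 limit of a fast relaxation
  source).  A finite-rate source would add ~10⁸ bookkeeping events/s to the
  SSA at bath-level targets with no effect at the output timescale.
* Whether dispersed, phosphorylated GAP species can return to the spine is
  left irreversible on the simulated timescale; the fixture has no
  spatial analogue, and the knockout flags for dimerization/dispersion act
  on label sets the network's metadata declares (empty for the fixture).
* No spatial discretisation, receptor kinetics or downstream gene
  expression; inputs enter as calcium, cAMP and Giβγ by design.
* The fixture's switch is effectively bistable on the hour timescale at
  default parameters: above-threshold stimuli leave ppERK elevated for the
  whole analysis window, so AUC there is window-limited (documented
  behaviour of the motif, and the reason suites report peaks alongside
  AUCs).
* Problem sizes in the shipped tests and acceptance script — 50 seeds for
  the stochastic/deterministic comparison at 1000 µm³, 100 repetitions for
  recovery rates, 500 for null calibration, 50 random draws for the
  robustness forest — are the package's standard configuration and run in
  a few minutes on one core.
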