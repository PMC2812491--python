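# Methods

`kinens` implements an ensemble kinetic-modeling workflow for
signal-transduction networks: a mass-action ODE model is fitted to
arbitrary-unit (immunoblot-style) data by a likelihood-weighted random
walk, and the resulting family of parameter sets — rather than a single
best fit — is propagated through sensitivity, robustness and synergy
analyses so that every prediction carries its parametric uncertainty.

## Model

A network of `n` species and `m` irreversible reactions defines

```
dx/dt = S r(x; k),      r_q = k_q ∏_{j ∈ reactants(q)} x_j^{σ_jq},
```

with integer stoichiometric matrix `S` (consumption negative, production
positive) and strictly positive rate constants `k`.  Conventions:

* **Irreversibility.** Reversible input syntax (`A + B <-> C | kf, kr`)
  is sugar; the loader always expands it into two irreversible steps, so
  parameter vectors index irreversible reactions only.  The net flux of
  the pair equals the reversible mass-action law (asserted symbolically
  in the test suite).
* **Catalysis.** Enzymes appear on both sides of a reaction (net zero in
  `S`); there is no modifier field, keeping the rate law literal.
* **Units.** Concentrations are arbitrary units (A.U.) because the
  training data are defined only up to per-blot scale factors; rate
  constants are per second (zero-order A.U. s⁻¹, first-order s⁻¹,
  second-order A.U.⁻¹ s⁻¹).  Protocol-level times are hours and are
  converted once, internally, to seconds.
* Because each rate is linear in exactly one rate constant, both the
  state Jacobian `A = ∂(Sr)/∂x` and the parameter-derivative matrix
  `B = ∂(Sr)/∂k` (`B[:,q] = S[:,q] r_q / k_q`) exist in closed form and
  are generated mechanically from the reaction list.

## Simulation

Integration uses LSODA with the analytic Jacobian at relative tolerance
1e-7 and absolute tolerance 1e-10.  Timed events (stimulus addition,
parameter scaling) stop and restart the integrator at the event time;
simultaneous events are applied in a fixed (kind, target) order so
protocol-file ordering cannot change results.  A stimulus "add 10 nM
hormone" is implemented as an *increment* of the extracellular hormone
species, not an overwrite: ligand is added to the medium on top of any
basal level.

Approximate steady state uses a windowed criterion: integrate windows of
`T = 10` simulated hours until `‖x(t+T) − x(t)‖₂ < 0.01` (plain Euclidean
norm over the full state vector), with a cap of 200 windows.  For a
bistable system this returns the steady state of the starting basin; the
criterion is protocol-dependent by construction.  Several windows are
integrated per solver call (the criterion is still checked window by
window), which matters because steady-state searches dominate the cost
of ensemble estimation.

## Ensemble estimation

Observations `M_ij` with standard deviation `σ_ij` (10% of the value
when unreported; an augmented 20–100% for flagged, poorly quantified
series) are compared to simulations started from the model's own
approximate steady state.  Because blots are accurate only to a
multiplicative constant, each (dataset, species) series gets a scale
factor

```
β = Σ M x̂ / σ²  ÷  Σ x̂² / σ² ,   clamped to β ≥ 0,
```

the exact minimizer of the normalized squared error; an identically zero
simulated series leaves β undefined and the series is scored unscaled.
Steady-state fold-change datasets can instead be scored in a "fold" mode
that divides both data and simulation by a control condition.  The
objective is the normalized mean squared error

```
E = (1/N_obs) Σ ((M − β x̂)/σ)² ,
```

normalized by the total observation count; this choice (the exact
denominator is a free convention) only rescales the acceptance
temperature.

The random walk proposes `log k → log k + N(0, σ²)` elementwise —
log-space steps handle the order-of-magnitude spread of rate constants
and keep positivity — and accepts with probability 1 when E does not
increase, else `exp(−ΔE/E0)`.  `E0` tunes the acceptance rate; as
`E0 → 0` the walk reduces to greedy descent (a tested invariant).
Multiple independent trajectories are run from one hand-tuned start and
pooled.  Each trajectory is thinned to approximate independence: the
empirical autocorrelation of its error series is fitted with
`C(τ) = exp(−τ/τ_c)` (the fit smooths autocorrelation noise) and every
`ceil(τ_c ln 20)`-th state is kept — the lag at which the fitted
autocorrelation falls to 5% of its initial value.  Thinning operates on
the scalar error series; it is a decorrelation heuristic, not a
convergence proof, and the pooled ensemble should be read as "plausible
parameter sets", not as a converged posterior sample.

Default chain settings (proposal σ = 0.1, temperature E0 = 0.5, a few
hundred steps per trajectory, 2–4 trajectories, 30% burn-in) are sized
so that the bundled toy study runs in minutes; they are ordinary
function arguments for larger studies.

## Sensitivity analysis (OSSC)

First-order sensitivities `s_j = ∂x/∂k_j` solve the forward equations
`ds_j/dt = A s_j + b_j`, `s_j(0) = 0`, integrated jointly with the
states as one extended system (so `A` and `b_j` are evaluated on the
current solution), all parameters in a single call.  The protocol: run
the clone to steady state, add the stimulus, solve sensitivities over a
100 s window on 101 uniform points.

The Overall State Sensitivity Coefficient aggregates over states and
times:

```
OSSC_j = sqrt( (1/(N_T N_x)) Σ_t Σ_i ((k_j / max(x_i, ε)) s_ij(t))² ),
```

with `ε = 1e-6 ×` the maximum state value guarding division by
near-zero states.  **This scaled-RMS form is the one reconstructed
formula in the package** — it follows the overall-sensitivity lineage of
Stelling-style coefficients (relative change of every state per relative
change of one parameter), and it is isolated in a single function so an
alternative normalization can be swapped in.  Parameters are ranked
ascending (largest OSSC → rank P = most fragile), ties broken by
parameter index for determinism.  Rank differences between clones are
tested per parameter with a two-sided Welch t-test across ensemble
members at 95% confidence, with no multiple-testing correction by
default (a Benjamini–Hochberg switch exists); shifts larger than one
standard deviation of all shifts are flagged "large".

## Robustness coefficients

A perturbation scales a protein's abundance by 10 (knock-in), 0.1
(knock-down) or 0 (knock-out): both the species' initial condition and
any zero-order expression source are scaled, so a knock-out cannot be
regenerated by constitutive expression.  A knocked-out species that is
also stored in a conserved complex (e.g. a translation factor held in an
inhibitory complex) *can* still be liberated from its partners — a known
limitation of per-species scaling, visible in the toy's translation
branch.  Perturbed systems are re-equilibrated to their own steady state
before the stimulus.  The coefficient is

```
f(i,j) = ∫ marker_i dt (perturbed) / ∫ marker_i dt (wild type)
```

by trapezoid on a shared 500-point log-spaced grid from the steady state
through 72 h after the 1 h stimulus (log spacing resolves the fast
post-stimulus phase).  `f = 1` exactly for the null perturbation; a zero
wild-type integral leaves f undefined (NaN).

## Synergy coefficients

For two axes A and B (each a set of species carrying one protein), four
hormone-free steady states are computed: wild type, A-only (B knocked
out), B-only, and the double knockout as control.  With
`Δ_A = q_A − q_ctrl`, `Δ_B = q_B − q_ctrl`, `Δ_AB = q_wt − q_ctrl`,

```
α = (Δ_AB − Δ_A − Δ_B) / q_wt
```

for every species concentration and reaction flux `q`.  Normalizing by
the wild-type level (rather than the control) is a deliberate choice:
the wild type is the only state guaranteed to carry the full pathway
flux, and the control level of strongly coupled outputs is near zero.
α is symmetric under axis swap and vanishes identically for systems in
which no bimolecular step couples the axes (both tested).  Over the
ensemble, a quantity is classified positive/negative only when the
2.5–97.5% percentile interval of α excludes zero — a percentile rather
than normal-approximation interval because no distributional claim is
made; an all-identical ensemble degenerates to classification by sign
with a 1e-8 tolerance.  The screen also reports whether every member
agrees in sign.

## The toy study

The bundled network (34 species, 41 irreversible reactions) is a
structural surrogate wired to exercise every analysis feature: a
ligand-activated, auto-activating receptor with adaptor recruitment; a
phosphatase negative feedback on the receptor whose expression is
repressed by the hormone receptor (the single clone-differentiating
parameter: AD ×1.0, MID ×0.5, AI ×0.01 on the phosphatase transcription
rate); a three-tier kinase cascade; a PI3K/Akt/TOR-like branch
liberating a translation factor from its sequestering complex; a
hormone receptor with chaperone sequestration, activated both by hormone
and by the terminal cascade kinase ("outlaw" route); and
transcription/translation of a secreted marker, a proliferation marker
and the phosphatase itself, with translation requiring free translation
factor and ribosome.  That last step couples the two signaling axes
multiplicatively, so protein outputs genuinely show positive synergy.
Ground-truth rate constants are fixed, deterministic values chosen to
place the cascade in a non-saturated regime (so clone differences
propagate) and all relaxation times at hours, reaching steady state
within a few windowed checks.

Pseudo-immunoblot data are simulated at the ground truth for six
datasets (hormone time courses per clone, a growth-factor transient,
and ±50% receptor/kinase perturbation steady states for two clones),
multiplied per (dataset, species) by a hidden log-uniform scale in
[0.1, 10] and blurred with Gaussian noise of σ = 10% of the value.  The
generator emulates the *structure* of literature training data — sparse
time points, unknown per-blot scales, reported-or-assumed 10% errors —
but not gel artifacts, saturation, correlated errors or biological
replicate variance; passing tests therefore demonstrate that the
machinery recovers what this noise model can encode, not performance on
real blots.

The recovery experiment designates nine parameters as identifiable by
construction — those governing the response *shapes* of the observed
species (activation/deactivation of the observed kinases and hormone
receptor, degradation of the observed markers); absolute production
rates are absorbed by β and are deliberately excluded.  Coverage is
summarized by z-scores of the ground truth against the pooled ensemble
in log space.

## Numerical choices and limitations

* Steady-state tolerance 0.01 on an unnormalized 2-norm means very small
  concentrations are weakly constrained at "steady state".
* The thinning interval is only as good as the exponential fit; chains
  shorter than a few autocorrelation times yield few members, and the
  workflow defaults accept that in exchange for runtime.
* Problem sizes in the bundled workflow (hundreds of Monte-Carlo steps,
  ensembles of O(10) members, 8–12 members in downstream analyses) are
  scaled-down study conditions chosen for desk-scale runs; all of them
  are parameters.
* No stochastic simulation, no spatial gradients, no separate nuclear
  compartment, no thermodynamic consistency checks on rate constants,
  and no second-order sensitivities.
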