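# Methods

## The kinetic model

The receptor is a tandem-SH2 (tSH2) module with two phosphotyrosine
binding pockets (C-SH2 and N-SH2) and an open/closed conformational
degree of freedom. Six species are tracked, written
`R<conformation><N-occupancy><C-occupancy>`:
`Ropen00` (open apo), `Ropen01` (open encounter complex, C-SH2
occupied), `Rclosed00` (ligand-free closed intermediate), `Rclosed01`
and `Rclosed10` (partially bound closed intermediates), `Rclosed11`
(closed holo-state). All transitions are mass action. The ligand
concentration `L` is an external, non-depleted parameter: single
binding events are first order in `L`, the direct double-binding event
`Rclosed00 → Rclosed11` is second order (`k3_plus·L²`). Transitions
into the holo-state from the partially bound intermediates, and the
direct `Ropen00 → Rclosed10` route, carry dimensionless penalty
weights `w1, w2, w3 ∈ [0, 1]` multiplying the encounter on-rate `kf` —
the thermodynamic brake. Each penalized step defines a dissociation
constant: `Kd1 = kb/kf` (encounter), `Kd2 = kb1/(w1·kf)` (N-SH2 step),
`Kd1* = kb2/(w2·kf)` (remodeled C-SH2 site). There is no feedback and
no ligand depletion; the network need not satisfy detailed balance
(the fitted off-rates are independent parameters), so steady states
can carry a circulating flux.

A reduced four-species model (`Ropen00`, `Ropen01`, a lumped
`Rclosed01/10`, `Rclosed11`) keeps the essential two-step structure —
fast encounter, slow ligand-independent open↔closed exchange of the
partial complexes (`k_plus`/`k_minus`), penalized entry into the
holo-state — and admits an exact steady state:

```
Ropen01      = (L/Kd1)·Ropen00
Rclosed01/10 = (2k+ + w1·kf·L)/(2k− + w2·kf·L) · (L/Kd1)·Ropen00
Rclosed11    = (w1·k− + w2·(k+ + w1·kf·L))/(2k− + w2·kf·L) · (L/Kd1)²·Ropen00
```

This closed form is the oracle against which the numerical steady
state is verified (relative error ≤ 1e−6 over random parameter draws;
in practice the two agree to machine precision).

### Observables

The bound fraction counts the closed, ligand-engaged species with the
partially bound intermediates at half weight (one of two pockets
occupied): `Φb = (½Rclosed01 + ½Rclosed10 + Rclosed11)/Rtotal`. The
reduced model, as derived, also counts the open encounter complex at
half weight; the single-site (`encounter_only`) variant counts the
singly bound species at full weight. These conventions are implemented
exactly as derived for each model and are *not* interchangeable — the
full-model convention deliberately excludes `Ropen01`, encoding that
the fluorescence quench reports domain closure rather than raw pocket
occupancy. `Φub = 1 − Φb`.

### Variants

* `full` — the complete network.
* `encounter_only` — single-site binding through the C-SH2 pocket
  (singly phosphorylated ligand, or an N-SH2 pocket mutant):
  `w1 = w2 = w3 = 0` and every rate outside
  `Ropen00 ↔ Ropen01 ↔ Rclosed01` zeroed.
* `syk_no_penalty` — the brake-free module: `w1 = w2 = w3 = 1`,
  `kb1 = kb2 = kb3 = kb`, ligand-free closed state negligible.
* `reduced` — the four-species system above (its own parameter type,
  not a mask).

## Parameters: anchors versus package defaults

Three dissociation constants are experimental anchors and are enforced
by construction throughout (including inside fits): `Kd1 = 2 nM`,
`Kd2 = 10 μM`, `Kd1* = 100 nM`. The encounter on-rate is set to
`kf = 8e−4 nM⁻¹s⁻¹` so that the pseudo-first-order encounter rate at
the stopped-flow ligand concentration (30 μM) is ≈ 24 s⁻¹, the
observed fast rate. The remaining microscopic rates are not published;
the package ships a named default set (`zap70_reference()`) chosen so
the simulated system reproduces the experimentally established
regimes: a biphasic steady-state curve whose second rise tracks `Kd2`,
plateau widening as `w1` falls, a slow kinetic phase of order 0.1 s⁻¹
at 30 μM ligand, an apo conformational equilibrium biased open, and a
narrow band of `Kd1` (≈ 8–20 nM) in which the unbound-fraction
transient is distinctly two-exponential while at `Kd1 = 2 nM` the two
visible rates lie within a factor of ~3 and merge into an effectively
single exponential. Defaults: `kclose = 10`, `kopen = 1`,
`w1 = 0.01`, `w2 = 0.1`, `w3 = 0.1`, `kb3 = kb1`, slow
`Rclosed00`-exchange rates (`kclose' = 1e−3`, `kopen' = 1`,
`k1± = 1e−5/0.01`, `k2± = 1e−5/0.01`, `k3+ = 1e−9 nM⁻²s⁻¹`,
`k3− = 1e−3`). All defaults are overridable via flat YAML parameter
files. In the `Kd1`-band analysis, `Kd1` is varied through the on-rate
at fixed off-rate; varying the off-rate instead cannot move the slow
phase into visibility at 0.5 μM ligand because holo occupancy there is
capped near `L/Kd2 ≈ 5%` by the anchor.

`reduced_reference()` uses `k+ = 7e−5 s⁻¹`, `k− = 7e−4 s⁻¹`
(`k−/k+ = 10`) with the same `Kd1` anchor.

### The brake-free (Syk) module is not exactly an independent-site system

`syk_reference()` applies the no-penalty mask at `Kd = 65 nM` with
fast symmetric conformational exchange (`kclose = kopen = 30 s⁻¹`),
giving a single fast kinetic phase and no slow component. One might
expect the no-penalty network to reduce to independent-site binding
with Hill coefficient exactly 1. It does not: with all weights equal
and `a = L/Kd`, any detailed-balanced steady state populates the apo
state with weight 1, *three* singly bound species (`Ropen01`,
`Rclosed01`, `Rclosed10`) with weight `a` each, and the holo-state
with `a²`, so the bound fraction is `Φb = (a + a²)/(1 + 3a + a²)` —
the conformational freedom of the encounter state inflates the
singly-bound level relative to the binomial weight `2a`, and `Ropen01`
is excluded from the count. A free-`Bmax` Hill fit of this curve
returns `nH ≈ 0.86` for any rate choice at detailed balance: the
brake-free module is intrinsically a *mildly negatively cooperative*
hyperbola-like binder, which matches the weak negative cooperativity
observed for Syk. Driving the conformational cycle (`kclose ≪ kopen`)
can push the fitted `nH` toward 1, but only by trapping the encounter
complex, which manufactures a large slow kinetic phase that the real
module does not have; the package therefore keeps the kinetically
faithful parameterization and documents `nH ≈ 0.86` as the model's
true value.

## Numerical methods

With `L` external the system is linear and time invariant,
`dx/dt = A(L)·x`, where `A` has non-negative off-diagonal entries and
zero column sums. Integration therefore uses matrix exponentials
(`expm(A·Δt)` applied along the time grid): exact for this system,
unconditionally stable across the full rate spread (1e−5 s⁻¹
conformational rates against >1 s⁻¹ binding), mass-conserving and
non-negativity-preserving to machine precision. A BDF stiff integrator
(`rtol = 1e−10`) is retained as an independent numerical route and is
cross-checked against the propagator in the tests.

Steady states come from two routes that are tested against each other:
(1) integration with a windowed convergence criterion — the state is
accepted when the maximum change over the last decade of integration
time is below 1e−9 relative to total receptor, starting from a 5 h
horizon and extending tenfold (up to ten times) before raising an
error; (2) a direct solve of the linear balance equations with the
conservation constraint, restricted to the species reachable from the
initial condition (unreachable species keep their initial values —
relevant for masked variants whose rate matrix is reducible). The
direct route is used inside iterative fits for speed.

Fitting: Hill and association fits use `lmfit` (Levenberg–Marquardt)
with data-driven initial guesses; weights are `1/SD²` when replicate
SDs are present. The double-exponential decomposition is multi-started
across widely separated rate-pair guesses (the surface has local
minima where both rates collapse onto one phase) and flags rate pairs
within 3× of each other as ambiguous rather than silently ordering
them. The windowed two-step protocol fits each acquisition window
independently with the single-exponential association law, truncates
the slow window to start after seven fast time constants, declares a
phase absent when the amplitude realized inside its window is below 5%
of the combined dynamic range (a numeric stand-in for the dashes used
in observed-rate tables), and then refines the fast rate by
subtracting the extrapolated slow exponential from the fast window —
without this correction the slow-phase ramp biases the fast rate low
by up to ~25% at a 40% slow amplitude. Model-to-data fits optimize the
free rates on a log scale with `Kd1`, `Kd2`, `Kd1*` substituted into
the off-rates by construction, multi-starting from a seeded generator.

## The synthetic-experiment generator

`gen_titration` emulates equilibrium tryptophan-quench titrations
(0.5 μM receptor regime): a mean signal from either the Hill law or
the model's dose–response, with i.i.d. Gaussian noise scaled to the
dynamic range, averaged over replicates (default 1% of range, 3
replicates — chosen to resemble triplicate fluorescence error bars).
`gen_stopped_flow` emulates the two-window stopped-flow geometry
(1 s / 101 points, 200 s / 1500 points; 100 nM protein, 30 μM ligand)
in either model mode (`intensity = baseline + amplitude·Φub(t)`) or
phenomenological mode (explicit sum of exponential phases, used to
target observed rates without knowing the unpublished microscopic
rates), paired with a protein-only blank (constant, optional linear
drift) and an optional dead-time truncation (default 0).
Preprocessing mirrors the instrument protocol: divide each trace by
its t = 0 (maximum) intensity, then subtract the normalized blank.

What the generator does *not* emulate: photophysics (bleaching, inner
filter), instrument dead time beyond a constant truncation,
correlated or multiplicative noise, receptor depletion of ligand, and
pipetting-style concentration errors. Passing recovery tests therefore
demonstrates estimator correctness under the stated noise model, not
robustness to instrument systematics.

## Known limitations

* The free-ligand approximation (total ≈ free) is used in all
  equilibrium fits; at 0.5 μM receptor against nanomolar `Kd1` the
  early titration points of real data violate it, which the package
  does not correct.
* Microscopic defaults other than the anchors are package choices;
  quantities that depend on them (plateau depth, exact band edges,
  model-mode observed rates) are regime-level, not quantitative,
  statements.
* The association-equation exponent is interpreted as `e^(−k·t)`; the
  observed rate is the fitted `k` per window.
* Hill fits float `Bmax` per curve; sharing `Bmax` across constructs
  is not implemented.
* No stochastic (Gillespie) simulation and no spatial/membrane
  geometry: deterministic mass action only.
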