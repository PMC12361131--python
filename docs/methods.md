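# Methods

`fieldmorph` simulates morphologically detailed multi-compartment neuron
models under uniform electric fields and asks whether any morphological
trait predicts a cell's field susceptibility.  This note documents the
model, its parameters, the synthetic-data generator, the numerics, and the
design choices that were genuinely open.

## The electrical model

Each cell is a tree of compartments obtained by cutting every unbranched
neurite section into ⌈L / L_max⌉ equal pieces (default L_max = 20 µm); the
soma is a single spherical compartment at the origin whose membrane area is
4πr² and whose cable "length" is its diameter.  The membrane equation per
compartment j is

    c_j dv_j/dt + i_ion,j = Σ_k ((v_k + e_k) − (v_j + e_j)) / r_jk + i_inj,j

with c_j = C_m·A_j, axial resistances from the half-compartment series rule
(R_a·Δx/2 per half, which reduces to the textbook d/(4R_aΔx²) coefficient on
uniform chains), and e_j an extracellular potential offset.  Because e_j
enters only through axial differences, adding a constant to every
compartment changes nothing (gauge invariance) — a property the tests
exploit repeatedly.

Ionic currents follow i = g_bar·(gating product)·(v − e_ion).  The channel
registry is a reduced, config-driven set — Ih, Im, transient Na, a
persistent K ("Kd"), a transient K ("Kv2-like"), Kv3-like, Ca-gated SK, and
low/high-voltage-activated Ca — with Hay-2011-style HH kinetics and fixed
reversals (E_Na 50, E_K −85, E_h −45, E_Ca 132 mV).  Channels are placed by
compartment type: Ih on soma and dendrites, Im on dendrites only, Kd and
Kv2 on the axon only, Na/Kv3 everywhere, SK and the Ca channels on soma and
axon.  Ca²⁺ dynamics run in a submembrane shell on soma and axon:

    dCa/dt = −10⁴·i_Ca·γ/(2Fd) − (Ca − m_Ca)/τ_d

(units: i_Ca in mA/cm², shell depth d in µm, concentrations in mM; defaults
γ = 0.05, τ_d = 80 ms, d = 0.1 µm, m_Ca = 10⁻⁴ mM).  SK reads the shell
concentration; only the Ca-channel currents feed it.  Default densities are
chosen so the model is subthreshold-quiescent at rest with no input (the
resting potential settles ~0.5 mV below e_pas = −70 mV); they are asserted
quiescent in the test suite, not assumed.

Passive defaults: C_m = 1 µF/cm², R_a = 100 Ω·cm, g_pas = 5·10⁻⁵ S/cm²
(R_m = 20 kΩ·cm², τ_m = 20 ms), e_pas = −70 mV, uniform across compartments.

## Field coupling

A uniform field E (mV/mm) along +z is applied as per-compartment
extracellular offsets, in one of two modes:

* **angular** (default): e_j = E·cos φ_j + ξ_j, φ_j the angle between the
  compartment midpoint position vector and +z (the soma, at the origin,
  takes cos φ = 1 by convention).  The distance component of the field is
  neglected: E's numeric value in mV/mm is applied directly in mV.  An
  axis-orientation reading of φ (the compartment's own tangent direction)
  is available via `angle_mode="axis"` but is not the default.
* **linear_potential**: e_j = E·z_j (z in mm) — the physically literal
  uniform gradient.  On this mode a passive straight cable reproduces the
  classical sealed-end polarization ±E·λ·tanh(ℓ/2λ), λ = √(d·R_m/4R_a),
  which anchors the solver to cable theory within 1%.

The two modes behave very differently on degenerate geometries: a perfectly
vertical cable receives *identical* angular offsets (hence zero polarization,
by gauge invariance) but a genuine gradient in linear-potential mode.  Both
ship; cross-mode results are never mixed.

Background noise ξ_j ~ N(μ_ξ = 0, σ_ξ = 4 mV) is drawn independently per
cell, compartment and trial — and, within a simulation, redrawn i.i.d. each
time step and held piecewise-constant over the step.  The per-step SD is
exactly σ_ξ; a √dt (spectral-density) convention would make the effective
noise power dt-dependent and was deliberately not used, since the analysis
works with windowed time means where only the zero-mean property matters.

Myelination zeroes all active channel densities on a Bernoulli(p) subset of
axonal compartments — p = 0.7 for PV cells, p = 0.15 for PC cells — leaving
passive properties untouched (deliberately literal: no capacitance change).
The mask is redrawn each trial by default; a fixed-per-cell mode exists.

## Protocol and susceptibility

Per cell: orientations (default upright 0°; optionally 0/90/180° about +y)
× field levels E ∈ {−50, −30, −10, 0, 10, 30, 50} mV/mm × 10 trials.  Each
trial rotates the model, recomputes angles, redraws myelin and noise, and
integrates; the somatic membrane potential is summarized over the analysis
window by its mean and coefficient of variation (per trial, then averaged —
the concatenated-trials alternative was rejected as it conflates slow
drift with trial variability).  Polarization is the windowed mean minus the
cell's trial-averaged E = 0 baseline at the same orientation.

Susceptibility is the endpoint slope S = (⟨V⟩₋₅₀ − ⟨V⟩₊₅₀)/ΔE with
ΔE = −100 mV/mm, computed from the upright orientation only.  For responses
exactly linear in E this equals the least-squares slope of ⟨V⟩ vs E.  The
formula is implemented literally; no sign convention is enforced on S
(under angular coupling the default cells yield S < 0 — the soma
hyperpolarizes for fields along +z).

## Statistics

* Pearson R with the two-sided Wald t-test p, t = R√((n−2)/(1−R²)) on
  t(n−2), written out explicitly (scipy's equivalent is a test-suite
  cross-check, not the implementation).
* Partial correlations by least-squares residual projection on covariates
  plus intercept, df reduced by the covariate count; for each whole-cell
  trait the other whole-cell traits are held constant.
* Mann–Whitney U with midrank ties; exact two-sided p by full enumeration
  of group labelings for n₁+n₂ ≤ 16, otherwise normal approximation with
  tie and continuity correction.  Used for layer- and class-wise group
  comparisons, treating cells as independent units.
* Raw p-values are reported with a p < 0.05 star, matching how such screens
  are usually displayed; no multiple-testing correction is applied by
  default.

## The synthetic-morphology generator

The generator replaces a fixed library of reconstructed cells so the whole
pipeline runs from a seed.  Growth is recursive stochastic branching:
log-normal section lengths, direction = parent direction blended with a
signed z-bias plus Gaussian angular jitter, dichotomous branching with a
per-section probability up to a maximum order, and diameters that taper
geometrically with branch order (child/parent ratio < 1, so dendritic
diameter is strictly non-increasing with order).  PC specs add a dominant
apical trunk toward +z; the axon grows downward.  Per-compartment channel
densities are sampled log-normally around the class target with CV = 0.2
(mean-preserving), emulating compartment-to-compartment biophysical
variability; the fixed-conductance control re-instantiates with CV = 0.

Class parameters are calibrated to *orderings*, not values: at the default
seed and layout (27 cells: PC 3/5/5 and PV 5/4/5 across L2/3, L4, L5), PV
groups have smaller mean z-length and vector magnitude and more axonal
branch points than same-layer PC groups, and deeper-layer PCs are taller.
What passing tests show is therefore that the *pipeline* behaves correctly
on populations with the right qualitative structure — not that the
generator reproduces any real population's trait distributions.  Real
reconstructions differ in ways the generator does not attempt: tortuosity,
3-D tropism, diameter profiles within sections, axon collaterals, spines.

All randomness flows from one root seed; per-neuron and per-trial child
seeds are split with `numpy.random.SeedSequence`, so populations and whole
experiments are reproducible byte-for-byte.

## Numerics

Backward Euler with tree-ordered (leaf-to-root) direct elimination — an
O(N)-per-step Hines-style solve — at dt = 0.025 ms, default duration
500 ms with the last half as analysis window (tests and screens use
shorter, explicitly stated durations sized to τ_m = 20 ms).  Gating
variables advance by exponential Euler staggered with the voltage solve;
the Ca shell uses the exact exponential update of its linear ODE, which
makes the closed-form decay and steady-state oracles exact up to the
frozen-current approximation.  The scheme is unconditionally stable and
first-order accurate; steady-state polarization (what the analysis
consumes) is independent of dt, and the suite verifies < 0.1% change in
steady state under dt halving plus observed first-order trajectory
convergence toward a dense matrix-exponential oracle.  Degenerate inputs
are rejected up front (zero-length sections, non-positive diameters,
disconnected compartments); a diverging trial raises with diagnostics at
the solver level and becomes a flagged NaN row, never a silent drop, in
the protocol loop.

## Calibration screens

Two seeded screens validate the statistics end to end at reduced scale
(passive cells, 100 ms runs):

* **null**: per replicate, 9 generated cells are simulated and their
  susceptibilities randomly re-paired against their traits, severing any
  genuine morphology–response link; the pooled p < 0.05 rate over 200
  replicates must sit at the nominal level.  Because the six screened
  traits are mutually correlated, the acceptance band is the
  cluster-conservative binomial CI with n = replicates.
* **planted**: passive straight cables with lengths spanning 250–1000 µm in
  linear-potential mode, where S grows as λ·tanh(ℓ/2λ); the length test
  must fire in ≥ 90% of replicates while an independent random marker
  covariate stays nominal.  Geometric traits other than the marker are
  *not* asserted nominal: in a passive cable every geometric parameter
  enters S through λ, so only a genuinely independent covariate is a fair
  null.

## Known limitations

* Channel kinetics are a reduced standard set, not any fitted model's;
  conclusions about specific real cell types require real densities.
* The angular coupling mode is deliberately literal about its convention
  (midpoint angle, soma cos φ = 1); adjacent compartments can receive very
  different offsets near the origin, which makes responses larger than a
  physical gradient would produce.  The linear-potential mode is the
  physically calibrated alternative.
* Myelination only zeroes active conductances; real myelin also changes
  capacitance and leak.
* Single cells in free space: no synapses, no network or ephaptic
  interactions, no tissue conductivity.
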