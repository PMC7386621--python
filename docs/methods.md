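# Methods

This note records the model, the estimation machinery, the synthetic-data
conditions, and the numerical choices made where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The conductance model

The reference neuron is a single-compartment model of a rostral
ventrolateral medulla (RVLM) cell with five membrane currents — transient
sodium (NaT), delayed-rectifier potassium (K), hyperpolarization-activated
cation (HCN), low-threshold calcium (CaT) and leak — seven state variables
(the membrane voltage V and six gate occupancies m, h, n, q, r, z) and 41
parameters. The voltage obeys

    C dV/dt = J_NaT + J_K + J_HCN + J_L − J_CaT + 0.01 I_inj / A,

with the ohmic currents in depolarizing-positive form J = g·gates·(E − V)
(mS·cm⁻², mV → µA·cm⁻²), the injected current I_inj in pA and the membrane
area A in units of 10⁴ µm². The published equation of motion carries an
overall minus sign in front of currents already written in (E − V) form; as
printed that combination is depolarizing-inverted and does not spike, so
the standard convention above is used. J_CaT is the Goldman–Hodgkin–Katz
(GHK) flux (outward-positive in the physiology convention, hence the minus
sign), driven by q²r gating, the maximal permeability p̄ (10⁻⁴ cm·s⁻¹
units) and fixed calcium concentrations. The concentrations are not part
of the published parameter set; the defaults are typical mammalian values
[Ca²⁺]ᵢ = 10⁻⁴ mM and [Ca²⁺]ₒ = 2 mM, exposed in `PhysicalConstants`, and
every CaT-related check in the package is self-consistent under whatever
values are configured.

Each gate relaxes as dx/dt = (x∞(V) − x)/τ(V) with

    x∞(V) = ½(1 + tanh((V − V_t)/δV)),
    τ(V) = t₀ + ε·(1 − tanh²((V − V_t)/δV_τ)),

so the recovery time is t₀ + ε at the activation threshold and t₀ in the
fully polarized states; the sign of δV sets activation vs. inactivation.

**GHK surrogate.** The exponential voltage factor of the GHK flux has
poles at V = ±2πi·RT/(zF) ≈ ±80.7i mV, so a Taylor series about V = 0
cannot converge over a 145 mV physiological range. The package therefore
uses the degree-25 Chebyshev interpolant of the exact factor on the
certified range [−100, 45] mV, converted to a power series in the scaled
variable and evaluated in Horner form. Its relative error against the
exact flux is ≈ 2×10⁻¹⁰ (swept in the tests; the certified bound is 10⁻⁶).
The surrogate — not the exact expression with its removable singularity —
is what enters the estimation residuals, keeping the symbolic derivative
tree polynomial-smooth in V.

## Twin experiments

Clean traces V_use are synthesized by forward integration (LSODA,
rtol 10⁻¹⁰, atol 10⁻¹², integrated segment-by-segment between protocol
edges so current steps never cross an integrator step) on a uniform
100 kHz base grid, from a deterministic initial state settled for 500 ms
at the protocol's first amplitude. Observations add seed-controlled
i.i.d. Gaussian noise, V_exp = V_use + σ·η_ζ, with η_ζ generated by a
Philox counter-based generator keyed by ζ; a negative σ is the sign-flipped
realization of the same η_ζ. This makes datasets bit-reproducible and
noise amplitudes continuously rampable at fixed realization — the property
the regularizer relies on.

**Stimulation protocol.** The published figures do not print the current
amplitudes, so the package ships versioned protocol fixtures. The default
(`mixed_steps_200ms_v1`, 200 ms) mixes depolarizing steps of 1.2–4 nA
(sub-threshold, near-rheobase and strongly supra-threshold; the model's
rheobase is ≈1.4 nA), hyperpolarizing steps of −1.5 to −4 nA reaching
≈ −90 mV (HCN activation and CaT de-inactivation), and durations of
10–30 ms; a stretched 500 ms variant and a held-out prediction protocol
follow the same design. All durations are multiples of 10 ms so protocol
edges coincide with collocation group boundaries for the mesh steps used.
Within a mesh group the injected current is the value governing the
group's interior, so edges at shared boundary points feed each adjacent
group its own amplitude.

What the generator does not emulate: correlated or multiplicative noise,
electrode/filter dynamics, channel (shot) noise, model mismatch between
the generating and fitting equations. Passing twin tests therefore
demonstrates the estimator under ideal observation models only.

## Collocation transcription

The estimation cost is c = ½Σᵢ[(V_exp(tᵢ) − V(tᵢ))² + u(tᵢ)²] over the
retained mesh, with u(t) ≥ 0 the nudging control entering the voltage
equation as u·(V_exp − V). Dynamics are enforced on 5-point groups: one
Boole's-rule constraint per state per group (weights (7,32,12,32,7)/45
with prefactor 2Δt; the published first weight is garbled and is fixed by
the degree-5 exactness property) and Hermite midpoint conditions
x_{i+1} = ½(x_i + x_{i+2}) + (Δt/4)(F_i − F_{i+2}) (the published Δt/8 is
a typo: the interpolation interval is 2Δt, and only Δt/4 is exact for
cubics, the property the tests pin down).

The published scheme retains two of the three Hermite conditions. With
two conditions each group has one undetermined degree of freedom per
state; the data term anchors the voltage but the unobserved gates acquire
~n/4 spurious degrees of freedom, which in practice lets spurious gate
trajectories satisfy all constraints while deviating arbitrarily from the
dynamics. The default transcription therefore uses all three conditions
(`n_hermite=3`), making the per-group state system well determined; the
two-condition variant is available as an option and its published
constraint counting L·G + 2(L+1)·G is covered by a test. The control u
carries the two midpoint conditions with its dynamics taken as the
constant half-group finite-difference slope, under which they reduce to
the linear rule u_{i+1} = ½(u_i + u_{i+2}); |du/dt| ≤ 1 ms⁻¹ is reported
as a diagnostic (u → 0 at every solution of interest, so the bound is
never active there).

**Gate-row normalization.** The raw gate residuals scale as 1/τ, so
inflating a recovery time uniformly deflates that gate's dynamics
residuals — a structural shortcut ("gate freezing") that attracts
penalty-type solvers into sub-optimal basins with pinned time constants.
The mirror shortcut exists too: scaling rows by the recovery time alone
would reward collapsing t+ε toward zero. The gate constraint rows are
therefore normalized by the smooth two-sided scale s_ℓ = √(q² + 1) with
q = (t_ℓ + ε_ℓ)/ref_ℓ (ref_ℓ the bounds midpoint scale): s grows with q for
large recovery times and is floored at 1 for small ones, so neither
inflation nor collapse deflates the residuals. This is an equivalent
formulation of the same equality constraints; its product-rule terms are
carried exactly through the Jacobian and Hessian.

**Mesh resolution.** At Δt = 50 µs the transcription error at action
potentials is large enough that the discretized problem's optimum lies
percent-level away from the generating parameters (inflated recovery
times "smooth" the spikes). At the 20 µs mesh used for all quantitative
experiments the warm-started recovery bias is a few 10⁻⁴ relative. The
adaptive mesh keeps the 20 µs step where V_exp > −65 mV and m× that step
elsewhere (m ∈ {1,2,4}), trimming trailing groups so the retained
interval count is a multiple of 4m.

## Solver

The NLP (state/control trajectories + parameters, bounds from the
published search intervals) is solved by an augmented-Lagrangian method
whose subproblems are minimized by an interior-point damped-Newton
iteration with exact symbolic derivatives (sympy-generated, CSE-compiled):

* the Newton matrix is the exact Lagrangian Hessian (multiplier-weighted
  constraint curvature included), not a Gauss–Newton approximation — the
  curvature coupling between gate trajectories and kinetic parameters is
  what lets the iteration move off compensated configurations;
* steps solve the KKT (augmented) system, block-eliminated in structure:
  batched (L+1)×(L+1) Cholesky of the point-local primal blocks, banded
  Cholesky of the constraint-space Schur complement (banded in time), and
  a dense K×K Schur complement over the parameters — O(n) per step and
  numerically stable at large penalties, unlike squared normal equations;
* a log-barrier acts on the parameter variables only (states and control
  are projected): gate occupancies legitimately ride their [0,1] bounds
  and must not feel barrier forces, while parameters must not stick to
  their box along sloppy directions mid-run;
* penalties ramp through `mu_schedule` with multiplier updates at the top
  level; feasibility tolerance 10⁻⁸ and optimality tolerance 10⁻⁶ on the
  projected Lagrangian gradient (scaled variables), both configurable.

Variables are affinely scaled (voltages by 50 mV, parameters to their
search intervals); parameters with degenerate intervals (the capacitance,
fixed at 1 µF·cm⁻² as published) keep their slot in the public decision
vector but are eliminated from the solver's variable set.

**Voltage-clamp pre-fit (stage 0).** Before the main ladder, the default
solve freezes V at the observations and u at zero, tightens the gate
dynamics into constraints (linear in the gates once V is fixed) while the
voltage-equation defect remains a soft least-squares term — the
current-balance regression classically performed on voltage-clamp data,
whose global minimum at zero noise is the true parameter set. Its
parameters then seed the main ladder through a fresh nudged-trajectory
initialization.

Initialization defaults: V and gates from integrating the nudged model
(fixed gain, default 0.5–0.95 ms⁻¹) over the observations — a
collocation-feasible start — with parameters at the interval midpoint,
taken geometrically for positive scale-type parameters whose interval
spans a decade or more (conductances, permeability, recovery times) and
linearly otherwise. Random initializations draw uniformly within bounds
from a named seed.

## Posterior and geometry machinery

Ensembles re-assimilate R fresh noise realizations of one clean trace,
warm-started from the σ = 0 solution's full decision vector (the
published recipe); the unbiased sample covariance and its eigenvalue
spectrum quantify sloppiness. The misfit geometry at a converged σ = 0
optimum p* uses F = ½Σε² + Σε·ε_mod, G = Σε·∂V/∂p and the error-weighted
Hessian; with G defined by that explicit formula the noise-induced offset
is δp = +H⁻¹G (the sign consistent with the actual shift of the
re-solved minimum, verified against the linear-Gaussian oracle).
First-order sensitivities of the forward map are exact (forward
sensitivity ODEs with symbolic ∂F/∂x, ∂F/∂p); second derivatives use
central differences of those exact sensitivities. The noise-equivalent
temperature inverts the Johnson–Nyquist relation σ² = 4k_B T R Δf.

## Noise-ramp regularization

The ramp machinery is generic over a warm-started solver. Defaults: σ
legs of ±10 µV … ±500 µV in 10 µV steps from zero; a saddle-node jump is
flagged at the first step whose interval-scaled parameter displacement
and cost change both exceed 10× the running median of earlier steps on
the same leg (a scale-free reading of the published figures' visible
jump); annealing retraces the grid to zero and a re-detected jump raises
an error (mis-detected basin). The final result never has higher cost
than the plain solve. The detector is validated on a tilted double-well
potential whose fold amplitude is known in closed form.

## Problem sizes and limitations

Default desk-scale study conditions (chosen once for a single CPU; stated
here as the package's own sizes): twin traces of 200 ms at 100 kHz;
collocation meshes of 20 µs steps (n = 10,000 intervals, the published
size) for recovery experiments; ensembles of R = 50 by default with
R = 1000 available behind a parameter; regularization ramp grids of
10–50 µV steps.

Known limitations:

* Global convergence from agnostic (midpoint/random) initializations on
  the full 41-parameter problem is not reliable: the cost surface has
  broad sub-optimal basins (compensated sub-threshold currents,
  mis-assigned kinetics), and although the structural measures above
  remove several artificial traps, the plain solver still terminates in
  such basins from distant starts — which is precisely the phenomenon
  the noise-ramp regularizer addresses, and consistent with the
  two-thirds plain success rate reported for the original interior-point
  implementation. Moreover, from such a *distant* sub-optimal basin the
  σ-ramp finds no saddle-node within ±2 mV — the fold-escape mechanism
  operates between a local minimum and its neighboring deeper basin, not
  across arbitrary distances in parameter space. Warm-started solves
  (from the truth's neighborhood, from a previous ramp point, or from
  the σ = 0 optimum) converge cleanly and are the basis of all
  ensemble/geometry experiments; the headline noise-free recovery
  therefore reports whatever deviation the default pipeline genuinely
  achieves rather than the published fraction-of-a-percent figure.
* Second-order sensitivities of the ODE forward map are exact only to
  the accuracy of the outer central difference.
* The adaptive mesh requires protocol edges to fall on group boundaries
  for exact transcription; misaligned edges are counted and reported on
  the assembled problem.
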