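# Methods

## Model class and frames

A model is a single well-mixed compartment of volume `Ω` (litres) holding
`N` species that interact through `R` irreversible reaction channels. Each
channel `j` carries a *mesoscopic propensity* `a_j(n)`: the probability per
unit time that the channel fires when the copy-number state is `n`. The
package works in two exactly convertible frames: integer molecule counts
`n` (used by the stochastic simulator) and molar concentrations
`φ = n/Ω_eff`, where the *effective system size* `Ω_eff = Ω·N_A`
(`N_A = 6.02214076×10²³ mol⁻¹`; for item-based substance units
`Ω_eff = Ω`). Propensities are stored symbolically with `Ω_eff` as a free
symbol, which is what makes the volume expansion below exact rather than
numeric.

Mass-action channels built through `NetworkBuilder.add_mass_action` take a
concentration-frame rate constant `k` (units `M^(1-order)/time`) and get
the falling-factorial propensity
`a_j = k · Ω_eff^(1-order) · Π_i n_i(n_i-1)…(n_i-s_ij+1)`.
Arbitrary symbolic propensities (Hill, Michaelis–Menten effective rates)
are accepted through `add_custom` or SBML kinetic laws.

## The expansion

Substituting `n = Ω_eff·φ` and collecting powers of `1/Ω_eff` gives, per
channel,

    a_j(Ω_eff φ)/Ω_eff = f⁰_j(φ) + f¹_j(φ)/Ω_eff + …

For mass action this series is exact and terminates (`f⁰` is the
macroscopic rate law, `f¹` the falling-factorial cross terms; both orders
are extracted as polynomial coefficients, not numerically). For
non-polynomial propensities a symbolic series around infinite volume is
attempted; saturating rates whose substitution leaves no residual
`Ω_eff`-dependence come out with `f⁰` equal to the microscopic form and all
higher coefficients zero. If neither route works the channel degrades
gracefully — `f⁰` is frozen at the numeric system size, `f¹ := 0` — and a
warning is attached to the tensors, because the solvers then still
reproduce the correct macroscopic dynamics while the finite-volume
corrections for that channel are silently absent.

From the expansion the package assembles, symbolically:

- rate vector `F = (f⁰_j)`, Jacobian `A = ∂(S F)/∂φ`, diffusion matrix
  `D = S diag(F) Sᵀ`;
- the Hessians `H_j = ∂²f⁰_j/∂φ∂φ` and the vector `f¹`;
- the mean-correction vector
  `Δ_i(φ,Σ) = Σ_j S_ij [ ½ tr(H_j Σ) + f¹_j ]`.

The three description levels then are: REs `dφ/dt = S F`; the LNA
covariance flow `dΣ/dt = AΣ + ΣAᵀ + D` (concentration covariance
`C = Σ/Ω_eff`); and the mean-correction ODE
`dδ/dt = Aδ + Δ(φ,Σ)/Ω_eff`, with corrected means `φ + δ`. For purely
unimolecular networks `H_j ≡ 0` and `f¹ ≡ 0`, so `δ ≡ 0` identically — the
corrected means reduce to the rate equations, which the test suite asserts
exactly. The correction is first order in `1/Ω_eff` by construction; a
log–log fit of `‖δ‖` against volume has slope −1, another asserted
invariant. Orders beyond the mean correction (second-order variance
corrections etc.) are out of scope.

## Conservation laws and reduction

Left null vectors of the stoichiometric matrix are conserved under every
channel. The basis is computed over exact rationals (sympy null space +
RREF), so `B·S = 0` holds with no tolerance; each law eliminates its pivot
species through an affine reconstruction map `x = offset + T·u` anchored
to the initial state. All solvers operate on the reduced coordinates
`u` — this is what makes the Jacobian invertible at stable fixed points —
and reconstruct full-space results afterwards; fluctuations satisfy the
laws exactly, so the full covariance is `T Σ_red Tᵀ`. The solved system
sizes are `N_r`, `N_r + N_r(N_r+1)/2` and `N_r(N_r+5)/2` for the three
levels, `N_r` the number of independent species.

## Numerical choices

- **Time stepping**: `scipy.integrate.solve_ivp`. The default (`stiff="auto"`)
  is LSODA — adaptive non-stiff integration with automatic switching to a
  stiff method; `stiff=False` selects RK45 with a BDF retry on failure,
  `stiff=True` BDF directly. Default tolerances `rtol=1e-6`, `atol=1e-9`.
  Only the upper triangle of `Σ` is integrated; the right-hand side
  symmetrises defensively.
- **Steady states**: damped Newton on the reduced residual with Armijo
  backtracking (the merit function is `½‖S F‖²`), tolerance `1e-9`,
  starting from the model's initial concentrations. If Newton stalls the
  system is pre-integrated for ten characteristic times (from the Jacobian
  spectrum) and the solve retried once. Undamped Newton demonstrably fails
  on saturating kinetics (a regression test constructs such a case), which
  is why the line search is not optional by default.
- **Steady-state noise**: `A Σ + Σ Aᵀ + D = 0` via
  `scipy.linalg.solve_continuous_lyapunov` after verifying `A` is Hurwitz;
  non-Hurwitz fixed points raise, since the LNA is meaningless there.
  Residual is asserted below `1e-8` relative in the tests.
- **Negative corrected means** are flagged with a warning rather than
  raised: the breakdown volume below which the correction turns unphysical
  is itself useful output. An `inversion_flag` matrix marks species pairs
  whose ordering the correction reverses.
- **Zero-variance species** get correlation 0 (flagged through the zeroed
  diagonal) instead of NaN.
- **Critical volume** (substrate/product inversion of the substrate-input
  enzyme): because `δ` is exactly proportional to `1/Ω_eff` at fixed
  macroscopic state, the crossing condition is linear in `1/Ω_eff`; the
  root is evaluated in closed form from one reference-volume solve and
  cross-checked in the tests against an independent bisection over a
  volume scan.

## Stochastic simulation

Waiting times are exponential in the total propensity and channels fire
with probability proportional to theirs; both the classic direct method
and the optimized direct method (ODM) are implemented. For purely
mass-action networks the sampler is a numba-compiled kernel; the ODM path
orders the channel search by firing frequency estimated in a short
pre-simulation window (a 64-point probe over the first 10% of the run) and
recomputes only the propensities that the fired channel can have changed,
via a species-sharing dependency graph, with an exact resummation every
4096 events to bound float drift. Non-mass-action models fall back to a
generic Python loop over the symbolic propensities — same law, different
stream. Event-resolved single trajectories (`ssa_direct`/`ssa_odm`) use
the generic sampler regardless, since ordering only changes lookup cost.

Randomness: realization `r` of seed `s` draws from a PCG32 stream whose
state is derived from `SeedSequence([s, r])`, so each path is a pure
function of `(s, r)`; ensembles accumulate their statistics in realization
order and are therefore bit-identical for any thread count (threads run
the kernel `nogil` over disjoint path ranges). Grid sampling is
right-continuous (the state at a grid time is the state after the last
event at or before it), the càdlàg convention for jump processes.
Concentration statistics divide counts by `Ω_eff`. Non-integer initial
amounts are rounded to the nearest integer at SSA initialisation only.

## SBML subset

Level 2 Version 4, single compartment, irreversible reactions. The kinetic
law is read as the mesoscopic propensity: species symbols denote molar
concentrations, the compartment symbol the volume, and a global `N_A`
parameter is written on export so that `X·cell·N_A` round-trips to the
count variable exactly. Events, assignment/rate/algebraic rules,
reversible reactions, constant or boundary species and explicit
time-dependent rates produce named validation errors
(`UNSUPPORTED_EVENT`, `UNSUPPORTED_RULE`, `REVERSIBLE_REACTION`,
`CONSTANT_SPECIES`, `TIME_DEPENDENT_RATE`, `MULTI_COMPARTMENT`); strict
parsing refuses such files outright, returning no partial network. A
non-second model time unit survives the round trip through a `time` unit
definition (the clock models run in days).

## Study models

- **Substrate-input Michaelis–Menten enzyme** (malate dehydrogenase
  constants: input 1.8×10⁻⁵ M/s, binding 5×10⁷ (Ms)⁻¹, unbinding and
  catalysis 5 s⁻¹, product removal 7 s⁻¹). Total enzyme 4 µM: 1204 copies
  at 0.5 fl, 24 copies at 10⁻¹⁷ l. The 4 µM total is a reconstruction —
  it must exceed the 3.6 µM the input flux demands at steady state, match
  the documented copy numbers at both volumes, and put the enzyme near
  saturation (90%) to produce the documented noise levels; all three
  conditions pin it jointly.
- **Four-subunit cooperative enzyme**: sequential binding with stepwise
  Michaelis constants 20, 2, 0.2, 0.02 µM (positive cooperativity), each
  complex catalysing at 10 s⁻¹; total enzyme 1 µM (602 copies at 1 fl, 60
  at 0.1 fl). Every complex is taken to release product, the standard
  reading of the multi-site scheme.
- **Single-gene clock circuit** (time unit days): transcription from the
  free gene, translation, nuclear import/export (all ~5 d⁻¹), two-step
  cooperative promoter binding by the nuclear protein (second step 10×
  faster; strong-feedback variant multiplies the binding constant by 100),
  Michaelis–Menten degradation enzymes for mRNA and cytosolic protein, and
  first-order dilution. Transcription and both promoter constants are
  rescaled by `Ω_eff` so the macroscopic equations are volume-independent
  despite the fixed single gene copy (asserted in the tests); the primed
  constants carry an implicit micromolar unit, consistent with the
  µM-scale Michaelis constants of the degradation enzymes, and the two
  degradation-enzyme totals are set to 1 µM. The promoter constants'
  joint rescaling makes gene switching fast, with occupancy set by the
  repressor *concentration* — the only dimensionally coherent reading of
  the rescaling. These reconstruction choices reproduce the circuit's
  qualitative repertoire (damped ~1-day population-level oscillations,
  bursty low-copy mRNA at 0.2 fl, sustained single-cell rhythms that run
  slower than the linearized period), but the quantitative single-cell
  period (~2 d) should be read as a property of this reconstruction, not
  a sharp prediction.
- **Oracle models** with closed-form statistics anchor the tests:
  birth–death (stationary Poisson: Fano factor 1, zero mean correction),
  input + dimerisation (the smallest network with a non-zero correction,
  `Δ = -2k(Σ - φ)`), and a unimolecular chain (corrections vanish
  identically).

## What the tests do and do not establish

The closed-form oracles (Poisson birth–death, flux-balance enzyme algebra,
exponential waiting times, finite-difference tensor checks, bisection
cross-check of the critical volume) validate the machinery independently
of the implementation paths they test. The replication suite checks the
enzyme-model noise statistics against their documented values at 10%
(deterministic) / 15% (stochastic); the clock-circuit periods depend on
the parameter reconstruction described above and are reported as computed.
Synthetic models are idealised: single compartment, time-independent
rates, no extrinsic noise, no cell growth or division — agreement here
says nothing about those effects. The expansion itself assumes a
monostable macroscopic flow; multistable or limit-cycle regimes are
outside its validity and the package raises on non-Hurwitz fixed points
rather than returning numbers there.
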