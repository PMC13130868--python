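# Methods

`lowshear` computes the shear viscosity of simple particle fluids at
arbitrarily low shear rates by combining a compact SLLOD shear simulator with
the transient-time correlation function (TTCF) estimator.  This note records
the model, the estimators, the numerical choices that were genuinely open,
and what the synthetic (simulated) data do and do not establish.

## Physical models

**WCA fluid.**  Truncated-and-shifted Lennard-Jones,
φ(r) = 4ε[(σ/r)¹² − (σ/r)⁶] + ε for r ≤ r_c = 2^{1/6}σ, zero beyond.  The
shift constant equals +ε so that energy and force vanish continuously at the
cutoff.  The reference state point is the Lennard-Jones triple point,
ρ* = 0.8442 and T* = 0.722, which requires a Nosé–Hoover thermostat
(α̇ = (Σp²/m − 3NkBT)/Q).  The default damping is Q = 3NkBT·τ² with
τ = 100Δt; Q is a free knob exposed on `ThermostatState`.

**DPD fluid.**  Standard dissipative particle dynamics with soft conservative
force F_C = a(1 − r/r_c)r̂, dissipative force F_D = −γ w_D(r)(r̂·v_ij)r̂ and
random force F_R = σ w_R(r) ξ_ij Δt^{−1/2} r̂, with w_D = w_R² = (1 − r/r_c)²
inside the cutoff.  Default parameters a = 25, γ = 4.5, σ = 3, r_c = 1,
ρ = 3, T = 1, k_B = 1, m = 1 (the standard simple DPD fluid).  The
fluctuation–dissipation constraint σ² = 2γk_BT is enforced at construction
for the full model; it is what makes F_D + F_R a momentum-conserving
canonical-ensemble thermostat, so DPD runs use no explicit thermostat.

Two conventions in this force field are frequently printed ambiguously in the
literature and are pinned here as follows, with the equilibrium-temperature
property test (⟨T_kin⟩ = 1.00 ± 0.02 over 10⁴ steps) as the arbiter:

* the dissipative projection uses the **unit vector**, (r̂·v_ij); the
  full-vector form is available via `ForceFieldSpec(vd_unit_vector=False)`;
* the random force scales as **Δt^{−1/2}** (the Groot–Warren convention);
  any other power breaks the thermostat at finite Δt.

The modified force fields `DPD_C` (conservative only), `DPD_C_RFIXED`
(conservative + random with one constant ξ for every pair) and
`DPD_CDR_XIFIXED` (all three forces, constant ξ) are evaluation-only probes
for the mapping diagnostics; they are never used to generate TTCF estimates
and no dissipation function is defined for them.

## Shear dynamics

Homogeneous planar shear (velocity along x, gradient along y) is imposed
through the SLLOD equations of motion with peculiar momenta,
ṙ = p/m + x̂γ̇y, ṗ = F − x̂γ̇p_y, integrated with velocity Verlet under the
frozen splitting: half-kick (including −γ̇p_y and, if thermostatted, −αp),
drift (including +γ̇y and the box deformation), force recomputation,
half-kick.  Forces are evaluated once per step; the dissipative force uses
the momenta available at the evaluation point (no self-consistent iteration),
which matches common engine behaviour and is adequate at Δt = 0.01 per the
temperature test.

The periodic cell deforms with the flow (Lagrangian-rhomboid/tilting-box
boundary conditions): the xy tilt advances by γ̇L_yΔt per step and is
recomputed from the step counter — not accumulated — so total strain is exact
in the integer-step sense; the tilt flips back by L_x when |tilt| > L_x/2,
with positions and peculiar momenta untouched by the flip.  Minimum-image
displacements wrap y first (shifting x by the tilt per crossed image), then
x, then z.  The relative velocity in F_D carries the streaming correction
γ̇·Δy_min-image so that drag is Galilean-consistent across sheared
boundaries; the correction is active whenever γ̇ ≠ 0, including at t = 0 (it
is exactly this term that breaks the mapping cancellation, see below).

Pair noise is counter-based: ξ_ij at a given step is a splitmix64 hash of
(seed, step, unordered pair) mapped through Box–Muller.  Hence ξ_ij = ξ_ji
(exact momentum conservation), runs are bit-reproducible from their seed,
and the evaluation order (brute force vs. neighbour list) is irrelevant.
Neighbour search uses a Verlet pair list (default skin 0.3) rebuilt by a
vectorized brute-force sweep whenever the two largest accumulated
displacements could have closed the skin gap; at the N ≤ a few hundred of
these protocols a cell decomposition would not pay for itself.

One caveat of the single-force-evaluation scheme: restarting a DPD segment
re-evaluates F_D/F_R at the synchronized state rather than the mid-step one,
so a run split into segments is not bit-identical to an unbroken run (it is
an equally valid realization).  Recorded daughters are always integrated in
one segment.

## Observables

The pressure tensor is the virial form
P_αβ = (1/V)Σ_i[m c_α c_β + ½Σ_{j≠i} r_ij,α F_ij,β] with peculiar velocities
c = p/m; the configurational part is accumulated per pair during force
evaluation, including whichever of F_C, F_D, F_R the variant defines.
Kinetic temperature uses 3N degrees of freedom (no constraint subtraction),
matching the thermostat target.  The recorded P_yx at step k combines the
kinetic term of the end-of-step momenta with the virial of that step's force
evaluation, as engines conventionally do.  Viscosity is Newton's law,
μ = −⟨P_yx⟩/γ̇ (the zero-shear limit is deliberately out of scope; it
belongs to equilibrium Green–Kubo estimators).

## The TTCF estimator

A single equilibrium "mother" trajectory is sampled at decorrelated
intervals; each snapshot seeds a nonequilibrium "daughter" transient with
the field switched on at t = 0 (the momenta are reinterpreted as peculiar,
exact because the streaming velocity vanishes at t = 0).  The transient
response is reconstructed as

    ⟨P_yx(t)⟩ = ⟨P_yx(0)⟩ − (γ̇V/k_BT) ∫₀ᵗ ⟨P_yx(0)P_yx(s)⟩ ds ,

with the integral on the uniform per-step grid by the trapezoidal rule.
With a finite ensemble ⟨P_yx(0)⟩ does not vanish and the integral drifts;
two remedies are provided:

* **Phase-space mappings** (WCA default): each snapshot spawns four
  daughters related by identity, momentum reversal, and y-reflection with
  (p_x,−p_y,p_z) or (−p_x,p_y,−p_z).  For position-only forces the
  quadruplet mean of P_yx(0) is zero *to the last bit* in this
  implementation, because the y-reflection stores y → −y without re-wrapping
  (negation is exact in IEEE arithmetic; minimum-image evaluation does not
  care about the wrap).
* **Covariance correction** (DPD default): the integrand is replaced by
  ⟨P_yx(0)P_yx(s)⟩ − ⟨P_yx(0)⟩⟨P_yx(s)⟩, and the additive ⟨P_yx(0)⟩ term
  may be replaced by its exact equilibrium value 0
  (`impose_zero_initial`) — legal only because ⟨P_yx⟩ = 0 in equilibrium is
  known analytically; the covariance subtraction still uses the empirical
  mean.

Mappings cannot rescue DPD: the dissipative force depends on the streaming
term γ̇Δy, whose quadruplet sum Σ_maps r_ij,x F^D_ij,y vanishes only when the
two beads share an x or y coordinate and grows linearly with γ̇; the random
force cancels only if ξ_ij were shared across the mapped daughters, which
this package does not attempt (per-daughter streams are independent;
synchronizing them across mappings is impractical in general).  The
diagnostics module measures both effects: `mapped_initial_stress` reproduces
the qualitative breakdown pattern (machine zero for WCA/DPD_C/DPD_C_RFIXED;
finite for full DPD; rate-proportional for fixed-ξ DPD), and
`dissipative_mapping_residual` returns the brute-force quadruplet sum
alongside the published closed-form expression.  The closed form carries a
bare x_i factor that is not translation-invariant, so brute force is treated
as ground truth and the two are reported side by side, never reconciled.

The estimators are scikit-learn style (`fit` on the daughters×steps matrix,
fitted `*_` attributes, `get_params`/`set_params`), so they clone cleanly
inside the bootstrap and compose with sklearn tooling.

## Uncertainty

The covariance-corrected TTCF response is a nonlinear function of ensemble
means, so its sampling distribution is estimated by a nonparametric
bootstrap: resample daughters with replacement (sample size = number of
daughters), refit the *full* estimator per resample, take the SD of the
resample distribution as the SE and the 2.5/97.5 percentiles as the 95% CI
(percentile CI chosen over BCa to match the plain construction; swappable).
Default 1200 resamples.  The resampling unit is the whole trajectory — never
individual timesteps, which are serially correlated — and, for mapped
ensembles, the whole quadruplet: the four mapped daughters of one snapshot
are mutually dependent, and single-row resampling would destroy the exact
⟨P_yx(0)⟩ = 0 cancellation, inflating the apparent t = 0 uncertainty by
orders of magnitude at low shear.  Each resample index derives its own seed,
so the procedure is deterministic and trivially partitionable.

Signal-to-noise ratios are SNR = ⟨P_yx⟩/SE; in cross-method comparisons the
numerator is always the TTCF mean (the direct average cannot define the
signal at low rates), divided by whichever method's SE is being assessed.
Because the TTCF response and its SE both scale linearly with γ̇, the TTCF
SNR is shear-rate independent, while the direct-averaging SE is a
rate-independent noise floor — this is the entire case for the method.

## Protocols and problem sizes

Reference protocols (`default_config`): DPD — L = 5 (N = 375), Δt = 0.01,
1500 equilibration steps, mother sampled every 100 steps, 10⁵ daughters of
420 steps, unmapped + corrected + imposed zero; LJ/WCA — N = 256,
Δt = 2.5·10⁻³, 10⁴ equilibration steps, sampled every 1000 steps, 4·10⁴
daughters of 600 steps, mapped.  Initialization is lattice placement
(simple cubic for the soft DPD fluid, FCC for dense WCA) with
Maxwell–Boltzmann momenta, zeroed total momentum and exact kinetic-
temperature rescale; the mother's own equilibration phase makes the start
otherwise immaterial.

Full-scale daughter counts are cluster work.  The package's test battery and
the reproduction script run the same pipelines at desk scale — 500–5000
daughters depending on the check — with statistical bands widened in
proportion.  At these counts the DPD viscosity point estimate carries an
intrinsic spread of roughly 0.2 reduced units (the bootstrap SE extrapolates
to SNR ≈ 10–20 at 10⁵ daughters, consistent with the full-scale study), so
scaled-down numerical agreement is assessed through bootstrap intervals, and
the steady-state value is taken as the plateau mean over the second half of
the transient window rather than the single noisiest final point.

## What the synthetic data do not show

All inputs are generated by the package's own simulator: a single-component,
single-interaction-type fluid in a small periodic cell.  Passing tests
demonstrate the correctness of the integrators, estimators and uncertainty
machinery under exactly these conditions.  They do not probe structured
fluids (polymers, surfactants), long stress-relaxation times (mother
sampling intervals would need re-tuning), system-size effects beyond
N ≈ 400, boundary-driven shear, or real-unit conversions.  The
direct-averaging/TTCF mean offset reported for some engine implementations
of SLLOD is an engine artifact and has no analogue here; no test asserts it.

## Known limitations

* Only xy tilt (planar shear); no general triclinic cells, walls, mixed
  bead types, electrostatics or many-body DPD.
* Segment-restart of stochastic runs is reproducible but not bit-identical
  to unbroken runs (see above).
* The Nosé–Hoover integration uses a simple explicit splitting for α,
  adequate at the protocols' timesteps but not symplectic.
* `viscosity()` refuses γ̇ = 0 by design; equilibrium estimators are out of
  scope.
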