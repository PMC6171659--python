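# Methods

This note records the model assumptions, parameter choices, numerical
decisions and known limitations of the package, in the spirit of a methods
section a maintainer can audit.

## Units

All internal computation uses a reduced system {volume = nm³, time = ps,
energy = kBT}, so β = 1 everywhere. SI-flavoured inputs (pressure in MPa,
viscosity in mPa·s, temperature in K) are converted at a single point
(`landscapes.to_reduced`): 1 MPa = 10⁻²¹ J/nm³ and 1 mPa·s = 10⁻¹⁸ J·ps/nm³,
divided by kBT in joules. Keeping one conversion point avoids the unit bugs
that mixed-convention formulas invite.

## Landscapes

The bubble free energy is G(v) = 4πγ₀r(v)² + pv with r(v) = (3v/4π)^{1/3};
for p < 0 it has a single maximum at vmax = 32πγ₀³/(3|p|³). The
curvature-corrected variant divides the surface term by (1 + 2δ/r(v)) with a
Tolman length δ ≥ 0, and its maximum has the closed form
(4π/3)(γ₀/|p|)³[1 − 4δ/r₀ + √(1+4δ/r₀)]³ with r₀ = 2γ₀/|p|. The bracket was
validated against dense-grid maximisation because the radical's scope is easy
to mis-transcribe; at δ = 0 it reduces exactly to 2³, recovering the plain
expression. Barrier curvature ω = |G''(vmax)| is analytic for the plain
model (G'' = −(2/9)γ₀(36π)^{1/3}v^{−4/3}) and by central differences with
step 10⁻⁴·vmax for the Tolman variant, whose closed-form second derivative
is long and error-prone.

The diffusivity is the Rayleigh–Plesset form D(v) = (3kBT/4η)·v — linear in
the bubble volume, no intercept, set by the liquid viscosity alone. At the
reference conditions (γ₀ = 17.09 kBT/nm², p = −135 MPa, T = 296.4 K,
η = 1.00 mPa·s) the slope is 3.069×10⁻³ nm³/ps, vmax = 4.659 nm³,
ω = 2.36 kBT/nm⁶ and D(vmax) = 1.43×10⁻² nm⁶/ps. These conditions are the
package-wide defaults.

## Synthetic trajectories

The generator integrates the Itô Langevin equation with the
multiplicative-noise drift D′(v) included, which is what preserves
equilibrium ∝ e^{−G} under state-dependent noise (verified by an
equilibrium-histogram test). Defaults emulate the reference study
conditions: time step Δt = 1 fs, samples recorded every 10 steps,
trajectories started exactly at the barrier top (an optional Gaussian jitter
exists but defaults to zero) and absorbed at walls placed symmetrically
±1.30 nm³ around vmax; 2000 trajectories per ensemble. Exit is detected
after a full step with no sub-step interpolation of the crossing time — an
O(Δt) error consistent with the integrator's own fidelity. Censored
trajectories (step cap reached) are retained and flagged, never silently
dropped. Each trajectory owns an RNG stream spawned from the ensemble seed
(consumed in fixed blocks of 1024 draws), so ensembles are bit-reproducible
and any single trajectory can be regenerated in isolation.

What the generator does not emulate: real molecular trajectories carry
short-time memory, a fluctuating (not analytic) landscape, and a reaction
coordinate that is itself an imperfect projection. Passing recovery tests on
synthetic data therefore demonstrates the estimator's correctness for
genuinely Markovian diffusive input, not that any particular molecular
coordinate satisfies those assumptions.

## Counting

Transitions are counted over non-overlapping windows of lag τ (τ must be an
integer multiple of the recording interval); overlap would break the
independence the product likelihood assumes. The source bin is the
fixed-grid bin of the window's first sample; the destination is obtained on
a grid shifted to centre that sample, operationally: i = j +
round(Δv_window/Δv). A trajectory exiting mid-window contributes one final
transition into the absorbing pseudo-bin at that window, and nothing after.
Absorbing columns of the count matrix are structurally zero.

## Inference

Parameters are the n+1 upward/absorbing rates (log space, guaranteeing
positivity) and the n interior log-occupancies (gauge-fixed to Σp = 1;
downward rates follow from detailed balance, diagonals from conservation).
The propagator of the singular augmented generator is evaluated two ways:
scaling-and-squaring on the full (n+2)² matrix (public `propagator`), and a
spectral route used inside the sampling loop — the interior block is
symmetrised by the diag(√p) similarity that detailed balance guarantees,
diagonalised stably with a symmetric tridiagonal eigensolver, and the
absorption probabilities recovered from the time integral of the interior
semigroup using expm1-safe divided differences. The two routes agree to
~10⁻¹⁵ and are cross-checked in the tests, together with stochasticity,
stationarity (reflective variant) and gauge-invariance invariants.

The annealed Metropolis sampler perturbs one parameter per step (uniform
displacement; rates and occupancies have separate step sizes auto-tuned to
30–50% acceptance during the first 10% of steps only), ramps α geometrically
from 0.1 to 100 over the first 80% of steps, then holds it; the chain stops
when the best log-likelihood improves by less than 10⁻³ over a trailing 10%
window (checked only after the ramp). The returned model is the
best-likelihood point visited. When no initial profile is supplied, D is
initialised constant at Δv²/(2τ) — the value for which τ equals the mean
one-bin residence time — and G flat; a prescribed-free-energy mode freezes
the occupancies to a supplied profile and samples only rates. An optional
deterministic refinement (`polish`: L-BFGS-B with tight tolerances, then a
simplex pass to absorb finite-difference noise) is available for analyses
that need the exact likelihood maximiser; it is off by default because
uncertainties are quoted as standard deviations over independent replicate
chains (5 by default), and a fully converged optimiser would collapse that
spread to numerical noise.

Profiles are reported as G at the n bin centres (gauge-shifted to zero at
the bin nearest the range centre) and D at the n−1 interior edges via
Δv²√(R_{j+1,j}R_{j,j+1}); the two absorbing rates are reported separately in
the diagnostics, since without an occupancy beyond the wall they are not
identifiable as diffusivities.

### Known discretisation bias

Fitting a nearest-neighbour master equation to binned continuous diffusion
is systematically biased at coarse discretisation. An independent oracle
makes this quantitative: for free diffusion, the infinite-data maximum
likelihood fit of the birth–death propagator e^{−2ρ}I_d(2ρ) to the exactly
discretised Gaussian displacement histogram overestimates D by +35% at
σ²/Δv² = 0.12 (the τ = 0.05 ps case below), +14.4% at σ²/Δv² = 1.22
(n = 24, τ = 0.5 ps), +5.8% at τ = 1.0 ps and +2.4% at n = 48 — and the full
pipeline reproduces each of these numbers to within a percentage point.
Roughly half of the +14.4% is Sheppard-type variance inflation from rounding
displacements to whole bins, the rest shape mismatch between the chain's
leptokurtic propagator and the Gaussian kernel. The bias falls rapidly with
larger τ or finer bins while the statistical spread grows with τ (fewer
windows) — the bias/variance trade-off that drives lag-time selection. The
free-energy estimate is far less affected (within ~0.2 kBT at n = 24).
Consequence: at the standard study conditions (n = 24, τ = 0.5 ps, range
2.60 nm³, 2000 trajectories) individual edge diffusivities sit ~11–19% above
the generating curve, and a per-edge 15% agreement band is right at the
systematic bias and is not reliably met; a 48-bin or τ = 1 ps analysis sits
well inside it.

## Mean first passage times

The empirical MFPT averages, over trajectories sharing a start point, the
first recorded time at which |v − v₀| ≥ b; trajectories never reaching b are
excluded and counted. Because crossings between recorded samples are
missed, the estimate carries a positive bias equivalent to a boundary shift
of ≈0.58·√(2D·dt_rec); MFPT ensembles are therefore recorded at stride 1–2,
and walls must lie beyond the largest probed b (ensembles whose walls are
inside are refused to avoid censoring bias). The parabolic-barrier closed
form (b²/2D)·₂F₂(1,1; 2,3/2; −ωb²/2) is summed directly with a term-ratio
stopping rule at 10⁻¹⁶ relative — the series converges absolutely for all
arguments and is benign in double precision over the range used (ωb²/2 ≤ 10)
— and is validated against an independent nested-quadrature form of the
backward equation (reflecting boundary at the symmetric barrier top,
absorbing at distance b), whose small-b expansion reproduces the quadratic
truncation (1 − ωb²/6) exactly. The lag-time rule returns Δv²/(2D(vmax)) as
a baseline with a practical [1×, 2×] range.

## Problem sizes in the shipped tests and acceptance script

The verification suite runs the reference study at 2000 trajectories with
five replicate chains of 40 000 Metropolis steps (lag times 0.05–3.0 ps),
flat-landscape MFPT at 5000 finely-recorded trajectories, and smaller
ensembles (200–600 trajectories) for distributional unit tests; the
acceptance script runs the recovery study at 1000 trajectories with three
replicates. These sizes keep a full run in the minutes range on one CPU
while leaving every statistical tolerance dominated by the effect under
test, not by the sample size.

## Limitations

- Uniform prior only; no continuity or reference-biasing priors on rates.
- Equal-width bins only; uncertainties by replicate spread, not posterior
  sampling.
- No curvature-dependent viscosity model for the diffusivity.
- The reflective-boundary generator variant exists for testing invariants,
  not as a production mode; production analyses assume absorbing ends.
- Molecular-dynamics input is read through the same trajectory container,
  but generating such data (thermostats, bubble-volume detection from
  coordinates) is out of scope.
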