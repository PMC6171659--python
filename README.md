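# ratescape

Extracting a position-dependent diffusion coefficient D(q) and a free-energy
profile G(q) along a one-dimensional reaction coordinate from ensembles of
short barrier-crossing trajectories, by Bayesian inference of a
detailed-balance rate matrix.

The package targets nucleation-type problems — the worked case throughout is
the cavitation of vapour bubbles in water under strong tension, with the
largest-bubble volume v as the reaction coordinate — but the machinery applies
to any scalar coordinate with approximately Markovian, diffusive dynamics:
crystallisation nuclei, droplet condensation, or any barrier crossing analysed
in the Kramers picture. Both the barrier shape G(q) and the diffusivity D(q)
enter classical nucleation-rate estimates (through the Zeldovich factor and
the attachment rate), and this package recovers them simultaneously from
dynamics alone.

## The method

The overdamped dynamics of the coordinate obeys a Smoluchowski equation

    ∂t p(q,t) = ∂q D(q) e^{−βG(q)} ∂q e^{βG(q)} p(q,t).

Discretising the coordinate into n bins of width Δq maps this to a master
equation with a tridiagonal rate matrix R whose off-diagonals encode both
profiles:

    R_{j+1,j} = (D_j + D_{j+1}) / (2Δq²) · (p_{j+1}/p_j)^{1/2},
    R_{j,j+1} = R_{j+1,j} · p_j / p_{j+1}      (detailed balance),

with p_j ∝ e^{−βG_j} the equilibrium occupancies. Trajectories started near
the barrier top and absorbed at the ends of the sampling range are sliced
into non-overlapping windows of a lag time τ; the number N_ij of j→i
transitions gives, under a uniform prior, the log-posterior

    ln L = Σ_ij N_ij ln (e^{τR})_{ij},

which is maximised over the independent parameters (upward and absorbing
rates in log space, log-occupancies) by single-parameter Metropolis moves
accepted with probability min[1, e^{α ΔlnL}] under a geometrically ramped
annealing parameter α. Absorbing walls enter as pseudo-bins with no outgoing
rates, which makes R singular; the propagator e^{τR} is still well defined
and is evaluated both by scaling-and-squaring and by a fast spectral route.
Free energies are read off as G_j = −ln p_j and edge diffusivities as
D_{j+1/2} = Δq²(R_{j+1,j} R_{j,j+1})^{1/2}; error bars are standard
deviations over independent replicate chains.

The built-in synthetic-data source integrates the Itô Langevin equation

    v(t+Δt) = v(t) + [D′(v) − βG′(v)D(v)]Δt + g √(2D(v)Δt)

on the classical-nucleation-theory landscape G(v) = 4πγ₀r(v)² + pv with the
Rayleigh–Plesset diffusivity D(v) = (3kBT/4η)·v, and a
mean-first-passage-time toolkit supplies the lag-time heuristic
τ ≈ Δv²/2D(vmax) together with the parabolic-barrier closed form
MFPT(b) = (b²/2D)·₂F₂(1,1; 2,3/2; −βωb²/2).

## A worked example

```python
import ratescape as rs

params = rs.LandscapeParams(gamma0=17.09, pressure=-135.0,
                            temperature=296.4, viscosity=1.00)
vmax = rs.critical_volume(params)            # 4.659 nm^3
cfg = rs.SimulationConfig(wall_lo=vmax - 1.3, wall_hi=vmax + 1.3,
                          n_traj=500, seed=7)
ens = rs.generate_ensemble(cfg, rs.NucleationLandscape(params),
                           barrier_top=vmax)
grid = rs.Grid.centered(vmax, 2.60, 24)
counts = rs.count_transitions(ens, grid, tau=0.5)
prof = rs.replicate_inference(counts, grid,
                              rs.McmcConfig(steps=30_000, replicates=3, seed=11))
```

Running `python examples/03_infer_profiles.py` (exactly this analysis, with
the comparison table) prints

```
 v (nm^3)   G_est    G_ref    |   v_edge    D_est      D_ref
   4.496   -0.020   -0.028   |    4.551 1.6254e-02 1.3967e-02
   4.821    0.081   -0.027   |    4.876 1.6605e-02 1.4964e-02
   ...
D(v) mean |relative error| on interior edges: 15.3%
```

G_est tracks the generating CNT profile to a few tenths of kBT across the
sampled range. D_est is systematically ~15% above the Rayleigh–Plesset line:
that is the known discretisation bias of a 24-bin analysis at this lag time
(see docs/methods.md), which shrinks rapidly with more bins or a longer lag
— the bias/variance trade-off that the lag-time study in the test suite
exercises. The other examples cover the barrier geometry and lag-time rule
(`01`), trajectory generation and counting (`02`), and MFPT analysis (`04`).

A thin CLI wraps the same calls: `ratescape simulate | count | infer | mfpt |
pipeline | fixtures | landscape` (see `ratescape --help`).

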