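"""Bayesian inference of a detailed-balance rate matrix from lag-time counts.

The discretised Smoluchowski equation yields a tridiagonal generator R whose
off-diagonals encode the diffusivity and equilibrium occupancies,

    R[j+1, j] = (D_j + D_{j+1}) / (2 dv^2) * sqrt(p_{j+1} / p_j),

with downward rates fixed by detailed balance, R[j, j+1] = R[j+1, j] p_j /
p_{j+1}, and diagonal entries set by probability conservation (interior
columns sum to zero).  Absorbing walls appear as pseudo-bins 0 and n+1 that
receive probability at finite rates but have no outgoing rates, making R
singular and mildly non-normal.

Given observed lag-tau transition counts N[i, j], the log-likelihood under a
uniform prior is  ln L = sum_ij N[i, j] * ln (exp(tau R))[i, j].  This module
maximises ln L over the independent parameters — the n+1 upward/absorbing
rates (in log space) and the n interior log-occupancies (gauge-fixed to sum
to one) — with single-parameter Metropolis moves accepted with probability
min(1, exp(alpha * dlnL)) under a geometrically ramped annealing parameter
alpha, optionally followed by a local quasi-Newton refinement of the best
point found.  Free energies are read off as G_j = -ln p_j and edge
diffusivities as D_{j+1/2} = dv^2 sqrt(R[j+1, j] R[j, j+1]).

The propagator of the augmented (n+2) generator is evaluated in two
independent ways: a general scaling-and-squaring matrix exponential
(:func:`propagator`), and a fast spectral route that exploits the symmetric
tridiagonal similarity transform of the interior block and obtains the
absorption probabilities from the time integral of the interior propagator
(used inside the likelihood loop).  The two agree to near machine precision
and are cross-checked in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import scipy.linalg
import scipy.optimize

from .discretize import ConfigError, Grid, TransitionCounts

__all__ = [
    "RateModel",
    "ProfileEstimate",
    "McmcConfig",
    "model_from_profiles",
    "build_rate_matrix",
    "propagator",
    "log_likelihood",
    "mcmc_optimize",
    "extract_profiles",
    "replicate_inference",
]

_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class RateModel:
    """Independent parameters of the detailed-balance rate matrix.

    ``log_rates`` has length n+1 in edge order: ln R[0, 1] (left absorbing),
    ln R[j+1, j] for j = 1..n-1, ln R[n+1, n] (right absorbing).
    ``log_p`` holds the n interior log-occupancies, gauge-fixed so the
    occupancies sum to one.
    """

    log_rates: np.ndarray
    log_p: np.ndarray
    grid: Grid
    tau: float

    def __post_init__(self) -> None:
        lr = np.asarray(self.log_rates, dtype=float)
        lp = np.asarray(self.log_p, dtype=float)
        if lr.shape != (self.grid.n + 1,):
            raise ValueError(f"log_rates must have length n+1={self.grid.n + 1}")
        if lp.shape != (self.grid.n,):
            raise ValueError(f"log_p must have length n={self.grid.n}")
        if not (np.all(np.isfinite(lr)) and np.all(np.isfinite(lp))):
            raise ValueError("non-finite model parameters")
        object.__setattr__(self, "log_rates", lr)
        object.__setattr__(self, "log_p", lp - _logsumexp(lp))

    @property
    def occupancies(self) -> np.ndarray:
        return np.exp(self.log_p)

    @property
    def up_rates(self) -> np.ndarray:
        """R[j+1, j] for j = 1..n-1 (interior upward rates)."""
        return np.exp(self.log_rates[1:-1])

    @property
    def down_rates(self) -> np.ndarray:
        """R[j, j+1] for j = 1..n-1, from detailed balance."""
        lp = self.log_p
        return np.exp(self.log_rates[1:-1] + lp[:-1] - lp[1:])

    @property
    def rate_left_abs(self) -> float:
        return float(np.exp(self.log_rates[0]))

    @property
    def rate_right_abs(self) -> float:
        return float(np.exp(self.log_rates[-1]))


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    return float(m + np.log(np.sum(np.exp(x - m))))


def model_from_profiles(
    grid: Grid,
    tau: float,
    G: Optional[np.ndarray] = None,
    D_edges: Optional[np.ndarray] = None,
    D0: Optional[float] = None,
) -> RateModel:
    """Build a RateModel from free-energy and diffusivity profiles.

    ``G`` is evaluated at bin centres (kBT; flat if omitted) and ``D_edges``
    at the n-1 interior edges.  If neither ``D_edges`` nor the constant
    ``D0`` is given, the heuristic D0 = dv^2 / (2 tau) is used — the
    diffusivity for which tau is the mean time to first leave a bin.
    Absorbing rates are initialised like interior edge rates with the
    occupancy factor set to one (no occupancy is defined beyond the wall).
    """
    n, dv = grid.n, grid.dv
    lp = np.zeros(n) if G is None else -np.asarray(G, dtype=float)
    lp = lp - _logsumexp(lp)
    if D_edges is None:
        d0 = dv * dv / (2.0 * tau) if D0 is None else D0
        D_edges = np.full(n - 1, d0)
    else:
        D_edges = np.asarray(D_edges, dtype=float)
        d0 = float(np.mean(D_edges))
    log_up = np.log(D_edges / (dv * dv)) + 0.5 * (lp[1:] - lp[:-1])
    log_abs = math.log(d0 / (dv * dv))
    log_rates = np.concatenate(([log_abs], log_up, [log_abs]))
    return RateModel(log_rates=log_rates, log_p=lp, grid=grid, tau=tau)


def build_rate_matrix(model: RateModel) -> np.ndarray:
    """Assemble the full (n+2)x(n+2) generator.

    Columns 0 and n+1 are identically zero (no escape from the absorbing
    pseudo-bins); interior columns sum to zero.
    """
    n = model.grid.n
    R = np.zeros((n + 2, n + 2))
    up = model.up_rates
    down = model.down_rates
    j = np.arange(1, n)  # interior edges between bins j and j+1
    R[j + 1, j] = up
    R[j, j + 1] = down
    R[0, 1] = model.rate_left_abs
    R[n + 1, n] = model.rate_right_abs
    cols = np.arange(1, n + 1)
    R[cols, cols] = 0.0
    R[cols, cols] = -R[:, cols].sum(axis=0)
    return R


def propagator(R: np.ndarray, tau: float) -> np.ndarray:
    """Stochastic propagator exp(tau R) of the augmented generator.

    Uses scaling-and-squaring (well-defined for the singular,
    non-diagonalisable generators that absorbing boundaries produce).
    Columns must sum to one within 1e-10; entries within -1e-12 of zero are
    clipped, anything more negative raises.
    """
    P = scipy.linalg.expm(tau * np.asarray(R, dtype=float))
    if np.min(P) < -1e-12:
        raise FloatingPointError(
            f"propagator entry {np.min(P):.3e} below tolerance; generator ill-conditioned"
        )
    np.clip(P, 0.0, None, out=P)
    colsums = P.sum(axis=0)
    if np.max(np.abs(colsums - 1.0)) > 1e-10:
        raise FloatingPointError("propagator columns do not sum to 1")
    return P


def _spectral_propagator(model: RateModel):
    """Fast propagator via the symmetric-tridiagonal similarity transform.

    Returns ``(P_int, p_left, p_right)``: the n x n interior block of
    exp(tau R), and the absorption probabilities into the left/right
    pseudo-bins from each interior source bin.  Detailed balance makes
    S = diag(p)^(-1/2) R_int diag(p)^(1/2) symmetric tridiagonal, so the
    interior block diagonalises stably; the absorption probabilities follow
    from  P_abs(tau) = r_abs * Integral_0^tau (exp(s R_int))[wall row] ds,
    evaluated spectrally with expm1 for accuracy.
    """
    n = model.grid.n
    up = model.up_rates
    down = model.down_rates
    diag = np.zeros(n)
    diag[:-1] -= up
    diag[1:] -= down
    diag[0] -= model.rate_left_abs
    diag[-1] -= model.rate_right_abs
    offdiag = np.sqrt(up * down)  # = up_j * sqrt(p_j / p_{j+1})
    if n > 1:
        w, V = scipy.linalg.eigh_tridiagonal(diag, offdiag)
    else:
        w, V = diag.copy(), np.ones((1, 1))
    s = np.exp(0.5 * model.log_p)
    tw = model.tau * w
    # interior block: diag(s) V exp(tau w) V^T diag(1/s)
    expw = np.exp(tw)
    A = V * expw
    M = A @ V.T
    P_int = (s[:, None] * M) / s[None, :]
    # integral of the semigroup: phi(w) = (exp(tau w) - 1) / w, -> tau as w -> 0
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(np.abs(tw) > 1e-8, np.expm1(tw) / w, model.tau * (1.0 + 0.5 * tw))
    F = (V * phi) @ V.T
    Q_row_first = (s[0] * F[0]) / s  # row of interior bin 1
    Q_row_last = (s[-1] * F[-1]) / s  # row of interior bin n
    p_left = model.rate_left_abs * Q_row_first
    p_right = model.rate_right_abs * Q_row_last
    np.clip(P_int, 0.0, None, out=P_int)
    np.clip(p_left, 0.0, None, out=p_left)
    np.clip(p_right, 0.0, None, out=p_right)
    return P_int, p_left, p_right


def log_likelihood(model: RateModel, counts: TransitionCounts) -> float:
    """ln L = sum over observed transitions of N_ij ln (exp(tau R))_ij.

    Under a uniform prior this is also the log-posterior.  Propagator
    entries at or below the floor (1e-300) with nonzero counts give -inf,
    which the Metropolis rule rejects.
    """
    if counts.grid != model.grid:
        raise ConfigError("counts and model use different grids")
    if abs(counts.tau - model.tau) > 1e-12:
        raise ConfigError("counts and model use different lag times")
    P_int, p_left, p_right = _spectral_propagator(model)
    n = model.grid.n
    N = counts.counts
    total = 0.0
    for probs, Nrow in (
        (P_int, N[1 : n + 1, 1 : n + 1]),
        (p_left, N[0, 1 : n + 1]),
        (p_right, N[n + 1, 1 : n + 1]),
    ):
        mask = Nrow > 0
        if not np.any(mask):
            continue
        pv = np.asarray(probs)[mask]
        if np.any(pv <= _LOG_FLOOR):
            return -math.inf
        total += float(np.sum(Nrow[mask] * np.log(pv)))
    return total


@dataclass(frozen=True)
class McmcConfig:
    """Settings for the annealed Metropolis maximisation.

    ``alpha`` is an artificial inverse temperature: low values let the chain
    traverse a rough likelihood landscape early on; it is ramped
    geometrically to ``alpha_final`` over the first ``ramp_fraction`` of the
    steps and held there.  Step sizes are tuned toward 30-50% acceptance
    during the initial low-alpha phase only.  ``polish`` runs a local
    deterministic refinement from the best sampled point; it is off by
    default because replicate-to-replicate spread of independent chains is
    the uncertainty estimate, and a fully converged local optimiser would
    collapse that spread.
    """

    steps: int = 40_000
    alpha_initial: float = 0.1
    alpha_final: float = 100.0
    ramp_fraction: float = 0.8
    rate_step: float = 0.25
    occ_step: float = 0.25
    seed: int = 0
    replicates: int = 5
    fixed_free_energy: Optional[np.ndarray] = None
    tol: float = 1e-3
    polish: bool = False
    autotune: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha_initial <= self.alpha_final:
            raise ValueError("need 0 < alpha_initial <= alpha_final")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.steps < 100:
            raise ValueError("steps must be >= 100")


class StepSizeError(RuntimeError):
    pass


def _pack(model: RateModel, fixed_G: bool) -> np.ndarray:
    if fixed_G:
        return model.log_rates.copy()
    return np.concatenate([model.log_rates, model.log_p])


def _unpack(x: np.ndarray, template: RateModel, fixed_G: bool) -> RateModel:
    n = template.grid.n
    if fixed_G:
        return replace(template, log_rates=x.copy())
    return replace(template, log_rates=x[: n + 1].copy(), log_p=x[n + 1 :].copy())


def mcmc_optimize(
    counts: TransitionCounts,
    grid: Grid,
    mcmc: McmcConfig,
    init: Optional[RateModel] = None,
) -> tuple:
    """Maximise the count likelihood by annealed single-parameter Metropolis.

    Returns ``(best_model, diagnostics)``.  If ``mcmc.fixed_free_energy`` is
    set, the occupancies are frozen to exp(-G) (renormalised) and only the
    rates are sampled — the prescribed-free-energy mode.  When ``init`` is
    omitted the chain starts from a flat (or prescribed) free energy and the
    constant diffusivity D0 = dv^2/(2 tau).
    """
    n = grid.n
    tau = counts.tau
    fixed_G = mcmc.fixed_free_energy is not None
    if init is None:
        G0 = mcmc.fixed_free_energy if fixed_G else None
        model = model_from_profiles(grid, tau, G=G0)
    else:
        model = init
        if fixed_G:
            lp = -np.asarray(mcmc.fixed_free_energy, dtype=float)
            model = replace(model, log_p=lp - _logsumexp(lp))

    rng = np.random.Generator(np.random.PCG64(mcmc.seed))
    n_rates = n + 1
    n_params = n_rates if fixed_G else n_rates + n
    x = _pack(model, fixed_G)
    lnL = log_likelihood(_unpack(x, model, fixed_G), counts)
    if not np.isfinite(lnL):
        raise RuntimeError("initial model has zero likelihood; check counts/grid/tau")

    best_x, best_lnL = x.copy(), lnL
    rate_step, occ_step = mcmc.rate_step, mcmc.occ_step
    ramp_steps = max(1, int(mcmc.ramp_fraction * mcmc.steps))
    log_alpha0, log_alpha1 = math.log(mcmc.alpha_initial), math.log(mcmc.alpha_final)
    tune_until = mcmc.steps // 10
    window = max(1, mcmc.steps // 10)

    n_accept = 0
    accept_window = 0
    window_start_best = best_lnL
    alpha_trace = []
    lnL_trace = []

    # pre-draw in blocks for speed
    for step in range(mcmc.steps):
        frac = min(step / ramp_steps, 1.0)
        alpha = math.exp(log_alpha0 + frac * (log_alpha1 - log_alpha0))
        k = int(rng.integers(n_params))
        delta = (rate_step if k < n_rates else occ_step) * (2.0 * rng.random() - 1.0)
        x_new = x.copy()
        x_new[k] += delta
        cand = _unpack(x_new, model, fixed_G)
        lnL_new = log_likelihood(cand, counts)
        if lnL_new - lnL > 0 or rng.random() < math.exp(
            min(0.0, alpha * (lnL_new - lnL))
        ):
            # renormalised gauge is applied inside RateModel construction
            x = _pack(cand, fixed_G)
            lnL = lnL_new
            n_accept += 1
            accept_window += 1
            if lnL > best_lnL:
                best_lnL = lnL
                best_x = x.copy()
        if mcmc.autotune and step < tune_until and (step + 1) % 250 == 0:
            rate = accept_window / 250.0
            if rate < 0.30:
                rate_step *= 0.8
                occ_step *= 0.8
            elif rate > 0.50:
                rate_step *= 1.25
                occ_step *= 1.25
            if rate == 0.0 and step + 1 >= 500:
                raise StepSizeError(
                    "no Metropolis moves accepted at alpha_initial; reduce "
                    "rate_step/occ_step or check that the counts are consistent "
                    "with the grid and lag time"
                )
            accept_window = 0
        if (step + 1) % window == 0:
            lnL_trace.append(best_lnL)
            alpha_trace.append(alpha)
            if step >= ramp_steps and best_lnL - window_start_best < mcmc.tol:
                break
            window_start_best = best_lnL

    model = _unpack(best_x, model, fixed_G)
    polish_improved = 0.0
    if mcmc.polish:
        model, gain = _polish(model, counts, fixed_G)
        polish_improved = gain
        best_lnL += gain

    diagnostics = {
        "log_likelihood": float(best_lnL),
        "acceptance_rate": n_accept / max(1, step + 1),
        "steps_run": step + 1,
        "alpha_final": alpha,
        "rate_step_final": rate_step,
        "occ_step_final": occ_step,
        "polish_gain": float(polish_improved),
        "lnL_trace": [float(v) for v in lnL_trace],
    }
    return model, diagnostics


def _polish(model: RateModel, counts: TransitionCounts, fixed_G: bool):
    """Local refinement of the sampled optimum.

    Quasi-Newton with finite differences first (tight tolerances: the
    log-likelihood magnitude is the total count, so the default relative
    stopping rule would quit far from the stationary point), then a
    derivative-free simplex pass to mop up finite-difference noise.
    """
    x0 = _pack(model, fixed_G)
    lnL0 = log_likelihood(model, counts)

    def neg_lnL(x):
        val = log_likelihood(_unpack(x, model, fixed_G), counts)
        return 1e12 if not np.isfinite(val) else -val

    res = scipy.optimize.minimize(
        neg_lnL,
        x0,
        method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-9},
    )
    x_best, f_best = (res.x, res.fun) if res.fun < -lnL0 else (x0, -lnL0)
    res2 = scipy.optimize.minimize(
        neg_lnL,
        x_best,
        method="Nelder-Mead",
        options={
            "maxiter": 20000,
            "maxfev": 20000,
            "fatol": 1e-9,
            "xatol": 1e-9,
            "adaptive": True,
        },
    )
    if res2.fun < f_best:
        x_best, f_best = res2.x, res2.fun
    if -f_best > lnL0:
        return _unpack(x_best, model, fixed_G), float(-f_best - lnL0)
    return model, 0.0


@dataclass(frozen=True)
class ProfileEstimate:
    """Free energy at bin centres and diffusivity at interior bin edges.

    ``G_centers`` is gauge-shifted so the bin nearest the range centre has
    G = 0.  ``D_edges`` has length n-1; the two absorbing rates are reported
    in ``diagnostics`` (they are not identifiable as diffusivities without
    an occupancy beyond the wall).  ``G_std``/``D_std`` are standard
    deviations over independent MCMC replicates (zero for a single run).
    """

    grid: Grid
    G_centers: np.ndarray
    D_edges: np.ndarray
    G_std: np.ndarray
    D_std: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def centers(self) -> np.ndarray:
        return self.grid.centers

    @property
    def edge_positions(self) -> np.ndarray:
        return self.grid.interior_edges


def _gauge_shift(G: np.ndarray, grid: Grid) -> np.ndarray:
    center = 0.5 * (grid.v_lo + grid.v_hi)
    anchor = int(np.argmin(np.abs(grid.centers - center)))
    return G - G[anchor]


def extract_profiles(model: RateModel, diagnostics: Optional[dict] = None) -> ProfileEstimate:
    """Read G and D off a rate model.

    G_j = -ln p_j up to the gauge shift; the edge diffusivity is the
    geometric-mean form D_{j+1/2} = dv^2 sqrt(R[j+1, j] R[j, j+1]), which
    equals (D_j + D_{j+1})/2 under the discretisation used to build R.
    """
    grid = model.grid
    G = _gauge_shift(-model.log_p, grid)
    D = grid.dv ** 2 * np.sqrt(model.up_rates * model.down_rates)
    diag = dict(diagnostics or {})
    diag.setdefault("rate_left_abs", model.rate_left_abs)
    diag.setdefault("rate_right_abs", model.rate_right_abs)
    return ProfileEstimate(
        grid=grid,
        G_centers=G,
        D_edges=D,
        G_std=np.zeros_like(G),
        D_std=np.zeros_like(D),
        diagnostics=diag,
    )


def replicate_inference(
    counts: TransitionCounts,
    grid: Grid,
    mcmc: McmcConfig,
    init: Optional[RateModel] = None,
) -> ProfileEstimate:
    """Run ``mcmc.replicates`` independent chains and aggregate profiles.

    Point estimates are per-point means over replicates; the spreads are
    per-point standard deviations, the replicate-error convention used for
    the error bars throughout.
    """
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
             np.random.SeedSequence(mcmc.seed).spawn(mcmc.replicates)]
    Gs, Ds, diags = [], [], []
    for s in seeds:
        model, d = mcmc_optimize(counts, grid, replace(mcmc, seed=s), init=init)
        prof = extract_profiles(model, d)
        Gs.append(prof.G_centers)
        Ds.append(prof.D_edges)
        diags.append(d)
    Gs, Ds = np.array(Gs), np.array(Ds)
    ddof = 1 if len(seeds) > 1 else 0
    diagnostics = {
        "replicates": len(seeds),
        "seeds": seeds,
        "log_likelihoods": [d["log_likelihood"] for d in diags],
        "acceptance_rates": [d["acceptance_rate"] for d in diags],
    }
    return ProfileEstimate(
        grid=grid,
        G_centers=Gs.mean(axis=0),
        D_edges=Ds.mean(axis=0),
        G_std=Gs.std(axis=0, ddof=ddof) if len(seeds) > 1 else np.zeros(grid.n),
        D_std=Ds.std(axis=0, ddof=ddof) if len(seeds) > 1 else np.zeros(grid.n - 1),
        diagnostics=diagnostics,
    )
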