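"""Overdamped Langevin simulator with multiplicative noise.

Trajectories of a scalar coordinate ``v`` (here the bubble volume) evolve by
the Ito form of the Langevin equation on a landscape G(v) with
position-dependent diffusivity D(v):

    v(t + dt) = v(t) + [D'(v) - G'(v) D(v)] dt + g * sqrt(2 D(v) dt)

with ``g`` a standard normal draw and beta = 1 (energies in kBT).  The
``D'`` drift term is required by the Ito convention so that the equilibrium
distribution remains proportional to ``exp(-G(v))`` despite the
state-dependent noise amplitude.

Ensembles of short trajectories are started near the barrier top and run
until they hit one of two absorbing walls; these are the raw data for the
transition counting and rate-matrix inference downstream.

Each trajectory owns an independent RNG stream spawned deterministically
from the ensemble seed, so the ensemble is reproducible and any single
trajectory can be regenerated in isolation.  Streams are consumed in fixed
blocks of :data:`NOISE_BLOCK` draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .landscapes import Landscape

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "TrajectoryEnsemble",
    "ito_step",
    "run_trajectory",
    "generate_ensemble",
]

#: Number of normal draws consumed per trajectory per block.
NOISE_BLOCK = 1024


class SimulationDomainError(RuntimeError):
    """The coordinate reached a region where D(v) <= 0."""


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for one trajectory ensemble.

    ``v_start`` may be a number (nm^3) or the string ``"barrier_top"``, in
    which case the caller resolves it to the landscape's barrier position.
    ``start_jitter`` adds a Gaussian spread (nm^3, std) around the start.
    """

    wall_lo: float
    wall_hi: float
    v_start: float | str = "barrier_top"
    dt: float = 0.001  # ps (1 fs)
    record_stride: int = 10
    max_steps: int = 2_000_000
    n_traj: int = 2000
    seed: int = 0
    start_jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        if not self.wall_lo < self.wall_hi:
            raise ValueError("wall_lo must be < wall_hi")
        if isinstance(self.v_start, (int, float)) and not (
            self.wall_lo < self.v_start < self.wall_hi
        ):
            raise ValueError("v_start must lie strictly between the walls")

    @property
    def dt_record(self) -> float:
        return self.dt * self.record_stride


@dataclass(frozen=True)
class Trajectory:
    """A uniformly sampled coordinate time series with termination metadata.

    ``values[0]`` is the start point; samples are ``dt_record`` apart.  A
    trajectory that hit a wall has ``exit`` set to ``"left"`` or ``"right"``
    and ``exit_time`` to the time of the first crossing step; an unterminated
    one is ``"censored"`` with ``exit_time`` equal to the simulated span.
    Recorded values always lie inside the walls (the crossing value itself is
    not recorded).
    """

    values: np.ndarray
    dt_record: float
    exit: str  # "left" | "right" | "censored"
    exit_time: float

    def __post_init__(self) -> None:
        if self.exit not in ("left", "right", "censored"):
            raise ValueError(f"invalid exit cause {self.exit!r}")


@dataclass(frozen=True)
class TrajectoryEnsemble:
    trajectories: tuple
    config: SimulationConfig
    landscape_name: str = "custom"

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    @property
    def dt_record(self) -> float:
        return self.config.dt_record

    def exit_counts(self) -> dict:
        out = {"left": 0, "right": 0, "censored": 0}
        for t in self.trajectories:
            out[t.exit] += 1
        return out


def ito_step(v, dt: float, landscape: Landscape, gauss):
    """One Euler--Maruyama update; ``v`` and ``gauss`` may be arrays."""
    v = np.asarray(v, dtype=float)
    D = np.asarray(landscape.diffusivity(v), dtype=float)
    if np.any(D <= 0):
        raise SimulationDomainError(
            f"non-positive diffusivity encountered at v={np.ravel(v)[np.argmin(D)]:.6g}"
        )
    drift = np.asarray(landscape.diffusivity_grad(v), dtype=float) - np.asarray(
        landscape.free_energy_grad(v), dtype=float
    ) * D
    out = v + drift * dt + np.asarray(gauss) * np.sqrt(2.0 * D * dt)
    return out if out.ndim else float(out)


def _resolve_start(config: SimulationConfig, barrier_top: float | None) -> float:
    if isinstance(config.v_start, str):
        if config.v_start != "barrier_top":
            raise ValueError(f"unknown v_start {config.v_start!r}")
        if barrier_top is None:
            raise ValueError("v_start='barrier_top' requires barrier_top=")
        return float(barrier_top)
    return float(config.v_start)


def run_trajectory(
    config: SimulationConfig,
    landscape: Landscape,
    rng: np.random.Generator,
    barrier_top: float | None = None,
) -> Trajectory:
    """Simulate a single trajectory using draws from ``rng``.

    Matches a trajectory of :func:`generate_ensemble` when ``rng`` is the
    corresponding spawned stream (noise is consumed in the same fixed
    blocks).
    """
    ens = _simulate_batch(config, landscape, [rng], _resolve_start(config, barrier_top))
    return ens[0]


def generate_ensemble(
    config: SimulationConfig,
    landscape: Landscape,
    barrier_top: float | None = None,
) -> TrajectoryEnsemble:
    """Generate ``config.n_traj`` independent trajectories.

    Per-trajectory generators are spawned from ``config.seed`` via
    ``SeedSequence.spawn``, so results are deterministic and trajectory ``i``
    does not depend on how many steps the others took.
    """
    v0 = _resolve_start(config, barrier_top)
    children = np.random.SeedSequence(config.seed).spawn(config.n_traj)
    rngs = [np.random.Generator(np.random.PCG64(c)) for c in children]
    trajs = _simulate_batch(config, landscape, rngs, v0)
    return TrajectoryEnsemble(
        trajectories=tuple(trajs), config=config, landscape_name=landscape.name
    )


def _simulate_batch(
    config: SimulationConfig,
    landscape: Landscape,
    rngs: Sequence[np.random.Generator],
    v0: float,
) -> list:
    """Vectorised synchronous integration of many trajectories.

    All trajectories advance one step per iteration; finished ones drop out
    of the active set.  Noise for trajectory ``i`` comes from ``rngs[i]``
    only, fetched in blocks of NOISE_BLOCK draws.
    """
    n = len(rngs)
    dt, stride = config.dt, config.record_stride
    lo, hi = config.wall_lo, config.wall_hi

    v = np.full(n, v0, dtype=float)
    if config.start_jitter > 0:
        for i, rng in enumerate(rngs):
            v[i] += config.start_jitter * rng.standard_normal()
        v = np.clip(v, np.nextafter(lo, hi), np.nextafter(hi, lo))

    exit_side = np.full(n, -1, dtype=np.int8)  # -1 active, 0 left, 1 right
    exit_step = np.zeros(n, dtype=np.int64)
    active_idx = np.arange(n)

    # Each record event stores (indices, values) for the then-active set.
    rec_idx: list[np.ndarray] = [active_idx.copy()]
    rec_val: list[np.ndarray] = [v.copy()]
    n_rec = np.ones(n, dtype=np.int64)  # samples recorded per trajectory

    D_fn = landscape.diffusivity
    Dp_fn = landscape.diffusivity_grad
    Gp_fn = landscape.free_energy_grad
    sqrt2dt = math.sqrt(2.0 * dt)

    step = 0
    va = v.copy()
    noise = np.empty((0, 0))
    noise_pos = NOISE_BLOCK  # force initial fill
    while active_idx.size and step < config.max_steps:
        if noise_pos >= NOISE_BLOCK:
            noise = np.empty((active_idx.size, NOISE_BLOCK))
            for row, i in enumerate(active_idx):
                noise[row] = rngs[i].standard_normal(NOISE_BLOCK)
            noise_pos = 0
        g = noise[:, noise_pos]
        noise_pos += 1
        D = np.asarray(D_fn(va), dtype=float)
        if D.min() <= 0.0:
            raise SimulationDomainError(
                f"non-positive diffusivity at v={va[np.argmin(D)]:.6g}"
            )
        va = va + (np.asarray(Dp_fn(va)) - np.asarray(Gp_fn(va)) * D) * dt + (
            g * np.sqrt(D)
        ) * sqrt2dt
        step += 1

        crossed = (va <= lo) | (va >= hi)
        if crossed.any():
            hit = active_idx[crossed]
            exit_side[hit] = (va[crossed] >= hi).astype(np.int8)
            exit_step[hit] = step
            keep = ~crossed
            active_idx = active_idx[keep]
            noise = noise[keep]
            va = va[keep]
        if step % stride == 0 and active_idx.size:
            rec_idx.append(active_idx.copy())
            rec_val.append(va.copy())
            n_rec[active_idx] += 1

    # Reassemble per-trajectory sample arrays from the record events.
    offsets = np.concatenate(([0], np.cumsum(n_rec)))
    flat = np.empty(offsets[-1])
    cursor = offsets[:-1].copy()
    for idx, vals in zip(rec_idx, rec_val):
        flat[cursor[idx]] = vals
        cursor[idx] += 1

    out = []
    for i in range(n):
        vals = flat[offsets[i] : offsets[i + 1]]
        if exit_side[i] < 0:
            out.append(
                Trajectory(
                    values=vals,
                    dt_record=config.dt_record,
                    exit="censored",
                    exit_time=step * dt,
                )
            )
        else:
            out.append(
                Trajectory(
                    values=vals,
                    dt_record=config.dt_record,
                    exit="right" if exit_side[i] else "left",
                    exit_time=float(exit_step[i] * dt),
                )
            )
    return out
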