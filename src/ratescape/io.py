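"""Plain-text file formats: trajectory ensembles, count matrices, profiles.

Everything round-trips: each writer has a reader returning an equal
in-memory object (floating-point values to full double precision via
``repr``-faithful formatting).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .discretize import Grid, TransitionCounts
from .infer import ProfileEstimate
from .simulate import SimulationConfig, Trajectory, TrajectoryEnsemble

__all__ = [
    "write_ensemble",
    "read_ensemble",
    "write_counts",
    "read_counts",
    "write_profiles",
    "read_profiles",
    "load_config",
    "dump_config",
]

_ENSEMBLE_MAGIC = "# ratescape-ensemble v1"


def write_ensemble(path, ensemble: TrajectoryEnsemble) -> None:
    """One text file per ensemble: a config header, then per-trajectory
    blocks (``@traj index exit exit_time`` followed by the sample line)."""
    path = Path(path)
    cfg = asdict(ensemble.config)
    with path.open("w") as fh:
        fh.write(_ENSEMBLE_MAGIC + "\n")
        fh.write(f"# config: {json.dumps(cfg)}\n")
        fh.write(f"# landscape: {ensemble.landscape_name}\n")
        fh.write(f"# n_traj: {len(ensemble)}\n")
        for k, traj in enumerate(ensemble):
            fh.write(f"@traj {k} {traj.exit} {float(traj.exit_time)!r}\n")
            fh.write(" ".join(repr(float(v)) for v in traj.values) + "\n")


def read_ensemble(path) -> TrajectoryEnsemble:
    path = Path(path)
    with path.open() as fh:
        magic = fh.readline().rstrip("\n")
        if magic != _ENSEMBLE_MAGIC:
            raise ValueError(f"{path} is not a ratescape ensemble file")
        cfg = json.loads(fh.readline().split("# config:", 1)[1])
        landscape_name = fh.readline().split("# landscape:", 1)[1].strip()
        n_traj = int(fh.readline().split("# n_traj:", 1)[1])
        config = SimulationConfig(**cfg)
        trajs = []
        for _ in range(n_traj):
            tag, _idx, exit_, exit_time = fh.readline().split()
            if tag != "@traj":
                raise ValueError("malformed trajectory block")
            values = np.array(fh.readline().split(), dtype=float)
            trajs.append(
                Trajectory(
                    values=values,
                    dt_record=config.dt_record,
                    exit=exit_,
                    exit_time=float(exit_time),
                )
            )
    return TrajectoryEnsemble(
        trajectories=tuple(trajs), config=config, landscape_name=landscape_name
    )


def write_counts(path, counts: TransitionCounts) -> None:
    """Dense integer CSV plus a ``.json`` sidecar holding grid and tau."""
    path = Path(path)
    np.savetxt(path, counts.counts, fmt="%d", delimiter=",")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "tau": counts.tau,
                "grid": {"n": counts.grid.n, "v_lo": counts.grid.v_lo, "v_hi": counts.grid.v_hi},
            }
        )
    )


def read_counts(path) -> TransitionCounts:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    counts = np.loadtxt(path, dtype=np.int64, delimiter=",")
    return TransitionCounts(counts=counts, tau=meta["tau"], grid=Grid(**meta["grid"]))


def write_profiles(path, prof: ProfileEstimate) -> None:
    """Profile table CSV: v, G, G_std, D_edge_v, D, D_std.

    The D columns (n-1 edges) are padded with empty cells on the last row.
    """
    n = prof.grid.n
    pad = [np.nan]
    df = pd.DataFrame(
        {
            "v": prof.centers,
            "G": prof.G_centers,
            "G_std": prof.G_std,
            "D_edge_v": np.concatenate([prof.edge_positions, pad]),
            "D": np.concatenate([prof.D_edges, pad]),
            "D_std": np.concatenate([prof.D_std, pad]),
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_profiles(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path) -> dict:
    """Read a YAML (or JSON, a YAML subset) configuration file."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration in {path} must be a mapping")
    return cfg


def dump_config(path, cfg: dict) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
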