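import numpy as np
import pytest

import ratescape as rs

D_CONST = 0.0143  # nm^6/ps, the RP diffusivity at the -135 MPa barrier top


def flat_landscape(d0: float = D_CONST) -> rs.Landscape:
    """Flat free energy, constant diffusivity (free diffusion)."""
    z = lambda v: np.zeros_like(np.asarray(v, dtype=float))
    return rs.CustomLandscape(
        free_energy=z,
        diffusivity=lambda v: np.full_like(np.asarray(v, dtype=float), d0),
        free_energy_grad=z,
        diffusivity_grad=z,
        name="flat",
    )


def parabolic_barrier_landscape(omega: float, d0: float = D_CONST, v0: float = 0.0) -> rs.Landscape:
    """Inverted parabola G = -omega (v - v0)^2 / 2 with constant D."""
    z = lambda v: np.zeros_like(np.asarray(v, dtype=float))
    return rs.CustomLandscape(
        free_energy=lambda v: -0.5 * omega * (np.asarray(v, dtype=float) - v0) ** 2,
        diffusivity=lambda v: np.full_like(np.asarray(v, dtype=float), d0),
        free_energy_grad=lambda v: -omega * (np.asarray(v, dtype=float) - v0),
        diffusivity_grad=z,
        name="parabola",
    )


@pytest.fixture(scope="session")
def params() -> rs.LandscapeParams:
    return rs.LandscapeParams()


@pytest.fixture(scope="session")
def vmax(params) -> float:
    return rs.critical_volume(params)


@pytest.fixture(scope="session")
def model_ensemble(params, vmax) -> rs.TrajectoryEnsemble:
    """Small barrier-top ensemble on the reference nucleation landscape."""
    cfg = rs.SimulationConfig(
        wall_lo=vmax - 1.3, wall_hi=vmax + 1.3, n_traj=300, seed=5
    )
    return rs.generate_ensemble(cfg, rs.NucleationLandscape(params), barrier_top=vmax)


@pytest.fixture(scope="session")
def flat_ensemble() -> rs.TrajectoryEnsemble:
    """Free-diffusion ensemble between absorbing walls, started at 0."""
    cfg = rs.SimulationConfig(
        wall_lo=-1.3, wall_hi=1.3, v_start=0.0, n_traj=400, seed=123
    )
    return rs.generate_ensemble(cfg, flat_landscape())


@pytest.fixture(scope="session")
def flat_mfpt_ensemble() -> rs.TrajectoryEnsemble:
    """Free diffusion with walls well beyond the largest probed distance."""
    cfg = rs.SimulationConfig(
        wall_lo=-1.2,
        wall_hi=1.2,
        v_start=0.0,
        n_traj=600,
        seed=17,
        max_steps=300_000,
        record_stride=2,  # fine sampling: first-passage detection bias ~ sqrt(2 D dt_rec)
    )
    return rs.generate_ensemble(cfg, flat_landscape())
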