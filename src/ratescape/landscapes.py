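"""Analytic free-energy and diffusivity models for bubble nucleation.

Classical nucleation theory (CNT) describes the free energy of a spherical
vapour bubble of volume ``v`` in a stretched liquid as the competition
between an interfacial cost, ``4*pi*gamma0*r(v)**2``, and a favourable bulk
term ``p*v`` (``p < 0`` under tension).  A first-order curvature correction
to the surface tension (Tolman length ``delta``) is available as a variant.
The stochastic dynamics of the bubble volume carries a position-dependent
diffusivity: the Rayleigh--Plesset equation for a bubble in an incompressible
viscous liquid, augmented with thermal noise, predicts
``D(v) = (3 kB T / 4 eta) * v``, linear in the volume with zero intercept.

All downstream computation uses a reduced unit system
``{length^3 = nm^3, time = ps, energy = kBT}`` so that ``beta = 1``.
SI quantities enter only through :func:`to_reduced`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "KB_JOULE_PER_K",
    "LandscapeParams",
    "ReducedUnits",
    "Landscape",
    "NucleationLandscape",
    "CustomLandscape",
    "to_reduced",
    "cnt_free_energy",
    "tolman_free_energy",
    "rp_diffusivity",
    "critical_volume",
    "barrier_curvature",
]

#: Boltzmann constant (CODATA exact), J/K.
KB_JOULE_PER_K = 1.380649e-23

# 4*pi*r(v)^2 = (36*pi)^(1/3) * v^(2/3) for a sphere of volume v.
_SPHERE_AREA_COEFF = (36.0 * math.pi) ** (1.0 / 3.0)


class NoBarrierError(ValueError):
    """Raised when a barrier quantity is requested at non-negative pressure."""


@dataclass(frozen=True)
class LandscapeParams:
    """Physical parameters of the nucleation model.

    Parameters
    ----------
    gamma0
        Planar surface tension, kBT/nm^2.
    pressure
        Liquid pressure in MPa; negative values put the liquid under tension,
        which is required for a nucleation barrier to exist.
    temperature
        Absolute temperature, K.
    viscosity
        Dynamic viscosity of the liquid, mPa*s.
    tolman_delta
        Tolman length in nm (first-order curvature correction to the surface
        tension); 0 recovers plain CNT.
    """

    gamma0: float = 17.09
    pressure: float = -135.0
    temperature: float = 296.4
    viscosity: float = 1.00
    tolman_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.viscosity <= 0:
            raise ValueError(f"viscosity must be positive, got {self.viscosity}")
        if self.gamma0 <= 0:
            raise ValueError(f"gamma0 must be positive, got {self.gamma0}")
        if self.tolman_delta < 0:
            raise ValueError(f"tolman_delta must be >= 0, got {self.tolman_delta}")


@dataclass(frozen=True)
class ReducedUnits:
    """Parameters converted to the reduced system {nm^3, ps, kBT}, beta = 1."""

    kBT_joule: float
    pressure_red: float  # kBT/nm^3
    viscosity_red: float  # kBT*ps/nm^3


def to_reduced(params: LandscapeParams) -> ReducedUnits:
    """Convert SI-flavoured parameters to reduced units.

    1 MPa = 1e-21 J/nm^3 and 1 mPa*s = 1e-18 J*ps/nm^3, so dividing by the
    thermal energy kB*T (in J) yields pressure in kBT/nm^3 and viscosity in
    kBT*ps/nm^3.
    """
    kBT = KB_JOULE_PER_K * params.temperature
    return ReducedUnits(
        kBT_joule=kBT,
        pressure_red=params.pressure * 1e-21 / kBT,
        viscosity_red=params.viscosity * 1e-18 / kBT,
    )


def _sphere_radius(v: np.ndarray | float) -> np.ndarray | float:
    """Radius in nm of a sphere with volume v in nm^3."""
    return (3.0 * np.asarray(v, dtype=float) / (4.0 * math.pi)) ** (1.0 / 3.0)


def _check_nonneg(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("bubble volume must be non-negative")
    return v


def cnt_free_energy(v, params: LandscapeParams):
    """CNT free energy ``G(v) = 4 pi gamma0 r(v)^2 + p v`` in kBT.

    ``v`` may be a scalar or array of volumes in nm^3.
    """
    v = _check_nonneg(v)
    red = to_reduced(params)
    return _SPHERE_AREA_COEFF * params.gamma0 * v ** (2.0 / 3.0) + red.pressure_red * v


def cnt_free_energy_grad(v, params: LandscapeParams):
    """dG/dv for the CNT landscape, kBT/nm^3.  Diverges as v -> 0."""
    v = _check_nonneg(v)
    red = to_reduced(params)
    return (
        (2.0 / 3.0) * _SPHERE_AREA_COEFF * params.gamma0 * v ** (-1.0 / 3.0)
        + red.pressure_red
    )


def tolman_free_energy(v, params: LandscapeParams):
    """Curvature-corrected free energy in kBT.

    The surface term is damped by ``1/(1 + 2*delta/r(v))``; at ``delta = 0``
    this is exactly the CNT expression, and the limit ``v -> 0`` is 0.
    """
    v = _check_nonneg(v)
    red = to_reduced(params)
    r = _sphere_radius(v)
    surface = np.where(
        np.asarray(v) > 0,
        _SPHERE_AREA_COEFF
        * params.gamma0
        * np.asarray(v) ** (2.0 / 3.0)
        / (1.0 + 2.0 * params.tolman_delta / np.where(r > 0, r, 1.0)),
        0.0,
    )
    out = surface + red.pressure_red * v
    return out if out.ndim else float(out)


def tolman_free_energy_grad(v, params: LandscapeParams, h_rel: float = 1e-6):
    """dG/dv for the Tolman landscape by central differences."""
    v = _check_nonneg(v)
    h = h_rel * np.maximum(np.asarray(v), 1e-3)
    lo = np.maximum(v - h, 0.0)
    hi = v + h
    return (tolman_free_energy(hi, params) - tolman_free_energy(lo, params)) / (hi - lo)


def rp_diffusivity(v, params: LandscapeParams):
    """Rayleigh--Plesset diffusivity ``D(v) = (3 kBT / 4 eta) v`` in nm^6/ps."""
    v = _check_nonneg(v)
    return rp_slope(params) * v


def rp_slope(params: LandscapeParams) -> float:
    """Slope ``3 kBT / (4 eta)`` of the RP diffusivity, nm^3/ps (beta = 1)."""
    red = to_reduced(params)
    return 3.0 / (4.0 * red.viscosity_red)


def critical_volume(params: LandscapeParams, tolman: bool = False) -> float:
    """Closed-form position of the free-energy maximum, nm^3.

    Plain CNT gives ``vmax = 32 pi gamma0^3 / (3 |p|^3)``.  With the Tolman
    correction, ``vmax = (4 pi / 3) (gamma0/|p|)^3 [1 - 4 d/r0 +
    sqrt(1 + 4 d/r0)]^3`` where ``r0 = 2 gamma0 / |p|`` is the uncorrected
    critical radius; the bracket reduces to 2^3 at ``delta = 0``.
    """
    red = to_reduced(params)
    if red.pressure_red >= 0:
        raise NoBarrierError("no free-energy barrier at non-negative pressure")
    ap = abs(red.pressure_red)
    if not tolman or params.tolman_delta == 0.0:
        return 32.0 * math.pi * params.gamma0 ** 3 / (3.0 * ap ** 3)
    r0 = 2.0 * params.gamma0 / ap
    x = 4.0 * params.tolman_delta / r0
    bracket = 1.0 - x + math.sqrt(1.0 + x)
    return (4.0 * math.pi / 3.0) * (params.gamma0 / ap) ** 3 * bracket ** 3


def barrier_curvature(params: LandscapeParams, tolman: bool = False) -> float:
    """Magnitude of d^2G/dv^2 at the barrier top, kBT/nm^6.

    For CNT this is analytic, ``|G''| = (2/9) gamma0 (36 pi)^(1/3)
    vmax^(-4/3)``; for the Tolman landscape it is obtained by central
    differences with step ``1e-4 * vmax``.  This curvature is the omega
    entering the Zeldovich factor and the parabolic-barrier MFPT.
    """
    vmax = critical_volume(params, tolman=tolman)
    if not tolman or params.tolman_delta == 0.0:
        return (2.0 / 9.0) * params.gamma0 * _SPHERE_AREA_COEFF * vmax ** (-4.0 / 3.0)
    h = 1e-4 * vmax
    g = tolman_free_energy(np.array([vmax - h, vmax, vmax + h]), params)
    return abs((g[0] - 2.0 * g[1] + g[2]) / h ** 2)


@dataclass(frozen=True)
class Landscape:
    """A G(v)/D(v) pair with analytic first derivatives, in reduced units.

    The Ito simulator needs G', D and D'; inference and MFPT analysis use
    G and D directly.  ``name`` identifies the landscape in file headers.
    """

    free_energy: Callable
    free_energy_grad: Callable
    diffusivity: Callable
    diffusivity_grad: Callable
    name: str = "custom"


def NucleationLandscape(params: LandscapeParams, tolman: bool = False) -> Landscape:
    """Bubble-nucleation landscape: CNT or Tolman G(v) with RP D(v).

    Coefficients are precomputed so the returned callables are cheap enough
    for the integrator's inner loop.
    """
    slope = rp_slope(params)
    d_fn = lambda v: slope * np.asarray(v, dtype=float)
    dp_fn = lambda v: np.full_like(np.asarray(v, dtype=float), slope)
    if tolman and params.tolman_delta > 0:
        return Landscape(
            free_energy=lambda v: tolman_free_energy(v, params),
            free_energy_grad=lambda v: tolman_free_energy_grad(v, params),
            diffusivity=d_fn,
            diffusivity_grad=dp_fn,
            name="tolman",
        )
    a = _SPHERE_AREA_COEFF * params.gamma0
    p_red = to_reduced(params).pressure_red
    two_thirds_a = (2.0 / 3.0) * a

    def g_fn(v):
        v = np.asarray(v, dtype=float)
        c = np.cbrt(v)
        return a * c * c + p_red * v

    def gp_fn(v):
        v = np.asarray(v, dtype=float)
        return two_thirds_a / np.cbrt(v) + p_red

    return Landscape(
        free_energy=g_fn,
        free_energy_grad=gp_fn,
        diffusivity=d_fn,
        diffusivity_grad=dp_fn,
        name="cnt",
    )


def CustomLandscape(
    free_energy: Callable,
    diffusivity: Callable,
    free_energy_grad: Callable | None = None,
    diffusivity_grad: Callable | None = None,
    h: float = 1e-6,
    name: str = "custom",
) -> Landscape:
    """Wrap arbitrary G/D callables, supplying central-difference derivatives
    where analytic ones are not given.  Mostly used to build flat, constant-D
    and parabolic test landscapes."""

    def _numdiff(f):
        def grad(v):
            v = np.asarray(v, dtype=float)
            return (f(v + h) - f(v - h)) / (2.0 * h)

        return grad

    return Landscape(
        free_energy=free_energy,
        free_energy_grad=free_energy_grad or _numdiff(free_energy),
        diffusivity=diffusivity,
        diffusivity_grad=diffusivity_grad or _numdiff(diffusivity),
        name=name,
    )
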