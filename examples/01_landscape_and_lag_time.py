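"""Barrier geometry of the bubble-nucleation landscape and the lag-time rule.

Builds the classical-nucleation-theory free energy for water under -135 MPa
of tension, locates the barrier, and derives the counting lag time a
discretised analysis of barrier-crossing trajectories should use.
"""

import ratescape as rs

params = rs.LandscapeParams(
    gamma0=17.09,      # surface tension, kBT/nm^2
    pressure=-135.0,   # MPa (negative: liquid under tension)
    temperature=296.4, # K
    viscosity=1.00,    # mPa s
)

vmax = rs.critical_volume(params)
omega = rs.barrier_curvature(params)
barrier = rs.cnt_free_energy(vmax, params)
d_top = rs.rp_diffusivity(vmax, params)

print(f"critical bubble volume   vmax  = {vmax:.3f} nm^3")
print(f"barrier height           G(vmax) = {barrier:.2f} kBT")
print(f"barrier curvature        |G''| = {omega:.3f} kBT/nm^6")
print(f"diffusivity at the top   D(vmax) = {d_top:.4e} nm^6/ps")

# A 24-bin grid spanning 2.6 nm^3 around the barrier: the recommended lag is
# the mean time to diffuse across one bin, and practice favours 1-2x that.
grid = rs.Grid.centered(vmax, 2.60, 24)
lag = rs.recommend_lag(grid, d_top)
print(f"bin width                dv = {grid.dv:.4f} nm^3")
print(f"lag-time baseline        dv^2/2D = {lag.baseline:.3f} ps "
      f"(use {lag.low:.2f}-{lag.high:.2f} ps)")
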