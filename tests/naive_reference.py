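"""Naive dense per-cell explicit-Euler transport reference.

Independent oracle for the vectorised transport stepper: plain Python
loops over grid cells with the same discrete formulae (5-point diffusion
and first-order upwind taxis in flux form, no-flux at outer edges and at
cortex faces).
"""

import numpy as np

from callusim.domain import DIFFUSIBLE, TACTIC
from callusim.pde import diffusivities


def naive_transport_step(state, domain, dt, params):
    """One explicit transport step computed cell by cell."""
    D = diffusivities(params)
    chi = {"cm": params.reactions.chi_cm, "cf": params.reactions.chi_cf}
    dx, dy = domain.dx, domain.dy
    act = domain.callus_mask
    g = state.gbc
    new = {}
    for name in DIFFUSIBLE:
        u = state[name]
        out = u.copy()
        for iy in range(domain.ny):
            for ix in range(domain.nx):
                div = 0.0
                # x faces: (iy, ix)-(iy, ix+1) and (iy, ix-1)-(iy, ix)
                for (jy, jx, sgn, h) in (
                        (iy, ix + 1, +1.0, dx), (iy, ix - 1, -1.0, dx),
                        (iy + 1, ix, +1.0, dy), (iy - 1, ix, -1.0, dy)):
                    if not (0 <= jy < domain.ny and 0 <= jx < domain.nx):
                        continue
                    if not (act[iy, ix] and act[jy, jx]):
                        continue
                    # flux from (iy,ix) toward (jy,jx)
                    J = -D[name] * (u[jy, jx] - u[iy, ix]) / h
                    if name in TACTIC and chi[name] > 0.0:
                        v = chi[name] * (g[jy, jx] - g[iy, ix]) / h
                        up = u[iy, ix] if v > 0.0 else u[jy, jx]
                        J += v * up
                    div -= J / h       # outflow through this face
                out[iy, ix] = u[iy, ix] + dt * div
        new[name] = out
    for name, arr in new.items():
        state[name] = arr
    return state
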