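"""Tissue-level taxis-diffusion-reaction dynamics and the multiscale driver.

The ten continuum fields advance by operator splitting: an explicit
flux-form transport step (diffusion for motile cells, growth factors and
oxygen; first-order upwind chemotaxis of MSCs and fibroblasts up the
osteochondrogenic-factor gradient), an explicit reaction step gated by
the oxygen-response multipliers, and an oxygen delivery/consumption
step coupled to the discrete vasculature.  Flux-form differencing makes
no-flux runs conservative to round-off; upwinding keeps the taxis step
positivity-preserving.  Negative excursions from the reaction step are
clipped to zero with a logged mass diagnostic and a hard failure when
the clipped mass is more than a configured fraction of the field total.

The cortex is inert geometry: no flux crosses its faces and no field
lives inside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .domain import (Domain, StateFields, BoundarySpec, FIELD_NAMES,
                     DIFFUSIBLE, TACTIC)
from .oxygen import (consumption_rate, delivery_rate, response_multiplier,
                     oxygen_diffusivity)
from .params import ModelParams
from . import vasculature as vasc


def diffusivities(params: ModelParams) -> dict[str, float]:
    r = params.reactions
    return {"cm": r.D_cm, "cf": r.D_cf, "gbc": r.D_gbc, "gv": r.D_gv,
            "n": oxygen_diffusivity(params.oxygen)}


def stability_limit(params: ModelParams) -> float:
    """Maximum stable explicit time step (diffusion CFL)."""
    dmax = max(diffusivities(params).values())
    dx = params.solver.dx
    return params.solver.cfl_safety * dx * dx / (4.0 * dmax)


def check_stability(params: ModelParams, dt: float) -> None:
    if params.solver.semi_implicit_diffusion:
        return
    limit = stability_limit(params)
    if dt > limit:
        raise RuntimeError(
            f"explicit step dt={dt:g} d exceeds the diffusion stability "
            f"limit {limit:g} d for dx={params.solver.dx:g} mm")


# ---------------------------------------------------------------------------
# transport
# ---------------------------------------------------------------------------

#: cached sparse backward-Euler diffusion solves, keyed by grid + D*dt
_IMPLICIT_CACHE: dict = {}


def _implicit_solver(domain: Domain, D: float, dt: float):
    """Factorised (I - dt*D*L) solve for the masked 5-point Laplacian."""
    from scipy.sparse import lil_matrix, csc_matrix
    from scipy.sparse.linalg import factorized

    key = (domain.ny, domain.nx, domain.dx, domain.cortex_mask.tobytes(),
           round(D * dt, 14))
    if key in _IMPLICIT_CACHE:
        return _IMPLICIT_CACHE[key]
    ny, nx = domain.shape
    act = domain.callus_mask
    idx = np.arange(ny * nx).reshape(ny, nx)
    a = lil_matrix((ny * nx, ny * nx))
    r = dt * D / domain.dx ** 2
    for iy in range(ny):
        for ix in range(nx):
            i = idx[iy, ix]
            a[i, i] = 1.0
            if not act[iy, ix]:
                continue
            for jy, jx in ((iy, ix - 1), (iy, ix + 1), (iy - 1, ix), (iy + 1, ix)):
                if 0 <= jy < ny and 0 <= jx < nx and act[jy, jx]:
                    a[i, i] += r
                    a[i, idx[jy, jx]] -= r
    solve = factorized(csc_matrix(a))
    _IMPLICIT_CACHE[key] = solve
    return solve


def _face_masks(domain: Domain) -> tuple[np.ndarray, np.ndarray]:
    act = domain.callus_mask
    fx = act[:, 1:] & act[:, :-1]     # vertical faces between x-neighbours
    fy = act[1:, :] & act[:-1, :]     # horizontal faces between y-neighbours
    return fx, fy


def transport_step(state: StateFields, domain: Domain,
                   boundary_spec: BoundarySpec | None, dt: float,
                   params: ModelParams, t: float = 0.0) -> StateFields:
    """One explicit transport step (in place); returns the state.

    Diffusion acts on cm, cf, gbc, gv and n; chemotaxis up grad(g_bc)
    on cm and cf.  All outer edges are no-flux; Dirichlet releases from
    the boundary spec are imposed after the fluxes.
    """
    check_stability(params, dt)
    dx, dy = domain.dx, domain.dy
    fx, fy = _face_masks(domain)
    D = diffusivities(params)
    chi = {"cm": params.reactions.chi_cm, "cf": params.reactions.chi_cf}

    g = state.gbc
    gx = (g[:, 1:] - g[:, :-1]) / dx
    gy = (g[1:, :] - g[:-1, :]) / dy

    implicit = params.solver.semi_implicit_diffusion
    for name in DIFFUSIBLE:
        u = state[name]
        # face flux J in +x / +y direction: J = -D du/dx + chi u dg/dx
        if implicit:
            Jx = np.zeros((u.shape[0], u.shape[1] - 1))
            Jy = np.zeros((u.shape[0] - 1, u.shape[1]))
        else:
            Jx = -D[name] * (u[:, 1:] - u[:, :-1]) / dx
            Jy = -D[name] * (u[1:, :] - u[:-1, :]) / dy
        if name in TACTIC and chi[name] > 0.0:
            vx = chi[name] * gx
            vy = chi[name] * gy
            ux = np.where(vx > 0.0, u[:, :-1], u[:, 1:])
            uy = np.where(vy > 0.0, u[:-1, :], u[1:, :])
            Jx = Jx + vx * ux
            Jy = Jy + vy * uy
        Jx = Jx * fx
        Jy = Jy * fy
        div = np.zeros_like(u)
        div[:, :-1] += Jx / dx
        div[:, 1:] -= Jx / dx
        div[:-1, :] += Jy / dy
        div[1:, :] -= Jy / dy
        u_new = u - dt * div
        if implicit:
            solve = _implicit_solver(domain, D[name], dt)
            u_new = solve(u_new.ravel()).reshape(u.shape)
        state[name] = u_new

    if boundary_spec is not None:
        boundary_spec.apply(state, domain, t)
    return state


# ---------------------------------------------------------------------------
# reactions
# ---------------------------------------------------------------------------

def oxygen_multipliers(n: np.ndarray) -> dict[str, np.ndarray]:
    """Evaluate every oxygen-response curve at the current tension."""
    return {proc: response_multiplier(proc, n)
            for proc in ("chondrogenic_differentiation",
                         "osteogenic_differentiation",
                         "proliferation_msc", "proliferation_chondrocyte",
                         "proliferation_fibroblast", "proliferation_osteoblast",
                         "death_msc", "death_chondrocyte",
                         "death_fibroblast", "death_osteoblast",
                         "gv_production", "gv_production_chondrocyte")}


def reaction_terms(state: StateFields, oxygen_mods: dict[str, np.ndarray],
                   params: ModelParams) -> dict[str, np.ndarray]:
    """Per-field rate of change from the local reaction network (no
    transport, no oxygen exchange).

    MSCs differentiate to osteoblasts at high oxygen and to chondrocytes
    at moderate oxygen, both driven by g_bc; chondrocytes convert to
    osteoblasts where oxygen returns (endochondral ossification); matrix
    production saturates as total density approaches the physiological
    maximum, and dense matrix inhibits proliferation.
    """
    r = params.reactions
    for name, arr in state.items():
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise FloatingPointError(f"invalid state in field {name}")

    cm, cf, cc, cb = state.cm, state.cf, state.cc, state.cb
    mf, mc, mb = state.mf, state.mc, state.mb
    gbc, gv, n = state.gbc, state.gv, state.n
    mods = oxygen_mods

    ctot = cm + cf + cc + cb
    mtot = mf + mc + mb
    room = np.clip(1.0 - ctot / r.c_max, 0.0, None)
    matrix_room = np.clip(1.0 - mtot / r.m_max, 0.0, None)
    prol = room * matrix_room

    f_osteo = gbc / (r.H_osteo + gbc) * mods["osteogenic_differentiation"]
    # cooperative (Hill-2) GF dependence: chondrogenic commitment needs a
    # substantially elevated osteochondrogenic GF concentration
    f_chondro = gbc ** 2 / (r.H_chondro ** 2 + gbc ** 2) \
        * mods["chondrogenic_differentiation"]

    diff_osteo = r.Y_osteo * f_osteo * cm
    diff_chondro = r.Y_chondro * f_chondro * cm
    endo = r.E_endo * mods["osteogenic_differentiation"] * cc

    d = {}
    d["cm"] = (r.A_m * mods["proliferation_msc"] * prol * cm
               - diff_osteo - diff_chondro
               - r.d_m * mods["death_msc"] * cm)
    d["cf"] = (r.A_f * mods["proliferation_fibroblast"] * prol * cf
               - r.d_f * mods["death_fibroblast"] * cf)
    d["cc"] = (r.A_c * mods["proliferation_chondrocyte"] * prol * cc
               + diff_chondro - endo
               - r.d_c * mods["death_chondrocyte"] * cc)
    d["cb"] = (r.A_b * mods["proliferation_osteoblast"] * prol * cb
               + diff_osteo + endo
               - r.d_b * mods["death_osteoblast"] * cb - r.d_b0 * cb)
    d["mf"] = r.P_f * cf * matrix_room - r.k_fc * mf * (cc + cb)
    d["mc"] = r.P_c * cc * matrix_room - r.k_cb * mc * cb
    d["mb"] = r.P_b * cb * matrix_room
    d["gbc"] = ((r.E_gbc_b * cb + r.E_gbc_c * cc) * n / (r.H_gn + n)
                - r.d_gbc * gbc - r.k_gbc_use * diff_chondro)
    # saturating VEGF output: guidance strength plateaus once a modest
    # density of viable hypoxic producers is present
    c_prod = (mods["gv_production"] * (cm + cf + cb)
              + mods["gv_production_chondrocyte"] * cc)
    d["gv"] = (r.E_gv * c_prod / (r.c_gv_half + c_prod) - r.d_gv * gv)
    d["n"] = np.zeros_like(n)
    return d


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

@dataclass
class StepEvents:
    t: float = 0.0
    clipped_mass: dict = dc_field(default_factory=dict)
    death_zone_fraction: float = 0.0
    treatments: list = dc_field(default_factory=list)


class Simulation:
    """Operator-splitting driver binding transport, reactions, oxygen and
    the vessel agents."""

    def __init__(self, domain: Domain, state: StateFields,
                 vessels: vasc.VesselNetwork, boundary: BoundarySpec,
                 params: ModelParams, scenario, rng: np.random.Generator):
        self.domain = domain
        self.state = state
        self.vessels = vessels
        self.boundary = boundary
        self.params = params
        self.scenario = scenario
        self.rng = rng
        self.t = 0.0
        self._occupancy = vessels.occupancy(domain)
        self._next_abm = params.vessels.abm_dt
        check_stability(params, params.solver.dt)

    # -- substeps ----------------------------------------------------------
    def _clip_negative(self, events: StepEvents) -> None:
        tol = self.params.solver.clip_tolerance
        for name, arr in self.state.items():
            neg = arr < 0.0
            if np.any(neg):
                lost = float(-arr[neg].sum())
                total = float(np.abs(arr).sum()) + 1e-300
                events.clipped_mass[name] = events.clipped_mass.get(name, 0.0) + lost
                arr[neg] = 0.0
                if lost > tol * max(total, 1.0):
                    raise RuntimeError(
                        f"clipped mass {lost:g} in field {name} exceeds "
                        f"tolerance at t={self.t:g}")

    def _abm_tick(self) -> None:
        p = self.params.vessels
        gv = self.state.gv
        vasc.sprout_from_seeds(self.vessels, gv, self.domain, self.rng, p, self.t)
        vasc.migrate_tips(self.vessels, gv, self.domain, p.abm_dt, self.rng, p)
        vasc.branch_and_select_tips(self.vessels, gv, self.domain, self.rng,
                                    p, self.params.notch)
        vasc.anastomose(self.vessels, params=p)
        vasc.active_segments(self.vessels)
        self._occupancy = self.vessels.occupancy(self.domain)

    def step(self) -> StepEvents:
        dt = self.params.solver.dt
        events = StepEvents(t=self.t)

        transport_step(self.state, self.domain, self.boundary, dt,
                       self.params, self.t)
        self._clip_negative(events)

        mods = oxygen_multipliers(self.state.n)
        rates = reaction_terms(self.state, mods, self.params)
        for name in FIELD_NAMES:
            u = self.state[name]
            # positivity limiter: a sink can at most empty the cell in one step
            self.state[name] = u + dt * np.maximum(rates[name], -u / dt)
        self._clip_negative(events)

        dens = {k: self.state[k] for k in ("cm", "cf", "cc", "cb")}
        sink = consumption_rate(dens, self.state.n, self.params.oxygen)
        src = delivery_rate(self._occupancy, self.state.n, self.params.oxygen,
                            self.domain.dx, self.domain.dy)
        self.state.n = np.clip(self.state.n + dt * (src - sink), 0.0, None)
        self.state.n[~self.domain.callus_mask] = 0.0

        self.boundary.apply(self.state, self.domain, self.t)

        self.t += dt
        if self.t + 1e-9 >= self._next_abm:
            self._abm_tick()
            self._next_abm += self.params.vessels.abm_dt

        central = self.domain.central_mask & self.domain.callus_mask
        if np.any(central):
            events.death_zone_fraction = float(
                np.mean(self.state.n[central] < 0.5))
        return events


def advance(state: StateFields, vessels: vasc.VesselNetwork, scenario,
            t: float, dt: float, *, domain: Domain, boundary: BoundarySpec,
            params: ModelParams, rng: np.random.Generator) -> tuple[StateFields, StepEvents]:
    """Single full multiscale step (functional surface over Simulation)."""
    sim = Simulation(domain, state, vessels, boundary, params, scenario, rng)
    sim.t = t
    sim._next_abm = (np.floor(t / params.vessels.abm_dt) + 1) * params.vessels.abm_dt
    events = sim.step()
    return sim.state, events
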