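"""Lattice-free sprouting-angiogenesis agent model.

Discrete endothelial cells (ECs) form polyline branches.  Tips migrate
up the angiogenic-factor (g_v) gradient with a bounded von-Mises random
deflection, laying stalk cells behind them; new sprouts are initiated
from stalk cells whose Dll4-Notch state resolves to tip fate; a tip that
comes within the anastomosis radius of a foreign segment fuses with it.
Segments connected to an initial seed vessel are *active* and deliver
oxygen; orphan fragments are inactive.  The network only ever grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .domain import Domain
from .notch import NotchState, update_notch
from .params import NotchParams, VesselParams


@dataclass
class Branch:
    """One vessel branch: an ordered EC polyline with a single leading tip."""

    points: list                    # list of np.ndarray (x, y), mm
    is_seed: bool = False           # part of the initial vasculature
    parent: int | None = None       # branch id this one sprouted from
    tip_active: bool = True         # False once anastomosed or stalled
    notch: NotchState | None = None
    direction: np.ndarray | None = None   # persistent tip heading

    @property
    def tip(self) -> np.ndarray:
        return self.points[-1]


@dataclass
class VesselNetwork:
    branches: list = field(default_factory=list)
    junctions: list = field(default_factory=list)   # (branch_a, idx_a, branch_b, idx_b)
    active: list = field(default_factory=list)      # bool per branch

    def add_branch(self, branch: Branch) -> int:
        self.branches.append(branch)
        self.active.append(False)
        return len(self.branches) - 1

    def n_ecs(self) -> int:
        return sum(len(b.points) for b in self.branches)

    def all_points(self):
        for bid, b in enumerate(self.branches):
            for i, p in enumerate(b.points):
                yield bid, i, p

    def occupancy(self, domain: Domain, active_only: bool = True) -> np.ndarray:
        """Per-grid-cell count of (active) endothelial cells."""
        occ = np.zeros(domain.shape)
        for bid, b in enumerate(self.branches):
            if active_only and not self.active[bid]:
                continue
            for p in b.points:
                iy, ix = domain.cell_of(p)
                occ[iy, ix] += 1.0
        return occ

    def front_position(self) -> float:
        """Leftmost x reached by any vessel (mm); np.inf if empty.

        The vasculature grows from the bony end (large x) toward the gap
        midline at x = 0, so smaller is further advanced."""
        xs = [p[0] for _, _, p in self.all_points()]
        return float(min(xs)) if xs else float("inf")


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def _polyline(p0, p1, spacing) -> list:
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    n = max(int(np.ceil(length / spacing)), 1)
    return [p0 + (p1 - p0) * k / n for k in range(n + 1)]


def seed_vessels(domain: Domain, scenario,
                 params: VesselParams | None = None) -> VesselNetwork:
    """Initial vasculature for a scenario.

    Standard: short vessels in the well-vascularised periosteum and
    marrow next to the bony end.  Case A adds seeds along the entire
    upper (muscle) border of the gap; case B along a partial interval.
    Alternative standard placements ("variant_0" .. "variant_5") shift
    the seed positions within the vascularised end region.
    """
    p = params or VesselParams()
    geo = scenario.geometry
    letters = scenario.case_letters()

    net = VesselNetwork()
    width = domain.nx * domain.dx
    height = domain.ny * domain.dy
    half_gap = domain.half_gap
    y_cortex_top = geo.marrow_height + geo.cortex_thickness

    variant = getattr(scenario, "seed_variant", 0)
    shift = 0.08 * (variant % 3) - 0.08
    flip = variant >= 3

    # periosteal seeds above the cortical segment, pointing into the callus
    x0 = min(half_gap + 0.3 + shift, width - 2 * p.ec_spacing)
    y_peri = min(y_cortex_top + 0.3 + (0.1 if flip else 0.0), height - p.ec_spacing)
    net.add_branch(Branch(_polyline((width, y_peri), (x0 + 0.3, y_peri), p.ec_spacing),
                          is_seed=True))
    net.add_branch(Branch(_polyline((width, min(y_peri + 0.25, height)),
                                    (x0 + 0.45, min(y_peri + 0.25, height)),
                                    p.ec_spacing), is_seed=True))
    # marrow seeds below the cortex
    y_marrow = max(geo.marrow_height - 0.25 - (0.1 if flip else 0.0), p.ec_spacing)
    net.add_branch(Branch(_polyline((width, y_marrow), (x0 + 0.3, y_marrow),
                                    p.ec_spacing), is_seed=True))

    if "A" in letters or "B" in letters:
        if "A" in letters:
            lo, hi = 0.0, half_gap
        else:
            frac = scenario.partial_fraction
            lo, hi = half_gap * (1.0 - frac), half_gap
        n_seeds = max(int(np.ceil((hi - lo) / 0.5)), 2)
        for x in np.linspace(lo + 0.05, hi - 0.05, n_seeds):
            net.add_branch(Branch(
                _polyline((x, height), (x, height - 0.2), p.ec_spacing),
                is_seed=True))

    active_segments(net)
    return net


# ---------------------------------------------------------------------------
# migration
# ---------------------------------------------------------------------------

def _gradient_at(field: np.ndarray, domain: Domain, pos) -> np.ndarray:
    """Central-difference gradient of a grid field at a continuous position."""
    iy, ix = domain.cell_of(pos)
    gx = (field[iy, min(ix + 1, domain.nx - 1)]
          - field[iy, max(ix - 1, 0)]) / (2 * domain.dx)
    gy = (field[min(iy + 1, domain.ny - 1), ix]
          - field[max(iy - 1, 0), ix]) / (2 * domain.dy)
    return np.array([gx, gy])


def _value_at(field: np.ndarray, domain: Domain, pos) -> float:
    iy, ix = domain.cell_of(pos)
    return float(field[iy, ix])


def _values_at(field: np.ndarray, domain: Domain, pts: np.ndarray) -> np.ndarray:
    """Grid lookup for an (m, 2) array of continuous positions."""
    ix = np.clip((pts[:, 0] / domain.dx).astype(int), 0, domain.nx - 1)
    iy = np.clip((pts[:, 1] / domain.dy).astype(int), 0, domain.ny - 1)
    return field[iy, ix]


def migrate_tips(net: VesselNetwork, gv: np.ndarray, domain: Domain, dt: float,
                 rng: np.random.Generator,
                 params: VesselParams | None = None) -> VesselNetwork:
    """Advance every active tip one agent tick.

    Direction = normalised g_v gradient rotated by a von-Mises random
    deflection; tips only migrate where g_v exceeds the sprouting
    threshold, and stop in a zero-gradient, zero-noise setting.  Steps
    that would leave the domain or enter the cortex are truncated.
    """
    p = params or VesselParams()
    step = p.v_tip * dt
    for bid, b in enumerate(net.branches):
        if not b.tip_active or b.is_seed:
            continue
        tip = b.tip
        if _value_at(gv, domain, tip) < p.g_sprout:
            continue
        grad = _gradient_at(gv, domain, tip)
        norm = float(np.linalg.norm(grad))
        prev = b.direction
        if norm < 1e-14 and prev is None and p.noise_weight == 0.0:
            continue
        # blend the chemotactic cue with the persistent heading
        cue = grad / norm if norm > 1e-14 else np.zeros(2)
        base = cue if prev is None else (1.0 - p.persistence) * cue \
            + p.persistence * prev
        bnorm = float(np.linalg.norm(base))
        if bnorm < 1e-14:
            if p.noise_weight == 0.0:
                continue
            theta = rng.uniform(-np.pi, np.pi)
        else:
            theta = float(np.arctan2(base[1], base[0]))
            if p.noise_weight > 0.0:
                theta += p.noise_weight * rng.vonmises(0.0, p.kappa)
        new = tip + step * np.array([np.cos(theta), np.sin(theta)])
        new[0] = np.clip(new[0], 0.0, domain.nx * domain.dx - 1e-9)
        new[1] = np.clip(new[1], 0.0, domain.ny * domain.dy - 1e-9)
        iy, ix = domain.cell_of(new)
        if not domain.callus_mask[iy, ix]:
            continue  # cortex is impenetrable; wait for another direction
        # lay stalk cells so EC spacing stays ~ec_spacing
        dist = float(np.linalg.norm(new - tip))
        if dist > 1e-12:
            b.direction = (new - tip) / dist
        n_sub = max(int(np.ceil(dist / p.ec_spacing)), 1)
        for k in range(1, n_sub + 1):
            b.points.append(tip + (new - tip) * k / n_sub)
    return net


# ---------------------------------------------------------------------------
# branching via Dll4-Notch
# ---------------------------------------------------------------------------

def branch_and_select_tips(net: VesselNetwork, gv: np.ndarray, domain: Domain,
                           rng: np.random.Generator,
                           params: VesselParams | None = None,
                           notch_params: NotchParams | None = None) -> VesselNetwork:
    """Initiate new sprouts where the lateral-inhibition rules permit.

    For each branch the Dll4-Notch chain dynamics are updated with the
    local g_v as VEGF input; stalk cells that resolve to tip fate, sit in
    a high-g_v region, and are not too close to the leading tip or to an
    existing junction found a new branch (at most one per branch per
    tick, the highest-Dll4 candidate).
    """
    p = params or VesselParams()
    np_ = notch_params or NotchParams()
    junction_pts = []
    for (ba, ia, bb, ib) in net.junctions:
        junction_pts.append(net.branches[ba].points[ia])
    for b in net.branches:
        if b.parent is not None and b.points:
            junction_pts.append(b.points[0])

    junction_arr = (np.asarray(junction_pts) if junction_pts
                    else np.empty((0, 2)))
    n_existing = len(net.branches)
    for bid in range(n_existing):
        b = net.branches[bid]
        m = len(b.points)
        if m < 3:
            continue
        pts_arr = np.asarray(b.points)
        gv_local = _values_at(gv, domain, pts_arr)
        if b.notch is None or len(b.notch.dll4) != m:
            old = b.notch
            b.notch = NotchState.undecided(m)
            if old is not None:
                k = min(len(old.dll4), m)
                b.notch.dll4[:k] = old.dll4[:k]
        update_notch(b.notch, gv_local, dt=p.abm_dt, params=np_, rng=rng)

        ok = (b.notch.fate == "tip") & (gv_local >= p.g_branch)
        if b.tip_active:
            ok &= np.linalg.norm(pts_arr - b.tip, axis=1) >= p.tip_exclusion
        if len(junction_arr):
            dj = np.linalg.norm(pts_arr[:, None, :] - junction_arr[None, :, :],
                                axis=2).min(axis=1)
            ok &= dj >= p.branch_spacing
        if not np.any(ok):
            continue
        cand_idx = np.nonzero(ok)[0]
        i_best = int(cand_idx[np.argmax(b.notch.dll4[cand_idx])])
        q = np.asarray(b.points[i_best], dtype=float)
        grad = _gradient_at(gv, domain, q)
        norm = float(np.linalg.norm(grad))
        if norm < 1e-14:
            theta = rng.uniform(-np.pi, np.pi)
        else:
            theta = float(np.arctan2(grad[1], grad[0]))
            theta += rng.choice([-1.0, 1.0]) * rng.uniform(0.3, 1.2)
        start = q + p.ec_spacing * np.array([np.cos(theta), np.sin(theta)])
        start[0] = np.clip(start[0], 0.0, domain.nx * domain.dx - 1e-9)
        start[1] = np.clip(start[1], 0.0, domain.ny * domain.dy - 1e-9)
        iy, ix = domain.cell_of(start)
        if not domain.callus_mask[iy, ix]:
            continue
        new_id = net.add_branch(Branch([q.copy(), start], parent=bid))
        net.junctions.append((bid, i_best, new_id, 0))
        junction_pts.append(q)
    return net


# ---------------------------------------------------------------------------
# anastomosis & activity
# ---------------------------------------------------------------------------

def anastomose(net: VesselNetwork, radius: float | None = None,
               params: VesselParams | None = None) -> VesselNetwork:
    """Fuse tips that come within ``radius`` of a foreign branch.

    The nearest foreign EC wins; ties break on the lowest branch id.
    The fused tip stops migrating and a junction is recorded.
    """
    p = params or VesselParams()
    r = radius if radius is not None else p.anastomosis_radius
    if r <= 0:
        raise ValueError("anastomosis radius must be positive")
    pts, bids, idxs = [], [], []
    for ob_id, ob in enumerate(net.branches):
        for i, q in enumerate(ob.points):
            pts.append(q)
            bids.append(ob_id)
            idxs.append(i)
    if not pts:
        return net
    pts = np.asarray(pts)
    bids = np.asarray(bids)
    idxs = np.asarray(idxs)
    for bid, b in enumerate(net.branches):
        if not b.tip_active or b.is_seed or len(b.points) < 2:
            continue
        # young sprouts are not yet fusion-competent
        if (len(b.points) - 1) * p.ec_spacing < p.min_fusion_length:
            continue
        tip = b.tip
        d = np.linalg.norm(pts - tip, axis=1)
        mask = (d < r) & (bids != bid)
        # never fuse back into the plexus neighbourhood the sprout left from
        near_origin = np.linalg.norm(pts - b.points[0], axis=1) < p.min_fusion_length
        mask &= ~near_origin
        if not np.any(mask):
            continue
        # nearest foreign EC wins; ties break on the lowest branch id
        cand = np.nonzero(mask)[0]
        order = np.lexsort((idxs[cand], bids[cand], np.round(d[cand], 12)))
        best = cand[order[0]]
        net.junctions.append((bid, len(b.points) - 1, int(bids[best]),
                              int(idxs[best])))
        b.tip_active = False
    return net


def active_segments(net: VesselNetwork) -> list:
    """Flag branches connected (through junctions/parents) to a seed.

    Only the active subnetwork delivers oxygen."""
    g = nx.Graph()
    g.add_nodes_from(range(len(net.branches)))
    for bid, b in enumerate(net.branches):
        if b.parent is not None:
            g.add_edge(bid, b.parent)
    for (ba, _ia, bb, _ib) in net.junctions:
        g.add_edge(ba, bb)
    seeds = {bid for bid, b in enumerate(net.branches) if b.is_seed}
    reachable = set()
    for s in seeds:
        reachable |= nx.node_connected_component(g, s)
    net.active = [bid in reachable for bid in range(len(net.branches))]
    return net.active


def sprout_from_seeds(net: VesselNetwork, gv: np.ndarray, domain: Domain,
                      rng: np.random.Generator,
                      params: VesselParams | None = None,
                      t: float = 0.0) -> VesselNetwork:
    """Seed vessels emit migrating sprouts while local g_v is high enough
    (seed polylines themselves never migrate).  Endothelial proliferation
    lets a seed maintain several live sprouts, with a refractory period
    between consecutive sprouting events."""
    p = params or VesselParams()
    for bid, b in enumerate(net.branches):
        if not b.is_seed:
            continue
        children = getattr(b, "_sprout_children", [])
        live = sum(1 for c in children if net.branches[c].tip_active)
        if live >= p.seed_children:
            continue
        if t - getattr(b, "_last_sprout_t", -1e9) < p.seed_cooldown:
            continue
        q = np.asarray(b.points[-1], dtype=float)
        if _value_at(gv, domain, q) < p.g_branch:
            continue
        grad = _gradient_at(gv, domain, q)
        norm = float(np.linalg.norm(grad))
        if norm < 1e-14:
            continue
        theta = float(np.arctan2(grad[1], grad[0]))
        start = q + p.ec_spacing * np.array([np.cos(theta), np.sin(theta)])
        start[0] = np.clip(start[0], 0.0, domain.nx * domain.dx - 1e-9)
        start[1] = np.clip(start[1], 0.0, domain.ny * domain.dy - 1e-9)
        iy, ix = domain.cell_of(start)
        if not domain.callus_mask[iy, ix]:
            continue
        new_id = net.add_branch(Branch([q.copy(), start], parent=bid))
        net.junctions.append((bid, len(b.points) - 1, new_id, 0))
        b._sprout_children = children + [new_id]
        b._last_sprout_t = t
    return net


def network_edges(net: VesselNetwork) -> list:
    """CSV-friendly edge list (x1, y1, x2, y2, branch, active)."""
    rows = []
    for bid, b in enumerate(net.branches):
        act = int(net.active[bid]) if bid < len(net.active) else 0
        for p0, p1 in zip(b.points[:-1], b.points[1:]):
            rows.append({"x1": p0[0], "y1": p0[1], "x2": p1[0], "y2": p1[1],
                         "branch": bid, "active": act})
    return rows
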