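"""Quarter-callus simulation domain, region masks, fields and boundaries.

The geometry is one fourth of the fracture callus of a segmental long-bone
defect (two-fold symmetry): x runs along the bone axis from the gap
midline (x = 0, a symmetry plane) toward the retained cortical bone end,
y runs radially from the marrow axis outward.  The origin sits at the
left-bottom corner.  Region bands, bottom to top:

* ``endosteal_callus`` (marrow canal / endosteal callus),
* ``cortex`` for x beyond the half gap, ``intercortical_callus`` across
  the gap at the same height,
* ``periosteal_callus`` on top.

A ``bone_marrow_edge`` strip at the far (right) edge of the endosteal
band marks the marrow source region.  The "central callus area" — the
zone initialised with a reduced biological potential — is the part of the
callus further than a periosteal-collar width from the bony end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .params import GeometryParams

REGIONS = (
    "periosteal_callus",
    "intercortical_callus",
    "endosteal_callus",
    "cortex",
    "bone_marrow_edge",
)
REGION_ID = {name: i for i, name in enumerate(REGIONS)}

FIELD_NAMES = ("cm", "cf", "cc", "cb", "mf", "mc", "mb", "gbc", "gv", "n")
#: fields that undergo diffusive transport (motile cells, GFs, oxygen)
DIFFUSIBLE = ("cm", "cf", "gbc", "gv", "n")
#: fields with a chemotactic flux up the g_bc gradient
TACTIC = ("cm", "cf")

EDGES = ("left", "right", "bottom", "top")


@dataclass(frozen=True)
class Domain:
    """Grid geometry and region masks for one gap size."""

    gap_size: float          # full gap, mm
    dx: float                # grid spacing, mm (square cells)
    nx: int
    ny: int
    region_id: np.ndarray    # (ny, nx) int labels into REGIONS
    central_mask: np.ndarray # (ny, nx) bool, reduced-potential zone
    origin: str = "left-bottom"

    @property
    def dy(self) -> float:
        return self.dx

    @property
    def half_gap(self) -> float:
        return self.gap_size / 2.0

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def cell_area(self) -> float:
        return self.dx * self.dy

    def region(self, name: str) -> np.ndarray:
        return self.region_id == REGION_ID[name]

    @property
    def cortex_mask(self) -> np.ndarray:
        return self.region("cortex")

    @property
    def callus_mask(self) -> np.ndarray:
        """Every cell a tissue can occupy (everything but the cortex)."""
        return ~self.cortex_mask

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx

    @property
    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.dy

    def contains(self, pos: np.ndarray) -> bool:
        x, y = pos
        return (0.0 <= x <= self.nx * self.dx) and (0.0 <= y <= self.ny * self.dy)

    def cell_of(self, pos) -> tuple[int, int]:
        """Grid cell (iy, ix) containing a continuous position (x, y)."""
        x, y = pos
        ix = min(max(int(x / self.dx), 0), self.nx - 1)
        iy = min(max(int(y / self.dy), 0), self.ny - 1)
        return iy, ix


def build_domain(gap_size: float, spacing: float | None = None,
                 geometry: GeometryParams | None = None) -> Domain:
    """Build the quarter-callus domain for a given full gap size (mm).

    The domain extends from the gap midline over half the gap size plus
    the retained cortical-end segment.  Rebuilding with the same
    arguments yields bit-identical masks.
    """
    geo = geometry or GeometryParams()
    if gap_size <= 0:
        raise ValueError("gap_size must be positive")
    if spacing is None:
        spacing = 0.25
    if spacing <= 0:
        raise ValueError("spacing must be positive")

    half_gap = gap_size / 2.0
    width = half_gap + geo.cortex_length
    height = geo.marrow_height + geo.cortex_thickness + geo.periosteal_height
    nx = max(int(round(width / spacing)), 2)
    ny = max(int(round(height / spacing)), 2)

    x = (np.arange(nx) + 0.5) * spacing
    y = (np.arange(ny) + 0.5) * spacing
    X, Y = np.meshgrid(x, y)

    in_cortex_band = (Y > geo.marrow_height) & (
        Y < geo.marrow_height + geo.cortex_thickness)
    beyond_gap = X > half_gap

    region = np.full((ny, nx), REGION_ID["periosteal_callus"], dtype=np.int8)
    region[Y <= geo.marrow_height] = REGION_ID["endosteal_callus"]
    region[in_cortex_band & ~beyond_gap] = REGION_ID["intercortical_callus"]
    region[in_cortex_band & beyond_gap] = REGION_ID["cortex"]
    marrow_edge = (Y <= geo.marrow_height) & (X > width - geo.marrow_edge_width)
    region[marrow_edge] = REGION_ID["bone_marrow_edge"]

    collar = min(geo.collar_max, half_gap / 2.0)
    central = (X <= half_gap - collar) & (region != REGION_ID["cortex"])

    return Domain(gap_size=float(gap_size), dx=float(spacing), nx=nx, ny=ny,
                  region_id=region, central_mask=central)


@dataclass
class StateFields:
    """The ten continuum fields, in model units, on the domain grid.

    Cell densities ``cm, cf, cc, cb`` (1.0 = 1e6 cells/ml), matrix
    densities ``mf, mc, mb`` (1.0 = 0.1 g/ml), growth factors
    ``gbc, gv`` (1.0 = 100 ng/ml) and oxygen tension ``n`` (%).
    """

    cm: np.ndarray
    cf: np.ndarray
    cc: np.ndarray
    cb: np.ndarray
    mf: np.ndarray
    mc: np.ndarray
    mb: np.ndarray
    gbc: np.ndarray
    gv: np.ndarray
    n: np.ndarray

    @classmethod
    def zeros(cls, domain: Domain) -> "StateFields":
        return cls(**{f: np.zeros(domain.shape) for f in FIELD_NAMES})

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in FIELD_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def __setitem__(self, name: str, value: np.ndarray) -> None:
        if name not in FIELD_NAMES:
            raise KeyError(name)
        setattr(self, name, value)

    def items(self) -> Iterator[tuple[str, np.ndarray]]:
        return ((f, getattr(self, f)) for f in FIELD_NAMES)

    def copy(self) -> "StateFields":
        return StateFields(**{f: getattr(self, f).copy() for f in FIELD_NAMES})

    def total_cells(self) -> np.ndarray:
        return self.cm + self.cf + self.cc + self.cb

    def total_matrix(self) -> np.ndarray:
        return self.mf + self.mc + self.mb

    def validate(self) -> None:
        for name, arr in self.items():
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(f"non-finite values in field {name}")
            if np.any(arr < 0):
                raise FloatingPointError(f"negative values in field {name}")


@dataclass(frozen=True)
class DirichletBC:
    """Fixed-value release of one variable on part of one edge."""

    variable: str
    edge: str                       # left | right | bottom | top
    value: float                    # model units
    active_interval: tuple[float, float] = (0.0, 90.0)
    extent: tuple[float, float] | None = None  # along-edge range (mm), None = full

    def __post_init__(self):
        if self.variable not in FIELD_NAMES:
            raise ValueError(f"unknown variable {self.variable!r}")
        if self.edge not in EDGES:
            raise ValueError(f"unknown edge {self.edge!r}")


@dataclass
class BoundarySpec:
    """No-flux everywhere by default, plus explicit Dirichlet releases."""

    dirichlet: list[DirichletBC] = field(default_factory=list)

    def active_at(self, t: float) -> list[DirichletBC]:
        return [bc for bc in self.dirichlet
                if bc.active_interval[0] <= t <= bc.active_interval[1]]

    def edge_cells(self, domain: Domain, bc: DirichletBC) -> tuple[np.ndarray, np.ndarray]:
        """(iy, ix) index arrays of the boundary cells a BC applies to."""
        if bc.edge in ("left", "right"):
            coords = domain.y_centers
            ix = 0 if bc.edge == "left" else domain.nx - 1
            sel = np.ones(domain.ny, dtype=bool)
            if bc.extent is not None:
                sel = (coords >= bc.extent[0]) & (coords <= bc.extent[1])
            iy_arr = np.nonzero(sel)[0]
            ix_arr = np.full_like(iy_arr, ix)
        else:
            coords = domain.x_centers
            iy = 0 if bc.edge == "bottom" else domain.ny - 1
            sel = np.ones(domain.nx, dtype=bool)
            if bc.extent is not None:
                sel = (coords >= bc.extent[0]) & (coords <= bc.extent[1])
            ix_arr = np.nonzero(sel)[0]
            iy_arr = np.full_like(ix_arr, iy)
        # Dirichlet releases only act on callus cells
        keep = domain.callus_mask[iy_arr, ix_arr]
        return iy_arr[keep], ix_arr[keep]

    def apply(self, state: StateFields, domain: Domain, t: float) -> None:
        for bc in self.active_at(t):
            iy, ix = self.edge_cells(domain, bc)
            state[bc.variable][iy, ix] = bc.value


def initial_state(domain: Domain, scenario) -> StateFields:
    """Initial fields: standard values near the bony ends, the scenario's
    (reduced) values inside the central callus area."""
    cv = scenario.central_values
    pv = scenario.peripheral_values
    for d in (cv, pv):
        for k, v in d.items():
            if v < 0:
                raise ValueError(f"negative initial value for {k}")

    state = StateFields.zeros(domain)
    callus = domain.callus_mask
    central = domain.central_mask & callus
    peripheral = callus & ~central

    for name in FIELD_NAMES:
        arr = state[name]
        if name in pv:
            arr[peripheral] = pv[name]
        if name in cv:
            arr[central] = cv[name]

    if scenario.oxygen_gradient is not None:
        # linear initial oxygen profile n(x) = slope * x, clipped
        slope, lo, hi = scenario.oxygen_gradient
        X = np.broadcast_to(domain.x_centers, domain.shape)
        state.n[central] = np.clip(slope * X, lo, hi)[central]

    for name, arr in state.items():
        arr[~callus] = 0.0
    return state


def boundary_spec(domain: Domain, scenario) -> BoundarySpec:
    """Standard releases plus the host-environment (muscle) sources.

    Standard case: MSCs and fibroblasts are released from the periosteum
    and soft tissues near the bony ends and from the bone marrow;
    osteochondrogenic growth factor is released from the degrading bone
    ends and the cortex.  Host cases C/D add Dirichlet sources of g_bc /
    c_m on the upper (muscle) border covering the full gap for the whole
    simulated period.
    """
    width = domain.nx * domain.dx
    half_gap = domain.half_gap
    days = scenario.days
    rel = (0.0, scenario.release_days)   # early soft-tissue release window

    spec = BoundarySpec()
    # periosteal release near the bony end (top edge, over the cortical segment)
    spec.dirichlet.append(DirichletBC(
        "cm", "top", scenario.release_cm, rel, (half_gap, width)))
    spec.dirichlet.append(DirichletBC(
        "cf", "top", scenario.release_cf, rel, (half_gap, width)))
    # marrow release at the far edge, below the cortex
    marrow_h = scenario.geometry.marrow_height
    spec.dirichlet.append(DirichletBC(
        "cm", "right", scenario.release_cm, rel, (0.0, marrow_h)))
    spec.dirichlet.append(DirichletBC(
        "cf", "right", scenario.release_cf, rel, (0.0, marrow_h)))
    # growth factor release from the degrading bone ends / cortex surface
    spec.dirichlet.append(DirichletBC(
        "gbc", "right", scenario.release_gbc, rel, None))

    case = scenario.host_case
    known = {"standard"} | set("ABCDEFGHIJ")
    if case not in known:
        raise ValueError(f"unknown host case {case!r}")
    letters = scenario.case_letters()
    if "C" in letters:
        spec.dirichlet.append(DirichletBC(
            "gbc", "top", scenario.release_gbc, (0.0, days), (0.0, half_gap)))
    if "D" in letters:
        spec.dirichlet.append(DirichletBC(
            "cm", "top", scenario.release_cm, (0.0, days), (0.0, half_gap)))
    return spec
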