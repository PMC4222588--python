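"""Scenario library: the standard compromised condition, host-environment
cases A-J, sensitivity sweeps, treatment schedules and toy test fixtures.

A :class:`ScenarioSpec` is fully dimensional (cells/ml, ng/ml, g/ml, %);
conversion to model units happens at the simulation boundary.  The
standard compromised condition neglects the host environment (the
worst case): the central callus area starts with a tenfold-reduced MSC
density (2e3 cells/ml) and growth-factor concentration (10 ng/ml)
relative to the tissue surrounding the bony ends (2e4 cells/ml,
100 ng/ml), fibroblasts at 1e4 cells/ml, granulation matrix at
0.01 g/ml and 3.7 % oxygen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import copy

import numpy as np
import yaml

from .domain import Domain, StateFields, build_domain, initial_state
from .params import CELL_SCALE, GF_SCALE, MATRIX_SCALE, GeometryParams

# host-case composition in terms of the four elementary sources:
# A full muscle vasculature, B partial muscle vasculature,
# C muscle g_bc release, D muscle MSC release.
CASE_LETTERS: dict[str, tuple[str, ...]] = {
    "standard": (),
    "A": ("A",), "B": ("B",), "C": ("C",), "D": ("D",),
    "E": ("C", "D"),
    "F": ("A", "C"), "G": ("A", "D"),
    "H": ("A", "C", "D"),
    "I": ("B", "C"), "J": ("B", "D"),
}

TREATMENT_SPECIES = ("cells", "gf", "combo")

# standard dimensional values
STANDARD_CENTRAL = dict(cm=2e3, cf=1e4, gbc=10.0, mf=0.01, n=3.7)
STANDARD_PERIPHERAL = dict(cm=2e4, cf=1e4, gbc=100.0, mf=0.01, n=6.0)
RELEASE = dict(cm=2e4, cf=1e4, gbc=2000.0)     # boundary Dirichlet values


@dataclass
class Treatment:
    """Single injection over the central callus area."""

    day: float
    species: str                 # cells | gf | combo
    cm: float = 0.0              # cells/ml
    gbc: float = 0.0             # ng/ml

    def __post_init__(self):
        if self.species not in TREATMENT_SPECIES:
            raise ValueError(f"unknown treatment species {self.species!r}")
        if not (0.0 <= self.day <= 90.0):
            raise ValueError("treatment day must lie in [0, 90]")
        if self.cm < 0 or self.gbc < 0:
            raise ValueError("treatment concentrations must be >= 0")


@dataclass
class ScenarioSpec:
    """Everything that defines one in-silico experiment."""

    name: str = "standard"
    gap_size: float = 5.0                        # mm
    host_case: str = "standard"
    central: dict = field(default_factory=lambda: dict(STANDARD_CENTRAL))
    peripheral: dict = field(default_factory=lambda: dict(STANDARD_PERIPHERAL))
    release: dict = field(default_factory=lambda: dict(RELEASE))
    oxygen_gradient_slope: float | None = None   # %/mm along x, else None
    treatments: list = field(default_factory=list)
    partial_fraction: float = 0.5                # case B muscle coverage
    release_days: float = 14.0                   # standard boundary-release window
    seed: int = 0
    seed_variant: int = 0                        # alternative EC placements
    days: float = 90.0
    geometry: GeometryParams = field(default_factory=GeometryParams)

    def __post_init__(self):
        if self.host_case not in CASE_LETTERS:
            raise ValueError(f"unknown host case {self.host_case!r}")
        for d in (self.central, self.peripheral):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"negative initial value {k}={v}")

    # -- model-unit views used by domain.initial_state ---------------------
    @property
    def central_values(self) -> dict:
        return _to_model_units(self.central)

    @property
    def peripheral_values(self) -> dict:
        return _to_model_units(self.peripheral)

    @property
    def oxygen_gradient(self):
        if self.oxygen_gradient_slope is None:
            return None
        return (self.oxygen_gradient_slope, 0.0, 4.0)

    @property
    def release_cm(self) -> float:
        return self.release["cm"] / CELL_SCALE

    @property
    def release_cf(self) -> float:
        return self.release["cf"] / CELL_SCALE

    @property
    def release_gbc(self) -> float:
        return self.release["gbc"] / GF_SCALE

    def case_letters(self) -> tuple[str, ...]:
        return CASE_LETTERS[self.host_case]

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["treatments"] = [asdict(t) if not isinstance(t, dict) else t
                           for t in self.treatments]
        d["geometry"] = asdict(self.geometry)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        d = copy.deepcopy(d)
        d["treatments"] = [Treatment(**t) for t in d.get("treatments", [])]
        d["geometry"] = GeometryParams(**d.get("geometry", {}))
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioSpec":
        return cls.from_dict(yaml.safe_load(text))


def _to_model_units(vals: dict) -> dict:
    out = {}
    for k, v in vals.items():
        if k in ("cm", "cf", "cc", "cb"):
            out[k] = v / CELL_SCALE
        elif k in ("mf", "mc", "mb"):
            out[k] = v / MATRIX_SCALE
        elif k in ("gbc", "gv"):
            out[k] = v / GF_SCALE
        elif k == "n":
            out[k] = v
        else:
            raise KeyError(f"unknown field {k!r}")
    return out


# ---------------------------------------------------------------------------
# scenario constructors
# ---------------------------------------------------------------------------

def standard_compromised(gap_size: float = 5.0) -> ScenarioSpec:
    """Worst-case scenario: no host contribution, tenfold-reduced central
    MSCs and growth factors."""
    if gap_size <= 0:
        raise ValueError("gap_size must be positive")
    return ScenarioSpec(name=f"standard_{gap_size:g}mm", gap_size=gap_size)


def host_case(letter: str, gap_size: float = 5.0) -> ScenarioSpec:
    """Host-environment case A..J on top of the standard initial state."""
    if letter not in CASE_LETTERS or letter == "standard":
        raise ValueError(f"invalid host case {letter!r}")
    return ScenarioSpec(name=f"case_{letter}_{gap_size:g}mm",
                        gap_size=gap_size, host_case=letter)


def with_treatment(base: ScenarioSpec, day: float, species: str,
                   cm: float = 0.0, gbc: float = 0.0) -> ScenarioSpec:
    sc = copy.deepcopy(base)
    sc.treatments = list(sc.treatments) + [Treatment(day, species, cm, gbc)]
    sc.name = f"{base.name}_{species}_d{day:g}"
    return sc


def apply_treatment(state: StateFields, domain: Domain, entry: Treatment,
                    t: float) -> StateFields:
    """Apply one injection over the central callus area (in place).

    Injection semantics are replace-if-higher: an injection can only add
    material, capped at the carrying capacity.  All non-targeted fields
    are untouched.
    """
    if t > entry.day + 1e-9:
        raise ValueError(f"treatment scheduled at day {entry.day} is in the past")
    central = domain.central_mask & domain.callus_mask
    if entry.species in ("cells", "combo") and entry.cm > 0:
        val = min(entry.cm / CELL_SCALE, 1.0)
        state.cm[central] = np.maximum(state.cm[central], val)
    if entry.species in ("gf", "combo") and entry.gbc > 0:
        val = entry.gbc / GF_SCALE
        state.gbc[central] = np.maximum(state.gbc[central], val)
    return state


# ---------------------------------------------------------------------------
# one-at-a-time sensitivity designs
# ---------------------------------------------------------------------------

#: scalar parameters registered for OAT sweeps -> setter
_OAT_SETTERS = {
    "n_init": lambda sc, v: sc.central.__setitem__("n", v),
    "cm_init": lambda sc, v: sc.central.__setitem__("cm", v),
    "cf_init": lambda sc, v: sc.central.__setitem__("cf", v),
    "gbc_init": lambda sc, v: sc.central.__setitem__("gbc", v),
    "mf_init": lambda sc, v: sc.central.__setitem__("mf", v),
    "gap_size": lambda sc, v: setattr(sc, "gap_size", v),
}


def oat_design(base: ScenarioSpec, parameter: str, values) -> list[ScenarioSpec]:
    """Scenarios identical to ``base`` except the one swept parameter."""
    if parameter not in _OAT_SETTERS:
        raise ValueError(f"unknown OAT parameter {parameter!r}")
    out = []
    for v in values:
        sc = copy.deepcopy(base)
        _OAT_SETTERS[parameter](sc, v)
        sc.name = f"{base.name}_oat_{parameter}_{v:g}"
        out.append(sc)
    return out


def oxygen_gradient_scenario(gap_size: float = 5.0) -> ScenarioSpec:
    """Initial oxygen rising linearly from 0 % at the gap midline to 4 %
    at the bony ends (0.8 %/mm for a 5 mm defect)."""
    sc = standard_compromised(gap_size)
    sc.oxygen_gradient_slope = 0.8
    sc.name = f"oxygen_gradient_{gap_size:g}mm"
    return sc


# ---------------------------------------------------------------------------
# toy fixtures for unit tests
# ---------------------------------------------------------------------------

def toy_fixture(name: str):
    """Miniature configurations for unit testing.

    * ``conservation_box`` - 10x10 all-callus box, no-flux everywhere,
      smooth random-free fields.
    * ``gradient_corridor`` - 16x8 corridor with g_v linear in x and a
      single seed vessel at the high end.
    * ``notch_chain_6`` - a 6-cell vessel chain under uniform high g_v.
    """
    from .vasculature import VesselNetwork, Branch, active_segments

    if name == "conservation_box":
        dom = _toy_domain(10, 10, 0.25)
        st = StateFields.zeros(dom)
        X = np.broadcast_to(dom.x_centers, dom.shape)
        Y = np.broadcast_to(dom.y_centers[:, None], dom.shape)
        for i, (fname, _) in enumerate(st.items()):
            st[fname] = 0.5 + 0.3 * np.sin(2 * np.pi * X / 2.5 + i) \
                * np.cos(np.pi * Y / 2.5)
            st[fname] = np.abs(st[fname])
        st.n = 3.0 + 0.0 * st.n
        return dom, st, VesselNetwork()

    if name == "gradient_corridor":
        dom = _toy_domain(8, 16, 0.25)
        st = StateFields.zeros(dom)
        X = np.broadcast_to(dom.x_centers, dom.shape)
        st.gv = (X / X.max()).copy()
        st.n = np.full(dom.shape, 3.0)
        net = VesselNetwork()
        net.add_branch(Branch([np.array([3.9, 1.0]), np.array([3.8, 1.0])],
                              is_seed=True))
        active_segments(net)
        return dom, st, net

    if name == "notch_chain_6":
        dom = _toy_domain(4, 8, 0.25)
        st = StateFields.zeros(dom)
        st.gv = np.full(dom.shape, 2.0)
        net = VesselNetwork()
        pts = [np.array([0.2 + 0.05 * k, 0.5]) for k in range(6)]
        net.add_branch(Branch(pts, is_seed=True))
        active_segments(net)
        return dom, st, net

    raise ValueError(f"unknown fixture {name!r}")


def _toy_domain(ny: int, nx: int, dx: float) -> Domain:
    region = np.zeros((ny, nx), dtype=np.int8)   # all periosteal_callus
    central = np.zeros((ny, nx), dtype=bool)
    return Domain(gap_size=nx * dx * 2, dx=dx, nx=nx, ny=ny,
                  region_id=region, central_mask=central)
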