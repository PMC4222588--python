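"""Central parameter tables for the fracture-healing model.

All fields are integrated in *model units*, the natural scales of the
fracture callus printed on the simulation colour bars:

=============  =====================  ==================
field          model unit of 1.0      symbol
=============  =====================  ==================
cell density   1e6 cells/ml           c_m, c_f, c_c, c_b
matrix         0.1 g/ml               m_f, m_c, m_b
growth factor  100 ng/ml              g_bc, g_v
oxygen         1 % O2                 n
length         1 mm
time           1 day
=============  =====================  ==================

Scenario I/O is always dimensional (cells/ml, g/ml, ng/ml, %); the
``scale_*`` helpers convert.  Oxygen consumption/delivery constants are
stored in mol/(cell*day) and converted to %/day with a Henry-law
solubility constant and the slab thickness of the 2D reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
import hashlib
import json

# reference scales (dimensional value corresponding to 1.0 model unit)
CELL_SCALE = 1.0e6     # cells/ml
MATRIX_SCALE = 0.1     # g/ml
GF_SCALE = 100.0       # ng/ml
OXYGEN_SCALE = 1.0     # % O2

#: mol O2 per ml tissue corresponding to 1 % O2 (Henry's law, 37 C)
O2_SOLUBILITY = 1.0e-8
#: out-of-plane slab thickness of the 2D domain reduction (mm)
SLAB_THICKNESS = 0.3
#: ml per mm^3
ML_PER_MM3 = 1.0e-3


def cells_per_ml(x):
    """Dimensional cells/ml -> model units."""
    return x / CELL_SCALE


def ng_per_ml(x):
    """Dimensional ng/ml -> model units."""
    return x / GF_SCALE


def g_per_ml(x):
    """Dimensional g/ml -> model units."""
    return x / MATRIX_SCALE


@dataclass(frozen=True)
class OxygenParams:
    """Oxygen delivery, diffusion and Michaelis-Menten consumption.

    The maximal per-cell consumption rates keep the cellular order
    chondrocytes < MSCs < osteoblasts < fibroblasts.
    """

    G_n: float = 3.2e-12     # vessel delivery, mol/(EC*day)
    D_n: float = 2.0e-12     # oxygen diffusion, m^2/s
    Q_c: float = 1.5e-14     # chondrocyte consumption, mol/(cell*day)
    Q_m: float = 3.5e-13     # MSC consumption
    Q_b: float = 4.0e-13     # osteoblast consumption
    Q_f: float = 4.7e-13     # fibroblast consumption
    K_m: float = 0.5         # MM half-saturation oxygen tension, %
    n_vessel: float = 8.0    # oxygen tension sustained inside vessels, %

    def __post_init__(self):
        for name in ("G_n", "D_n", "Q_c", "Q_m", "Q_b", "Q_f", "K_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"OxygenParams.{name} must be >= 0")

    @property
    def consumption_order_ok(self) -> bool:
        return self.Q_c < self.Q_m < self.Q_b < self.Q_f

    def sink_coefficient(self, Q: float) -> float:
        """Convert mol/(cell*day) to (%/day) per model-unit cell density.

        sink [%/day] = Q [mol/cell/day] * c [cells/ml] / solubility [mol/ml/%];
        with c in model units of 1e6 cells/ml the coefficient is Q*1e6/1e-8.
        """
        return Q * CELL_SCALE / O2_SOLUBILITY


def mm2_per_day(D_m2_per_s: float) -> float:
    """m^2/s -> mm^2/day."""
    return D_m2_per_s * 1.0e6 * 86400.0


@dataclass(frozen=True)
class ReactionParams:
    """Rate constants of the tissue-level reaction network (per day,
    model units).  See docs/methods.md for provenance of each value."""

    # random motility / diffusion (mm^2/day)
    D_cm: float = 0.01
    D_cf: float = 0.01
    D_gbc: float = 0.30
    D_gv: float = 0.30
    # chemotaxis of MSCs/fibroblasts up the osteochondrogenic GF gradient
    chi_cm: float = 0.02     # mm^2/day per model GF unit
    chi_cf: float = 0.01
    # proliferation (logistic, 1/day)
    A_m: float = 1.0
    A_f: float = 0.8
    A_c: float = 1.0
    A_b: float = 0.6
    # differentiation (1/day at GF saturation)
    Y_osteo: float = 0.8     # MSC -> osteoblast
    Y_chondro: float = 5.0   # MSC -> chondrocyte
    H_osteo: float = 1.0     # GF half-saturation (100 ng/ml)
    H_chondro: float = 2.0   # GF half-point (200 ng/ml, Hill-2)
    E_endo: float = 0.6      # chondrocyte -> osteoblast (endochondral), 1/day
    # hypoxic death (1/day when the death curve is fully on)
    d_m: float = 2.0
    d_f: float = 2.0
    d_c: float = 2.0
    d_b: float = 1.0
    d_b0: float = 0.05       # baseline osteoblast apoptosis
    # matrix production (model-matrix-units/day per model cell unit)
    P_f: float = 3.0
    P_c: float = 0.6
    P_b: float = 0.8
    k_fc: float = 1.5        # fibrous degraded by chondro/osteoblast activity
    k_cb: float = 1.5        # cartilage resorbed during osteoblast invasion
    # growth factor production / decay
    E_gbc_b: float = 2.0     # g_bc by osteoblasts
    E_gbc_c: float = 0.25    # g_bc by (hypertrophic) chondrocytes
    H_gn: float = 1.0        # oxygen half-saturation of g_bc production, %
    d_gbc: float = 1.0       # 1/day
    k_gbc_use: float = 50.0  # g_bc consumed per unit of chondrogenic conversion
    E_gv: float = 1.5        # max hypoxia-driven g_v production (units/day)
    c_gv_half: float = 0.05  # producer density giving half-max g_v production
    d_gv: float = 0.5        # 1/day
    # carrying capacities (model units)
    c_max: float = 1.0
    m_max: float = 1.0

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"ReactionParams.{name} must be >= 0")


@dataclass(frozen=True)
class VesselParams:
    """Lattice-free endothelial-agent parameters."""

    v_tip: float = 0.07          # tip migration speed, mm/day
    ec_spacing: float = 0.05     # stalk-cell spacing along a branch, mm
    kappa: float = 20.0          # von-Mises concentration of random deflection
    noise_weight: float = 1.0    # 0 disables the stochastic component
    persistence: float = 0.5     # weight of the previous heading in the cue
    g_sprout: float = 0.20       # g_v needed for tip migration (model units)
    g_branch: float = 0.4        # g_v needed to initiate a new sprout
    branch_spacing: float = 0.12 # min distance between junctions, mm
    tip_exclusion: float = 0.10  # no branching this close behind a tip, mm
    anastomosis_radius: float = 0.08  # mm
    min_fusion_length: float = 1.00   # sprout length before it can fuse, mm
    require_loop: bool = False   # stricter perfusion-like activity rule
    abm_dt: float = 0.25         # agent tick, day
    seed_children: int = 3       # live sprouts a seed vessel may maintain
    seed_cooldown: float = 2.0   # days between sprouts from one seed


@dataclass(frozen=True)
class NotchParams:
    """Dll4-Notch lateral-inhibition rule constants (arbitrary units)."""

    vegf_half: float = 0.5     # g_v giving half-maximal Dll4 drive
    inhibition: float = 10.0   # strength of neighbour Notch inhibition
    hill: float = 2.0          # cooperativity of the inhibition
    relax: float = 0.5         # synchronous-update relaxation factor
    tip_threshold: float = 0.5 # Dll4 level above which tip fate is possible
    jitter: float = 1e-6       # symmetry-breaking initial Dll4 jitter
    n_iter: int = 30           # iterations per fate resolution


@dataclass(frozen=True)
class GeometryParams:
    """Callus geometry constants (mm); murine tibia scale."""

    marrow_height: float = 0.5      # endosteal band below the cortex
    cortex_thickness: float = 0.25
    periosteal_height: float = 0.75 # periosteal band above the cortex
    cortex_length: float = 1.0      # retained cortical-end segment
    collar_max: float = 0.5         # periosteal collar excluded from the
                                    # central (reduced-potential) zone
    marrow_edge_width: float = 0.25 # marrow source strip at the far edge


@dataclass(frozen=True)
class SolverParams:
    dx: float = 0.25             # grid spacing, mm
    dt: float = 0.02             # PDE step, day
    cfl_safety: float = 0.9
    clip_tolerance: float = 1e-6  # max clipped negative mass per field/step
    semi_implicit_diffusion: bool = False


@dataclass(frozen=True)
class ModelParams:
    """Bundle of every tunable of the simulator."""

    oxygen: OxygenParams = field(default_factory=OxygenParams)
    reactions: ReactionParams = field(default_factory=ReactionParams)
    vessels: VesselParams = field(default_factory=VesselParams)
    notch: NotchParams = field(default_factory=NotchParams)
    geometry: GeometryParams = field(default_factory=GeometryParams)
    solver: SolverParams = field(default_factory=SolverParams)

    def to_dict(self) -> dict:
        return asdict(self)

    def settings_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def with_overrides(self, **groups) -> "ModelParams":
        """Return a copy with nested overrides, e.g.
        ``params.with_overrides(oxygen={"G_n": 1e-12})``."""
        updates = {}
        for group, vals in groups.items():
            cur = getattr(self, group)
            updates[group] = replace(cur, **vals)
        return replace(self, **updates)


def desk_profile() -> ModelParams:
    """Coarse-grid profile used for routine runs and the test suite."""
    return ModelParams()


def paper_profile() -> ModelParams:
    """High-resolution profile (>=100 cells across the 5 mm half gap)."""
    return ModelParams(solver=SolverParams(dx=0.025, dt=5e-4,
                                           semi_implicit_diffusion=True))


PROFILES = {"desk": desk_profile, "paper": paper_profile}
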