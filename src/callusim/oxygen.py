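"""Oxygen delivery, Michaelis-Menten consumption and the piecewise
oxygen-response multipliers that gate every oxygen-dependent process.

Cellular oxygen consumption follows Michaelis-Menten kinetics with a
cell-type-specific maximal rate ordered chondrocytes < MSCs <
osteoblasts < fibroblasts; the MM factor itself provides the reduced
consumption in hypoxic tissue.  Active vessel segments act as local
oxygen sources.  Each oxygen-dependent process (differentiation,
proliferation, death, hypoxia-driven angiogenic-factor production)
carries a continuous piecewise-linear response curve in oxygen tension;
the anchor tensions follow the model's oxygen-response chart: optimal
chondrogenic differentiation at 3 %, chondrocyte/MSC proliferation peaks
at 3 %/4 %, MSC death below 0.5 % (chondrocytes, the most
hypoxia-tolerant skeletal cells, persist down to 0.3 %).
"""

from __future__ import annotations

import numpy as np

from .params import (OxygenParams, O2_SOLUBILITY, ML_PER_MM3,
                     SLAB_THICKNESS, mm2_per_day)

# ---------------------------------------------------------------------------
# piecewise-linear oxygen response curves: (oxygen %, multiplier) anchors.
# Values are held constant beyond the outermost anchors.
# ---------------------------------------------------------------------------
RESPONSE_CURVES: dict[str, list[tuple[float, float]]] = {
    # differentiation
    "chondrogenic_differentiation": [(0.0, 0.0), (0.5, 0.2), (3.0, 1.0),
                                     (5.0, 0.3), (8.0, 0.1)],
    "osteogenic_differentiation":   [(0.0, 0.0), (2.0, 0.05), (5.0, 1.0),
                                     (21.0, 1.0)],
    # proliferation (peak tensions: chondrocyte 3 %, MSC 4 %)
    "proliferation_msc":        [(0.0, 0.0), (0.5, 0.02), (2.0, 0.05),
                                 (3.0, 0.15), (4.0, 1.0), (6.0, 0.6),
                                 (21.0, 0.6)],
    "proliferation_chondrocyte": [(0.0, 0.0), (0.5, 0.05), (1.5, 0.15),
                                  (3.0, 1.0), (4.0, 0.5), (6.0, 0.1),
                                  (21.0, 0.05)],
    "proliferation_fibroblast": [(0.0, 0.0), (2.0, 0.05), (4.0, 0.1),
                                 (6.0, 1.0), (21.0, 1.0)],
    "proliferation_osteoblast": [(0.0, 0.0), (2.0, 0.2), (6.0, 1.0),
                                 (21.0, 1.0)],
    # death indicators: sharp switches just below each survival threshold;
    # fibroblasts tolerate deep hypoxia (they persist in the avascular
    # centre and lay down the dense fibrous tissue seen there), while
    # osteoblasts need near-normoxia
    "death_msc":        [(0.0, 1.0), (0.45, 1.0), (0.5, 0.0), (21.0, 0.0)],
    "death_chondrocyte": [(0.0, 1.0), (0.25, 1.0), (0.3, 0.0), (21.0, 0.0)],
    "death_fibroblast": [(0.0, 1.0), (0.05, 1.0), (0.1, 0.0), (21.0, 0.0)],
    "death_osteoblast": [(0.0, 1.0), (0.65, 1.0), (0.7, 0.0), (21.0, 0.0)],
    # hypoxia-dependent angiogenic growth factor production: zero above the
    # 3 % breakpoint, and zero below the producing cell's own viability
    # limit (moribund cells stop synthesising VEGF)
    "gv_production":    [(0.0, 0.0), (0.5, 0.0), (0.65, 1.0), (1.5, 1.0),
                         (3.0, 0.0), (21.0, 0.0)],
    "gv_production_chondrocyte": [(0.0, 0.0), (0.3, 0.0), (0.4, 1.0),
                                  (1.5, 1.0), (3.0, 0.0), (21.0, 0.0)],
}


def response_multiplier(process: str, n) -> np.ndarray | float:
    """Piecewise-linear oxygen-response multiplier in [0, 1].

    ``n`` may be a scalar or an array of oxygen tensions (%).
    """
    if process not in RESPONSE_CURVES:
        raise ValueError(f"unknown oxygen-dependent process {process!r}")
    pts = RESPONSE_CURVES[process]
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    scalar = np.isscalar(n)
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 0):
        raise ValueError("oxygen tension must be >= 0")
    out = np.interp(n_arr, xs, ys)
    return float(out) if scalar else out


def response_table() -> "list[dict]":
    """All response curves as records (process, oxygen %, multiplier),
    convenient for a CSV dump."""
    rows = []
    for process, pts in RESPONSE_CURVES.items():
        for x, y in pts:
            rows.append({"process": process, "oxygen_pct": x, "multiplier": y})
    return rows


def mm_factor(n: np.ndarray, K_m: float) -> np.ndarray:
    """Michaelis-Menten saturation factor n / (K_m + n)."""
    return n / (K_m + n)


def consumption_rate(cell_densities: dict[str, np.ndarray], n: np.ndarray,
                     params: OxygenParams) -> np.ndarray:
    """Oxygen sink (%/day): sum over cell types of Q * c * n/(K_m + n).

    ``cell_densities`` maps cm/cf/cc/cb to model-unit densities.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("oxygen tension must be >= 0")
    q = {"cm": params.Q_m, "cf": params.Q_f, "cc": params.Q_c, "cb": params.Q_b}
    sat = mm_factor(n, params.K_m)
    sink = np.zeros_like(n)
    for name, dens in cell_densities.items():
        dens = np.asarray(dens, dtype=float)
        if np.any(dens < 0):
            raise ValueError(f"negative cell density for {name}")
        sink = sink + params.sink_coefficient(q[name]) * dens * sat
    return sink


def delivery_coefficient(params: OxygenParams, dx: float, dy: float) -> float:
    """(%/day) contributed per active endothelial cell in one grid cell.

    G_n [mol/EC/day] is spread over the tissue volume of the grid cell
    (area * slab thickness) and converted with the O2 solubility.
    """
    vol_ml = dx * dy * SLAB_THICKNESS * ML_PER_MM3
    return params.G_n / (vol_ml * O2_SOLUBILITY)


def delivery_rate(active_occupancy: np.ndarray, n: np.ndarray,
                  params: OxygenParams, dx: float, dy: float) -> np.ndarray:
    """Oxygen source (%/day) from the active vasculature.

    Linear in G_n and in the per-cell count of active endothelial
    agents; the (1 - n/n_vessel) factor caps tissue oxygen at the
    vessel tension.
    """
    coeff = delivery_coefficient(params, dx, dy)
    relief = np.clip(1.0 - np.asarray(n) / params.n_vessel, 0.0, None)
    return coeff * np.asarray(active_occupancy, dtype=float) * relief


def oxygen_diffusivity(params: OxygenParams) -> float:
    """D_n in mm^2/day."""
    return mm2_per_day(params.D_n)
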