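"""Outcome measures: binarised tissue fractions per callus region,
union / non-union classification and oxygen summaries.

Tissue fractions follow the binarisation convention: each matrix field
is thresholded (default threshold 10 % of its physiological maximum
density), and when several tissues co-occur in one grid cell the cell's
area is split equally between them.  The cortex is excluded from every
denominator.  A defect counts as a *union* only when a 4-connected path
of binarised bone links the cortical bone end to the gap-midline column
(the symmetry plane); absent bridging, a run whose bone fraction no
longer grows between day 60 and 90 is a stalled (atrophic) non-union.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .domain import Domain, StateFields

#: binarisation thresholds in model units (1.0 = 0.1 g/ml)
DEFAULT_THRESHOLDS = {"mb": 0.1, "mc": 0.1, "mf": 0.1}

TISSUES = {"bone": "mb", "cartilage": "mc", "fibrous": "mf"}
REGION_GROUPS = {
    "endosteal": ("endosteal_callus", "bone_marrow_edge"),
    "periosteal": ("periosteal_callus",),
    "intercortical": ("intercortical_callus",),
}


@dataclass
class TissueFractions:
    day: float
    fractions: dict            # region -> {bone, cartilage, fibrous}

    def __getitem__(self, region: str) -> dict:
        return self.fractions[region]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"day": self.day, "region": reg, "tissue": t, "fraction": f}
                for reg, d in self.fractions.items() for t, f in d.items()]
        return pd.DataFrame(rows)


def binarize(state: StateFields, thresholds: dict | None = None) -> dict:
    thr = thresholds or DEFAULT_THRESHOLDS
    out = {}
    for tissue, fld in TISSUES.items():
        if fld not in thr:
            raise KeyError(f"missing binarisation threshold for {fld}")
        out[tissue] = state[fld] >= thr[fld]
    return out


def tissue_fractions(state: StateFields, domain: Domain,
                     thresholds: dict | None = None,
                     day: float = 0.0) -> TissueFractions:
    """Area fractions of bone/cartilage/fibrous tissue per callus region.

    Grid cells containing k tissues contribute area/k to each.
    """
    masks = binarize(state, thresholds)
    count = sum(m.astype(int) for m in masks.values())
    weight = np.where(count > 0, 1.0 / np.maximum(count, 1), 0.0)

    fractions: dict = {}
    region_masks = {name: _region_mask(domain, name)
                    for name in (*REGION_GROUPS, "whole")}
    for reg, rmask in region_masks.items():
        area = float(rmask.sum())
        fractions[reg] = {}
        for tissue, m in masks.items():
            if area == 0:
                fractions[reg][tissue] = 0.0
            else:
                fractions[reg][tissue] = float((weight * (m & rmask)).sum() / area)
    return TissueFractions(day=day, fractions=fractions)


def _region_mask(domain: Domain, name: str) -> np.ndarray:
    if name == "whole":
        return domain.callus_mask
    parts = REGION_GROUPS[name]
    mask = np.zeros(domain.shape, dtype=bool)
    for p in parts:
        mask |= domain.region(p)
    return mask


def bone_bridged(state: StateFields, domain: Domain,
                 thresholds: dict | None = None) -> bool:
    """True when a 4-connected binarised-bone path spans from the
    cortical bone end to the gap-midline column."""
    bone = binarize(state, thresholds)["bone"]
    labeled, nlab = ndimage.label(bone, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if nlab == 0:
        return False
    # cells adjacent to the cortex region
    cortex = domain.cortex_mask
    adj = ndimage.binary_dilation(cortex, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]])) & ~cortex
    start_labels = set(labeled[adj & bone].ravel()) - {0}
    # the gap-midline (symmetry) column is the one farthest from the cortex
    cortex_cols = np.nonzero(cortex.any(axis=0))[0]
    mid = 0 if cortex_cols.mean() > domain.nx / 2 else domain.nx - 1
    end_labels = set(labeled[:, mid][bone[:, mid]].ravel()) - {0}
    return bool(start_labels & end_labels)


@dataclass
class HealingOutcome:
    classification: str               # union | non_union
    bridging_day: float | None
    bone_series: pd.DataFrame         # day, bone fraction (whole callus)
    stalled: bool = False

    @property
    def is_union(self) -> bool:
        return self.classification == "union"


def classify_outcome(snapshots: list, domain: Domain,
                     thresholds: dict | None = None,
                     stall_tolerance: float = 0.005) -> HealingOutcome:
    """Classify a run from (day, StateFields) snapshots.

    The series must reach at least day 60-90 so stalling can be judged.
    """
    if not snapshots:
        raise ValueError("empty snapshot series")
    days = [d for d, _ in snapshots]
    if max(days) < 90.0 - 1e-6 or not any(d >= 60.0 for d in days):
        raise ValueError("snapshot series must cover days 60-90")

    rows = []
    bridging_day = None
    for day, st in sorted(snapshots, key=lambda p: p[0]):
        tf = tissue_fractions(st, domain, thresholds, day)
        rows.append({"day": day, "bone": tf["whole"]["bone"]})
        if bridging_day is None and bone_bridged(st, domain, thresholds):
            bridging_day = day
    series = pd.DataFrame(rows)

    b60 = float(np.interp(60.0, series.day, series.bone))
    b90 = float(series.bone.iloc[-1])
    stalled = (b90 - b60) < stall_tolerance

    cls = "union" if bridging_day is not None else "non_union"
    return HealingOutcome(classification=cls, bridging_day=bridging_day,
                          bone_series=series, stalled=stalled)


def central_oxygen_mean(state: StateFields, domain: Domain) -> float:
    """Area-weighted mean oxygen tension (%) over the central callus area."""
    central = domain.central_mask & domain.callus_mask
    if not np.any(central):
        raise ValueError("central mask is empty")
    return float(state.n[central].mean())
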