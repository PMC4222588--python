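"""Batch simulation driver: single runs, the shipped experiment families
and reproducible seed handling.

A run executes one scenario to day 90 (by default), recording a per-day
summary (tissue fractions, central oxygen, vessel front, EC count) and
sparse field snapshots, and classifies the healing outcome.  Experiment
families reproduce the in-silico designs: the gap-size sweep, the
host-environment cases A-J, day-zero treatments in the permissive
(partially vascularised) environment, treatment-timing sweeps in the
compromised environment, and a one-at-a-time sensitivity table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import pathlib

import numpy as np
import pandas as pd

from .domain import build_domain, initial_state, boundary_spec
from .params import ModelParams, desk_profile, PROFILES
from .pde import Simulation
from .quantify import (tissue_fractions, classify_outcome,
                       central_oxygen_mean, HealingOutcome)
from .scenarios import (ScenarioSpec, standard_compromised, host_case,
                        with_treatment, apply_treatment, oat_design)
from .vasculature import seed_vessels, network_edges

SNAPSHOT_DAYS = (0, 7, 14, 21, 28, 35, 42, 49, 56, 60, 63, 70, 80, 90)


@dataclass
class RunRecord:
    scenario: ScenarioSpec
    seed: int
    settings_hash: str
    summary: pd.DataFrame
    outcome: HealingOutcome | None
    status: str = "completed"
    snapshots: list = field(default_factory=list)   # (day, StateFields)
    output_dir: str | None = None


def child_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-replicate seeds spawned from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def run(scenario: ScenarioSpec, days: float | None = None,
        seed: int | None = None, params: ModelParams | None = None,
        outdir: str | None = None,
        snapshot_days=SNAPSHOT_DAYS) -> RunRecord:
    """Execute one scenario and summarise it."""
    params = params or desk_profile()
    days = float(days if days is not None else scenario.days)
    seed = int(seed if seed is not None else scenario.seed)
    rng = np.random.default_rng(seed)

    domain = build_domain(scenario.gap_size, params.solver.dx,
                          scenario.geometry)
    state = initial_state(domain, scenario)
    bcs = boundary_spec(domain, scenario)
    vessels = seed_vessels(domain, scenario, params.vessels)
    sim = Simulation(domain, state, vessels, bcs, params, scenario, rng)

    pending = sorted(scenario.treatments, key=lambda tr: tr.day)
    snapshot_days = sorted(set(float(d) for d in snapshot_days if d <= days)
                           | {days})
    dt = params.solver.dt
    n_steps = int(round(days / dt))

    rows = []
    snapshots = []
    next_day = 0.0
    status = "completed"

    def record(day: float):
        tf = tissue_fractions(sim.state, domain, day=day)
        rows.append({
            "day": day,
            "bone": tf["whole"]["bone"],
            "cartilage": tf["whole"]["cartilage"],
            "fibrous": tf["whole"]["fibrous"],
            "central_oxygen": central_oxygen_mean(sim.state, domain)
            if np.any(domain.central_mask & domain.callus_mask) else np.nan,
            "vessel_front": sim.vessels.front_position(),
            "n_ec": sim.vessels.n_ecs(),
        })

    try:
        record(0.0)
        if any(abs(d) < 1e-9 for d in snapshot_days):
            snapshots.append((0.0, sim.state.copy()))
        while pending and pending[0].day <= 1e-9:
            apply_treatment(sim.state, domain, pending.pop(0), sim.t)
        next_day = 1.0
        for k in range(n_steps):
            sim.step()
            # treatments are applied on the step their day is reached
            while pending and sim.t + 1e-9 >= pending[0].day:
                tr = pending.pop(0)
                apply_treatment(sim.state, domain, tr, tr.day)
            if sim.t + 1e-9 >= next_day:
                record(round(sim.t))
                next_day += 1.0
            for d in snapshot_days:
                if abs(sim.t - d) < dt / 2 and all(abs(sd - d) > 1e-9
                                                   for sd, _ in snapshots):
                    snapshots.append((float(d), sim.state.copy()))
    except RuntimeError as exc:
        status = f"aborted: {exc}"

    summary = pd.DataFrame(rows)
    outcome = None
    if status == "completed" and days >= 90.0 - 1e-6:
        outcome = classify_outcome(snapshots, domain)

    rec = RunRecord(scenario=scenario, seed=seed,
                    settings_hash=params.settings_hash(), summary=summary,
                    outcome=outcome, status=status, snapshots=snapshots,
                    output_dir=outdir)
    if outdir is not None:
        _write_outputs(rec, domain, sim, pathlib.Path(outdir))
    return rec


def _write_outputs(rec: RunRecord, domain, sim, outdir: pathlib.Path) -> None:
    import h5py

    outdir.mkdir(parents=True, exist_ok=True)
    rec.summary.to_csv(outdir / "summary.csv", index=False)
    meta = {"scenario": rec.scenario.to_dict(), "seed": rec.seed,
            "settings_hash": rec.settings_hash, "status": rec.status}
    (outdir / "run.json").write_text(json.dumps(meta, indent=2, default=float))
    pd.DataFrame(network_edges(sim.vessels)).to_csv(
        outdir / "vessels.csv", index=False)
    with h5py.File(outdir / "snapshots.h5", "w") as h5:
        h5.attrs["settings_hash"] = rec.settings_hash
        h5.create_dataset("region_id", data=domain.region_id)
        h5.create_dataset("central_mask", data=domain.central_mask)
        for day, st in rec.snapshots:
            grp = h5.create_group(f"day_{day:g}")
            for name, arr in st.items():
                grp.create_dataset(name, data=arr)


# ---------------------------------------------------------------------------
# experiment families
# ---------------------------------------------------------------------------

GAP_SWEEP_MM = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0)
HOST_CASES = ("standard", "A", "B", "C", "D", "E", "F", "G", "H", "I", "J")
TIMING_DAYS = (0, 7, 14, 28, 35, 42, 49, 56, 63)

# treatment doses (dimensional)
PERMISSIVE_CELL_DOSE = 2e5        # cells/ml, day-0 injections, permissive host
PERMISSIVE_GF_DOSE = 1e3          # ng/ml
COMPROMISED_CELL_DOSE = 1e6       # cells/ml, timing sweep, compromised host
COMPROMISED_GF_DOSE = 1e3         # ng/ml


def _experiment_scenarios(name: str) -> list[ScenarioSpec]:
    if name == "gap_sweep":
        return [standard_compromised(g) for g in GAP_SWEEP_MM]
    if name == "host_cases":
        return [standard_compromised(5.0)] + [host_case(c, 5.0)
                                              for c in HOST_CASES[1:]]
    if name == "permissive_treatments":
        base = host_case("B", 5.0)
        return [
            base,
            with_treatment(base, 0.0, "cells", cm=PERMISSIVE_CELL_DOSE),
            with_treatment(base, 0.0, "gf", gbc=PERMISSIVE_GF_DOSE),
            with_treatment(base, 0.0, "combo", cm=PERMISSIVE_CELL_DOSE,
                           gbc=PERMISSIVE_GF_DOSE),
        ]
    if name == "compromised_timing":
        base = standard_compromised(5.0)
        out = [base]
        for day in TIMING_DAYS:
            out.append(with_treatment(base, day, "cells",
                                      cm=COMPROMISED_CELL_DOSE))
            out.append(with_treatment(base, day, "gf",
                                      gbc=COMPROMISED_GF_DOSE))
            out.append(with_treatment(base, day, "combo",
                                      cm=COMPROMISED_CELL_DOSE,
                                      gbc=COMPROMISED_GF_DOSE))
        return out
    if name == "oat_table":
        base = standard_compromised(5.0)
        out = []
        out += oat_design(base, "n_init", (0.5, 0.7, 3.7, 4.0))
        out += oat_design(base, "cm_init", (2e3, 2e4, 2e5))
        out += oat_design(base, "gbc_init", (10.0, 100.0, 1000.0))
        return out
    raise ValueError(f"unknown experiment {name!r}")


def run_experiment(name: str, replicates: int = 1, master_seed: int = 0,
                   params: ModelParams | None = None,
                   days: float = 90.0) -> pd.DataFrame:
    """Run a scenario family and aggregate day-90 outcomes.

    One row per (scenario, seed): tissue fractions of the whole callus,
    the union/non-union classification and the stalling flag.
    """
    scenarios = _experiment_scenarios(name)
    seeds = child_seeds(master_seed, replicates)
    rows = []
    for sc in scenarios:
        for rep, seed in enumerate(seeds):
            rec = run(sc, days=days, seed=seed, params=params)
            last = rec.summary.iloc[-1]
            rows.append({
                "experiment": name,
                "scenario": sc.name,
                "gap_size": sc.gap_size,
                "host_case": sc.host_case,
                "treatment_day": sc.treatments[0].day if sc.treatments else np.nan,
                "treatment": sc.treatments[0].species if sc.treatments else "none",
                "replicate": rep,
                "seed": seed,
                "status": rec.status,
                "bone": last["bone"],
                "cartilage": last["cartilage"],
                "fibrous": last["fibrous"],
                "central_oxygen": last["central_oxygen"],
                "classification": rec.outcome.classification
                if rec.outcome else "incomplete",
                "stalled": rec.outcome.stalled if rec.outcome else np.nan,
            })
    return pd.DataFrame(rows)


def aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and spread of the tissue fractions over replicates."""
    keys = ["experiment", "scenario"]
    agg = table.groupby(keys).agg(
        bone_mean=("bone", "mean"), bone_std=("bone", "std"),
        cartilage_mean=("cartilage", "mean"),
        fibrous_mean=("fibrous", "mean"),
        union_rate=("classification", lambda s: float((s == "union").mean())),
        n=("bone", "size")).reset_index()
    return agg
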