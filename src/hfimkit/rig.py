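"""Forward simulation of the physical hollow-fiber rig.

The rig is a tri-compartment system: drug is infused into the central
reservoir (volume ``V_central``), which is connected to the cartridge
intracapillary space (ICS, ``V_ICS``) by a fast circulation loop
(``Q_cartridge``); drug crosses the fiber membrane into the extracapillary
space (ECS, ``V_ECS``) at a constant bidirectional diffusion flow
``Q_diffusion``; elimination is a dilution flow ``CL_elim`` through the
central reservoir. In amounts ``A``:

    dA_c/dt = in(t) + Q_cart*(C_i - C_c) - CL_elim*C_c
    dA_i/dt = Q_cart*(C_c - C_i) + Q_diff*(C_e - C_i)
    dA_e/dt = Q_diff*(C_i - C_e)

Within each sub-interval of a piecewise-constant infusion this is a linear
time-invariant system, so the simulator propagates the exact solution via
a matrix exponential per step (cached per distinct (rate, step) pair)
instead of numerically integrating a stiff ODE: the ICS equilibrates about
200x faster than elimination, yet the propagation is exact to machine
precision at any step size, and mass balance holds to ~1e-14.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .design import InfusionSchedule, PumpProgram, RawSchedule, RigConfig
from .pk import ConcentrationSeries

__all__ = [
    "RigSimResult",
    "partition_volumes",
    "simulate_rig",
    "expected_lumped_profile",
    "central_vs_ecs_metrics",
]


def partition_volumes(v_cartridge_l: float, f_ics: float) -> tuple[float, float]:
    """Split the cartridge volume into (V_ICS, V_ECS) = (f*V, (1-f)*V)."""
    if v_cartridge_l <= 0:
        raise ValueError("v_cartridge must be > 0")
    if not (0 <= f_ics < 1):
        raise ValueError("f_ics must be in [0, 1)")
    v_ics = f_ics * v_cartridge_l
    return v_ics, v_cartridge_l - v_ics


@dataclass
class RigSimResult:
    """Simulation output: concentrations plus mass-balance bookkeeping."""

    times_h: np.ndarray
    conc: dict[str, np.ndarray]  # central / ICS / ECS, mg/L
    amounts: dict[str, np.ndarray]  # mg
    cumulative_infused_mg: np.ndarray
    cumulative_eliminated_mg: np.ndarray
    rig: RigConfig

    @property
    def series(self) -> ConcentrationSeries:
        frames = [
            pd.DataFrame(
                {
                    "time_h": self.times_h,
                    "conc_mg_L": self.conc[comp],
                    "compartment": comp,
                    "replicate": "sim",
                }
            )
            for comp in ("central", "ICS", "ECS")
        ]
        return ConcentrationSeries(pd.concat(frames, ignore_index=True))

    def mass_balance_error(self) -> float:
        """Max relative deviation of (infused - eliminated) from rig content."""
        content = sum(self.amounts.values())
        resid = self.cumulative_infused_mg - self.cumulative_eliminated_mg - content
        scale = np.maximum(self.cumulative_infused_mg, 1e-300)
        mask = self.cumulative_infused_mg > 0
        if not mask.any():
            return float(np.max(np.abs(resid)))
        return float(np.max(np.abs(resid[mask]) / scale[mask]))


def _as_schedule(
    schedule: InfusionSchedule | PumpProgram | RawSchedule,
) -> InfusionSchedule:
    if isinstance(schedule, InfusionSchedule):
        return schedule
    return schedule.to_infusion_schedule()


def simulate_rig(
    rig: RigConfig,
    q_diffusion_l_h: float,
    schedule: InfusionSchedule | PumpProgram | RawSchedule,
    grid: Sequence[float],
) -> RigSimResult:
    """Exact piecewise-LTI simulation of the tri-compartment rig.

    ``schedule`` is a piecewise-constant infusion (mg/h) into the central
    reservoir. The state is propagated through the sorted union of the
    output grid and the schedule breakpoints; matrix exponentials are
    cached per distinct (rate, step), so uniform grids are cheap.
    """
    if q_diffusion_l_h < 0:
        raise ValueError("q_diffusion must be >= 0")
    sched = _as_schedule(schedule)
    if np.any(sched.rates_mg_h < 0):
        raise ValueError("infusion rates must be >= 0")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be non-empty and strictly increasing")

    vc, vi, ve = rig.v_central_l, rig.v_ics_l, rig.v_ecs_l
    qc, qd, cl = rig.q_cartridge_l_h, q_diffusion_l_h, rig.cl_elim_l_h
    if vi <= 0:
        raise ValueError("rig has no ICS volume; tri-compartment model undefined")
    # state: [A_central, A_ics, A_ecs, eliminated, 1]
    base = np.zeros((5, 5))
    base[0, :3] = [-(qc + cl) / vc, qc / vi, 0.0]
    base[1, :3] = [qc / vc, -(qc + qd) / vi, qd / ve]
    base[2, :3] = [0.0, qd / vi, -qd / ve]
    base[3, 0] = cl / vc

    events = np.unique(
        np.concatenate(
            [
                grid,
                sched.breakpoints[
                    (sched.breakpoints > grid[0]) & (sched.breakpoints < grid[-1])
                ],
            ]
        )
    )
    if grid[0] > 0:
        events = np.concatenate([[0.0], events])

    bp, rates = sched.breakpoints, sched.rates_mg_h
    cache: dict[tuple[float, float], np.ndarray] = {}
    state = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
    out_states = np.empty((grid.size, 5))
    infused = np.empty(grid.size)
    cum_in = 0.0
    gi = 0
    if events[0] >= grid[0] - 1e-15:
        out_states[0] = state
        infused[0] = cum_in
        gi = 1
    for k in range(events.size - 1):
        t0, t1 = events[k], events[k + 1]
        dt = t1 - t0
        j = np.searchsorted(bp, t0 + 1e-12) - 1
        rate = rates[j] if 0 <= j < rates.size and t0 < bp[-1] - 1e-12 else 0.0
        key = (round(rate, 15), round(dt, 15))
        P = cache.get(key)
        if P is None:
            m = base.copy()
            m[0, 4] = rate
            P = expm(m * dt)
            cache[key] = P
        state = P @ state
        cum_in += rate * dt
        if gi < grid.size and abs(t1 - grid[gi]) < 1e-12:
            out_states[gi] = state
            infused[gi] = cum_in
            gi += 1
    if gi != grid.size:
        raise RuntimeError("internal grid alignment failure")

    amounts = {
        "central": out_states[:, 0],
        "ICS": out_states[:, 1],
        "ECS": out_states[:, 2],
    }
    return RigSimResult(
        times_h=grid,
        conc={
            "central": amounts["central"] / vc,
            "ICS": amounts["ICS"] / vi,
            "ECS": amounts["ECS"] / ve,
        },
        amounts=amounts,
        cumulative_infused_mg=infused,
        cumulative_eliminated_mg=out_states[:, 3],
        rig=rig,
    )


def expected_lumped_profile(
    schedule: InfusionSchedule | PumpProgram | RawSchedule,
    ke: float,
    v_total: float,
    grid: Sequence[float],
) -> ConcentrationSeries:
    """One-compartment well-mixed simulation of the rig under a program.

    The whole rig volume ``v_total`` is treated as a single compartment
    with elimination ``ke``; within each constant-rate segment the exact
    update ``A <- A e^(-ke dt) + r (1 - e^(-ke dt))/ke`` is applied.
    This is the "expected concentration" a program should produce if the
    rig mixed instantly.
    """
    if ke < 0 or v_total <= 0:
        raise ValueError("ke must be >= 0 and v_total > 0")
    sched = _as_schedule(schedule)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be non-empty and strictly increasing")
    events = np.unique(
        np.concatenate(
            [
                grid,
                sched.breakpoints[
                    (sched.breakpoints > grid[0]) & (sched.breakpoints < grid[-1])
                ],
            ]
        )
    )
    if grid[0] > 0:
        events = np.concatenate([[0.0], events])
    bp, rates = sched.breakpoints, sched.rates_mg_h
    a = 0.0
    out = np.empty(grid.size)
    gi = 0
    if events[0] >= grid[0] - 1e-15:
        out[0] = a
        gi = 1
    for k in range(events.size - 1):
        t0, t1 = events[k], events[k + 1]
        dt = t1 - t0
        j = np.searchsorted(bp, t0 + 1e-12) - 1
        rate = rates[j] if 0 <= j < rates.size and t0 < bp[-1] - 1e-12 else 0.0
        if ke == 0:
            a = a + rate * dt
        else:
            decay = math.exp(-ke * dt)
            a = a * decay + rate * (1.0 - decay) / ke
        if gi < grid.size and abs(t1 - grid[gi]) < 1e-12:
            out[gi] = a
            gi += 1
    if gi != grid.size:
        raise RuntimeError("internal grid alignment failure")
    return ConcentrationSeries.from_arrays(grid, out / v_total, compartment="lumped")


def central_vs_ecs_metrics(
    series: ConcentrationSeries,
    dose_times: Sequence[float],
    tau: float,
    snap_h: float | None = None,
) -> pd.DataFrame:
    """Per-dose central-vs-ECS delay and attenuation.

    For each dosing interval: ECS-minus-central Tmax difference (h),
    ECS/central Cmax ratio and ECS/central AUCτ ratio (linear trapezoid on
    the simulation grid). ``snap_h`` optionally snaps Tmax values to a
    coarser reporting grid (e.g. 0.25 h) before differencing, mirroring a
    sparse experimental sampling scheme.
    """
    comps = series.compartments
    for needed in ("central", "ECS"):
        if needed not in comps:
            raise ValueError(f"series lacks the {needed} compartment")
    cen = series.subset(compartment="central")
    ecs = series.subset(compartment="ECS")
    tc, cc = cen.times(), cen.concs()
    te, ce = ecs.times(), ecs.concs()
    rows = []
    for idx, td in enumerate(sorted(dose_times)):
        sc = (tc >= td - 1e-12) & (tc < td + tau - 1e-12)
        se = (te >= td - 1e-12) & (te < td + tau - 1e-12)
        if not sc.any() or not se.any():
            continue
        tmax_c = tc[sc][np.argmax(cc[sc])]
        tmax_e = te[se][np.argmax(ce[se])]
        if snap_h is not None:
            tmax_c = round(tmax_c / snap_h) * snap_h
            tmax_e = round(tmax_e / snap_h) * snap_h
        auc_c = np.trapezoid(cc[sc], tc[sc])
        auc_e = np.trapezoid(ce[se], te[se])
        rows.append(
            dict(
                dose_index=idx + 1,
                dtmax_h=float(tmax_e - tmax_c),
                cmax_ratio=float(ce[se].max() / cc[sc].max()),
                auc_ratio=float(auc_e / auc_c) if auc_c > 0 else np.nan,
            )
        )
    return pd.DataFrame(rows)
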