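"""Pump-program design for the hollow-fiber rig.

Absorption mode: a first-order absorption profile is approximated by a
series of ``n`` piecewise-constant infusions from an ambulatory pump. Each
sub-interval delivers the same amount of drug; sub-interval end times are
spaced so that the cumulative amount delivered by ``t_i`` equals
``Dose * (1 - e^(-ka * t_i))`` — the cumulative input of the continuous
first-order process. Only a fraction ``f_dose = 1 - e^(-ka * t_n)`` of the
nominal dose is ever delivered; the remainder would require infusing past
the end of the dosing interval.

IV mode: a single short zero-order infusion, with the dose corrected for
elimination occurring during the infusion.

Elimination in both modes is mimicked by a peristaltic pump flushing the
central reservoir with drug-free medium at ``CL_elim = ke * V_total``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pk import TargetPK, tmax_first_dose, EQUAL_RATE_RTOL

__all__ = [
    "RigConfig",
    "RawSchedule",
    "SubInterval",
    "PumpProgram",
    "IVDesign",
    "InfusionSchedule",
    "compute_dose",
    "compute_fdose",
    "build_schedule",
    "select_infusion_concentration",
    "quantize_program",
    "elimination_setup",
    "design_iv",
    "design_absorption",
]


@dataclass(frozen=True)
class RigConfig:
    """Physical volumes and flows of the hollow-fiber rig.

    ``v_total_design`` — the volume the dose calculation targets — is the
    central reservoir plus the cartridge extracapillary space (ECS); the
    intracapillary space only matters to the tri-compartment simulator.

    Defaults are a 300 mL reservoir with a pediatric dialyzer cartridge
    (78 mL, of which 18 mL fiber lumen), a 60 mL/min circulation loop and a
    96 h experiment.
    """

    v_central_l: float = 0.300
    v_cartridge_l: float = 0.078
    f_ics: float = 0.018 / 0.078
    q_cartridge_l_h: float = 3.6
    cl_elim_l_h: float = 0.0828
    q_diffusion_l_h: float = 0.387
    exp_duration_h: float = 96.0

    def __post_init__(self) -> None:
        if self.v_central_l <= 0 or self.v_cartridge_l <= 0:
            raise ValueError("volumes must be > 0")
        if not (0 <= self.f_ics < 1):
            raise ValueError("f_ics must be in [0, 1)")
        if self.q_cartridge_l_h < 0 or self.q_diffusion_l_h < 0:
            raise ValueError("flows must be >= 0")
        if self.cl_elim_l_h < 0:
            raise ValueError("cl_elim must be >= 0")

    @property
    def v_ics_l(self) -> float:
        return self.f_ics * self.v_cartridge_l

    @property
    def v_ecs_l(self) -> float:
        return self.v_cartridge_l - self.v_ics_l

    @property
    def v_total_design_l(self) -> float:
        """Volume seen by the design equations (reservoir + ECS)."""
        return self.v_central_l + self.v_ecs_l


@dataclass(frozen=True)
class InfusionSchedule:
    """Piecewise-constant infusion: rate ``rates_mg_h[i]`` applies on
    ``[breakpoints[i], breakpoints[i+1])``; zero outside."""

    breakpoints: np.ndarray
    rates_mg_h: np.ndarray

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        r = np.asarray(self.rates_mg_h, dtype=float)
        if bp.size != r.size + 1:
            raise ValueError("need len(breakpoints) == len(rates) + 1")
        if np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise ValueError("rates must be finite")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "rates_mg_h", r)

    @classmethod
    def single_infusion(cls, dose_mg: float, t_inf_h: float, t_start_h: float = 0.0):
        return cls(
            np.array([t_start_h, t_start_h + t_inf_h]),
            np.array([dose_mg / t_inf_h]),
        )

    def repeated(self, tau_h: float, n_doses: int) -> "InfusionSchedule":
        """Repeat the same program every ``tau_h`` for ``n_doses`` doses.

        Duration quantization can push a program's total length slightly
        past the dosing interval (e.g. rounding 12 sub-intervals up by a
        minute in total); overruns up to 2% of ``tau_h`` are truncated at
        the interval boundary, larger ones are an error.
        """
        end = self.breakpoints[-1]
        if end > tau_h * 1.02 + 1e-12:
            raise ValueError("schedule longer than the dosing interval")
        base = self
        if end > tau_h + 1e-12:
            keep = self.breakpoints < tau_h - 1e-12
            bp_clip = np.append(self.breakpoints[keep], tau_h)
            base = InfusionSchedule(bp_clip, self.rates_mg_h[: bp_clip.size - 1])
        return base._tile(tau_h, n_doses)

    def _tile(self, tau_h: float, n_doses: int) -> "InfusionSchedule":
        bps: list[float] = []
        rates: list[float] = []
        for d in range(n_doses):
            seg_bp = self.breakpoints + d * tau_h
            if not bps:
                bps.extend(seg_bp)
                rates.extend(self.rates_mg_h)
                continue
            if abs(bps[-1] - seg_bp[0]) < 1e-12:
                bps.pop()
            else:  # zero-rate gap between end of one program and next dose
                rates.append(0.0)
            bps.extend(seg_bp)
            rates.extend(self.rates_mg_h)
        return InfusionSchedule(np.array(bps), np.array(rates))

    def total_amount_mg(self) -> float:
        return float(np.sum(self.rates_mg_h * np.diff(self.breakpoints)))


@dataclass(frozen=True)
class RawSchedule:
    """Unquantized sub-interval schedule (the exact algorithm output)."""

    dose_mg: float
    ka: float
    n: int
    t_n_h: float
    f_dose: float
    t_ends_h: np.ndarray  # length n, strictly increasing, ends at t_n
    rates_mg_h: np.ndarray  # length n, infusion rate per sub-interval

    @property
    def per_interval_amount_mg(self) -> float:
        return self.dose_mg * self.f_dose / self.n

    @property
    def durations_h(self) -> np.ndarray:
        return np.diff(np.concatenate([[0.0], self.t_ends_h]))

    def to_infusion_schedule(self) -> InfusionSchedule:
        return InfusionSchedule(
            np.concatenate([[0.0], self.t_ends_h]), self.rates_mg_h
        )


@dataclass(frozen=True)
class SubInterval:
    index: int
    t_start_h: float
    t_end_h: float
    duration_min: float
    flow_ml_h: float
    amount_mg: float  # nominal (equal-amount) value, as programmed
    delivered_mg: float  # flow * duration * c_infusion after quantization
    zero_flow_warning: bool = False


@dataclass(frozen=True)
class PumpProgram:
    """Quantized ambulatory-pump program plus elimination-pump settings."""

    sub_intervals: tuple[SubInterval, ...]
    c_infusion_mg_ml: float
    per_subinterval_volume_ml: float
    tau_h: float
    n_doses_total: int
    dose_per_interval_mg: float  # nominal Dose of the design equations
    f_dose: float
    cl_elim_l_h: float = 0.0
    v_diluent_l: float = 0.0

    @property
    def n(self) -> int:
        return len(self.sub_intervals)

    def delivered_per_dose_mg(self) -> float:
        return sum(s.delivered_mg for s in self.sub_intervals)

    def to_infusion_schedule(self, quantized: bool = True) -> InfusionSchedule:
        """Schedule in mg/h from the (quantized) durations and flows."""
        durations_h = np.array([s.duration_min for s in self.sub_intervals]) / 60.0
        bps = np.concatenate([[0.0], np.cumsum(durations_h)])
        rates = (
            np.array([s.flow_ml_h for s in self.sub_intervals]) * self.c_infusion_mg_ml
        )
        return InfusionSchedule(bps, rates)


# ---------------------------------------------------------------------------
# design equations
# ---------------------------------------------------------------------------


def compute_dose(
    cmax1: float, ka: float, ke: float, v_total: float, f: float = 1.0
) -> float:
    """Nominal dose making the first-dose absorption peak equal ``cmax1``.

    Inverts ``C(t_max) = F*Dose*ka / (V*(ka-ke)) * (e^(-ke t) - e^(-ka t))``
    at the first-dose peak time.
    """
    if ka <= 0 or ke <= 0:
        raise ValueError("rate constants must be > 0")
    if not (0 < f <= 1):
        raise ValueError("F must be in (0, 1]")
    if v_total <= 0:
        raise ValueError("v_total must be > 0")
    if cmax1 == 0:
        return 0.0
    tmax = tmax_first_dose(ka, ke)
    if abs(ka - ke) < EQUAL_RATE_RTOL * ke:
        unit = ke * tmax * math.exp(-ke * tmax)  # flip-flop limit of ka*(...)/(ka-ke)
        return cmax1 * v_total / (f * unit)
    unit = ka / (ka - ke) * (math.exp(-ke * tmax) - math.exp(-ka * tmax))
    return cmax1 * v_total / (f * unit)


def compute_fdose(ka: float, t_n: float) -> float:
    """Fraction of the nominal dose delivered by the last sub-interval end,
    ``1 - e^(-ka * t_n)``."""
    if ka <= 0 or t_n <= 0:
        raise ValueError("ka and t_n must be > 0")
    return -math.expm1(-ka * t_n)


def build_schedule(dose_mg: float, ka: float, n: int, t_n_h: float) -> RawSchedule:
    """Exact (unquantized) equal-amount sub-interval schedule.

    End times ``t_i = -ln(1 - f_dose*i/n) / ka`` make the cumulative amount
    delivered by ``t_i`` equal ``Dose*(1 - e^(-ka t_i))``; the per-interval
    rate is the remaining-amount difference over the duration.
    """
    if n < 2:
        raise ValueError("need at least 2 sub-intervals")
    if dose_mg <= 0:
        raise ValueError("dose must be > 0")
    fd = compute_fdose(ka, t_n_h)
    i = np.arange(0, n + 1, dtype=float)
    t = -np.log1p(-fd * i / n) / ka
    t[-1] = t_n_h  # exact by construction; avoid last-digit float drift
    amounts_remaining = dose_mg * np.exp(-ka * t)
    rates = (amounts_remaining[:-1] - amounts_remaining[1:]) / np.diff(t)
    return RawSchedule(
        dose_mg=dose_mg,
        ka=ka,
        n=n,
        t_n_h=t_n_h,
        f_dose=fd,
        t_ends_h=t[1:],
        rates_mg_h=rates,
    )


def select_infusion_concentration(
    schedule: RawSchedule, target_volume_ml: float = 2.0
) -> float:
    """Infusion-solution concentration making each sub-interval deliver
    ``target_volume_ml`` (the smallest volume the pump injects precisely)."""
    if target_volume_ml <= 0:
        raise ValueError("target_volume must be > 0")
    amount = schedule.per_interval_amount_mg
    if amount <= 0:
        raise ValueError("schedule delivers no drug; concentration undefined")
    return amount / target_volume_ml


def _round_half_up(x: float, resolution: float) -> float:
    return math.floor(x / resolution + 0.5) * resolution


def quantize_program(
    schedule: RawSchedule,
    c_infusion_mg_ml: float,
    flow_resolution_ml_h: float = 0.1,
    duration_resolution_min: float = 1.0,
    duration_display_precision_min: float = 0.1,
    tau_h: float | None = None,
    n_doses_total: int = 1,
    cl_elim_l_h: float = 0.0,
    v_diluent_l: float = 0.0,
) -> PumpProgram:
    """Round the exact schedule onto the pump's programmable grid.

    Flows ``S_i / C_infusion`` are rounded to the nearest
    ``flow_resolution_ml_h``. Durations are first expressed at the pump
    app's display precision (0.1 min), then rounded half-up to
    ``duration_resolution_min`` — matching how programs are transcribed to
    the pump (a raw 41.495 min shows as 41.5 and is programmed as 42).
    Delivered amounts are recomputed as flow x duration x concentration;
    the nominal equal amount is kept alongside.
    """
    if flow_resolution_ml_h <= 0 or duration_resolution_min <= 0:
        raise ValueError("resolutions must be > 0")
    if c_infusion_mg_ml <= 0:
        raise ValueError("c_infusion must be > 0")
    amount = schedule.per_interval_amount_mg
    durations_min = schedule.durations_h * 60.0
    flows = schedule.rates_mg_h / c_infusion_mg_ml
    subs = []
    t_cursor = 0.0
    for i in range(schedule.n):
        d_disp = _round_half_up(durations_min[i], duration_display_precision_min)
        d_q = _round_half_up(d_disp, duration_resolution_min)
        f_q = _round_half_up(flows[i], flow_resolution_ml_h)
        delivered = f_q * (d_q / 60.0) * c_infusion_mg_ml
        subs.append(
            SubInterval(
                index=i + 1,
                t_start_h=t_cursor,
                t_end_h=t_cursor + d_q / 60.0,
                duration_min=d_q,
                flow_ml_h=f_q,
                amount_mg=amount,
                delivered_mg=delivered,
                zero_flow_warning=(f_q == 0.0 and schedule.rates_mg_h[i] > 0),
            )
        )
        t_cursor += d_q / 60.0
    return PumpProgram(
        sub_intervals=tuple(subs),
        c_infusion_mg_ml=c_infusion_mg_ml,
        per_subinterval_volume_ml=amount / c_infusion_mg_ml,
        tau_h=tau_h if tau_h is not None else schedule.t_n_h,
        n_doses_total=n_doses_total,
        dose_per_interval_mg=schedule.dose_mg,
        f_dose=schedule.f_dose,
        cl_elim_l_h=cl_elim_l_h,
        v_diluent_l=v_diluent_l,
    )


def elimination_setup(
    ke: float, v_total: float, exp_duration_h: float
) -> tuple[float, float]:
    """Elimination-pump flow ``CL_elim = ke * V_total`` and the diluent
    volume ``CL_elim * Exp_duration`` needed for the whole experiment."""
    if ke < 0 or v_total <= 0 or exp_duration_h <= 0:
        raise ValueError("ke must be >= 0, v_total and duration > 0")
    cl = ke * v_total
    return cl, cl * exp_duration_h


@dataclass(frozen=True)
class IVDesign:
    """Short-infusion setup reproducing an IV profile."""

    dose_mg: float
    c_infusion_mg_ml: float
    infusion_volume_ml: float
    flow_ml_h: float
    t_infusion_h: float
    cl_elim_l_h: float
    v_diluent_l: float

    def to_infusion_schedule(self) -> InfusionSchedule:
        return InfusionSchedule.single_infusion(self.dose_mg, self.t_infusion_h)


def design_iv(
    target: TargetPK, rig: RigConfig, infusion_volume_ml: float = 5.0
) -> IVDesign:
    """Size the short infusion so the end-of-infusion peak equals ``cmax1``.

    The dose carries the elimination-during-infusion correction
    ``ke*t_inf / (1 - e^(-ke*t_inf))``; without it a 30-min infusion
    undershoots the peak by roughly ``ke*t_inf/2``.
    """
    if target.mode != "iv":
        raise ValueError("design_iv requires a TargetPK in iv mode")
    if infusion_volume_ml <= 0:
        raise ValueError("infusion_volume must be > 0")
    assert target.t_infusion is not None
    v_total = rig.v_total_design_l
    x = target.ke * target.t_infusion
    dose = target.cmax1 * v_total * x / (-math.expm1(-x))
    cl, v_dil = elimination_setup(target.ke, v_total, rig.exp_duration_h)
    return IVDesign(
        dose_mg=dose,
        c_infusion_mg_ml=dose / infusion_volume_ml,
        infusion_volume_ml=infusion_volume_ml,
        flow_ml_h=infusion_volume_ml / target.t_infusion,
        t_infusion_h=target.t_infusion,
        cl_elim_l_h=cl,
        v_diluent_l=v_dil,
    )


def design_absorption(
    target: TargetPK,
    rig: RigConfig,
    n_sub_intervals: int = 12,
    t_n_h: float | None = None,
    target_volume_ml: float = 2.0,
    flow_resolution_ml_h: float = 0.1,
    duration_resolution_min: float = 1.0,
    bioavailability: float = 1.0,
) -> PumpProgram:
    """Full absorption-mode design: dose, schedule, concentration,
    quantization and elimination pump, in one call."""
    if target.mode != "absorption":
        raise ValueError("design_absorption requires a TargetPK in absorption mode")
    assert target.ka is not None
    t_n = target.tau if t_n_h is None else t_n_h
    v_total = rig.v_total_design_l
    dose = compute_dose(target.cmax1, target.ka, target.ke, v_total, bioavailability)
    raw = build_schedule(dose, target.ka, n_sub_intervals, t_n)
    c_inf = select_infusion_concentration(raw, target_volume_ml)
    cl, v_dil = elimination_setup(target.ke, v_total, rig.exp_duration_h)
    return quantize_program(
        raw,
        c_inf,
        flow_resolution_ml_h=flow_resolution_ml_h,
        duration_resolution_min=duration_resolution_min,
        tau_h=target.tau,
        n_doses_total=target.n_doses_total,
        cl_elim_l_h=cl,
        v_diluent_l=v_dil,
    )
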