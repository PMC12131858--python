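"""Closed-form one-compartment pharmacokinetics for HFIM target profiles.

The hollow-fiber rig reproduces one of two target profiles:

* **IV mode** — a zero-order infusion of duration ``t_infusion`` into a
  single well-mixed volume with first-order elimination ``ke``; this mimics
  unbound plasma concentrations after a short intravenous infusion.
* **Absorption mode** — first-order input at rate ``ka`` into the same
  volume; this mimics site-of-action profiles (e.g. CSF) whose rise is slow
  and delayed relative to plasma.

All rate constants are per hour, times in hours, concentrations in mg/L.
Multi-dose profiles are built by superposition of the single-dose solution,
scaled so that the first-dose peak equals the target ``cmax1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TargetPK",
    "DerivedPK",
    "ConcentrationSeries",
    "tmax_first_dose",
    "half_life",
    "n_doses_to_steady_state",
    "accumulation_ratio_iv",
    "derive_secondary",
    "simulate_mono_profile",
    "pk_metrics_from_series",
]

#: relative |ka-ke|/ke below which the equal-rate (flip-flop) limit is used,
#: avoiding catastrophic cancellation in (e^{-ke t} - e^{-ka t})/(ka - ke)
EQUAL_RATE_RTOL = 1e-8


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetPK:
    """Mono-compartmental target profile a rig design is built from.

    Parameters
    ----------
    cmax1:
        Target maximal concentration after the first dose (mg/L).
    ke:
        First-order elimination rate constant (1/h).
    tau:
        Dosing interval (h).
    mode:
        ``"iv"`` (zero-order infusion) or ``"absorption"`` (first-order input).
    ka:
        Absorption rate constant (1/h); required in absorption mode.
    t_infusion:
        Infusion duration (h); required in IV mode.
    n_doses_total:
        Number of doses administered over the experiment.
    """

    cmax1: float
    ke: float
    tau: float
    mode: str
    ka: float | None = None
    t_infusion: float | None = None
    n_doses_total: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("iv", "absorption"):
            raise ValueError(f"mode must be 'iv' or 'absorption', got {self.mode!r}")
        if self.cmax1 <= 0:
            raise ValueError("cmax1 must be > 0")
        if self.ke <= 0:
            raise ValueError("ke must be > 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.n_doses_total < 1:
            raise ValueError("n_doses_total must be >= 1")
        if self.mode == "absorption":
            if self.ka is None or self.ka <= 0:
                raise ValueError("absorption mode requires ka > 0")
        else:
            if self.t_infusion is None or self.t_infusion <= 0:
                raise ValueError("iv mode requires t_infusion > 0")


@dataclass(frozen=True)
class DerivedPK:
    """Secondary parameters derived from a :class:`TargetPK`.

    ``tmax_ss`` is the time of the steady-state peak within a dosing
    interval (h after dose), not an absolute experiment time.
    """

    t_half: float
    tmax1: float
    n_dose_to_ss: int
    rac: float
    cmax_ss: float
    cmin_ss: float
    tmax_ss: float


REQUIRED_COLUMNS = ("time_h", "conc_mg_L", "compartment", "replicate")


@dataclass
class ConcentrationSeries:
    """Time-stamped concentrations per compartment and replicate.

    Thin wrapper over a :class:`pandas.DataFrame` with columns
    ``time_h, conc_mg_L, compartment, replicate``. Times must be strictly
    increasing within each (compartment, replicate) group and concentrations
    non-negative.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        self.data = self.data[list(REQUIRED_COLUMNS)].reset_index(drop=True)
        if (self.data["conc_mg_L"] < 0).any():
            raise ValueError("concentrations must be >= 0")
        for (comp, rep), grp in self.data.groupby(["compartment", "replicate"], sort=False):
            t = grp["time_h"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise ValueError(
                    f"times must be strictly increasing within group ({comp}, {rep})"
                )

    @classmethod
    def from_arrays(
        cls,
        time_h: Sequence[float],
        conc_mg_L: Sequence[float],
        compartment: str | Sequence[str] = "lumped",
        replicate: str | Sequence[str] = "sim",
    ) -> "ConcentrationSeries":
        n = len(time_h)
        comp = [compartment] * n if isinstance(compartment, str) else list(compartment)
        rep = [replicate] * n if isinstance(replicate, str) else list(replicate)
        return cls(
            pd.DataFrame(
                {
                    "time_h": np.asarray(time_h, dtype=float),
                    "conc_mg_L": np.asarray(conc_mg_L, dtype=float),
                    "compartment": comp,
                    "replicate": rep,
                }
            )
        )

    def subset(
        self, compartment: str | None = None, replicate: str | None = None
    ) -> "ConcentrationSeries":
        df = self.data
        if compartment is not None:
            df = df[df["compartment"] == compartment]
        if replicate is not None:
            df = df[df["replicate"] == replicate]
        return ConcentrationSeries(df.reset_index(drop=True))

    @property
    def compartments(self) -> list[str]:
        return list(dict.fromkeys(self.data["compartment"]))

    @property
    def replicates(self) -> list[str]:
        return list(dict.fromkeys(self.data["replicate"]))

    def times(self) -> np.ndarray:
        """Times of a single-group series (raises if more than one group)."""
        self._assert_single_group()
        return self.data["time_h"].to_numpy()

    def concs(self) -> np.ndarray:
        self._assert_single_group()
        return self.data["conc_mg_L"].to_numpy()

    def _assert_single_group(self) -> None:
        if len(self.compartments) > 1 or len(self.replicates) > 1:
            raise ValueError("series holds several groups; use .subset first")

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# secondary-parameter arithmetic
# ---------------------------------------------------------------------------


def tmax_first_dose(ka: float, ke: float) -> float:
    """Time of the first-dose peak of the first-order-absorption model.

    ``t_max,1 = ln(ka/ke) / (ka - ke)``, with the flip-flop limit ``1/ke``
    when ka and ke coincide to within :data:`EQUAL_RATE_RTOL`.
    """
    if ka <= 0 or ke <= 0:
        raise ValueError("rate constants must be > 0")
    if abs(ka - ke) < EQUAL_RATE_RTOL * ke:
        return 1.0 / ke
    return math.log(ka / ke) / (ka - ke)


def half_life(ke: float) -> float:
    """Terminal half-life ln(2)/ke (h)."""
    if ke <= 0:
        raise ValueError("ke must be > 0")
    return math.log(2.0) / ke


def n_doses_to_steady_state(t_half: float, tau: float) -> int:
    """Doses needed to reach ~90% of steady state (3.3 half-lives).

    Smallest integer N >= 1 with N*tau >= 3.3*t_half.
    """
    if t_half <= 0 or tau <= 0:
        raise ValueError("t_half and tau must be > 0")
    x = 3.3 * t_half / tau
    return max(1, math.ceil(x - 1e-9))


def accumulation_ratio_iv(ke: float, tau: float) -> float:
    """Accumulation ratio Cmax,ss / Cmax,1 = 1 / (1 - e^(-ke*tau))."""
    if ke <= 0 or tau <= 0:
        raise ValueError("ke and tau must be > 0")
    return -1.0 / math.expm1(-ke * tau)


def _absorption_unit(t: np.ndarray, ka: float, ke: float) -> np.ndarray:
    """Unscaled single-dose absorption shape, zero before t=0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    if abs(ka - ke) < EQUAL_RATE_RTOL * ke:
        out[pos] = t[pos] * ke * np.exp(-ke * t[pos])
    else:
        out[pos] = np.exp(-ke * t[pos]) - np.exp(-ka * t[pos])
    return out


def _iv_unit(t: np.ndarray, ke: float, t_inf: float) -> np.ndarray:
    """Unscaled single-dose zero-order-infusion shape, zero before t=0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    rising = (t > 0) & (t <= t_inf)
    out[rising] = -np.expm1(-ke * t[rising])
    falling = t > t_inf
    peak = -math.expm1(-ke * t_inf)
    out[falling] = peak * np.exp(-ke * (t[falling] - t_inf))
    return out


def _absorption_ss_tmax(ka: float, ke: float, tau: float) -> float:
    """Within-interval time of the steady-state peak (absorption mode)."""
    if abs(ka - ke) < EQUAL_RATE_RTOL * ke:
        # numeric fallback on a fine grid; the limit case is rare
        t = np.linspace(0, tau, 200001)
        css = _absorption_ss_profile(t, ka, ke, tau)
        return float(t[np.argmax(css)])
    num = ka * (-math.expm1(-ke * tau))
    den = ke * (-math.expm1(-ka * tau))
    return math.log(num / den) / (ka - ke)


def _absorption_ss_profile(t: np.ndarray, ka: float, ke: float, tau: float) -> np.ndarray:
    """Unscaled steady-state profile over one interval (absorption mode)."""
    t = np.asarray(t, dtype=float)
    if abs(ka - ke) < EQUAL_RATE_RTOL * ke:
        # superpose enough doses of the limit shape to converge
        n = max(10, int(math.ceil(33.0 / (ke * tau))))
        out = np.zeros_like(t)
        for d in range(n):
            out += _absorption_unit(t + d * tau, ka, ke)
        return out
    return np.exp(-ke * t) / (-math.expm1(-ke * tau)) - np.exp(-ka * t) / (
        -math.expm1(-ka * tau)
    )


def derive_secondary(target: TargetPK) -> DerivedPK:
    """Secondary parameters (half-life, accumulation, steady-state peaks).

    IV mode uses the repeated-identical-dose closed forms; absorption mode
    maximizes the closed-form steady-state profile within one interval.
    """
    th = half_life(target.ke)
    nss = n_doses_to_steady_state(th, target.tau)
    if target.mode == "iv":
        rac = accumulation_ratio_iv(target.ke, target.tau)
        cmax_ss = target.cmax1 * rac
        assert target.t_infusion is not None
        cmin_ss = cmax_ss * math.exp(-target.ke * (target.tau - target.t_infusion))
        return DerivedPK(
            t_half=th,
            tmax1=target.t_infusion,
            n_dose_to_ss=nss,
            rac=rac,
            cmax_ss=cmax_ss,
            cmin_ss=cmin_ss,
            tmax_ss=target.t_infusion,
        )
    assert target.ka is not None
    tmax1 = tmax_first_dose(target.ka, target.ke)
    scale = target.cmax1 / _absorption_unit(np.array([tmax1]), target.ka, target.ke)[0]
    t_ss = _absorption_ss_tmax(target.ka, target.ke, target.tau)
    css_peak = scale * _absorption_ss_profile(
        np.array([t_ss]), target.ka, target.ke, target.tau
    )[0]
    css_trough = scale * _absorption_ss_profile(
        np.array([target.tau]), target.ka, target.ke, target.tau
    )[0]
    return DerivedPK(
        t_half=th,
        tmax1=tmax1,
        n_dose_to_ss=nss,
        rac=css_peak / target.cmax1,
        cmax_ss=css_peak,
        cmin_ss=css_trough,
        tmax_ss=t_ss,
    )


# ---------------------------------------------------------------------------
# profile simulation and NCA-style metrics
# ---------------------------------------------------------------------------


def simulate_mono_profile(target: TargetPK, grid: Sequence[float]) -> ConcentrationSeries:
    """Multi-dose mono-compartmental profile on ``grid``.

    Superposition of the closed-form single-dose solution, scaled so the
    first-dose peak equals ``target.cmax1`` (exactly, by construction).
    """
    t = np.asarray(grid, dtype=float)
    if t.size == 0:
        raise ValueError("grid must not be empty")
    if target.mode == "absorption":
        assert target.ka is not None
        tmax1 = tmax_first_dose(target.ka, target.ke)
        unit_peak = _absorption_unit(np.array([tmax1]), target.ka, target.ke)[0]
        shape = lambda x: _absorption_unit(x, target.ka, target.ke)  # noqa: E731
    else:
        assert target.t_infusion is not None
        unit_peak = -math.expm1(-target.ke * target.t_infusion)
        shape = lambda x: _iv_unit(x, target.ke, target.t_infusion)  # noqa: E731
    scale = target.cmax1 / unit_peak
    conc = np.zeros_like(t)
    for d in range(target.n_doses_total):
        conc += shape(t - d * target.tau)
    return ConcentrationSeries.from_arrays(t, scale * conc)


def pk_metrics_from_series(
    series: ConcentrationSeries,
    dose_times: Iterable[float],
    tau: float,
    min_terminal_points: int = 3,
) -> pd.DataFrame:
    """Per-dose Cmax/Tmax/Cmin/AUCτ and terminal half-life.

    Cmax/Tmax are taken on the sampling grid (no interpolation, mirroring
    grid-quantized reporting). AUCτ uses the linear-up / log-down trapezoid.
    The terminal half-life comes from a log-linear regression over the
    points after the last interval's peak (positive concentrations,
    at least ``min_terminal_points``); if too few points follow the peak,
    the metric is returned as NaN and flagged ``incomplete``.

    Returns a DataFrame with one row per dose: ``dose_index, t_dose_h,
    cmax, tmax, cmin, auc_tau, t_half, incomplete``.
    """
    t = series.times()
    c = series.concs()
    dose_times = sorted(dose_times)
    rows = []
    for idx, td in enumerate(dose_times):
        sel = (t >= td - 1e-12) & (t < td + tau - 1e-12)
        if not sel.any():
            rows.append(
                dict(dose_index=idx + 1, t_dose_h=td, cmax=np.nan, tmax=np.nan,
                     cmin=np.nan, auc_tau=np.nan, t_half=np.nan, incomplete=True)
            )
            continue
        ti, ci = t[sel], c[sel]
        imax = int(np.argmax(ci))
        incomplete = (ci.size - 1 - imax) < min_terminal_points
        row = dict(
            dose_index=idx + 1,
            t_dose_h=td,
            cmax=float(ci[imax]),
            tmax=float(ti[imax] - td),
            cmin=float(ci.min()),
            auc_tau=_auc_lin_log(ti, ci),
            t_half=np.nan,
            incomplete=bool(incomplete),
        )
        if idx == len(dose_times) - 1:
            post = np.arange(imax + 1, ci.size)
            post = post[ci[post] > 0]
            if post.size >= min_terminal_points:
                slope = np.polyfit(ti[post], np.log(ci[post]), 1)[0]
                if slope < 0:
                    row["t_half"] = float(math.log(2.0) / -slope)
        rows.append(row)
    return pd.DataFrame(rows)


def _auc_lin_log(t: np.ndarray, c: np.ndarray) -> float:
    """Linear-up/log-down trapezoidal AUC over the given samples."""
    if t.size < 2:
        return float("nan")
    dt = np.diff(t)
    c0, c1 = c[:-1], c[1:]
    lin = (c0 + c1) / 2.0 * dt
    down = (c1 < c0) & (c1 > 0) & (c0 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_seg = (c0 - c1) / np.log(c0 / c1) * dt
    seg = np.where(down, log_seg, lin)
    return float(seg.sum())
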