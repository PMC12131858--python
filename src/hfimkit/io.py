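"""Configuration files and on-disk formats.

Two CSV dialects (comma separator, decimal point, header mandatory):

* concentration series — ``time_h,conc_mg_L,compartment,replicate``;
* pump program — a ``#`` key=value header block (infusion concentration,
  dosing interval, dose counts, elimination-pump settings) followed by
  ``sub_interval,duration_min,flow_mL_h,amount_mg`` rows, one per
  sub-interval, with the nominal equal amount per sub-interval.

Study configs are YAML validated by pydantic with ``extra="forbid"`` so
typos fail loudly rather than being ignored.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .design import PumpProgram, RigConfig, SubInterval
from .pk import REQUIRED_COLUMNS, ConcentrationSeries, TargetPK

__all__ = [
    "RegimenConfig",
    "RigFileConfig",
    "StudyConfig",
    "load_config",
    "export_pump_program",
    "read_pump_program",
    "read_concentrations",
    "write_concentrations",
]

log = logging.getLogger("hfimkit")


class RegimenConfig(BaseModel):
    """One named dosing regimen of a study."""

    model_config = ConfigDict(extra="forbid")

    label: str
    mode: Literal["iv", "absorption"]
    cmax1_mg_L: float = Field(gt=0)
    ke_per_h: float = Field(gt=0)
    tau_h: float = Field(gt=0)
    n_doses_total: int = Field(ge=1, default=1)
    ka_per_h: float | None = Field(default=None, gt=0)
    t_infusion_h: float | None = Field(default=None, gt=0)
    n_sub_intervals: int | None = Field(default=None, ge=2)
    t_n_h: float | None = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _mode_fields(self) -> "RegimenConfig":
        if self.mode == "absorption" and self.ka_per_h is None:
            raise ValueError(f"regimen {self.label!r}: absorption mode requires ka_per_h")
        if self.mode == "iv" and self.t_infusion_h is None:
            raise ValueError(f"regimen {self.label!r}: iv mode requires t_infusion_h")
        return self

    def to_target(self) -> TargetPK:
        return TargetPK(
            cmax1=self.cmax1_mg_L,
            ke=self.ke_per_h,
            tau=self.tau_h,
            mode=self.mode,
            ka=self.ka_per_h,
            t_infusion=self.t_infusion_h,
            n_doses_total=self.n_doses_total,
        )


class RigFileConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    v_central_L: float = Field(gt=0, default=0.300)
    v_cartridge_L: float = Field(gt=0, default=0.078)
    f_ics: float = Field(ge=0, lt=1, default=0.018 / 0.078)
    q_cartridge_L_h: float = Field(ge=0, default=3.6)
    cl_elim_L_h: float = Field(ge=0, default=0.0828)
    q_diffusion_L_h: float = Field(ge=0, default=0.387)
    exp_duration_h: float = Field(gt=0, default=96.0)

    def to_rig(self) -> RigConfig:
        return RigConfig(
            v_central_l=self.v_central_L,
            v_cartridge_l=self.v_cartridge_L,
            f_ics=self.f_ics,
            q_cartridge_l_h=self.q_cartridge_L_h,
            cl_elim_l_h=self.cl_elim_L_h,
            q_diffusion_l_h=self.q_diffusion_L_h,
            exp_duration_h=self.exp_duration_h,
        )


class StudyConfig(BaseModel):
    """Validated study description: regimens, rig and run defaults."""

    model_config = ConfigDict(extra="forbid")

    regimens: list[RegimenConfig]
    rig: RigFileConfig = RigFileConfig()
    seed: int = 0
    grid_step_h: float = Field(gt=0, default=0.01)
    flow_resolution_mL_h: float = Field(gt=0, default=0.1)
    duration_resolution_min: float = Field(gt=0, default=1.0)
    target_subinterval_volume_mL: float = Field(gt=0, default=2.0)
    output_dir: str = "hfim_out"

    @model_validator(mode="after")
    def _unique_labels(self) -> "StudyConfig":
        labels = [r.label for r in self.regimens]
        if len(set(labels)) != len(labels):
            raise ValueError("regimen labels must be unique")
        return self


def load_config(path: str | Path) -> StudyConfig:
    """Load and validate a YAML study config; unknown keys are errors.

    The fully resolved parameter set (defaults included) is echoed to the
    ``hfimkit`` logger.
    """
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raise ValueError(f"{path}: empty config")
    cfg = StudyConfig.model_validate(raw)
    log.info("loaded config %s: %s", path, cfg.model_dump())
    return cfg


# ---------------------------------------------------------------------------
# pump-program CSV
# ---------------------------------------------------------------------------

_NUM = "{:.10g}".format


def export_pump_program(program: PumpProgram, path: str | Path) -> None:
    """Write a pump program: ``#`` header block then one row per
    sub-interval. Deterministic formatting, so write-read-write is
    byte-identical."""
    path = Path(path)
    lines = [
        f"# c_infusion_mg_mL={_NUM(program.c_infusion_mg_ml)}",
        f"# tau_h={_NUM(program.tau_h)}",
        f"# n_doses={program.n_doses_total}",
        f"# dose_per_interval_mg={_NUM(program.dose_per_interval_mg)}",
        f"# f_dose={_NUM(program.f_dose)}",
        f"# cl_elim_L_h={_NUM(program.cl_elim_l_h)}",
        f"# v_diluent_L={_NUM(program.v_diluent_l)}",
        "sub_interval,duration_min,flow_mL_h,amount_mg",
    ]
    for s in program.sub_intervals:
        lines.append(
            f"{s.index},{_NUM(s.duration_min)},{_NUM(s.flow_ml_h)},{s.amount_mg:.3f}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_pump_program(path: str | Path) -> PumpProgram:
    """Read a pump program written by :func:`export_pump_program`."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[tuple[int, float, float, float]] = []
    saw_columns = False
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            try:
                key, val = line[1:].split("=", 1)
            except ValueError:
                raise ValueError(f"{path}:{ln}: malformed header line") from None
            header[key.strip()] = float(val)
            continue
        if not saw_columns:
            if line != "sub_interval,duration_min,flow_mL_h,amount_mg":
                raise ValueError(f"{path}:{ln}: unexpected column header")
            saw_columns = True
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise ValueError(f"{path}:{ln}: expected 4 fields, got {len(parts)}")
        try:
            rows.append((int(parts[0]), float(parts[1]), float(parts[2]), float(parts[3])))
        except ValueError:
            raise ValueError(f"{path}:{ln}: unparseable numeric field") from None
    if not saw_columns or not rows:
        raise ValueError(f"{path}: no sub-interval rows found")
    c_inf = header["c_infusion_mg_mL"]
    subs = []
    t = 0.0
    for idx, dur, flow, amount in rows:
        subs.append(
            SubInterval(
                index=idx,
                t_start_h=t,
                t_end_h=t + dur / 60.0,
                duration_min=dur,
                flow_ml_h=flow,
                amount_mg=amount,
                delivered_mg=flow * (dur / 60.0) * c_inf,
                zero_flow_warning=(flow == 0.0 and amount > 0),
            )
        )
        t += dur / 60.0
    return PumpProgram(
        sub_intervals=tuple(subs),
        c_infusion_mg_ml=c_inf,
        per_subinterval_volume_ml=rows[0][3] / c_inf if c_inf else float("nan"),
        tau_h=header["tau_h"],
        n_doses_total=int(header["n_doses"]),
        dose_per_interval_mg=header["dose_per_interval_mg"],
        f_dose=header["f_dose"],
        cl_elim_l_h=header.get("cl_elim_L_h", 0.0),
        v_diluent_l=header.get("v_diluent_L", 0.0),
    )


# ---------------------------------------------------------------------------
# concentration CSV
# ---------------------------------------------------------------------------


def read_concentrations(path: str | Path) -> ConcentrationSeries:
    """Read a concentration-series CSV; an empty (header-only) file yields
    an empty series with a warning."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        log.warning("%s: empty concentration series", path)
    df["replicate"] = df["replicate"].astype(str)
    return ConcentrationSeries(df)


def write_concentrations(series: ConcentrationSeries, path: str | Path) -> None:
    series.data.to_csv(path, index=False)
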