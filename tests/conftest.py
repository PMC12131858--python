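import numpy as np
import pytest

from hfimkit import (
    RigConfig,
    TargetPK,
    design_absorption,
    design_iv,
)


@pytest.fixture(scope="session")
def rig() -> RigConfig:
    """Reference rig: 300 mL reservoir, 78 mL cartridge (18 mL fiber lumen),
    60 mL/min loop, elimination 0.0828 L/h, 96 h experiment."""
    return RigConfig()


@pytest.fixture(scope="session")
def csf_target() -> TargetPK:
    """CSF-like absorption target: 600 mg q12h regimen approximation."""
    return TargetPK(
        cmax1=4.25, ke=0.230, tau=12.0, mode="absorption", ka=0.300, n_doses_total=8
    )


@pytest.fixture(scope="session")
def plasma_target() -> TargetPK:
    """Plasma-like IV target: 600 mg q12h, 30-min infusion."""
    return TargetPK(
        cmax1=10.7, ke=0.230, tau=12.0, mode="iv", t_infusion=0.5, n_doses_total=8
    )


@pytest.fixture(scope="session")
def csf_program(csf_target, rig):
    """Quantized 12-sub-interval pump program for the CSF target."""
    return design_absorption(csf_target, rig, n_sub_intervals=12)


@pytest.fixture(scope="session")
def iv_design(plasma_target, rig):
    return design_iv(plasma_target, rig, infusion_volume_ml=5.0)


@pytest.fixture(scope="session")
def fine_grid():
    return np.arange(0.0, 12.0001, 0.01)
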