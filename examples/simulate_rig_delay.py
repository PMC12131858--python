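"""Simulate the physical rig and measure the central-vs-ECS delay.

The cartridge ECS — where the bacteria live — equilibrates with the
central reservoir through the fiber membrane (Q_diffusion ~ 0.387 L/h).
After a 30-min infusion the ECS peak is visibly delayed and attenuated;
under the slow absorption program it is not.
"""

import numpy as np

from hfimkit import (
    RigConfig, TargetPK, central_vs_ecs_metrics, design_absorption, design_iv,
    simulate_rig,
)

rig = RigConfig()
q_diff = rig.q_diffusion_l_h

# 30-min IV infusion, 4 doses q12h
iv = design_iv(TargetPK(cmax1=10.7, ke=0.230, tau=12.0, mode="iv",
                        t_infusion=0.5), rig)
sched = iv.to_infusion_schedule().repeated(12.0, 4)
grid = np.arange(0.0, 48.001, 0.01)
res = simulate_rig(rig, q_diff, sched, grid)
m = central_vs_ecs_metrics(res.series, [0.0, 12.0, 24.0, 36.0], 12.0)
print("IV mode (30-min infusion), per dose:")
print(m.to_string(index=False, float_format="%.3f"))
print(f"mass-balance error {res.mass_balance_error():.2e} (relative)")
print()

# absorption program, 3 doses q12h
target = TargetPK(cmax1=4.25, ke=0.230, tau=12.0, mode="absorption", ka=0.300)
program = design_absorption(target, rig, n_sub_intervals=12)
sched_abs = program.to_infusion_schedule().repeated(12.0, 3)
res_abs = simulate_rig(rig, q_diff, sched_abs, np.arange(0.0, 36.001, 0.01))
m_abs = central_vs_ecs_metrics(res_abs.series, [0.0, 12.0, 24.0], 12.0,
                               snap_h=0.25)
print("absorption mode (pump program), per dose, Tmax on 0.25 h grid:")
print(m_abs.to_string(index=False, float_format="%.3f"))
print()
print("dtmax_h > 0: the ECS peak lags the central reservoir; cmax_ratio < 1:")
print("the lag costs peak height; auc_ratio ~ 1: exposure is preserved.")
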