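"""Estimate the membrane diffusion flow from (synthetic) observations.

A synthetic experiment is generated at a known Q_diffusion with 10%
proportional assay noise, the tri-compartment model is refit with all
rig parameters fixed, and the fit is validated by the 90% prediction
interval rule.
"""

import numpy as np

from hfimkit import (
    RigConfig, TargetPK, design_iv, fit_qdiffusion,
    generate_synthetic_observations, prediction_interval_check,
)

rig = RigConfig()
Q_TRUE = 0.387  # L/h

iv = design_iv(TargetPK(cmax1=10.7, ke=0.230, tau=12.0, mode="iv",
                        t_infusion=0.5), rig)
sched = iv.to_infusion_schedule()
# dense early samples resolve the ECS rise (time constant ~9 min)
times = np.concatenate([np.arange(0.05, 1.51, 0.05), np.arange(2.0, 12.1, 1.0)])
obs = generate_synthetic_observations(
    rig, Q_TRUE, sched, times, sd_proportional=0.10, n_replicates=2, seed=1,
)

fit = fit_qdiffusion(obs, rig, sched)
coverage, ok = prediction_interval_check(fit, obs, n_sims=1000, seed=2)

print(f"true Q_diffusion      {Q_TRUE:.3f} L/h ({Q_TRUE*1000/60:.2f} mL/min)")
print(f"estimated             {fit.q_diffusion_l_h:.3f} L/h "
      f"(SE {fit.se_l_h:.3f}), converged={fit.converged}")
print(f"residual error        prop {fit.sd_proportional:.3f}, "
      f"add {fit.sd_additive:.3g} mg/L")
print(f"90% PI coverage       {coverage:.3f} -> {'PASS' if ok else 'FAIL'} "
      f"(rule: >= 0.90 of observations inside the band)")
print()
print("For well-calibrated data the coverage fluctuates around 0.90, so the")
print("hard >= 0.90 rule fails about half the time by Monte-Carlo chance; a")
print("clear misfit drives the coverage far below 0.90 instead.")
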