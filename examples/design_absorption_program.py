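"""Design an ambulatory-pump program that mimics first-order absorption.

A CSF-like linezolid target (Cmax,1 = 4.25 mg/L, ka = 0.300/h,
ke = 0.230/h, q12h) is converted into 12 equal-amount sub-interval
infusions for a 0.360 L rig. Each row is one pump step: durations grow
and flow rates shrink so that the cumulative amount delivered tracks
Dose*(1 - e^(-ka*t)).
"""

from hfimkit import RigConfig, TargetPK, design_absorption

rig = RigConfig()
target = TargetPK(cmax1=4.25, ke=0.230, tau=12.0, mode="absorption", ka=0.300,
                  n_doses_total=8)
program = design_absorption(target, rig, n_sub_intervals=12)

print(f"design volume      {rig.v_total_design_l:.3f} L")
print(f"nominal dose       {program.dose_per_interval_mg:.3f} mg per interval")
print(f"delivered fraction {program.f_dose:.1%} (rest falls past the interval)")
print(f"infusion solution  {program.c_infusion_mg_ml:.4f} mg/mL "
      f"({program.per_subinterval_volume_ml:.1f} mL per sub-interval)")
print(f"elimination pump   {program.cl_elim_l_h:.4f} L/h, "
      f"{program.v_diluent_l:.2f} L diluent for {rig.exp_duration_h:.0f} h")
print()
print("sub  duration(min)  flow(mL/h)  amount(mg)")
for s in program.sub_intervals:
    print(f"{s.index:>3}  {s.duration_min:>12.0f}  {s.flow_ml_h:>10.1f}  "
          f"{s.amount_mg:>10.3f}")
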