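"""Secondary PK parameters of the target profiles.

For each dosing regimen the design needs the terminal half-life, the
number of doses to ~90% of steady state (3.3 half-lives), the
accumulation ratio Cmax,ss/Cmax,1 and the steady-state peak/trough.
"""

from hfimkit import TargetPK, derive_secondary

regimens = {
    "plasma 600 q12h (IV)": TargetPK(cmax1=10.7, ke=0.230, tau=12.0, mode="iv",
                                     t_infusion=0.5),
    "plasma 900 q8h (IV)": TargetPK(cmax1=16.1, ke=0.230, tau=8.0, mode="iv",
                                    t_infusion=0.5),
    "CSF 600 q12h (absorption)": TargetPK(cmax1=4.25, ke=0.230, tau=12.0,
                                          mode="absorption", ka=0.300),
    "CSF 900 q8h (absorption)": TargetPK(cmax1=6.38, ke=0.190, tau=8.0,
                                         mode="absorption", ka=0.300),
}

print(f"{'regimen':<28}{'t1/2':>6}{'Ndose':>6}{'Rac':>6}{'Tmax1':>7}"
      f"{'Cmax,ss':>9}{'Cmin,ss':>9}")
for name, target in regimens.items():
    d = derive_secondary(target)
    print(f"{name:<28}{d.t_half:>6.2f}{d.n_dose_to_ss:>6}{d.rac:>6.2f}"
          f"{d.tmax1:>7.2f}{d.cmax_ss:>9.2f}{d.cmin_ss:>9.2f}")
print()
print("t1/2 and Tmax1 in h; Cmax/Cmin in mg/L. Rac > 1 means the profile")
print("accumulates dose-to-dose; Ndose doses are needed before sampling at")
print("steady state makes sense.")
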