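k0_s: 0.0003
k_s: 2.2
K_I: 0.6
n_I: 2.0
K_SS: 4.0
n_SS: 2.0
g_s: 0.6
k_S: 1.0
K_34: 0.6
n_34: 2.0
g_S: 0.3
k0_34: 0.001
k_34: 0.35
K_S34: 0.7
n_S34: 4.0
K_Z34: 1.0
n_Z34: 2.0
g_34: 0.15
k0_z: 0.003
k_z: 0.25
K_Sz: 3.0
n_Sz: 3.0
k_zZ: 0.3
K_Zz: 0.4
n_Zz: 2.0
g_z: 0.6
kon: 2.0
koff: 0.8
gc:
- 0.3
- 0.35
- 0.4
- 0.45
- 0.5
lam:
- 0.9
- 0.9
- 0.9
- 0.9
- 0.9
l_trans:
- 0.4
- 0.1
- 0.01
- 0.0
- 0.0
k_Z: 2.0
g_Z: 0.3
k0_m: 0.15
k_m: 0.1
K_Zm: 0.6
n_Zm: 3.0
K_Sm: 3.0
n_Sm: 2.0
g_m: 0.01
k_f: 3.0
mode_Sf: act
leak_Sf: 0.05
K_Sf: 2.0
n_Sf: 2.0
mode_Zf: rep
leak_Zf: 0.1
K_Zf: 3.0
n_Zf: 2.0
kon_f: 0.1
koff_f: 0.05
g_f: 0.05
g_cf: 0.05
lam_f: 0.5
k_d: 0.0
g_d: 0.05
kon_d: 0.1
koff_d: 0.05
g_cd: 0.05
lam_d: 0.5
zeb1_lo: 0.3
zeb1_hi: 1.0
mir200_lo: 0.5
mir200_hi: 2.0
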