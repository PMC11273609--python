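# Per-element parameters used across the package.
# mass_amu        : atomic mass
# charge_default_e: partial charge assumed when no companion charge table is given
# rmin_half_A     : Lennard-Jones Rmin/2 (Lorentz-Berthelot: Rmin_ij = rmin_half_i + rmin_half_j)
# epsilon_kJ_mol  : Lennard-Jones well depth
element	mass_amu	charge_default_e	rmin_half_A	epsilon_kJ_mol
H	1.008	0.0	0.90	0.192
C	12.011	0.0	2.00	0.293
N	14.007	0.0	1.85	0.837
O	15.999	0.0	1.70	0.502
S	32.060	0.0	2.00	1.883
P	30.974	0.0	2.15	2.448
FE	55.845	0.0	0.65	0.042
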