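# EMT6/Ro mouse mammary carcinoma spheroid parameter profile.
# Units: concentrations in mM (= mol/m^3), diffusivities in m^2/s,
# consumption rates in mol/m^3/s, A in 1/h, Ap and An in 1/s.

[nutrient.glucose]
D_tissue = 4.22e-11
D_medium = 9.27e-10
Vmax = 4.36e-2
Km = 4.0e-2
C_crit = 0.06
C_bulk = 0.8

[nutrient.oxygen]
D_tissue = 1.65e-9
D_medium = 2.6e-9
Vmax = 2.74e-2
Km = 4.64e-3
C_crit = 0.02
C_bulk = 0.28

[kinetics]
A = 3.3e-2       # proliferation, 1/h (doubling time 21 h)
Ap = 1.2153e-9   # apoptosis, 1/s
An = 2e-6        # necrosis, 1/s

[fluid]
density = 993.3     # kg/m^3, water at 37 C
viscosity = 6.92e-4 # Pa s, water at 37 C
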