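# Thermophysical constants for common TRXL solvents (nominal literature
# values near 25 C; adequate for signal-level planning, not calorimetry).
# columns: name  composition  density_g_mL  molar_mass_g_mol  Cv_J_mol_K  Cp_J_mol_K  alpha_p_per_K
cyclohexane           C:6,H:12     0.7739   84.161  118.0  156.0  1.15e-3
acetonitrile          C:2,H:3,N:1  0.7857   41.053   71.0   91.7  1.37e-3
methanol              C:1,H:4,O:1  0.7914   32.042   68.0   81.1  1.49e-3
ethanol               C:2,H:6,O:1  0.7893   46.068   95.0  112.3  1.09e-3
dichloromethane       C:1,H:2,Cl:2 1.3266   84.933   80.0  101.2  1.39e-3
chloroform            C:1,H:1,Cl:3 1.4788  119.378   90.0  114.2  1.21e-3
carbon_tetrachloride  C:1,Cl:4     1.5940  153.823  105.0  131.3  1.14e-3
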