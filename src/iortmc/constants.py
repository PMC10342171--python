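"""Physical constants and water medium defaults (CODATA / standard dosimetry values)."""

AVOGADRO = 6.02214076e23          # 1/mol
WATER_MOLAR_MASS = 18.015         # g/mol
WATER_DENSITY = 1.0               # g/cm^3
WATER_NUMBER_DENSITY = WATER_DENSITY * AVOGADRO / WATER_MOLAR_MASS  # molecules/cm^3

ELECTRON_MASS_U = 5.48579909e-4   # electron mass in unified atomic mass units
ELECTRON_MC2_MEV = 0.51099895     # electron rest energy
CLASSICAL_E_RADIUS_CM = 2.8179403262e-13

EV_PER_MEV = 1.0e6
JOULE_PER_MEV = 1.602176634e-13
JOULE_PER_EV = 1.602176634e-19

# Dosimetric water parameters
WATER_MEAN_EXCITATION_EV = 75.0   # mean excitation energy I for stopping power
WATER_ZA = 0.55509                # Z/A
WATER_RADIATION_LENGTH_CM = 36.08 # radiation length (g/cm^2 == cm at unit density)
WATER_Z_EFF = 7.42

# Track-structure energy bookkeeping
IP_LIQUID_EV = 10.79              # extrapolated liquid-water ionization potential
IP_GAS_EV = 12.8                  # gas-phase ionization threshold
KSHELL_BINDING_EV = 540.0
THERMAL_CUTOFF_EV = 0.025         # electrons below this are thermalized
ROT_LOSS_EV = 0.015               # constant rotational energy loss used in transport
ROT_AVG_300K_EV = 0.012           # average rotational excitation energy at 300 K (metadata)
VIB_THRESHOLD_EV = 0.2
EXC_THRESHOLD_EV = 4.5
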