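"""Physical constants used at unit boundaries (CODATA 2018)."""

BOHR_ANGSTROM = 0.529177210903  # 1 bohr in Angstrom
KBOLTZ_EV = 8.617333262e-5      # Boltzmann constant in eV / K
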