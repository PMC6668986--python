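"""Physical constants shared across the quantification chain."""

# 1 barn = 1e-28 m^2 = 1e-10 nm^2
BARN_TO_NM2 = 1e-10

# Fe L-edge partial ionization cross section used for areal-density
# normalization, integrated up to 780 eV (barns per atom).
FE_CROSS_SECTION_BARNS = 2664.9

# Default Fe L3 edge onset (eV); the quantification window runs from
# here up to the 780 eV integration limit.
FE_L3_ONSET_EV = 708.0

# Upper integration limit of the Fe L edge window (eV).
FE_L_INTEGRATION_UPPER_EV = 780.0
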