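# temperature_K: 348.15
metabolite	mu0_kJ_mol	dg_kJ_mol
hv	68.6	0.0
H2O	-470.2	0.0
GLC	-600.0	20.0
CO2	-178.6	20.0
NO3	-110.0	20.0
NH3	-30.0	20.0
Pi	120.5	20.0
Ac	-50.0	20.0
GLYC	-100.0	20.0
SO4	-30.0	20.0
H2S	5.0	20.0
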