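# strain: SYN
[METABOLITES]
id	name	compartment	external	mu0	conc_lo	conc_hi
hv	photon		1			
CO2	carbon dioxide		1			
NO3	nitrate		1			
Pi	phosphate		1			
NH3	ammonia		1			
Ac	acetate		1			
GLYC	glycolate		1			
CFIX	fixed carbon pool		0			

[REACTIONS]
id	formula	lb	ub	kind	objective
EX_hv	1.0 hv -> 	-1000.0	0.0	exchange	0.0
EX_CO2	1.0 CO2 -> 	-1000.0	0.0	exchange	0.0
EX_NO3	1.0 NO3 -> 	-1000.0	0.0	exchange	0.0
EX_Pi	1.0 Pi -> 	-1.0	0.0	exchange	0.0
EX_NH3	1.0 NH3 -> 	0.0	1000.0	exchange	0.0
EX_Ac	1.0 Ac -> 	0.0	1000.0	exchange	0.0
EX_GLYC	1.0 GLYC -> 	0.0	1000.0	exchange	0.0
RIBULOSE-BISPHOSPHATE-CARBOXYLASE-RXN	1.0 hv + 1.0 CO2 -> 1.0 CFIX	0.0	1000.0	internal	0.0
RXN-961	1.0 hv + 1.0 CO2 -> 1.0 GLYC	0.0	1000.0	internal	0.0
NITRATE-REDUCTION	1.0 NO3 -> 1.0 NH3	0.0	1000.0	internal	0.0
ACETATE-SYNTHESIS	1.0 CFIX -> 1.0 Ac	0.0	1000.0	internal	0.0
BIOMASS_SYN	0.1 CFIX + 0.9652421652421652 NH3 + 1.0 Pi + 0.31662962962962965 hv -> 	0.0	1000.0	biomass	1.0
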