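# strain: FAP
[METABOLITES]
id	name	compartment	external	mu0	conc_lo	conc_hi
hv	photon		1			
Ac	acetate		1			
NH3	ammonia		1			
Pi	phosphate		1			

[REACTIONS]
id	formula	lb	ub	kind	objective
EX_hv	1.0 hv -> 	-1000.0	0.0	exchange	0.0
EX_Ac	1.0 Ac -> 	-1000.0	0.0	exchange	0.0
EX_NH3	1.0 NH3 -> 	-1000.0	0.0	exchange	0.0
EX_Pi	1.0 Pi -> 	-1.0	0.0	exchange	0.0
BIOMASS_FAP	0.3 Ac + 1.0 NH3 + 1.0 Pi + 0.47469565217391313 hv -> 	0.0	1000.0	biomass	1.0
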