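# strain: SRB
[METABOLITES]
id	name	compartment	external	mu0	conc_lo	conc_hi
Ac	acetate		1			
NH3	ammonia		1			
Pi	phosphate		1			
SO4	sulfate		1			
H2S	hydrogen sulfide		1			

[REACTIONS]
id	formula	lb	ub	kind	objective
EX_Ac	1.0 Ac -> 	-1000.0	0.0	exchange	0.0
EX_NH3	1.0 NH3 -> 	-1000.0	0.0	exchange	0.0
EX_Pi	1.0 Pi -> 	-1000.0	0.0	exchange	0.0
EX_SO4	1.0 SO4 -> 	-1.0	0.0	exchange	0.0
EX_H2S	1.0 H2S -> 	0.0	1000.0	exchange	0.0
BIOMASS_SRB	1.0 Ac + 0.8307692307692308 NH3 + 0.8202247191011236 Pi + 1.0 SO4 -> 1.0 H2S	0.0	1000.0	biomass	1.0
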