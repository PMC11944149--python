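# Measured growth parameters of an E. coli wildtype and six adaptively
# evolved strains (glucose minimal medium, 37 C), with the fitted
# attained-fraction b and Lagrange constant c of the mode-usage distribution.
# mu: specific growth rate [1/h]; qs: specific glucose uptake [mmol/h.gCDW],
# positive magnitude; yield_bg: biomass yield on glucose [g/g].
strain	mu	qs	yield_bg	b	c
WT	0.670	8.46	0.444	0.30410	-1.44
ALE-1	0.886	11.57	0.425	0.42324	-1.55
ALE-2	0.869	10.79	0.447	0.39574	-1.57
ALE-3	0.891	11.97	0.414	0.41514	-1.20
ALE-4	0.819	10.29	0.442	0.36869	-1.42
ALE-5	0.934	11.82	0.439	0.40408	-1.11
ALE-6	0.936	12.46	0.417	0.34908	0.35
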