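# Experimental gas-phase heats of formation of atomic species at 298.15 K
# (kcal/mol), standard thermochemical compilation values. Editable.
element,dhf_exp_kcal
H,52.102
C,171.29
N,113.00
O,59.56
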