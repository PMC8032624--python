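# BCP-glucuronide, the urinary conjugate of BCP.
# A polar, strongly acidic conjugate: essentially confined to body water,
# weakly protein-bound.  Package estimates; override as needed.
name: bcp_glucuronide
molecular_weight: 383.62   # g/mol
logKow: 0.5
pKa: 3.2
ionization: acid
fup: 0.9
blood_plasma_ratio: 1.0
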